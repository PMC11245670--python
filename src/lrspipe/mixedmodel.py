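"""Hierarchical linear mixed models, stepwise selection and validation.

The outcome (offspring LRS) is modelled with random intercepts at farm
and dam level (3-level: calf within dam within farm) or dam level only
(2-level, single-herd data):

    y_ijk = b0 + B x_ijk + f_k + u_jk + e_ijk,
    f_k ~ N(0, s2_farm),  u_jk ~ N(0, s2_dam),  e_ijk ~ N(0, s2_resid)

fitted by maximum likelihood via statsmodels MixedLM.  Fixed effects
enter through a forward stepwise search: at each step every remaining
candidate is refitted against the growing model and the candidate with
the smallest joint Wald P-value below the entry threshold (default
0.05) is added; within a min/median/max subgroup of a milk variable at
most one member may enter.  Polynomial terms (to degree 3) of selected
continuous predictors are then tested, and declared interactions are
accepted when significant and AIC-improving.  Model fit is summarised
by marginal and conditional variance-explained (fixed effects alone vs
fixed plus random) and by leave-one-group-out cross-validation in
which predictions for the held-out farm use fixed effects only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "ModelFit", "fit_lmm", "forward_select", "variance_explained",
    "loocv_by_group", "spearman_matrix",
]


@dataclass
class ModelFit:
    """A fitted mixed model with term-level Wald summaries."""
    formula: str
    terms: list
    result: object                      # statsmodels MixedLMResults
    grouping: tuple
    converged: bool = True
    term_pvalues: dict = field(default_factory=dict)

    @property
    def params(self):
        return self.result.fe_params

    def conf_int(self):
        ci = self.result.conf_int()
        return ci.loc[self.result.fe_params.index]

    @property
    def variance_components(self) -> dict:
        res = self.result
        out = {"resid": float(res.scale)}
        if len(self.grouping) == 2:
            out["farm"] = float(np.asarray(res.cov_re)[0, 0])
            out["dam"] = float(res.vcomp[0]) if len(res.vcomp) else 0.0
        else:
            out["dam"] = float(np.asarray(res.cov_re)[0, 0])
        return out

    @property
    def llf(self) -> float:
        return float(self.result.llf)

    @property
    def aic(self) -> float:
        # ML AIC over all estimated parameters (fixed + variance)
        k = len(self.result.fe_params) + len(self.result.vcomp) + 1 \
            + self.result.k_re ** 2 // 1
        return float(-2.0 * self.result.llf + 2.0 * k)


def _prepare(df: pd.DataFrame, grouping) -> pd.DataFrame:
    """Recode the dam label within farm so the VC design stays small.

    Dams are nested in farms, so reusing dam codes across farms is
    statistically equivalent and keeps the variance-component design at
    (dams per farm) columns instead of (total dams).
    """
    data = df.copy()
    if len(grouping) == 2:
        farm_col, dam_col = grouping
        data["_dam_code"] = (
            data.groupby(farm_col, sort=True)[dam_col]
            .transform(lambda s: pd.factorize(s, sort=True)[0]))
    return data


def fit_lmm(df: pd.DataFrame, outcome: str, fixed_terms: list,
            grouping=("farm_id", "dam_id")) -> ModelFit:
    """ML fit of the mixed model with the given fixed-effect terms.

    ``grouping`` is (farm, dam) for the 3-level model or (dam,) for the
    2-level one.  Aliased (rank-deficient) fixed columns are dropped by
    the underlying least-squares start values; a singular variance
    component is reported as 0.  Returns a ModelFit with joint Wald
    P-values per term (chi-square across all of a categorical term's
    columns).
    """
    grouping = tuple(grouping)
    data = _prepare(df, grouping)
    rhs = " + ".join(fixed_terms) if fixed_terms else "1"
    formula = f"{outcome} ~ {rhs}"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if len(grouping) == 2:
            model = smf.mixedlm(formula, data, groups=grouping[0],
                                re_formula="1",
                                vc_formula={"dam": "0 + C(_dam_code)"},
                                missing="drop")
        else:
            model = smf.mixedlm(formula, data, groups=grouping[0],
                                re_formula="1", missing="drop")
        # Powell is robust but can stop short of the optimum on small
        # samples; polishing with gradient methods from its solution
        # reproduces lme4's ML optimum (checked in the test suite).
        result = model.fit(reml=False, method="powell", maxiter=1000)
        converged = bool(result.converged)
        for method in ("lbfgs", "cg"):
            try:
                polished = model.fit(reml=False, method=method,
                                     start_params=result.params_object,
                                     maxiter=1000)
            except Exception:
                continue
            if polished.llf > result.llf:
                result = polished
                converged = converged or bool(polished.converged)
    fit = ModelFit(formula=formula, terms=list(fixed_terms), result=result,
                   grouping=grouping, converged=converged)
    fit.term_pvalues = _term_wald_pvalues(fit)
    return fit


def _term_wald_pvalues(fit: ModelFit) -> dict:
    """Joint Wald chi-square P-value for each fixed-effect model term."""
    res = fit.result
    design_info = res.model.data.design_info
    fe_names = list(res.fe_params.index)
    cov = res.cov_params().loc[fe_names, fe_names].to_numpy()
    beta = res.fe_params.to_numpy()
    out = {}
    for term in design_info.terms:
        name = term.name()
        if name == "Intercept":
            continue
        sl = design_info.term_name_slices[name]
        cols = [i for i in range(*sl.indices(len(fe_names)))]
        b = beta[cols]
        V = cov[np.ix_(cols, cols)]
        try:
            w = float(b @ np.linalg.solve(V, b))
            out[name] = float(stats.chi2.sf(w, df=len(cols)))
        except np.linalg.LinAlgError:
            out[name] = np.nan
    return out


def forward_select(df: pd.DataFrame, outcome: str, candidates: list,
                   grouping=("farm_id", "dam_id"), threshold: float = 0.05,
                   subgroups: dict | None = None, poly_degree: int = 3,
                   continuous: list | None = None,
                   interactions: list | None = None
                   ) -> tuple[ModelFit, pd.DataFrame]:
    """Forward stepwise selection by smallest Wald P below the threshold.

    ``subgroups`` maps a name to the candidate terms forming a
    min/median/max triplet; once one member enters, the others are
    withdrawn.  Candidate P-values are recomputed against the growing
    model at every step; ties break by declaration order.  After main
    effects, square and cube terms of selected continuous predictors
    are tested (degree ``poly_degree``), then declared interactions,
    accepted when P < threshold and AIC decreases.  Returns the final
    fit and the full selection trace.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("entry threshold must be in (0, 1)")
    subgroups = subgroups or {}
    continuous = continuous or []
    interactions = interactions or []
    member_of = {}
    for gname, members in subgroups.items():
        for m in members:
            member_of[m] = gname

    selected: list = []
    remaining = list(candidates)
    trace = []
    current = fit_lmm(df, outcome, selected, grouping)
    step = 0
    while remaining:
        step += 1
        best = None
        pvals = {}
        for cand in remaining:
            try:
                trial = fit_lmm(df, outcome, selected + [cand], grouping)
            except Exception:
                trace.append({"step": step, "candidate": cand, "p": np.nan,
                              "decision": "failed"})
                continue
            if not trial.converged:
                trace.append({"step": step, "candidate": cand, "p": np.nan,
                              "decision": "nonconverged"})
                continue
            p = trial.term_pvalues.get(cand, np.nan)
            pvals[cand] = p
            if not np.isnan(p) and p < threshold and \
                    (best is None or p < pvals[best]):
                best = cand
        for cand, p in pvals.items():
            trace.append({"step": step, "candidate": cand, "p": p,
                          "decision": "entered" if cand == best else "rejected"})
        if best is None:
            break
        selected.append(best)
        current = fit_lmm(df, outcome, selected, grouping)
        remaining.remove(best)
        if best in member_of:
            g = member_of[best]
            dropped = [m for m in remaining if member_of.get(m) == g]
            for m in dropped:
                remaining.remove(m)
                trace.append({"step": step, "candidate": m, "p": np.nan,
                              "decision": "withdrawn (subgroup)"})

    # polynomial terms for selected continuous predictors
    for var in [v for v in continuous if v in selected]:
        for degree in range(2, poly_degree + 1):
            step += 1
            term = f"I({var} ** {degree})"
            trial = fit_lmm(df, outcome, selected + [term], grouping)
            p = trial.term_pvalues.get(term, np.nan)
            ok = trial.converged and not np.isnan(p) and p < threshold
            trace.append({"step": step, "candidate": term, "p": p,
                          "decision": "entered" if ok else "rejected"})
            if not ok:
                break
            selected.append(term)
            current = trial

    for inter in interactions:
        parts = inter.split(":")
        if not all(p in selected for p in parts):
            continue
        step += 1
        trial = fit_lmm(df, outcome, selected + [inter], grouping)
        p = trial.term_pvalues.get(inter, np.nan)
        ok = (trial.converged and not np.isnan(p) and p < threshold
              and trial.aic < current.aic)
        trace.append({"step": step, "candidate": inter, "p": p,
                      "decision": "entered" if ok else "rejected"})
        if ok:
            selected.append(inter)
            current = trial

    return current, pd.DataFrame(trace, columns=["step", "candidate", "p", "decision"])


def variance_explained(fit: ModelFit) -> tuple[float, float]:
    """Marginal and conditional variance-explained (Nakagawa R2).

    marginal = var(Xb) / (var(Xb) + sum(variance components) + resid);
    conditional adds the non-residual components to the numerator.
    """
    res = fit.result
    fixed_pred = np.asarray(res.model.exog) @ np.asarray(res.fe_params)
    var_f = float(np.var(fixed_pred))
    vc = fit.variance_components
    var_random = sum(v for k, v in vc.items() if k != "resid")
    denom = var_f + var_random + vc["resid"]
    return var_f / denom, (var_f + var_random) / denom


def loocv_by_group(df: pd.DataFrame, outcome: str, fixed_terms: list,
                   grouping=("farm_id", "dam_id"), group_col: str | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Leave-one-group-out cross-validation of the selected fixed structure.

    For each held-out group (default: the top grouping level) the model
    is refitted on the remaining groups and held-out rows are predicted
    from fixed effects only (the random effect of an unseen group is 0).
    Returns (per-fold metrics, pooled observed-vs-predicted table);
    folds that fail to converge are flagged and excluded from pooling.
    """
    group_col = group_col or grouping[0]
    groups = sorted(df[group_col].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups for leave-one-group-out CV")
    fold_rows, pooled = [], []
    for g in groups:
        train = df[df[group_col] != g]
        test = df[df[group_col] == g]
        try:
            fit = fit_lmm(train, outcome, fixed_terms, grouping)
            ok = fit.converged
        except Exception:
            ok = False
        if not ok:
            fold_rows.append({"group": g, "n": len(test), "rmse": np.nan,
                              "converged": False})
            continue
        pred = np.asarray(fit.result.predict(exog=test))
        obs = test[outcome].to_numpy(dtype=float)
        keep = ~np.isnan(pred)
        rmse = float(np.sqrt(np.mean((obs[keep] - pred[keep]) ** 2)))
        fold_rows.append({"group": g, "n": int(keep.sum()), "rmse": rmse,
                          "converged": True})
        pooled.append(pd.DataFrame({"group": g, "observed": obs[keep],
                                    "predicted": pred[keep]}))
    folds = pd.DataFrame(fold_rows)
    pooled_df = pd.concat(pooled, ignore_index=True) if pooled else \
        pd.DataFrame(columns=["group", "observed", "predicted"])
    return folds, pooled_df


def spearman_matrix(df: pd.DataFrame, cols: list | None = None) -> pd.DataFrame:
    """Spearman rank correlations among numeric predictors.

    Pairwise-complete; requires >=3 rows.  Constant columns give NaN
    entries and are listed in ``out.attrs["constant_columns"]``.
    """
    data = df[cols] if cols is not None else df.select_dtypes("number")
    if len(data) < 3:
        raise ValueError("need at least 3 rows for rank correlations")
    out = data.corr(method="spearman")
    constant = [c for c in data.columns if data[c].nunique(dropna=True) <= 1]
    out.attrs["constant_columns"] = constant
    return out
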