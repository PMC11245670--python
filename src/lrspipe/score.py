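"""Lifetime resilience score (LRS) with an additive component breakdown.

The LRS rewards a cow's ability to recalve, with secondary corrections
relative to her herd:

    LRS_i = CbarInt + 300*L_i + (730 - AFC_i)
            + sum_{j=1..L_i-1} (CbarInt_j - CInt_{i,j})
            + sum_{j=1..L_i} [ S_{i,j} / Sbar_j - 1 ] * 100
            + min(0, DIM_{i,L_i} - 100)

where CbarInt is the herd mean calving interval over all selected
years, L_i the lactation in which cow i exited, AFC_i her age at first
calving in days (reference 730 d), CInt_{i,j} her j-th calving
interval, CbarInt_j the herd mean interval for transition j -> j+1,
S_{i,j} the sum of her daily milk yields over days 1..max(305,
DIM_{i,j}) of lactation j, Sbar_j the same sum of the herd-average
daily curve, and DIM_{i,L_i} the days in milk at which she exited (a
penalty applies strictly below 100 DIM).

Daily yields come from the fitted lactation curves (monthly recordings
cannot supply daily sums); the herd daily average at day k of lactation
j is the mean of the fitted curves of all selected cows, extrapolated
(and floored at 0) past 305 d where a lactation ran longer.  Averages
can be grouped by farm, or farm x subherd for research herds split by
feed trial and genetic line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lactation import milkbot, wood

__all__ = ["HerdAverages", "herd_averages", "compute_lrs", "score_herd",
           "score_against", "LACTATION_BONUS", "AFC_REFERENCE_DAYS",
           "EXIT_PENALTY_DIM"]

LACTATION_BONUS = 300.0
AFC_REFERENCE_DAYS = 730.0
EXIT_PENALTY_DIM = 100.0

COMPONENT_COLS = ["baseline", "lactation_bonus", "afc", "calving_interval",
                  "yield", "early_exit_penalty"]


@dataclass
class HerdAverages:
    """Herd (or subherd) averages entering the LRS equation."""
    group: object
    mean_interval: float                       # CbarInt, days
    mean_interval_by_transition: dict          # j -> CbarInt_j, days
    mean_daily_curve: dict                     # j -> np.ndarray, kg at day k (index k-1)
    n_cows: int = 0

    def curve_sum(self, lactation: int, horizon: int) -> float:
        """Sum of the herd-average daily curve for days 1..horizon."""
        curve = self.mean_daily_curve.get(lactation)
        if curve is None or len(curve) < horizon:
            raise KeyError(
                f"herd average daily curve for lactation {lactation} "
                f"not available to day {horizon} in group {self.group!r}")
        return float(np.sum(curve[:horizon]))


def _predict_curve(row, days: np.ndarray) -> np.ndarray:
    if row.get("model", "milkbot") == "wood":
        vals = wood(days, row["scale"], row["ramp"], row["offset"])
    else:
        vals = milkbot(days, row["scale"], row["ramp"], row["offset"], row["decay"])
    return np.maximum(vals, 0.0)


def _cow_lactation_table(cows: pd.DataFrame, calvings: pd.DataFrame,
                         milk: pd.DataFrame | None) -> pd.DataFrame:
    """One row per cow-lactation with interval / end-DIM bookkeeping.

    DIM at the end of lactation j is the calving interval for non-final
    lactations and (exit date - last calving date) for the final one;
    a missing exit date falls back to the cow's last milk-recording
    date + 1 d (flagged in column ``exit_proxy``).
    """
    calv = calvings.copy()
    calv["calving_date"] = pd.to_datetime(calv["calving_date"])
    calv = calv.sort_values(["cow_id", "calving_date"])
    calv["lactation"] = calv.groupby("cow_id").cumcount() + 1
    calv["next_calving"] = calv.groupby("cow_id")["calving_date"].shift(-1)
    calv["interval"] = (calv["next_calving"] - calv["calving_date"]).dt.days

    cw = cows.copy()
    for col in ("birth_date", "exit_date"):
        if col in cw.columns:
            cw[col] = pd.to_datetime(cw[col])
    calv = calv.drop(columns=[c for c in ("farm_id", "subherd") if c in calv.columns])
    out = calv.merge(cw[["cow_id", "farm_id", "birth_date"]
                        + (["exit_date"] if "exit_date" in cw.columns else [])
                        + ([c for c in ("subherd",) if c in cw.columns])],
                     on="cow_id", how="inner")

    last_milk = None
    if milk is not None and len(milk):
        m = milk.copy()
        m["date"] = pd.to_datetime(m["date"])
        last_milk = m.groupby("cow_id")["date"].max()

    exit_date = out["exit_date"] if "exit_date" in out.columns else pd.Series(
        pd.NaT, index=out.index)
    proxy = exit_date.isna()
    if last_milk is not None:
        fallback = out["cow_id"].map(last_milk) + pd.Timedelta(days=1)
        exit_date = exit_date.fillna(fallback)
    out["exit_proxy"] = proxy & exit_date.notna()
    final = out["next_calving"].isna()
    end_dim = out["interval"].astype(float)
    end_dim[final] = (exit_date[final] - out.loc[final, "calving_date"]).dt.days
    out["end_dim"] = end_dim
    out["is_final"] = final
    return out


def herd_averages(cows: pd.DataFrame, calvings: pd.DataFrame,
                  fits: pd.DataFrame, milk: pd.DataFrame | None = None,
                  group_cols=("farm_id",)) -> dict:
    """Compute HerdAverages per group from the analysis selection.

    Only cows with a converged fit for every lactation up to their exit
    lactation contribute to the milk-yield averages (and to the interval
    averages), mirroring the exclusion of cows with no usable milk in a
    lactation.  Raises for a group with no calving intervals.
    """
    group_cols = list(group_cols)
    full_table = _cow_lactation_table(cows, calvings, milk)
    fit_ok = fits[fits["converged"]].set_index(["cow_id", "lactation"])

    # scoreable cows: converged fit for every lactation
    n_lact = full_table.groupby("cow_id")["lactation"].max()
    n_fit = fits[fits["converged"]].groupby("cow_id")["lactation"].nunique()
    scoreable = set(n_lact.index[n_lact <= n_lact.index.map(n_fit).fillna(0)])
    table = full_table[full_table["cow_id"].isin(scoreable)]

    # horizon per (group, lactation): longest end-DIM over ALL group cows
    # (non-scoreable cows still get scored against these averages)
    gkey = group_cols[0] if len(group_cols) == 1 else group_cols
    all_horizons = full_table.groupby(
        [full_table[c] for c in group_cols] + [full_table["lactation"]]
    )["end_dim"].max()

    result = {}
    for key, grp in table.groupby(gkey):
        intervals = grp["interval"].dropna()
        if len(intervals) == 0:
            raise ValueError(f"group {key!r} has no calving intervals")
        by_j = grp.dropna(subset=["interval"]).groupby("lactation")["interval"].mean()

        hkey = (key,) if len(group_cols) == 1 else tuple(key)
        horizons = all_horizons.loc[hkey].fillna(305.0)
        curves = {}
        for j, sub in grp.groupby("lactation"):
            horizon = int(max(305, np.nan_to_num(horizons.get(j, 305), nan=305.0)))
            days = np.arange(1, horizon + 1, dtype=float)
            acc = np.zeros(horizon)
            n = 0
            for cow in sub["cow_id"]:
                try:
                    row = fit_ok.loc[(cow, j)]
                except KeyError:
                    continue
                acc += _predict_curve(row, days)
                n += 1
            if n:
                curves[int(j)] = acc / n
        result[key] = HerdAverages(
            group=key,
            mean_interval=float(intervals.mean()),
            mean_interval_by_transition={int(j): float(v) for j, v in by_j.items()},
            mean_daily_curve=curves,
            n_cows=int(grp["cow_id"].nunique()))
    return result


def compute_lrs(cow_lactations: pd.DataFrame, fits_indexed: pd.DataFrame,
                avgs: HerdAverages) -> dict:
    """Score one cow (rows of her cow-lactation table) against herd averages.

    Returns the LRS with its additive component breakdown; a missing
    (non-converged) fitted curve for any lactation gives a missing LRS.
    """
    grp = cow_lactations.sort_values("lactation")
    L = int(grp["lactation"].max())
    afc = float((grp["calving_date"].iloc[0] - grp["birth_date"].iloc[0]).days)

    baseline = avgs.mean_interval
    bonus = LACTATION_BONUS * L
    afc_comp = AFC_REFERENCE_DAYS - afc

    interval_comp = 0.0
    for r in grp.itertuples():
        if r.lactation < L and not np.isnan(r.interval):
            cbar_j = avgs.mean_interval_by_transition.get(int(r.lactation))
            if cbar_j is None:
                return _missing(L, afc)
            interval_comp += cbar_j - r.interval

    yield_comp = 0.0
    final_dim = np.nan
    for r in grp.itertuples():
        j = int(r.lactation)
        end_dim = r.end_dim
        if np.isnan(end_dim):
            return _missing(L, afc)
        if r.is_final:
            final_dim = float(end_dim)
        horizon = int(max(305, end_dim))
        try:
            fit_row = fits_indexed.loc[(grp["cow_id"].iloc[0], j)]
        except KeyError:
            return _missing(L, afc)
        days = np.arange(1, horizon + 1, dtype=float)
        num = float(np.sum(_predict_curve(fit_row, days)))
        try:
            den = avgs.curve_sum(j, horizon)
        except KeyError:
            return _missing(L, afc)
        yield_comp += (num / den - 1.0) * 100.0

    exit_comp = min(0.0, final_dim - EXIT_PENALTY_DIM)
    components = {
        "baseline": baseline, "lactation_bonus": bonus, "afc": afc_comp,
        "calving_interval": interval_comp, "yield": yield_comp,
        "early_exit_penalty": exit_comp,
    }
    return {"lrs": float(sum(components.values())), "exit_lactation": L,
            "afc": afc, **components}


def _missing(L, afc):
    out = {c: np.nan for c in COMPONENT_COLS}
    return {"lrs": np.nan, "exit_lactation": L, "afc": afc, **out}


def score_against(cows: pd.DataFrame, calvings: pd.DataFrame,
                  fits: pd.DataFrame, avgs: HerdAverages,
                  milk: pd.DataFrame | None = None) -> pd.DataFrame:
    """Score the given cows against externally supplied herd averages.

    Useful for what-if evaluation (e.g. a reference cow at exact herd
    average) without the cows entering the averages themselves.
    """
    table = _cow_lactation_table(cows, calvings, milk)
    fits_indexed = fits[fits["converged"]].set_index(["cow_id", "lactation"])
    rows = []
    for cow, cgrp in table.groupby("cow_id"):
        res = compute_lrs(cgrp, fits_indexed, avgs)
        rows.append({"cow_id": cow, **res})
    return pd.DataFrame(rows)


def score_herd(cows: pd.DataFrame, calvings: pd.DataFrame, fits: pd.DataFrame,
               milk: pd.DataFrame | None = None,
               group_cols=("farm_id",)) -> pd.DataFrame:
    """LRS for every cow with >=1 calving, herd averages computed per group."""
    group_cols = list(group_cols)
    avgs = herd_averages(cows, calvings, fits, milk, group_cols)
    table = _cow_lactation_table(cows, calvings, milk)
    fits_indexed = fits[fits["converged"]].set_index(["cow_id", "lactation"])

    rows = []
    for key, grp in table.groupby(group_cols[0] if len(group_cols) == 1 else group_cols):
        av = avgs[key]
        for cow, cgrp in grp.groupby("cow_id"):
            res = compute_lrs(cgrp, fits_indexed, av)
            rec = {"cow_id": cow, "group": key}
            if len(group_cols) == 1:
                rec[group_cols[0]] = key
            rec.update(res)
            rows.append(rec)
    out = pd.DataFrame(rows)
    out.attrs["n_missing"] = int(out["lrs"].isna().sum()) if len(out) else 0
    return out
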