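"""Record cleaning, pedigree pairing and treatment categorisation.

Implements the selection cascade applied to commercial herd exports
before analysis: cows must have a unique identity (one farm only), must
have entered the herd on their date of birth with no prior lactation,
must be born inside the study window, and must have a plausible age at
first calving (strictly between 458 and 1,461 days).  Milk records are
bracketed into lactations by calving dates, implausible yields
(>100 kg/d) removed, and free-text treatment events matched to a
licensed-product list by partial-ratio fuzzy matching.  Every exclusion
step is logged in a CleaningReport whose counts are monotone
non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .text import best_match

__all__ = [
    "CleaningReport",
    "AFC_MIN_DAYS",
    "AFC_MAX_DAYS",
    "clean_cows",
    "clean_milk",
    "match_treatments",
    "filter_recording_herd_years",
    "match_pairs",
]

# age at first calving must be strictly inside (458, 1461) days
AFC_MIN_DAYS = 458
AFC_MAX_DAYS = 1461

STRESSOR_CATEGORIES = ("mastitis", "lameness", "antimicrobial", "anti_inflammatory")

DRY_COW_KEYWORDS = ("dry cow", "drycow", " dc ", " dc")


@dataclass
class CleaningReport:
    """Ordered log of (step, animals remaining, records remaining)."""
    steps: list = field(default_factory=list)

    def add(self, name: str, n_animals: int, n_records: int | None = None):
        self.steps.append({"step": name, "n_animals": int(n_animals),
                           "n_records": None if n_records is None else int(n_records)})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


def _first_calving(calvings: pd.DataFrame) -> pd.Series:
    return calvings.groupby("cow_id")["calving_date"].min()


def clean_cows(cows: pd.DataFrame, calvings: pd.DataFrame,
               birth_window: tuple | None = None) -> tuple[pd.DataFrame, CleaningReport]:
    """Apply the cow-level selection cascade.

    Steps, in order: unique cow id across farms; entry on date of birth;
    no lactation before herd entry; birth date inside ``birth_window``;
    at least one calving with age at first calving strictly between
    458 and 1,461 d.
    """
    report = CleaningReport()
    df = cows.copy()
    for col in ("birth_date", "entry_date", "exit_date"):
        if col in df.columns:
            df[col] = pd.to_datetime(df[col])
    calv = calvings.copy()
    calv["calving_date"] = pd.to_datetime(calv["calving_date"])
    report.add("animal records", len(df))

    # 1. cow identification number occurred on one farm only
    farms_per_id = df.groupby("cow_id")["farm_id"].nunique()
    dup_ids = set(farms_per_id[farms_per_id > 1].index)
    df = df[~df["cow_id"].isin(dup_ids)]
    report.add("cow id on one farm only", len(df))

    # 2. cows entered herd on their date of birth
    df = df[df["entry_date"] == df["birth_date"]]
    report.add("entered herd on date of birth", len(df))

    # 3. no previous lactation on entry to herd
    first_calv = _first_calving(calv)
    fc = df["cow_id"].map(first_calv)
    df = df[fc.isna() | (fc >= df["entry_date"])]
    report.add("no previous lactation on entry", len(df))

    # 4. born inside the study window
    if birth_window is not None:
        lo, hi = pd.Timestamp(birth_window[0]), pd.Timestamp(birth_window[1])
        df = df[(df["birth_date"] >= lo) & (df["birth_date"] <= hi)]
    report.add("born in study window", len(df))

    # 5. calved at least once, with plausible age at first calving
    fc = df["cow_id"].map(first_calv)
    afc = (fc - df["birth_date"]).dt.days
    df = df[afc.notna() & (afc > AFC_MIN_DAYS) & (afc < AFC_MAX_DAYS)]
    n_calv = calv[calv["cow_id"].isin(df["cow_id"])].shape[0]
    report.add(f"age at first calving >{AFC_MIN_DAYS} d and <{AFC_MAX_DAYS} d",
               len(df), n_calv)
    return df.reset_index(drop=True), report


def clean_milk(milk: pd.DataFrame, cows: pd.DataFrame, calvings: pd.DataFrame
               ) -> tuple[pd.DataFrame, CleaningReport]:
    """Clean milk records of already-cleaned cows and assign lactations.

    Records of unknown cows are dropped (counted).  A record dated
    before a cow's first calving shows she was not first-parity at
    entry; the cow and all her records are excluded.  Records are
    assigned to lactation j by half-open bracketing [calving_j,
    calving_{j+1}) with DIM counted from the calving date (day 0);
    records with yield > 100 kg/d are removed.
    """
    report = CleaningReport()
    df = milk.copy()
    df["date"] = pd.to_datetime(df["date"])
    calv = calvings.copy()
    calv["calving_date"] = pd.to_datetime(calv["calving_date"])
    known = set(cows["cow_id"])
    report.add("milk records", df["cow_id"].nunique(), len(df))

    n_unknown = int((~df["cow_id"].isin(known)).sum())
    df = df[df["cow_id"].isin(known)]
    report.add("records of selected cows", df["cow_id"].nunique(), len(df))
    report.steps[-1]["n_dropped_unknown"] = n_unknown

    first_calv = _first_calving(calv[calv["cow_id"].isin(known)])
    fc = df["cow_id"].map(first_calv)
    pre_calving_cows = set(df.loc[df["date"] < fc, "cow_id"])
    df = df[~df["cow_id"].isin(pre_calving_cows)]
    report.add("records within lactations (no pre-first-calving milk)",
               df["cow_id"].nunique(), len(df))

    df = df[df["yield"] <= 100.0]
    report.add("records with yield >100 kg removed", df["cow_id"].nunique(), len(df))

    # lactation assignment by bracketing calving dates
    calv = calv.sort_values(["cow_id", "calving_date"])
    calv["lactation"] = calv.groupby("cow_id").cumcount() + 1
    merged = pd.merge_asof(
        df.sort_values("date"),
        calv[["cow_id", "calving_date", "lactation"]].sort_values("calving_date"),
        left_on="date", right_on="calving_date", by="cow_id", direction="backward")
    merged["dim"] = (merged["date"] - merged["calving_date"]).dt.days
    merged = merged.drop(columns=["calving_date"]).sort_values(["cow_id", "date"])
    report.add("records assigned to a lactation", merged["cow_id"].nunique(), len(merged))
    return merged.reset_index(drop=True), report


def match_treatments(events: pd.DataFrame, products: pd.DataFrame,
                     threshold: float = 90.0,
                     dry_cow_keywords: tuple = DRY_COW_KEYWORDS
                     ) -> pd.DataFrame:
    """Categorise events; fuzzy-match free-text treatments to products.

    Rows whose ``event_type`` is already a clinical category (mastitis,
    lameness) keep it.  Treatment rows are scored against every product
    name with the partial-ratio measure; the best-scoring product at or
    above ``threshold`` assigns its use category, otherwise the record
    is retained as ``unmatched``.  Products whose (case-folded) name
    contains a dry-cow keyword set ``dry_cow_flag`` so dry-cow therapies
    can be included or excluded per analysis.  Matched name and score
    are kept as an audit trail for manual review.
    """
    df = events.copy()
    df["category"] = "other"
    df["dry_cow_flag"] = False
    df["matched_product"] = ""
    df["match_score"] = np.nan

    clinical = df["event_type"].isin(("mastitis", "lameness"))
    df.loc[clinical, "category"] = df.loc[clinical, "event_type"]

    is_treat = df["event_type"] == "treatment"
    names = products["name"].tolist()
    cats = products["category"].tolist()
    dry = [any(k in str(n).casefold() for k in dry_cow_keywords) for n in names]
    if not names:
        df.loc[is_treat, "category"] = "unmatched"
        return df

    cache: dict[str, tuple[int, float]] = {}
    for idx in df.index[is_treat]:
        text = str(df.at[idx, "raw_text"])
        if text not in cache:
            cache[text] = best_match(text, names)
        i, score = cache[text]
        df.at[idx, "match_score"] = score
        if score >= threshold:
            df.at[idx, "category"] = cats[i]
            df.at[idx, "matched_product"] = names[i]
            df.at[idx, "dry_cow_flag"] = bool(dry[i])
        else:
            df.at[idx, "category"] = "unmatched"
    return df


def filter_recording_herd_years(events: pd.DataFrame, cows: pd.DataFrame
                                ) -> set[tuple]:
    """Herd-years with at least one recorded stressor.

    A (farm, year) is retained iff >=1 event categorised as mastitis,
    lameness, antimicrobial or anti-inflammatory is dated in that year
    on that farm.  Vaccines and unmatched records do not count.
    """
    if len(events) == 0:
        return set()
    df = events.merge(cows[["cow_id", "farm_id"]], on="cow_id", how="inner")
    df = df[df["category"].isin(STRESSOR_CATEGORIES)]
    years = pd.to_datetime(df["date"]).dt.year
    return set(zip(df["farm_id"], years))


def match_pairs(cows: pd.DataFrame, calvings: pd.DataFrame,
                generation_gap: int = 1) -> pd.DataFrame:
    """Offspring-ancestor pairs via the pregnancy that produced them.

    gap 1: each daughter is paired with the pregnancy of her dam whose
    calving date equals the daughter's birth date.  gap 2: each
    granddaughter is paired with the pregnancy of her granddam that
    produced the mother.  Pairs where the producing pregnancy is the
    ancestor's first are excluded (the ancestor was not lactating during
    that pregnancy).  Broken pedigree links are skipped and counted in
    ``df.attrs["n_broken"]``.
    """
    if generation_gap not in (1, 2):
        raise ValueError("generation_gap must be 1 or 2")
    cw = cows.copy()
    cw["birth_date"] = pd.to_datetime(cw["birth_date"])
    calv = calvings.copy()
    calv["calving_date"] = pd.to_datetime(calv["calving_date"])
    calv = calv.sort_values(["cow_id", "calving_date"])
    calv["pregnancy"] = calv.groupby("cow_id").cumcount() + 1
    preg_of = {(r.cow_id, r.calving_date): r.pregnancy for r in calv.itertuples()}
    dam_of = dict(zip(cw["cow_id"], cw["dam_id"]))
    birth_of = dict(zip(cw["cow_id"], cw["birth_date"]))

    rows, n_broken = [], 0
    for r in cw.itertuples():
        dam = dam_of.get(r.cow_id)
        if dam is None or (isinstance(dam, float) and np.isnan(dam)) or dam == "":
            continue
        if generation_gap == 1:
            ancestor, key_birth = dam, r.birth_date
        else:
            granddam = dam_of.get(dam)
            if granddam is None or (isinstance(granddam, float) and np.isnan(granddam)) \
                    or granddam == "" or dam not in birth_of:
                n_broken += 1
                continue
            ancestor, key_birth = granddam, birth_of[dam]
        preg = preg_of.get((ancestor, key_birth))
        if preg is None:
            n_broken += 1
            continue
        if preg == 1:  # ancestor not lactating during her first pregnancy
            continue
        rows.append({"offspring_id": r.cow_id, "ancestor_id": ancestor,
                     "pregnancy": int(preg)})
    out = pd.DataFrame(rows, columns=["offspring_id", "ancestor_id", "pregnancy"])
    out.attrs["n_broken"] = n_broken
    return out
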