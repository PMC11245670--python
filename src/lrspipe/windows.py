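"""Gestation exposure windows and model-feature assembly.

Maternal exposures are summarised over three windows of each pregnancy,
expressed in days relative to conception (bovine gestation ~283 d):

    T1: -7 .. 94    (7 d preconception through early organogenesis)
    T2: 95 .. 189   (mid-gestation growth)
    T3: 190 .. 283  (late-gestation fetal tissue accretion)

The windows partition [-7, 283] (291 days) with no overlap or gap.
Where insemination dates are unknown, conception is estimated as
283 d before the calving date.  Within each window the dam's health
events are reduced to presence/absence flags, daily THI_max to its
mean, and milk-recording quality measures (fat, protein, fat/protein
ratio, SCC, yield) to min/median/max mapped onto categorical bands;
the half-open convention ">a-b" = (a, b] makes the bands exhaustive
and disjoint, with an explicit "missing" level when no recording falls
in the window.  Body-condition and locomotion summaries cover the
research-herd variant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "GESTATION_DAYS", "WINDOWS",
    "conception_date", "assign_window", "window_dates",
    "summarize_events", "categorize_milk", "categorize_condition",
    "season_of_birth", "farm_features", "build_features",
]

GESTATION_DAYS = 283
WINDOWS = {"T1": (-7, 94), "T2": (95, 189), "T3": (190, 283)}

EVENT_FLAG_CATEGORIES = ("mastitis", "lameness", "antimicrobial", "anti_inflammatory")

# categorical bands; ">a-b" is the half-open interval (a, b]
MILK_BANDS = {
    "fat": [0, 3, 5],            # >0-3, >3-5, >5  (%)
    "protein": [0, 3, 4],        # >0-3, >3-4, >4  (%)
    "fpr": [0, 1, 1.2, 1.4],     # fat/protein ratio
    "scc": [0, 50, 100, 200, 400],  # x1,000 cells/mL
    "yield": [0, 20, 30, 40],    # L/d
}

REFERENCE_LEVELS = {"preg_cat": "2", "yield": ">20-30", "fat": ">3-5",
                    "protein": ">3-4", "scc": ">0-50", "fpr": ">1-1.2"}


def conception_date(calving_date, mode: str = "estimated",
                    insemination_date=None) -> pd.Timestamp:
    """Date of conception: calving - 283 d, or the last insemination date."""
    calving = pd.Timestamp(calving_date)
    if mode == "estimated":
        return calving - pd.Timedelta(days=GESTATION_DAYS)
    if mode == "insemination":
        ins = pd.Timestamp(insemination_date)
        if ins >= calving:
            raise ValueError("insemination date must precede calving")
        return ins
    raise ValueError(f"unknown conception mode: {mode!r}")


def assign_window(day: int) -> str:
    """Trimester window of a day counted from conception (-7..283)."""
    d = int(day)
    for name, (lo, hi) in WINDOWS.items():
        if lo <= d <= hi:
            return name
    raise ValueError(f"day {d} outside the gestation range [-7, {GESTATION_DAYS}]")


def window_dates(conception) -> dict:
    """Calendar (start, end) of each window for one conception date."""
    c = pd.Timestamp(conception)
    return {name: (c + pd.Timedelta(days=lo), c + pd.Timedelta(days=hi))
            for name, (lo, hi) in WINDOWS.items()}


def summarize_events(events: pd.DataFrame, conception,
                     include_dry_cow: bool = False) -> dict:
    """Presence/absence of each stressor category per window for one dam.

    ``events`` holds the dam's categorised events.  Dry-cow therapies
    are excluded from the antimicrobial flag unless requested.  Also
    flags ``health_event`` (any stressor) per window.
    """
    bounds = window_dates(conception)
    out = {}
    if len(events):
        dates = pd.to_datetime(events["date"])
    for w, (lo, hi) in bounds.items():
        flags = {}
        for cat in EVENT_FLAG_CATEGORIES:
            if len(events) == 0:
                flags[cat] = False
                continue
            sel = (events["category"] == cat) & (dates >= lo) & (dates <= hi)
            if cat == "antimicrobial" and not include_dry_cow:
                sel &= ~events["dry_cow_flag"].astype(bool)
            flags[cat] = bool(sel.any())
        flags["health_event"] = any(flags.values())
        out[w] = flags
    return out


def _band(value: float, edges: list[float]) -> str:
    """Map a value onto its ">a-b" band; NaN or <= lowest edge -> missing."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "missing"
    for lo, hi in zip(edges[:-1], edges[1:]):
        if lo < value <= hi:
            return f">{lo:g}-{hi:g}"
    if value > edges[-1]:
        return f">{edges[-1]:g}"
    return "missing"


def categorize_milk(milk: pd.DataFrame, conception) -> dict:
    """Min/median/max milk-quality bands per window for one dam.

    Uses recordings dated inside each window (by recording date).  Fat,
    protein and yield are summarised as min/median/max; the fat/protein
    ratio and SCC as their maximum, following the variables used for
    monthly-recorded herds.  No recording in the window -> "missing".
    """
    bounds = window_dates(conception)
    m = milk.copy()
    if len(m):
        m["date"] = pd.to_datetime(m["date"])
    out = {}
    for w, (lo, hi) in bounds.items():
        sub = m[(m["date"] >= lo) & (m["date"] <= hi)] if len(m) else m
        feats = {}
        for stat in ("min", "median", "max"):
            for var, col in (("fat", "fat_pct"), ("protein", "protein_pct"),
                             ("yield", "yield")):
                val = getattr(sub[col], stat)() if len(sub) else np.nan
                feats[f"{var}_{stat}"] = _band(float(val) if len(sub) else np.nan,
                                               MILK_BANDS[var])
        if len(sub):
            fpr = (sub["fat_pct"] / sub["protein_pct"]).max()
            scc = sub["scc"].max()
        else:
            fpr = scc = np.nan
        feats["fpr_max"] = _band(fpr, MILK_BANDS["fpr"])
        feats["scc_max"] = _band(scc, MILK_BANDS["scc"])
        out[w] = feats
    return out


def categorize_condition(scores, kind: str) -> str:
    """Body-condition / locomotion category over one window (research herd).

    BCS: mean score < 1.5 -> "under", 1.5..3.25 inclusive -> "normal",
    > 3.25 -> "over".  Locomotion: "lame" iff the maximum score in the
    window is >= 4, else "not_lame".  No scores -> "missing".
    """
    vals = np.asarray(pd.Series(scores).dropna(), dtype=float)
    if vals.size == 0:
        return "missing"
    if kind == "bcs":
        m = vals.mean()
        if m < 1.5:
            return "under"
        if m > 3.25:
            return "over"
        return "normal"
    if kind == "locomotion":
        return "lame" if vals.max() >= 4 else "not_lame"
    raise ValueError(f"unknown condition kind: {kind!r}")


def season_of_birth(date) -> str:
    """Meteorological season of a birth date."""
    m = pd.Timestamp(date).month
    if m in (3, 4, 5):
        return "spring"
    if m in (6, 7, 8):
        return "summer"
    if m in (9, 10, 11):
        return "autumn"
    return "winter"


def pregnancy_category(pregnancy: int) -> str:
    """Collapse pregnancy number to the {2, 3, 4+} analysis categories."""
    p = int(pregnancy)
    if p < 2:
        raise ValueError("first pregnancies are excluded from analysis")
    return str(p) if p <= 3 else "4plus"


def farm_features(birth_date, lactations: pd.DataFrame,
                  calvings: pd.DataFrame, farm_id) -> dict:
    """Farm-level covariates at a calf's birth.

    mean_305d_yield: mean of the 305-d yields of all farm lactations
    whose calving (lactation start) date falls in the 12 months strictly
    before the calf's birth day.  mean_parity: mean parity of dams
    calving on the farm in the calf's birth calendar year.  Missing when
    no qualifying record exists.
    """
    birth = pd.Timestamp(birth_date)
    lact = lactations[lactations["farm_id"] == farm_id]
    start = pd.to_datetime(lact["calving_date"])
    in_window = (start > birth - pd.Timedelta(days=365)) & (start < birth)
    yields = lact.loc[in_window, "yield_305"].dropna()
    mean_yield = float(yields.mean()) if len(yields) else np.nan

    calv = calvings[calvings["farm_id"] == farm_id].copy()
    calv["calving_date"] = pd.to_datetime(calv["calving_date"])
    year_mask = calv["calving_date"].dt.year == birth.year
    parities = calv.loc[year_mask, "parity"].dropna()
    mean_parity = float(parities.mean()) if len(parities) else np.nan
    return {"farm_mean_305d_yield": mean_yield, "farm_mean_parity": mean_parity}


def build_features(pairs: pd.DataFrame, cows: pd.DataFrame,
                   calvings: pd.DataFrame, events: pd.DataFrame,
                   milk: pd.DataFrame, weather: pd.DataFrame,
                   farm_station: pd.DataFrame, lrs: pd.DataFrame,
                   lactations: pd.DataFrame | None = None,
                   retained_herd_years: set | None = None,
                   mode: str = "daughter") -> pd.DataFrame:
    """Assemble one model-feature row per offspring-ancestor pair.

    The outcome is the offspring's LRS; explanatory variables describe
    the ancestor's pregnancy that produced the offspring (daughter mode)
    or the offspring's mother (granddaughter mode): per-window stressor
    flags, mean THI_max, milk-quality categories, pregnancy-number
    category, centred ancestor LRS, season of birth and farm-level
    covariates.  Rows with a missing outcome are dropped (counted in
    ``df.attrs["n_dropped"]``); centring of ancestor LRS is over the
    emitted dataset.
    """
    cw = cows.set_index("cow_id")
    calv = calvings.copy()
    calv["calving_date"] = pd.to_datetime(calv["calving_date"])
    calv = calv.sort_values(["cow_id", "calving_date"])
    calv["pregnancy"] = calv.groupby("cow_id").cumcount() + 1
    calv_idx = calv.set_index(["cow_id", "pregnancy"])

    lrs_of = dict(zip(lrs["cow_id"], lrs["lrs"]))
    weather = weather.copy()
    weather["date"] = pd.to_datetime(weather["date"])
    station_of = dict(zip(farm_station["farm_id"], farm_station["station_id"]))
    # date-indexed THI per station for fast window means (equivalent to
    # climate.mean_thi over the closed interval; asserted in tests)
    wx_by_station = {
        sid: grp.set_index("date")["thi_max"].sort_index()
        for sid, grp in weather.groupby("station_id")}
    events_by_cow = {cid: grp for cid, grp in events.groupby("cow_id")}
    milk_by_cow = {cid: grp for cid, grp in milk.groupby("cow_id")}
    lact_by_farm = ({} if lactations is None else
                    {fid: grp for fid, grp in lactations.groupby("farm_id")})
    calv_by_farm = {fid: grp for fid, grp in calvings.groupby("farm_id")} \
        if "farm_id" in calvings.columns else {}

    dam_of = dict(zip(cows["cow_id"], cows["dam_id"]))
    rows, n_dropped = [], 0
    empty_events = events.iloc[0:0]
    empty_milk = milk.iloc[0:0]
    for r in pairs.itertuples():
        outcome = lrs_of.get(r.offspring_id, np.nan)
        if outcome is None or (isinstance(outcome, float) and np.isnan(outcome)):
            n_dropped += 1
            continue
        try:
            ancestor_calving = calv_idx.loc[(r.ancestor_id, r.pregnancy), "calving_date"]
        except KeyError:
            n_dropped += 1
            continue
        farm = cw.loc[r.offspring_id, "farm_id"]
        if retained_herd_years is not None and \
                (farm, pd.Timestamp(ancestor_calving).year) not in retained_herd_years:
            n_dropped += 1
            continue
        conception = conception_date(ancestor_calving)

        row = {"offspring_id": r.offspring_id, "ancestor_id": r.ancestor_id,
               "farm_id": farm, "dam_id": dam_of.get(r.offspring_id, ""),
               "outcome_lrs": float(outcome),
               "preg_cat": pregnancy_category(r.pregnancy),
               "season": season_of_birth(cw.loc[r.offspring_id, "birth_date"])}

        anc_lrs = lrs_of.get(r.ancestor_id, np.nan)
        row["ancestor_lrs"] = anc_lrs
        if mode == "granddaughter":
            mother = dam_of.get(r.offspring_id)
            row["mother_lrs"] = lrs_of.get(mother, np.nan)

        ev = events_by_cow.get(r.ancestor_id, empty_events)
        flags = summarize_events(ev, conception)
        for w, f in flags.items():
            for cat, val in f.items():
                row[f"{cat}_{w.lower()}"] = bool(val)

        mk = milk_by_cow.get(r.ancestor_id, empty_milk)
        bands = categorize_milk(mk, conception)
        for w, f in bands.items():
            for var, val in f.items():
                row[f"{var}_{w.lower()}"] = val

        sid = station_of.get(farm)
        wx = wx_by_station.get(sid)
        for w, (lo, hi) in window_dates(conception).items():
            if wx is None:
                row[f"mean_thi_{w.lower()}"] = np.nan
            else:
                vals = wx.loc[lo:hi]
                row[f"mean_thi_{w.lower()}"] = (
                    float(vals.mean()) if len(vals) else np.nan)

        if lactations is not None:
            row.update(farm_features(
                cw.loc[r.offspring_id, "birth_date"],
                lact_by_farm.get(farm, lactations.iloc[0:0]),
                calv_by_farm.get(farm, calvings.iloc[0:0]), farm))
        rows.append(row)

    out = pd.DataFrame(rows)
    if len(out):
        out["ancestor_lrs_centered"] = out["ancestor_lrs"] - out["ancestor_lrs"].mean()
        if mode == "granddaughter":
            out["mother_lrs_centered"] = out["mother_lrs"] - out["mother_lrs"].mean()
    out.attrs["n_dropped"] = n_dropped
    return out
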