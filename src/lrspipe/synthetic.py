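"""Synthetic multi-farm herd generator with known ground truth.

Generates longitudinal herd-management tables (cows, calvings, monthly
milk recordings, free-text health/treatment events, daily station
weather, farm locations, a licensed-product list) whose schema matches
what the cleaning pipeline consumes, together with truth tables holding
every quantity the pipeline is supposed to recover.

The generator works on a latent resilience scale.  Each cow receives

    r = farm_effect + dam_effect + sum_w beta_w * (x_w - x_ref) + noise

where x_w are in-utero exposures over the gestation windows of the
pregnancy that produced her (e.g. mean THI_max in trimester 3) and
beta_w the injected effects in score points per unit.  The latent is
then translated into survival (number of lactations), age at first
calving, calving-interval deviations and a yield multiplier, with
shares chosen so one latent point moves the expected computed lifetime
resilience score by about one point.  The signal therefore reaches the
analysis only through the actual scoring function, never through a
shortcut variable.

Default rates and variance components follow the multi-herd study
conditions: stressor incidences matching the published per-pregnancy
proportions, and farm / dam / residual SDs of 142.27 / 81.42 / 477.17
score points.  Event recording is thinned per farm-year so recording
heterogeneity (and the herd-year stressor filter) has something to act
on.  All dates are on a daily grid; identical configs (including seed)
reproduce byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .climate import add_thi, match_nearest_station
from .lactation import milkbot
from .windows import GESTATION_DAYS, WINDOWS

__all__ = ["SimConfig", "PRODUCTS", "simulate_weather", "simulate_herds",
           "write_tables"]

DAY = pd.Timedelta(days=1)

PRODUCTS = pd.DataFrame([
    ("Betamox LA", "antimicrobial"),
    ("Synulox RTU", "antimicrobial"),
    ("Pen & Strep", "antimicrobial"),
    ("Tetroxy LA", "antimicrobial"),
    ("Cobactan 2.5%", "antimicrobial"),
    ("Ubro Yellow Milking Cow", "antimicrobial"),
    ("Cepravin Dry Cow", "antimicrobial"),
    ("Orbenin Dry Cow", "antimicrobial"),
    ("Bovaclox DC Xtra", "antimicrobial"),
    ("Metacam 20 mg/ml", "anti_inflammatory"),
    ("Finadyne Solution", "anti_inflammatory"),
    ("Ketofen 10%", "anti_inflammatory"),
    ("Bovilis BVD", "vaccine"),
    ("Rotavec Corona", "vaccine"),
    ("Huskvac", "vaccine"),
], columns=["name", "category"])

_DRY_COW_NAMES = ["Cepravin Dry Cow", "Orbenin Dry Cow", "Bovaclox DC Xtra"]
_BY_CATEGORY = {c: PRODUCTS.loc[(PRODUCTS["category"] == c) &
                                (~PRODUCTS["name"].isin(_DRY_COW_NAMES)), "name"].tolist()
                for c in ("antimicrobial", "anti_inflammatory", "vaccine")}


@dataclass
class WeatherConfig:
    t_baseline: float = 13.0       # degC at the reference latitude, annual mean of daily max
    t_amplitude: float = 7.5       # degC seasonal amplitude of daily max
    peak_doy: int = 200            # day of year of the warm peak (mid July)
    lat_ref: float = 54.0
    lat_coeff: float = 0.9         # degC warmer per degree south of lat_ref
    daily_sd: float = 2.5          # degC day-to-day noise
    monthly_anomaly_sd: float = 2.5  # degC station-month weather anomalies
    dew_offset_mean: float = 3.5   # degC dewpoint depression (t_max - dewpoint)
    dew_offset_sd: float = 1.5


@dataclass
class SimConfig:
    """Study conditions for the synthetic herd."""
    n_farms: int = 8
    cows_per_farm: int = 40                 # founder dams per farm
    start_year: int = 2006                  # offspring birth window
    end_year: int = 2015
    herd_calving_interval_mean: float = 400.0   # days
    herd_calving_interval_sd: float = 45.0
    # lactation-curve parameters (MilkBot), with farm-level scale spread
    scale_mean: float = 33.0
    scale_sd_farm: float = 2.5
    ramp: float = 22.0
    offset: float = -1.0
    decay: float = 0.0018
    # daily stressor hazards (per cow-day); per ~290-d pregnancy these give
    # the published proportions (mastitis 0.11, antimicrobial 0.13,
    # lameness 0.02, anti-inflammatory 0.02)
    event_rates: dict = field(default_factory=lambda: {
        "mastitis": 4.0e-4, "lameness": 7.0e-5, "antimicrobial": 4.8e-4,
        "anti_inflammatory": 7.0e-5, "vaccine": 3.0e-4})
    dry_cow_prob: float = 0.5               # dry-cow therapy per completed lactation
    typo_prob: float = 0.25                 # free-text corruption of product names
    recording_completeness_mean: float = 0.9  # per farm-year event keep-probability
    recording_completeness_sd: float = 0.08
    weather: WeatherConfig = field(default_factory=WeatherConfig)
    missing_station_years: dict = field(default_factory=dict)  # station -> {year: frac missing}
    # injected in-utero effects, score points per unit of the window feature
    injected_effects: dict = field(default_factory=lambda: {
        "mean_thi_t1": -5.18, "mean_thi_t3": -5.76})
    thi_reference: float = 55.0             # exposure centring point (index points)
    noise_sd: float = 477.17                # residual latent noise, points
    farm_sd: float = 142.27                 # farm-level SD, points
    dam_sd: float = 81.42                   # dam-level SD, points
    retention_prob: float = 0.45            # heifer calf retained in herd
    generations: int = 3                    # founders + daughters (+ granddaughters)
    seed: int = 0

    def validate(self):
        for k, v in self.event_rates.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"event rate {k} outside [0, 1]")
        for name in ("dry_cow_prob", "typo_prob", "recording_completeness_mean",
                     "retention_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")
        for name in ("herd_calving_interval_sd", "noise_sd", "farm_sd", "dam_sd",
                     "recording_completeness_sd", "scale_sd_farm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.end_year < self.start_year:
            raise ValueError("invalid date range: end_year before start_year")
        if self.generations not in (2, 3):
            raise ValueError("generations must be 2 or 3")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "weather" in raw:
            raw["weather"] = WeatherConfig(**raw["weather"])
        return cls(**raw)

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


# ---------------------------------------------------------------- weather

def _make_farms_stations(config: SimConfig, rng: np.random.Generator):
    lat = rng.uniform(50.5, 57.5, size=config.n_farms)
    lon = rng.uniform(-5.5, 0.5, size=config.n_farms)
    farms = pd.DataFrame({
        "farm_id": [f"F{i + 1:02d}" for i in range(config.n_farms)],
        "latitude": np.round(lat, 4), "longitude": np.round(lon, 4)})
    stations = pd.DataFrame({
        "station_id": [f"S{i + 1:02d}" for i in range(config.n_farms)],
        "latitude": np.round(lat + rng.normal(0, 0.15, config.n_farms), 4),
        "longitude": np.round(lon + rng.normal(0, 0.15, config.n_farms), 4)})
    return farms, stations


def simulate_weather(config: SimConfig, stations: pd.DataFrame | None = None,
                     date_range: tuple | None = None,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Daily station summaries with seasonal structure and optional gaps.

    One record per station per day; dewpoint never exceeds t_max (the
    dewpoint depression is drawn non-negative).  Station-year
    missingness fractions from ``config.missing_station_years`` remove
    that share of days, for QC testing.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    if stations is None:
        _, stations = _make_farms_stations(config, rng)
    if date_range is None:
        date_range = (pd.Timestamp(year=config.start_year - 6, month=1, day=1),
                      pd.Timestamp(year=config.end_year + 9, month=12, day=31))
    start, end = pd.Timestamp(date_range[0]), pd.Timestamp(date_range[1])
    if end < start:
        raise ValueError("invalid date range")
    dates = pd.date_range(start, end, freq="D")
    doy = dates.dayofyear.to_numpy()
    w = config.weather
    seasonal = w.t_baseline + w.t_amplitude * np.cos(
        2.0 * np.pi * (doy - w.peak_doy) / 365.25)
    month_key = dates.year.to_numpy() * 100 + dates.month.to_numpy()
    uniq_months = np.unique(month_key)
    frames = []
    for r in stations.itertuples():
        anomalies = dict(zip(uniq_months,
                             rng.normal(0.0, w.monthly_anomaly_sd, len(uniq_months))))
        t_max = (seasonal
                 + w.lat_coeff * (w.lat_ref - r.latitude)
                 + np.array([anomalies[m] for m in month_key])
                 + rng.normal(0.0, w.daily_sd, len(dates)))
        depression = np.abs(rng.normal(w.dew_offset_mean, w.dew_offset_sd, len(dates)))
        df = pd.DataFrame({
            "station_id": r.station_id, "date": dates,
            "t_max": np.round(t_max, 2),
            "dewpoint": np.round(t_max - depression, 2),
            "latitude": r.latitude, "longitude": r.longitude})
        drop_frac = config.missing_station_years.get(r.station_id, {})
        if drop_frac:
            keep = np.ones(len(df), dtype=bool)
            years = dates.year.to_numpy()
            for year, frac in drop_frac.items():
                idx = np.flatnonzero(years == int(year))
                n_drop = int(round(frac * len(idx)))
                if n_drop:
                    keep[rng.choice(idx, size=n_drop, replace=False)] = False
            df = df[keep]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------- careers

def _career(r: float, config: SimConfig, rng: np.random.Generator) -> dict:
    """Translate a latent resilience value into a lactation career.

    Shares (survival 0.45, AFC 0.15, intervals 0.15, yield 0.25) are
    chosen so d(expected LRS)/d(latent) is close to 1.
    """
    L = int(np.clip(round(3.2 + 0.45 * r / 300.0 + rng.normal(0.0, 0.6)), 1, 9))
    afc = float(np.clip(730.0 + rng.normal(0.0, 55.0) - 0.15 * r, 470.0, 1450.0))
    intervals = []
    if L > 1:
        dev = -0.15 * r / (L - 1)
        intervals = list(np.clip(
            rng.normal(config.herd_calving_interval_mean,
                       config.herd_calving_interval_sd, L - 1) + dev,
            280.0, 700.0))
    if rng.random() < 0.07:
        final_dim = float(rng.uniform(10.0, 300.0))
    else:
        final_dim = float(np.clip(rng.normal(330.0, 60.0), 110.0, 500.0))
    yield_mult = 1.0 + float(np.clip(0.25 * r / (100.0 * max(L, 2)), -0.6, 1.5))
    return {"L": L, "afc": round(afc), "intervals": [round(x) for x in intervals],
            "final_dim": round(final_dim), "yield_mult": yield_mult}


def _corrupt(name: str, rng: np.random.Generator) -> str:
    """Free-text style corruption of a product name."""
    s = name.lower()
    op = rng.integers(0, 3)
    i = int(rng.integers(0, len(s)))
    if op == 0 and len(s) > 4:          # drop a character
        s = s[:i] + s[i + 1:]
    elif op == 1:                        # substitute a character
        s = s[:i] + chr(ord('a') + int(rng.integers(0, 26))) + s[i + 1:]
    else:                                # truncate to a prefix
        s = s[: max(4, int(rng.integers(len(s) // 2, len(s))))]
    return s


def _window_exposures(thi: pd.Series, conception: pd.Timestamp) -> dict:
    out = {}
    for w, (lo, hi) in WINDOWS.items():
        vals = thi.loc[conception + lo * DAY: conception + hi * DAY]
        out[f"mean_thi_{w.lower()}"] = float(vals.mean()) if len(vals) else np.nan
    return out


def simulate_herds(config: SimConfig) -> tuple[dict, dict]:
    """Generate herd tables and ground truth.

    Returns (tables, truth); tables holds cows, calvings, milk, events,
    weather, farms, products; truth holds per-cow latent values and
    exposures, injected effect sizes, variance components and the
    pedigree.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    farms, stations = _make_farms_stations(config, rng)
    weather = simulate_weather(config, stations=stations, rng=rng)
    weather = add_thi(weather)
    farm_station = match_nearest_station(farms, stations)
    station_of = dict(zip(farm_station["farm_id"], farm_station["station_id"]))
    thi_by_station = {sid: grp.set_index("date")["thi_max"].sort_index()
                      for sid, grp in weather.groupby("station_id")}

    farm_eff = dict(zip(farms["farm_id"],
                        rng.normal(0.0, config.farm_sd, config.n_farms)))
    farm_scale = dict(zip(farms["farm_id"],
                          rng.normal(config.scale_mean, config.scale_sd_farm,
                                     config.n_farms)))
    dam_eff: dict = {}

    window_start = pd.Timestamp(year=config.start_year, month=1, day=1)
    window_end = pd.Timestamp(year=config.end_year, month=12, day=31)
    event_cats = ("mastitis", "lameness", "antimicrobial", "anti_inflammatory",
                  "vaccine")

    cows_rows, calv_rows, event_rows, truth_rows = [], [], [], []
    counter = {"n": 0}
    dam_of_cow: dict = {}

    def new_cow_id(farm):
        counter["n"] += 1
        return f"{farm}-C{counter['n']:05d}"

    def exposures_for(farm, birth_date):
        thi = thi_by_station[station_of[farm]]
        conception = birth_date - GESTATION_DAYS * DAY
        return conception, _window_exposures(thi, conception)

    def event_exposure_flags(true_events, conception):
        flags = {}
        for w, (lo, hi) in WINDOWS.items():
            lo_d, hi_d = conception + lo * DAY, conception + hi * DAY
            for cat in event_cats[:4]:
                flags[f"{cat}_{w.lower()}"] = float(any(
                    e["cat"] == cat and lo_d <= e["date"] <= hi_d
                    for e in true_events))
        return flags

    def add_cow(farm, birth_date, dam_id, granddam_id, generation,
                exposure_feats, injected):
        """Draw the latent, build the career, emit rows; returns career info."""
        cow_id = new_cow_id(farm)
        d_eff = 0.0
        if dam_id:
            if dam_id not in dam_eff:
                dam_eff[dam_id] = float(rng.normal(0.0, config.dam_sd))
            d_eff = dam_eff[dam_id]
        noise = float(rng.normal(0.0, config.noise_sd))
        latent = farm_eff[farm] + d_eff + injected + noise
        dam_of_cow[cow_id] = dam_id or ""
        career = _career(latent, config, rng)
        first_calving = birth_date + career["afc"] * DAY
        calvings = [first_calving]
        for iv in career["intervals"]:
            calvings.append(calvings[-1] + int(iv) * DAY)
        exit_date = calvings[-1] + career["final_dim"] * DAY
        cows_rows.append({
            "cow_id": cow_id, "farm_id": farm,
            "birth_date": birth_date, "dam_id": dam_id or "",
            "entry_date": birth_date, "exit_date": exit_date})
        for j, c in enumerate(calvings, start=1):
            calv_rows.append({"cow_id": cow_id, "farm_id": farm,
                              "calving_date": c, "parity": j})
        truth_rows.append({
            "cow_id": cow_id, "farm_id": farm, "dam_id": dam_id or "",
            "granddam_id": granddam_id or "", "generation": generation,
            "latent": latent, "farm_eff": farm_eff[farm], "dam_eff": d_eff,
            "injected": injected, **exposure_feats})
        return cow_id, career, calvings, exit_date

    def true_events_for(career, calvings, exit_date):
        start = calvings[0] - 30 * DAY
        span = max(1, (exit_date - start).days)
        evs = []
        for cat in event_cats:
            n = rng.poisson(config.event_rates[cat] * span)
            for off in sorted(rng.integers(0, span, size=n)):
                evs.append({"cat": cat, "date": start + int(off) * DAY,
                            "dry_cow": False})
        for j in range(len(calvings) - 1):
            if rng.random() < config.dry_cow_prob:
                d = calvings[j + 1] - (60 + int(rng.integers(-5, 6))) * DAY
                evs.append({"cat": "antimicrobial", "date": d, "dry_cow": True})
        evs.sort(key=lambda e: (e["date"], e["cat"]))
        return evs

    # --- founders ------------------------------------------------------
    herd = []   # (cow_id, farm, career, calvings, exit, true_events, generation)
    for farm in farms["farm_id"]:
        for _ in range(config.cows_per_farm):
            birth = (pd.Timestamp(year=config.start_year - 5, month=1, day=1)
                     + int(rng.integers(0, 730)) * DAY)
            cow_id, career, calvings, exit_date = add_cow(
                farm, birth, None, None, 0,
                {"mean_thi_t1": np.nan, "mean_thi_t2": np.nan,
                 "mean_thi_t3": np.nan}, 0.0)
            herd.append((cow_id, farm, career, calvings, exit_date,
                         true_events_for(career, calvings, exit_date), 0))

    # --- descendants ---------------------------------------------------
    def spawn(parent_entry, generation):
        cow_id, farm, career, calvings, exit_date, true_events, _ = parent_entry
        children = []
        for c in calvings:
            if generation == 1 and not (window_start <= c <= window_end):
                continue
            if rng.random() >= config.retention_prob:
                continue
            conception, exposure = exposures_for(farm, c)
            feats = dict(exposure)
            needed = set(config.injected_effects) - set(feats)
            if needed:
                feats.update({k: v for k, v in
                              event_exposure_flags(true_events, conception).items()
                              if k in needed})
            injected = sum(beta * ((feats.get(name, np.nan) - config.thi_reference)
                                   if name.startswith("mean_thi") else
                                   feats.get(name, 0.0))
                           for name, beta in config.injected_effects.items())
            granddam = dam_of_cow.get(cow_id) if generation == 2 else None
            child_id, child_career, child_calvings, child_exit = add_cow(
                farm, c, cow_id, granddam, generation, feats, float(injected))
            entry = (child_id, farm, child_career, child_calvings, child_exit,
                     true_events_for(child_career, child_calvings, child_exit),
                     generation)
            children.append(entry)
        return children

    gen1 = []
    for entry in list(herd):
        gen1.extend(spawn(entry, 1))
    herd.extend(gen1)
    if config.generations >= 3:
        gen2 = []
        for entry in gen1:
            gen2.extend(spawn(entry, 2))
        herd.extend(gen2)

    # --- event recording (farm-year thinning) --------------------------
    year_lo = min(e[3][0].year for e in herd) - 1
    year_hi = max(e[4].year for e in herd) + 1
    completeness = {}
    for farm in farms["farm_id"]:
        for year in range(year_lo, year_hi + 1):
            completeness[(farm, year)] = float(np.clip(
                rng.normal(config.recording_completeness_mean,
                           config.recording_completeness_sd), 0.0, 1.0))
    for cow_id, farm, career, calvings, exit_date, true_events, gen in herd:
        for ev in true_events:
            if rng.random() >= completeness[(farm, ev["date"].year)]:
                continue
            cat = ev["cat"]
            if cat in ("mastitis", "lameness"):
                event_rows.append({"cow_id": cow_id, "date": ev["date"],
                                   "event_type": cat,
                                   "raw_text": cat.capitalize()})
            else:
                pool = _DRY_COW_NAMES if ev["dry_cow"] else _BY_CATEGORY[cat]
                name = pool[int(rng.integers(0, len(pool)))]
                text = _corrupt(name, rng) if rng.random() < config.typo_prob \
                    else name
                event_rows.append({"cow_id": cow_id, "date": ev["date"],
                                   "event_type": "treatment", "raw_text": text})

    # --- milk recordings ------------------------------------------------
    milk_rows = []
    sched_start = pd.Timestamp(year=config.start_year - 5, month=1, day=1)
    max_exit = max(e[4] for e in herd)
    for farm in farms["farm_id"]:
        offs = int(rng.integers(0, 30))
        schedule = pd.date_range(sched_start + offs * DAY, max_exit, freq="30D")
        cows_on_farm = [e for e in herd if e[1] == farm]
        mast_dates = {e[0]: [ev["date"] for ev in e[5] if ev["cat"] == "mastitis"]
                      for e in cows_on_farm}
        for cow_id, _, career, calvings, exit_date, true_events, gen in cows_on_farm:
            scale = farm_scale[farm] * career["yield_mult"]
            for j, c in enumerate(calvings, start=1):
                milk_end = (calvings[j] - 60 * DAY) if j < len(calvings) else exit_date
                sel = schedule[(schedule >= c) & (schedule <= milk_end)]
                if len(sel) == 0:
                    continue
                dim = (sel - c).days.to_numpy()
                y = milkbot(dim, scale, config.ramp, config.offset, config.decay)
                y = np.clip(y * np.exp(rng.normal(0.0, 0.07, len(dim))), 0.1, 99.0)
                fat = np.clip(rng.normal(4.1, 0.7, len(dim)), 1.5, 7.5)
                prot = np.clip(rng.normal(3.35, 0.3, len(dim)), 2.2, 4.8)
                lact = np.clip(rng.normal(4.5, 0.15, len(dim)), 3.8, 5.2)
                scc = np.exp(rng.normal(np.log(80.0), 0.9, len(dim)))
                for i, d in enumerate(sel):
                    boost = any(0 <= (d - md).days <= 30 for md in mast_dates[cow_id])
                    milk_rows.append({
                        "cow_id": cow_id, "date": d,
                        "yield": round(float(y[i]), 2),
                        "fat_pct": round(float(fat[i]), 2),
                        "protein_pct": round(float(prot[i]), 2),
                        "lactose_pct": round(float(lact[i]), 2),
                        "scc": round(float(scc[i] * (6.0 if boost else 1.0)), 1)})

    tables = {
        "farms": farms,
        "cows": pd.DataFrame(cows_rows),
        "calvings": pd.DataFrame(calv_rows),
        "milk": pd.DataFrame(milk_rows),
        "events": pd.DataFrame(event_rows,
                               columns=["cow_id", "date", "event_type", "raw_text"]),
        "weather": weather,
        "products": PRODUCTS.copy(),
    }
    truth = {
        "cows": pd.DataFrame(truth_rows),
        "effects": pd.DataFrame(
            [{"feature": k, "coefficient": v}
             for k, v in config.injected_effects.items()]),
        "variance_components": pd.DataFrame([
            {"level": "farm", "sd": config.farm_sd},
            {"level": "dam", "sd": config.dam_sd},
            {"level": "residual", "sd": config.noise_sd}]),
        "pedigree": pd.DataFrame(
            [{"cow_id": r["cow_id"], "dam_id": r["dam_id"],
              "granddam_id": r["granddam_id"]} for r in truth_rows]),
    }
    return tables, truth


def write_tables(tables: dict, out_dir, truth: dict | None = None):
    """Write the table set (and optionally truth) as CSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
    if truth is not None:
        tdir = out / "truth"
        tdir.mkdir(exist_ok=True)
        for name, df in truth.items():
            df.to_csv(tdir / f"{name}.csv", index=False)
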