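"""End-to-end orchestration: simulate -> clean -> fit -> score -> features -> model.

Chains the individual stages on in-memory tables so the whole analysis
can run from one config and one seed, as the CLI and the test-suite
use it.  Each stage is the public function of its module; this file
only wires them together and carries the intermediate artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import climate, lactation, mixedmodel, records, score, synthetic, windows

__all__ = ["PipelineResult", "run_pipeline", "DEFAULT_CANDIDATES",
           "DEFAULT_SUBGROUPS", "DEFAULT_CONTINUOUS"]

DEFAULT_CANDIDATES = ["mean_thi_t1", "mean_thi_t3", "preg_cat",
                      "ancestor_lrs_centered"]
DEFAULT_SUBGROUPS: dict = {}
DEFAULT_CONTINUOUS = ["mean_thi_t1", "mean_thi_t3", "ancestor_lrs_centered"]


@dataclass
class PipelineResult:
    tables: dict
    truth: dict
    cows: pd.DataFrame
    milk: pd.DataFrame
    cow_report: object
    milk_report: object
    events: pd.DataFrame
    fits: pd.DataFrame
    lrs: pd.DataFrame
    farm_station: pd.DataFrame
    pairs: pd.DataFrame
    features: pd.DataFrame
    model: object = None
    trace: pd.DataFrame = None
    r2: tuple = None


def run_pipeline(config: synthetic.SimConfig, mode: str = "daughter",
                 candidates: list | None = None,
                 continuous: list | None = None,
                 subgroups: dict | None = None,
                 fit_model: bool = True,
                 birth_window: tuple | None = None,
                 match_threshold: float = 90.0) -> PipelineResult:
    """Run the full analysis on a freshly simulated herd.

    ``birth_window`` restricts the analysis to cows born inside it
    (dropping ancestors born earlier); by default all generations are
    kept so pedigree pairs span the whole simulation.
    """
    tables, truth = synthetic.simulate_herds(config)

    cows, cow_report = records.clean_cows(
        tables["cows"], tables["calvings"], birth_window=birth_window)
    calvings = tables["calvings"][
        tables["calvings"]["cow_id"].isin(set(cows["cow_id"]))]
    milk, milk_report = records.clean_milk(tables["milk"], cows, calvings)

    events = records.match_treatments(tables["events"], tables["products"],
                                      threshold=match_threshold)
    herd_years = records.filter_recording_herd_years(events, cows)

    fits = lactation.fit_lactations(milk)
    lrs = score.score_herd(cows, calvings, fits, milk)

    qc = climate.qc_stations(tables["weather"], mode="multi")
    ok_stations = sorted(set(qc.loc[qc["retained"], "station_id"]))
    stations = tables["weather"].drop_duplicates("station_id")[
        ["station_id", "latitude", "longitude"]]
    stations = stations[stations["station_id"].isin(ok_stations)]
    farm_station = climate.match_nearest_station(tables["farms"], stations)

    pairs = records.match_pairs(cows, calvings,
                                generation_gap=2 if mode == "granddaughter" else 1)

    lact_table = fits.merge(
        calvings.rename(columns={"parity": "lactation"})[
            ["cow_id", "farm_id", "calving_date", "lactation"]],
        on=["cow_id", "lactation"], how="left")
    features = windows.build_features(
        pairs, cows, calvings, events, milk, tables["weather"], farm_station,
        lrs, lactations=lact_table, retained_herd_years=herd_years, mode=mode)

    result = PipelineResult(
        tables=tables, truth=truth, cows=cows, milk=milk,
        cow_report=cow_report, milk_report=milk_report, events=events,
        fits=fits, lrs=lrs, farm_station=farm_station, pairs=pairs,
        features=features)

    if fit_model and len(features):
        cand = candidates or DEFAULT_CANDIDATES
        complete = features.dropna(
            subset=[c for c in cand + ["outcome_lrs"] if c in features.columns])
        model, trace = mixedmodel.forward_select(
            complete, "outcome_lrs", cand,
            grouping=("farm_id", "dam_id"),
            continuous=continuous or DEFAULT_CONTINUOUS,
            subgroups=subgroups or DEFAULT_SUBGROUPS)
        result.model = model
        result.trace = trace
        result.r2 = mixedmodel.variance_explained(model)
    return result
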