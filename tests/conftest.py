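"""Shared fixtures: reference herds with analytically known scores."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lrspipe import synthetic

MILKBOT_PARAMS = (30.0, 22.0, -1.0, 0.002)  # scale, ramp, offset, decay


def make_fits(cow_ids, n_lactations, scale_mult=None,
              params=MILKBOT_PARAMS) -> pd.DataFrame:
    """Converged lactation-fit rows with known curve parameters."""
    scale, ramp, offset, decay = params
    rows = []
    for i, cow in enumerate(cow_ids):
        mult = 1.0 if scale_mult is None else scale_mult[i]
        for j in range(1, n_lactations + 1):
            rows.append({"cow_id": cow, "lactation": j,
                         "scale": scale * mult, "ramp": ramp,
                         "offset": offset, "decay": decay,
                         "converged": True, "n_obs": 10, "rss": 0.0,
                         "yield_305": np.nan, "model": "milkbot"})
    return pd.DataFrame(rows)


def make_herd(n_cows=10, n_lactations=3, interval=400, afc=730,
              final_dim=400, first_calving="2010-01-01", farm="F01",
              scale_mult=None):
    """A herd of identical cows: every interval equal, shared curve shape.

    Such a herd has herd averages CbarInt = interval, CbarInt_j =
    interval for every transition, and a mean daily curve equal to each
    cow's own curve, so every deviation component of the LRS vanishes.
    """
    first = pd.Timestamp(first_calving)
    cows_rows, calv_rows = [], []
    for i in range(n_cows):
        cow = f"{farm}-H{i:03d}"
        calvings = [first + pd.Timedelta(days=interval * j)
                    for j in range(n_lactations)]
        cows_rows.append({
            "cow_id": cow, "farm_id": farm,
            "birth_date": first - pd.Timedelta(days=afc),
            "dam_id": "", "entry_date": first - pd.Timedelta(days=afc),
            "exit_date": calvings[-1] + pd.Timedelta(days=final_dim)})
        for j, c in enumerate(calvings, start=1):
            calv_rows.append({"cow_id": cow, "farm_id": farm,
                              "calving_date": c, "parity": j})
    cows = pd.DataFrame(cows_rows)
    calvings = pd.DataFrame(calv_rows)
    fits = make_fits(cows["cow_id"], n_lactations, scale_mult)
    return cows, calvings, fits


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated herd shared across tests (read-only)."""
    cfg = synthetic.SimConfig(n_farms=3, cows_per_farm=12, seed=11)
    tables, truth = synthetic.simulate_herds(cfg)
    return cfg, tables, truth
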