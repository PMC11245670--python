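"""Lifetime resilience score: analytic values, invariants, naive oracle."""

import numpy as np
import pandas as pd
import pytest

from lrspipe import score
from lrspipe.lactation import milkbot

from conftest import MILKBOT_PARAMS, make_fits, make_herd


def single_cow(cow_id="T-001", afc=730, intervals=(), final_dim=400,
               first_calving="2010-01-01", farm="F01", scale_mult=1.0):
    """One test cow with the shared curve shape scaled by `scale_mult`."""
    first = pd.Timestamp(first_calving)
    calvings = [first]
    for iv in intervals:
        calvings.append(calvings[-1] + pd.Timedelta(days=int(iv)))
    cows = pd.DataFrame([{
        "cow_id": cow_id, "farm_id": farm,
        "birth_date": first - pd.Timedelta(days=afc), "dam_id": "",
        "entry_date": first - pd.Timedelta(days=afc),
        "exit_date": calvings[-1] + pd.Timedelta(days=final_dim)}])
    calv = pd.DataFrame([{"cow_id": cow_id, "farm_id": farm,
                          "calving_date": c, "parity": j + 1}
                         for j, c in enumerate(calvings)])
    fits = make_fits([cow_id], len(calvings), [scale_mult])
    return cows, calv, fits


@pytest.fixture(scope="module")
def herd_avgs():
    """Averages of a herd of identical cows: interval 400, 3 lactations."""
    cows, calvings, fits = make_herd(n_cows=10, n_lactations=3, interval=400)
    return score.herd_averages(cows, calvings, fits)["F01"]


class TestAnalytic:
    def test_herd_average_cow_scores_baseline_plus_bonus(self, herd_avgs):
        # all deviation terms vanish: LRS = CbarInt + 300 * L = 400 + 300
        cows, calv, fits = single_cow(afc=730, intervals=(), final_dim=400)
        res = score.score_against(cows, calv, fits, herd_avgs)
        assert res["lrs"].iloc[0] == pytest.approx(400.0 + 300.0, abs=1e-9)

    def test_each_completed_lactation_adds_exactly_300(self, herd_avgs):
        scores = []
        for intervals in [(), (400,), (400, 400)]:
            cows, calv, fits = single_cow(intervals=intervals)
            res = score.score_against(cows, calv, fits, herd_avgs)
            scores.append(res["lrs"].iloc[0])
        assert scores[1] - scores[0] == pytest.approx(300.0, abs=1e-9)
        assert scores[2] - scores[1] == pytest.approx(300.0, abs=1e-9)

    def test_afc_component_zero_crossing_at_730(self, herd_avgs):
        comps = {}
        for afc in (600, 730, 900):
            cows, calv, fits = single_cow(afc=afc)
            res = score.score_against(cows, calv, fits, herd_avgs)
            comps[afc] = res["afc"].iloc[0]
        assert comps[730] == 0.0
        assert comps[600] == 130.0 and comps[900] == -170.0

    def test_exit_penalty_strictly_below_100_dim(self, herd_avgs):
        for dim, expected in [(99, -1.0), (100, 0.0), (150, 0.0)]:
            cows, calv, fits = single_cow(final_dim=dim)
            res = score.score_against(cows, calv, fits, herd_avgs)
            assert res["early_exit_penalty"].iloc[0] == expected

    def test_golden_hand_computed_example(self, herd_avgs):
        # AFC 700, L = 2, CInt_1 = 380 vs herd 400, yields +10% in both
        # lactations, exit at DIM 50:
        # 400 + 600 + 30 + 20 + (10 + 10) - 50 = 1020
        cows, calv, fits = single_cow(afc=700, intervals=(380,), final_dim=50,
                                      scale_mult=1.1)
        res = score.score_against(cows, calv, fits, herd_avgs)
        assert res["lrs"].iloc[0] == pytest.approx(1020.0, abs=1e-9)

    def test_lrs_equals_sum_of_components(self, herd_avgs):
        cows, calv, fits = single_cow(afc=700, intervals=(380,), final_dim=50,
                                      scale_mult=1.1)
        res = score.score_against(cows, calv, fits, herd_avgs).iloc[0]
        total = sum(res[c] for c in ["baseline", "lactation_bonus", "afc",
                                     "calving_interval", "yield",
                                     "early_exit_penalty"])
        assert res["lrs"] == pytest.approx(total, abs=1e-12)
        assert res["lactation_bonus"] == 300.0 * res["exit_lactation"]


class TestHerdAverages:
    def test_identical_cows_give_constant_averages(self):
        cows, calvings, fits = make_herd(n_cows=6, interval=400)
        avgs = score.herd_averages(cows, calvings, fits)["F01"]
        assert avgs.mean_interval == 400.0
        assert all(v == 400.0 for v in avgs.mean_interval_by_transition.values())

    def test_two_point_mean(self):
        c1, v1, f1 = single_cow("a", intervals=(380,))
        c2, v2, f2 = single_cow("b", intervals=(420,))
        cows = pd.concat([c1, c2])
        calv = pd.concat([v1, v2])
        fits = pd.concat([f1, f2])
        avgs = score.herd_averages(cows, calv, fits)["F01"]
        assert avgs.mean_interval == 400.0
        assert avgs.mean_interval_by_transition[1] == 400.0

    def test_per_transition_means_match_groupby_oracle(self):
        rng = np.random.default_rng(8)
        frames = []
        for i in range(12):
            n_int = int(rng.integers(0, 4))
            ivs = tuple(int(x) for x in rng.integers(340, 460, n_int))
            frames.append(single_cow(f"c{i}", intervals=ivs))
        cows = pd.concat(f[0] for f in frames)
        calv = pd.concat(f[1] for f in frames)
        fits = pd.concat(f[2] for f in frames)
        avgs = score.herd_averages(cows, calv, fits)["F01"]
        # independent aggregation: per-cow interval lists
        all_ints, by_j = [], {}
        for f in frames:
            dates = sorted(f[1]["calving_date"])
            for j, (a, b) in enumerate(zip(dates, dates[1:]), start=1):
                d = (b - a).days
                all_ints.append(d)
                by_j.setdefault(j, []).append(d)
        assert avgs.mean_interval == pytest.approx(np.mean(all_ints))
        for j, vals in by_j.items():
            assert avgs.mean_interval_by_transition[j] == \
                pytest.approx(np.mean(vals))

    def test_subherd_grouping_computes_averages_per_subherd(self):
        """Research-herd variant: averages per farm x feed/genetic subherd."""
        a = make_herd(n_cows=4, interval=380)
        b = make_herd(n_cows=4, interval=420)
        cows_a, calv_a, fits_a = a
        cows_b, calv_b, fits_b = b
        cows_b = cows_b.assign(cow_id=cows_b["cow_id"] + "x")
        calv_b = calv_b.assign(cow_id=calv_b["cow_id"] + "x")
        fits_b = fits_b.assign(cow_id=fits_b["cow_id"] + "x")
        cows = pd.concat([cows_a.assign(subherd="select"),
                          cows_b.assign(subherd="control")])
        calv = pd.concat([calv_a, calv_b])
        fits = pd.concat([fits_a, fits_b])
        avgs = score.herd_averages(cows, calv, fits,
                                   group_cols=("farm_id", "subherd"))
        assert avgs[("F01", "select")].mean_interval == 380.0
        assert avgs[("F01", "control")].mean_interval == 420.0
        res = score.score_herd(cows, calv, fits,
                               group_cols=("farm_id", "subherd"))
        # every cow is at its own subherd average: baseline + 3 lactations
        expect = {"select": 380.0 + 900.0, "control": 420.0 + 900.0}
        for r in res.itertuples():
            assert r.lrs == pytest.approx(expect[r.group[1]], abs=1e-9)

    def test_group_without_intervals_raises(self):
        cows, calv, fits = single_cow("solo", intervals=())
        with pytest.raises(ValueError, match="F01"):
            score.herd_averages(cows, calv, fits)

    def test_missing_fit_gives_missing_lrs_counted(self):
        cows, calvings, fits = make_herd(n_cows=5, n_lactations=2)
        # remove the lactation-2 fit of one herd cow
        broken = fits[~((fits["cow_id"] == cows["cow_id"].iloc[0])
                        & (fits["lactation"] == 2))]
        res = score.score_herd(cows, calvings, broken)
        assert res.attrs["n_missing"] == 1
        assert res["lrs"].isna().sum() == 1


class TestInvariants:
    def test_translation_in_afc_shifts_scores_by_delta(self, herd_avgs):
        cows, calv, fits = single_cow(afc=700, intervals=(380,), final_dim=200)
        base = score.score_against(cows, calv, fits, herd_avgs)["lrs"].iloc[0]
        cows2, calv2, fits2 = single_cow(afc=700 + 40, intervals=(380,),
                                         final_dim=200)
        shifted = score.score_against(cows2, calv2, fits2, herd_avgs)["lrs"].iloc[0]
        assert base - shifted == pytest.approx(40.0, abs=1e-9)

    def test_common_yield_scaling_leaves_yield_component_zero(self):
        cows, calvings, fits = make_herd(n_cows=6, n_lactations=2)
        for factor in (0.5, 2.0):
            scaled = fits.copy()
            scaled["scale"] *= factor
            res = score.score_herd(cows, calvings, scaled)
            assert np.allclose(res["yield"], 0.0, atol=1e-9)

    def test_naive_reference_implementation_agrees(self):
        """Day-by-day, cow-by-cow re-computation of the full equation."""
        rng = np.random.default_rng(42)
        frames = []
        for i in range(100):
            n_int = int(rng.integers(0, 4))
            ivs = tuple(int(x) for x in rng.integers(330, 470, n_int))
            frames.append(single_cow(
                f"c{i:03d}", afc=int(rng.integers(600, 900)), intervals=ivs,
                final_dim=int(rng.integers(30, 450)),
                scale_mult=float(rng.uniform(0.7, 1.3))))
        cows = pd.concat(f[0] for f in frames).reset_index(drop=True)
        calv = pd.concat(f[1] for f in frames).reset_index(drop=True)
        fits = pd.concat(f[2] for f in frames).reset_index(drop=True)
        got = score.score_herd(cows, calv, fits).set_index("cow_id")["lrs"]

        # ---- independent naive reference ----
        scale0, ramp, offset, decay = MILKBOT_PARAMS
        curves = {(r.cow_id, r.lactation):
                  (r.scale, r.ramp, r.offset, r.decay)
                  for r in fits.itertuples()}

        def daily(cow, j, k):
            s, rm, of, dc = curves[(cow, j)]
            return max(milkbot(float(k), s, rm, of, dc), 0.0)

        percow = {}
        for f in frames:
            cid = f[0]["cow_id"].iloc[0]
            dates = sorted(f[1]["calving_date"])
            exit_date = f[0]["exit_date"].iloc[0]
            ints = [(b - a).days for a, b in zip(dates, dates[1:])]
            end_dims = ints + [(exit_date - dates[-1]).days]
            afc = (dates[0] - f[0]["birth_date"].iloc[0]).days
            percow[cid] = dict(L=len(dates), afc=afc, ints=ints,
                               end_dims=end_dims)
        all_ints = [d for c in percow.values() for d in c["ints"]]
        cbar = np.mean(all_ints)
        cbar_j = {}
        for c in percow.values():
            for j, d in enumerate(c["ints"], start=1):
                cbar_j.setdefault(j, []).append(d)
        cbar_j = {j: np.mean(v) for j, v in cbar_j.items()}

        for cid, info in percow.items():
            expect = cbar + 300.0 * info["L"] + (730.0 - info["afc"])
            for j, d in enumerate(info["ints"], start=1):
                expect += cbar_j[j] - d
            for j, end in enumerate(info["end_dims"], start=1):
                K = int(max(305, end))
                num = sum(daily(cid, j, k) for k in range(1, K + 1))
                herd = [c2 for c2, inf2 in percow.items()
                        if len(inf2["end_dims"]) >= j]
                den = sum(np.mean([daily(c2, j, k) for c2 in herd])
                          for k in range(1, K + 1))
                expect += (num / den - 1.0) * 100.0
            expect += min(0.0, info["end_dims"][-1] - 100.0)
            assert got[cid] == pytest.approx(expect, abs=1e-9)
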