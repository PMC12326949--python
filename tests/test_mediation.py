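"""Three-step regression pathways, gating and dominance aggregation."""

import numpy as np
import pandas as pd
import pytest

from telefire.mediation import (aggregate_contributions, enumerate_pathways,
                                pathway_contribution_frame, pathway_fit,
                                per_cell_dominance)
from telefire.preprocess import FireSeason, build_samples

TIME = pd.period_range("2003-01", periods=264, freq="M")


def frame(predictor, response):
    return build_samples(response, predictor, TIME, FireSeason(7))


def chain(rng, i=4, j=6, med_noise=0.0, ba_noise=0.0):
    """TCM -> mediator (lag i) -> BA (lag j) with optional link noise."""
    tcm = rng.standard_normal(264 + 48)
    med = np.roll(tcm, i) + med_noise * rng.standard_normal(tcm.size)
    ba = np.roll(med, j) + ba_noise * rng.standard_normal(tcm.size)
    tcm, med, ba = tcm[48:], med[48:], ba[48:]
    return frame(tcm, ba), frame(med, ba)


class TestPathwayFit:
    def test_noiseless_chain_contribution_one(self, rng):
        ts, ms = chain(rng)
        fit = pathway_fit(ts.response, ts.lagged_predictor(10),
                          ms.lagged_predictor(6), i=4, j=6)
        assert fit.r1_sq == pytest.approx(1.0)
        assert fit.r2_sq == pytest.approx(1.0)
        assert fit.r3_sq == pytest.approx(1.0)
        assert fit.contribution == pytest.approx(1.0)

    def test_first_gate_blocks_when_ba_independent(self, rng):
        blocked = 0
        for _ in range(50):
            tcm, ba = rng.standard_normal(264), rng.standard_normal(264)
            med = np.roll(tcm, 4)
            fit = pathway_fit(frame(tcm, ba).response,
                              frame(tcm, ba).lagged_predictor(10),
                              frame(med, ba).lagged_predictor(6), i=4, j=6)
            if fit.p1 >= 0.05:
                blocked += 1
                assert np.isnan(fit.r2_sq)  # regressions 2-3 never run
            assert fit.contribution == 0 or fit.p1 < 0.05
        assert blocked >= 40  # ~95% expected

    def test_second_gate_blocks_disconnected_mediator(self, rng):
        """BA driven by the TCM directly; the mediator is pure noise."""
        hits = 0
        for _ in range(50):
            tcm = rng.standard_normal(264 + 48)
            ba = np.roll(tcm, 10)[48:]
            med = rng.standard_normal(264)
            fit = pathway_fit(frame(tcm[48:], ba).response,
                              frame(tcm[48:], ba).lagged_predictor(10),
                              frame(med, ba).lagged_predictor(6), i=4, j=6)
            assert fit.p1 < 0.05  # link 1 is real
            hits += fit.contribution > 0
        assert hits <= 5  # p2 gate blocks ~95%

    def test_third_gate_blocks_broken_final_link(self, rng):
        """p1 and p2 significant but the mediator is uncorrelated with BA:
        only the p3 gate can zero the contribution.  Constructed directly on
        the sample frame: BA = TCM + e, mediator = TCM - e, so
        corr(mediator, BA) = 0 while both correlate with the TCM."""
        hits = 0
        for _ in range(50):
            t = rng.standard_normal(60)
            e = rng.standard_normal(60)
            ba, med = t + e, t - e
            fit = pathway_fit(ba, t, med, i=4, j=6)
            if fit.p1 < 0.05 and np.isfinite(fit.p2) and fit.p2 < 0.05:
                hits += fit.contribution > 0
        assert hits <= 5

    def test_degenerate_variance_contribution_zero(self, rng):
        y = rng.standard_normal(264)
        ts = frame(np.ones(264), y)
        with pytest.warns(UserWarning, match="degenerate"):
            fit = pathway_fit(ts.response, ts.lagged_predictor(0),
                              ts.lagged_predictor(1))
        assert fit.contribution == 0.0


class TestEnumeration:
    @pytest.mark.parametrize("max_lag,count", [(24, 325), (0, 1), (2, 6)])
    def test_lag_pair_counts(self, rng, max_lag, count):
        ts, ms = chain(rng, med_noise=1.0, ba_noise=1.0)
        fits = enumerate_pathways(ts, ms, max_total_lag=max_lag)
        assert len(fits) == count
        pairs = [(f.i, f.j) for f in fits]
        assert pairs == sorted(pairs)
        assert all(f.i + f.j <= max_lag for f in fits)

    def test_vectorized_frame_matches_explicit_fits(self, rng):
        ts, ms = chain(rng, med_noise=1.0, ba_noise=1.0)
        fits = enumerate_pathways(ts, ms, max_total_lag=6)
        df = pathway_contribution_frame(ts, ms, max_total_lag=6)
        for fit, (_, row) in zip(fits, df.iterrows()):
            assert (fit.i, fit.j) == (row.i, row.j)
            assert fit.r1_sq == pytest.approx(row.r1_sq, abs=1e-10)
            assert fit.contribution == pytest.approx(row.contribution, abs=1e-10)

    def test_gate_soundness_and_bounds_over_all_fits(self, rng):
        ts, ms = chain(rng, med_noise=1.2, ba_noise=1.2)
        df = pathway_contribution_frame(ts, ms)
        assert ((df.contribution >= 0) & (df.contribution <= 1)).all()
        nz = df[df.contribution > 0]
        assert ((nz.p1 < 0.05) & (nz.p2 < 0.05) & (nz.p3 < 0.05)).all()

    def test_planted_lag_pair_is_argmax(self, rng):
        ts, ms = chain(rng, med_noise=1.0, ba_noise=1.0)
        df = pathway_contribution_frame(ts, ms)
        best = df.loc[df.contribution.idxmax()]
        assert best.i + best.j == 10


class TestAggregation:
    def _fits(self, contribs):
        rows = []
        for (cell, tcm, med), c in contribs.items():
            rows.append({"region_id": 1, "cell": cell, "tcm": tcm,
                         "mediator": med, "i": 0, "j": 0, "contribution": c})
        return pd.DataFrame(rows)

    def test_single_fuel_pathway_dominates(self):
        fits = self._fits({(0, "ENSO", "SM"): 0.8, (0, "ENSO", "VPD"): 0.1,
                           (1, "ENSO", "SM"): 0.7})
        table = aggregate_contributions(fits)
        dom = table.dominance.set_index("tcm").loc["ENSO"]
        assert dom.dominant_mediator == "SM"
        assert dom.dominant_group_sum == "fuel"
        fr = table.by_mediator.query("tcm == 'ENSO' and mediator == 'SM'")["fraction"]
        assert float(fr.iloc[0]) == pytest.approx(1.5 / 1.6)

    def test_fractions_sum_to_one_and_group_sum_ge_max(self, rng):
        meds = ["Tmax", "ET0", "VPD", "Wind", "NDVI", "EVI", "FPAR", "SM"]
        fits = self._fits({(c, t, m): rng.random()
                           for c in range(3) for t in ("ENSO", "IOD") for m in meds})
        table = aggregate_contributions(fits)
        sums = table.by_mediator.groupby(["region_id", "tcm"])["fraction"].sum()
        assert np.allclose(sums, 1.0)
        assert (table.by_group.group_sum >= table.by_group.group_max - 1e-12).all()

    def test_equal_pathways_tie_reported(self):
        fits = self._fits({(0, "ENSO", "VPD"): 0.5, (0, "ENSO", "SM"): 0.5})
        table = aggregate_contributions(fits)
        assert bool(table.dominance.iloc[0].group_tie)

    def test_zero_total_flagged_undefined(self):
        fits = self._fits({(0, "ENSO", "SM"): 0.0})
        table = aggregate_contributions(fits)
        assert table.by_mediator["undefined"].all()
        assert table.dominance.iloc[0].dominant_mediator is None

    def test_mediator_relabeling_permutes_rows(self):
        fits = self._fits({(0, "ENSO", "SM"): 0.3, (0, "ENSO", "VPD"): 0.6})
        swapped = fits.copy()
        swapped["mediator"] = swapped["mediator"].map({"SM": "VPD", "VPD": "SM"})
        def contribs(f):
            bm = aggregate_contributions(f).by_mediator
            bm = bm[bm.tcm == "ENSO"]
            return bm.set_index("mediator")["contribution"].to_dict()

        a, b = contribs(fits), contribs(swapped)
        assert a["SM"] == b["VPD"] and a["VPD"] == b["SM"]

    def test_all_tcm_aggregate_present(self):
        fits = self._fits({(0, "ENSO", "SM"): 0.3, (0, "IOD", "SM"): 0.2})
        table = aggregate_contributions(fits)
        allrow = table.by_mediator.query("tcm == 'All' and mediator == 'SM'")
        assert float(allrow["contribution"].iloc[0]) == pytest.approx(0.5)


class TestPerCellDominance:
    def test_planted_fuel_region_all_fuel_dominant(self):
        rows = [{"cell": c, "mediator": m, "contribution": 0.6 if m == "SM" else 0.05}
                for c in range(5) for m in ("SM", "NDVI", "VPD", "Tmax")]
        dom = per_cell_dominance(pd.DataFrame(rows))
        assert (dom.dominant_group_sum == "fuel").all()
        assert (dom.dominant_group_max == "fuel").all()
        assert dom.rules_agree.all()

    def test_all_zero_cells_unclassified(self):
        rows = [{"cell": 0, "mediator": "SM", "contribution": 0.0}]
        dom = per_cell_dominance(pd.DataFrame(rows))
        assert dom.iloc[0].dominant_group_sum is None

    def test_stronger_weather_pathway_wins_both_rules(self):
        rows = [{"cell": 0, "mediator": "VPD", "contribution": 0.8},
                {"cell": 0, "mediator": "SM", "contribution": 0.4}]
        dom = per_cell_dominance(pd.DataFrame(rows))
        assert dom.iloc[0].dominant_group_sum == "weather"
        assert dom.iloc[0].dominant_group_max == "weather"
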