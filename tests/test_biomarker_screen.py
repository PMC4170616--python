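"""Optimal-cutpoint scan, panel screening, consensus and Cox reduction."""

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test as ll_logrank

from gliostrat import (
    CohortSpec,
    GenePanel,
    SurvivalData,
    backward_eliminate,
    consensus_probes,
    dichotomize,
    generate_cohort,
    miller_siegmund,
    optimal_cutpoint,
    screen_probes,
)
from gliostrat.biomarker_screen import ScreenResult, logrank_scan

from conftest import make_dataset


def planted_step_data(seed, n=300, hazard_ratio=4.0, threshold=5.0):
    """Expression uniform on (0,10); hazard multiplied above the threshold."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, 10.0, size=n)
    rate = 0.01 * np.where(x > threshold, hazard_ratio, 1.0)
    t = rng.exponential(1.0 / rate)
    c = rng.exponential(1.0 / 0.004, size=n)
    data = SurvivalData(np.maximum(np.minimum(t, c), 1e-9), (t <= c).astype(int))
    return x, data


class TestOptimalCutpoint:
    def test_matches_brute_force_lifelines_scan(self, toy_survival):
        rng = np.random.default_rng(21)
        x = rng.normal(size=50)
        res = optimal_cutpoint(x, toy_survival)
        lo, hi = np.quantile(x, (0.1, 0.9))
        best = -1.0
        for c in np.unique(x[(x >= lo) & (x <= hi)]):
            grp = x > c
            if grp.all() or not grp.any():
                continue
            r = ll_logrank(
                toy_survival.time[~grp], toy_survival.time[grp],
                toy_survival.event[~grp], toy_survival.event[grp],
            )
            best = max(best, float(r.test_statistic))
        assert res.chi_square == pytest.approx(best, rel=1e-9)

    def test_planted_threshold_recovered(self):
        hits = 0
        for seed in range(20):
            x, data = planted_step_data(seed)
            res = optimal_cutpoint(x, data)
            hits += 4.5 < res.cutpoint < 5.5
            assert res.direction == "high"
        assert hits >= 16

    def test_corrected_p_stochastically_larger_than_raw(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=80)
            t = rng.exponential(100.0, size=80)
            data = SurvivalData(t, np.ones(80, dtype=int))
            res = optimal_cutpoint(x, data)
            assert res.p_corrected >= res.p_value

    def test_monotone_transform_preserves_split(self, toy_survival):
        rng = np.random.default_rng(22)
        x = rng.normal(size=50)
        res_raw = optimal_cutpoint(x, toy_survival)
        res_exp = optimal_cutpoint(np.exp(x), toy_survival)
        np.testing.assert_array_equal(x > res_raw.cutpoint, np.exp(x) > res_exp.cutpoint)
        assert res_exp.chi_square == pytest.approx(res_raw.chi_square)

    def test_constant_expression_rejected(self, toy_survival):
        with pytest.raises(ValueError, match="constant"):
            optimal_cutpoint(np.ones(50), toy_survival)

    def test_too_few_samples_rejected(self):
        data = SurvivalData(np.arange(1.0, 6.0), np.ones(5, dtype=int))
        with pytest.raises(ValueError):
            optimal_cutpoint(np.arange(5.0), data)

    def test_miller_siegmund_bounds(self):
        assert miller_siegmund(1e-6) < 1e-3
        assert 0.9 <= miller_siegmund(0.9) <= 1.0
        assert miller_siegmund(0.01) > 0.01


class TestLogrankScan:
    def test_cutpoint_interior_and_groups_nonempty(self, toy_survival):
        rng = np.random.default_rng(30)
        x = rng.normal(size=50)
        cands, chi, _ = logrank_scan(x, toy_survival)
        assert np.all(cands < x.max())
        assert np.all(chi >= 0)


class TestScreenProbes:
    def test_empty_panel_gives_empty_result(self, toy_survival):
        ds = make_dataset(np.random.default_rng(0).normal(size=(3, 50)))
        result = screen_probes(ds, toy_survival, GenePanel({"G": ["zzz"]}))
        assert len(result.table) == 0
        assert result.significant_probes == []

    def test_constant_probe_skipped_and_recorded(self, toy_survival):
        vals = np.vstack([np.ones(50), np.random.default_rng(1).normal(size=50)])
        ds = make_dataset(vals, probes=["flat", "ok"])
        result = screen_probes(ds, toy_survival)
        assert "flat" in result.failures
        assert list(result.table["probe_id"]) == ["ok"]

    def test_planted_probes_detected(self):
        # 3 strongly prognostic probes among 27 null at n=400
        found = 0
        for seed in range(5):
            spec = CohortSpec(
                n_samples=400, n_probes=30,
                prognostic_effects={f"probe_0000{i}": 1.0 for i in range(3)},
                censoring_rate=0.2, seed=seed,
            )
            cohort = generate_cohort(spec)
            res = screen_probes(cohort.expression, cohort.survival)
            found += sum(
                f"probe_0000{i}" in res.significant_probes for i in range(3)
            )
        assert found >= 12  # >= 80% of the 15 planted probe-instances

    def test_bh_significant_subset_of_raw(self, small_cohort):
        res = screen_probes(small_cohort.expression, small_cohort.survival)
        sig = res.table["p_adjusted"] <= 0.05
        assert np.all(res.table.loc[sig, "p_corrected"] <= 0.05)


class TestConsensus:
    def _screen(self, rows):
        table = pd.DataFrame(
            rows,
            columns=["probe_id", "gene", "cutpoint", "direction", "chi_square",
                     "p_value", "p_corrected", "p_adjusted"],
        )
        return ScreenResult(table=table, alpha=0.05)

    def test_significant_in_one_only_excluded(self):
        a = self._screen([("p1", "G", 1.0, "high", 9.0, 0.002, 0.01, 0.01)])
        b = self._screen([("p1", "G", 1.2, "high", 1.0, 0.3, 0.5, 0.5)])
        assert consensus_probes(a, b) == []

    def test_discordant_direction_excluded(self):
        a = self._screen([("p1", "G", 1.0, "high", 9.0, 0.002, 0.01, 0.01)])
        b = self._screen([("p1", "G", 1.2, "low", 9.0, 0.002, 0.01, 0.01)])
        assert consensus_probes(a, b) == []

    def test_concordant_significant_retained(self):
        a = self._screen([("p1", "G", 1.0, "low", 9.0, 0.002, 0.01, 0.01)])
        b = self._screen([("p1", "G", 1.2, "low", 9.0, 0.002, 0.01, 0.01)])
        assert consensus_probes(a, b) == ["p1"]


class TestBackwardEliminate:
    def _cohort_pair(self, seed, effects, n=400, n_probes=6):
        out = []
        for s in (seed, seed + 1000):
            spec = CohortSpec(
                n_samples=n, n_probes=n_probes, prognostic_effects=effects,
                censoring_rate=0.2, seed=s,
            )
            cohort = generate_cohort(spec)
            cuts = {
                p: float(np.median(cohort.expression.probe_values(p)))
                for p in cohort.expression.probe_ids
            }
            out.append((dichotomize(cohort.expression, cuts), cohort.survival))
        return out

    def test_strong_probes_are_fixed_point(self):
        effects = {"probe_00000": 1.0, "probe_00001": -1.0}
        cohorts = self._cohort_pair(1, effects, n=500, n_probes=2)
        res = backward_eliminate(cohorts, ["probe_00000", "probe_00001"])
        assert sorted(res.final_probes) == ["probe_00000", "probe_00001"]
        assert not res.empty

    def test_planted_probes_recovered_exactly(self):
        effects = {"probe_00000": 0.7, "probe_00001": 0.7}
        exact = 0
        for seed in range(10):
            cohorts = self._cohort_pair(seed, effects)
            res = backward_eliminate(cohorts, [f"probe_0000{i}" for i in range(6)])
            exact += sorted(res.final_probes) == ["probe_00000", "probe_00001"]
        assert exact >= 8

    def test_pure_noise_returns_empty_with_flag(self):
        cohorts = self._cohort_pair(5, {}, n=200, n_probes=4)
        res = backward_eliminate(cohorts, [f"probe_0000{i}" for i in range(4)], alpha=1e-6)
        assert res.empty and res.final_probes == []

    def test_terminates_within_probe_count_rounds(self):
        cohorts = self._cohort_pair(6, {}, n=200, n_probes=5)
        res = backward_eliminate(cohorts, [f"probe_0000{i}" for i in range(5)])
        assert len(res.history) <= 2 * 5  # two cohorts, <= n_probes rounds each

    def test_requires_probes(self):
        with pytest.raises(ValueError):
            backward_eliminate([], [])
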