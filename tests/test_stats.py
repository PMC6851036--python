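"""Cohort statistics: summaries, signed-rank test, correlation."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import organmorph as om
from organmorph.errors import (
    PairingError,
    SampleSizeError,
    UndefinedStatisticError,
)


class TestSummarise:
    def test_worked_example(self):
        s = om.summarise([1, 2, 3, 4, 5])
        assert s.mean == 3 and s.median == 3
        assert s.q1 == 2 and s.q3 == 4
        assert s.sd == pytest.approx(np.sqrt(2.5))
        assert s.whisker_low == 1 and s.whisker_high == 5

    def test_constant_list(self):
        s = om.summarise([7.0] * 5)
        assert s.sd == 0 and s.q1 == s.median == s.q3 == 7.0

    def test_outlier_excluded_from_whiskers(self):
        s = om.summarise([1, 2, 3, 4, 100])
        assert s.whisker_high == 4

    def test_too_small(self):
        with pytest.raises(SampleSizeError):
            om.summarise([1.0])


class TestWilcoxon:
    def test_enumeration_oracle_small(self):
        # full 2^3 sign enumeration: W distribution over {0..6}, P(W>=6)=1/8
        w, p = om.wilcoxon_signed_rank([1, 2, 3])
        assert w == 6.0
        assert p == pytest.approx(0.25)

    def test_sign_symmetry(self):
        w, p = om.wilcoxon_signed_rank([-1, -2, -3])
        assert w == 0.0
        assert p == pytest.approx(0.25)

    def test_matches_full_enumeration_with_ties(self):
        d = np.array([1.0, 1.0, -2.0, 3.0, 3.0])
        ranks = sps.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        stats = []
        for signs in itertools.product([1, -1], repeat=len(d)):
            stats.append(ranks[np.array(signs) > 0].sum())
        stats = np.array(stats)
        lower = np.mean(stats <= w_obs)
        upper = np.mean(stats >= w_obs)
        expected_p = min(1.0, 2 * min(lower, upper))
        w, p = om.wilcoxon_signed_rank(d)
        assert w == w_obs
        assert p == pytest.approx(expected_p, rel=1e-12)

    def test_zero_differences_dropped(self):
        w_a, p_a = om.wilcoxon_signed_rank([0.0, 1.0, 2.0, 3.0, 0.0])
        w_b, p_b = om.wilcoxon_signed_rank([1.0, 2.0, 3.0])
        assert (w_a, p_a) == (w_b, p_b)

    def test_all_zero_degenerate(self):
        with pytest.raises(UndefinedStatisticError):
            om.wilcoxon_signed_rank([0.0, 0.0])

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(5)
        for n in (8, 15, 25):
            d = rng.normal(0.4, 1.0, n)
            _, p = om.wilcoxon_signed_rank(d)
            assert p == pytest.approx(
                sps.wilcoxon(d, correction=True).pvalue, rel=1e-6
            )

    def test_large_sample_tail(self):
        d = np.abs(np.random.default_rng(0).normal(1, 1, 30)) + 0.01
        w, p = om.wilcoxon_signed_rank(d)
        assert w == 30 * 31 / 2
        assert p < 0.0001

    def test_exact_and_normal_agree_at_switch_point(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            d25 = rng.normal(0.2, 1.0, 25)
            _, p_exact = om.wilcoxon_signed_rank(d25)
            d26 = np.append(d25, 1e-12)  # push past the exact cutoff
            _, p_normal = om.wilcoxon_signed_rank(d26)
            assert abs(p_exact - p_normal) < 0.02


class TestCorrelate:
    def test_pearson_formula_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        r, p = om.correlate(x, y, "pearson")
        xc, yc = x - x.mean(), y - y.mean()
        r_direct = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert r == pytest.approx(r_direct, rel=1e-12)
        assert p == pytest.approx(sps.pearsonr(x, y).pvalue, rel=1e-9)

    def test_perfect_correlation(self):
        x = np.arange(5.0)
        r, p = om.correlate(x, x, "pearson")
        assert r == 1.0 and p == 0.0

    def test_spearman_on_monotone_relation(self):
        radii = np.linspace(10, 30, 6)
        volumes = 4 / 3 * np.pi * radii**3
        curvatures = 1.0 / radii
        rho, _ = om.correlate(volumes, curvatures, "spearman")
        assert rho == -1.0

    def test_spearman_monotone_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        rho, p = om.correlate(x, y, "spearman")
        rho2, p2 = om.correlate(np.exp(x), y**3, "spearman")
        assert rho2 == pytest.approx(rho, rel=1e-12)
        assert p2 == pytest.approx(p, rel=1e-12)

    def test_spearman_exact_permutation_small_n(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 5])
        rho, p = om.correlate(x, y, "spearman")
        # brute-force permutation null over all 5! rankings
        xr = sps.rankdata(x)
        yr = sps.rankdata(y)
        xc = xr - xr.mean()
        rhos = []
        for perm in itertools.permutations(yr):
            yc = np.asarray(perm) - np.mean(perm)
            rhos.append((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))
        expected = np.mean(np.abs(rhos) >= abs(rho) - 1e-12)
        assert p == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            om.correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], "pearson")

    def test_type_one_error_calibration(self):
        # null replicates: independent features, alpha = 5%
        rng = np.random.default_rng(123)
        rejections = 0
        reps = 400
        for _ in range(reps):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            _, p = om.correlate(x, y, "pearson")
            rejections += p < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.025)


class TestAnalyseCohort:
    @staticmethod
    def _table(n=12, seed=0, sources=("truth",)):
        rng = np.random.default_rng(seed)
        rows = []
        for source in sources:
            radii = rng.uniform(15, 45, n)
            for i, r in enumerate(radii):
                rows.append(
                    {
                        "case_id": f"case_{i:03d}",
                        "source": source,
                        "volume_cm3": 4 / 3 * np.pi * r**3 / 1000,
                        "global_curvature_per_mm": 1.0 / r + rng.normal(0, 1e-4),
                    }
                )
        return pd.DataFrame(rows)

    def test_report_structure_and_negative_correlation(self):
        report = om.analyse_cohort(self._table(n=20, seed=1))
        assert set(report) == {"summaries", "correlations", "wilcoxon"}
        corr = report["correlations"]["truth"]
        assert corr["spearman"]["r"] < 0
        assert corr["spearman"]["p"] < 0.0001

    def test_identical_sources_reported_degenerate(self):
        t = self._table(n=8, seed=2)
        p = t.copy()
        p["source"] = "predicted"
        report = om.analyse_cohort(pd.concat([t, p], ignore_index=True))
        key = "predicted_vs_truth_volume_cm3"
        assert report["wilcoxon"][key] == {"degenerate": True}

    def test_too_few_cases(self):
        with pytest.raises(SampleSizeError):
            om.analyse_cohort(self._table(n=2, seed=3))

    def test_unmatched_case_ids(self):
        t = self._table(n=5, seed=4)
        p = self._table(n=5, seed=5)
        p["source"] = "predicted"
        p.loc[0, "case_id"] = "case_999"
        with pytest.raises(PairingError):
            om.analyse_cohort(pd.concat([t, p], ignore_index=True))
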