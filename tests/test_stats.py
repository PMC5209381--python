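"""Group comparisons, bootstrap spectral bands, and weight correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sst

import pupcalls as pc
from pupcalls.stats import (
    aggregate,
    benjamini_hochberg,
    bootstrap_spectra,
    compare_groups,
    per_call_comparison,
    ttest_two_tailed,
    weight_correlation,
)
from pupcalls.synth import draw_animal


class TestTTest:
    def test_identical_groups(self):
        res = ttest_two_tailed([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.t == 0.0
        assert res.p == 1.0

    def test_hand_computed_pooled_t(self):
        # oracle by hand: pooled s^2 = 1, t = (2-5)/sqrt(2/3) = -3.674
        res = ttest_two_tailed([1, 2, 3], [4, 5, 6])
        assert res.t == pytest.approx(-3.674, abs=0.001)
        assert res.df == 4
        assert res.p == pytest.approx(0.0214, abs=0.0005)

    def test_reported_summary_cross_check(self):
        # groups constructed to the reported P8 intra-bout pause moments:
        # 0.133 +/- 0.002 SEM (n=41) vs 0.144 +/- 0.003 SEM (n=15)
        rng = np.random.default_rng(0)

        def matched(n, mean, sem):
            z = rng.standard_normal(n)
            z = (z - z.mean()) / z.std(ddof=1)
            return mean + sem * np.sqrt(n) * z

        res = ttest_two_tailed(matched(41, 0.133, 0.002), matched(15, 0.144, 0.003))
        assert abs(res.t) == pytest.approx(2.841, abs=0.3)

    def test_group_swap_flips_sign(self):
        a, b = [1.0, 2.0, 4.0], [3.0, 5.0, 6.0]
        assert ttest_two_tailed(a, b).t == pytest.approx(-ttest_two_tailed(b, a).t)

    def test_matches_permutation_test(self):
        # oracle equivalence: pooled t two-tailed p ~ permutation p on small groups
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 1.0, 6)
        b = rng.normal(1.2, 1.0, 6)
        res = ttest_two_tailed(a, b)
        perm = sst.permutation_test(
            (a, b),
            lambda x, y, axis=-1: np.mean(x, axis=axis) - np.mean(y, axis=axis),
            permutation_type="independent",
            n_resamples=5000,
            alternative="two-sided",
            rng=2,
        )
        assert res.p == pytest.approx(perm.pvalue, abs=0.03)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            ttest_two_tailed([1.0], [2.0, 3.0])


class TestPerCallComparison:
    def test_identical_calls_zero_width_ci(self):
        res = per_call_comparison([2.0, 2.0, 2.0], [1.0, 3.0, 2.0])
        assert res.ci_a == (2.0, 2.0)

    def test_ci_matches_t_interval(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = per_call_comparison(x, [0.0, 1.0, 2.0])
        lo, hi = sst.t.interval(0.95, 3, loc=np.mean(x), scale=sst.sem(x))
        assert res.ci_a == pytest.approx((lo, hi))

    def test_detects_duration_effect_at_call_level(self, wt8, ko8):
        # per-call analysis has high n; the configured duration difference must
        # reach significance in nearly every simulated cohort
        rng = np.random.default_rng(3)
        hits = 0
        runs = 20
        for _ in range(runs):
            a = rng.normal(wt8.mean_call_duration, 0.013, 800)
            b = rng.normal(ko8.mean_call_duration, 0.013, 300)
            if per_call_comparison(a, b).test.p < 0.05:
                hits += 1
        assert hits >= int(0.95 * runs)


class TestBootstrapSpectra:
    def _groups(self, rng, n=8, bins=40, offset=0.0, band=None):
        base = np.linspace(1.0, 2.0, bins)
        a = base + rng.normal(0, 0.05, (n, bins))
        b = base + rng.normal(0, 0.05, (n, bins)) + offset
        if band is not None:
            b[:, band] -= 1.0
        return {"WT": a, "KO": b}

    def test_identical_subjects_zero_width(self):
        spectra = np.tile(np.linspace(1, 2, 10), (5, 1))
        band = bootstrap_spectra({"A": spectra, "B": spectra}, np.arange(10), reps=200, seed=0)
        assert np.allclose(band.lower["A"], band.upper["A"])
        assert not band.significant.any()

    def test_isolated_significant_bin_suppressed(self):
        rng = np.random.default_rng(4)
        groups = self._groups(rng, band=slice(20, 21))  # single deviant bin
        band = bootstrap_spectra(groups, np.arange(40), reps=500, seed=1)
        assert band.significant[20]
        assert not band.significant_adjacent[20]

    def test_attenuated_band_detected_contiguously(self):
        rng = np.random.default_rng(5)
        groups = self._groups(rng, band=slice(25, 33))
        band = bootstrap_spectra(groups, np.arange(40), reps=500, seed=1)
        assert band.significant_adjacent[26:32].all()
        assert not band.significant_adjacent[:20].any()

    def test_seed_stability_of_ci_endpoints(self):
        rng = np.random.default_rng(6)
        groups = self._groups(rng, n=20)
        b1 = bootstrap_spectra(groups, np.arange(40), reps=1000, seed=1)
        b2 = bootstrap_spectra(groups, np.arange(40), reps=1000, seed=2)
        rel = np.abs(b1.lower["WT"] - b2.lower["WT"]) / np.abs(b1.mean["WT"])
        assert np.max(rel) < 0.01

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="subjects"):
            bootstrap_spectra(
                {"A": np.ones((2, 5)), "B": np.ones((5, 5))}, np.arange(5), reps=10
            )


class TestAggregate:
    def test_inclusion_rule_applied(self):
        rows = [
            {"animal_id": "a", "genotype": "WT", "day": 8, "n_calls": 9},
            {"animal_id": "b", "genotype": "WT", "day": 8, "n_calls": 10},
        ]
        out = aggregate(rows)
        assert list(out["animal_id"]) == ["b"]

    def test_missing_stage_named(self):
        with pytest.raises(ValueError, match="n_calls"):
            aggregate([{"animal_id": "a"}])

    def test_compare_groups_table_shape(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(
            {
                "genotype": ["WT"] * 10 + ["KO"] * 8,
                "day": 8,
                "n_calls": 300,
                "call_duration": np.r_[rng.normal(0.052, 0.01, 10), rng.normal(0.046, 0.01, 8)],
            }
        )
        out = compare_groups(df, ["call_duration"], day=8)
        assert len(out) == 1
        assert out.loc[0, "n_a"] == 10 and out.loc[0, "n_b"] == 8
        assert 0 <= out.loc[0, "p"] <= 1


class TestWeightCorrelation:
    def _summary(self, weights, metric):
        return pd.DataFrame(
            {"genotype": "WT", "day": 8, "weight": weights, "metric": metric}
        )

    def test_weight_against_itself(self):
        w = np.arange(10, dtype=float)
        df = self._summary(w, w)
        r, p = weight_correlation(df, "metric")
        assert r == pytest.approx(1.0)

    def test_constant_metric_rejected(self):
        df = self._summary(np.arange(5, dtype=float), np.ones(5))
        with pytest.raises(ValueError, match="constant"):
            weight_correlation(df, "metric")

    def test_independent_null_small_r(self):
        rng = np.random.default_rng(8)
        df = self._summary(rng.normal(4.3, 0.7, 40), rng.normal(0.13, 0.01, 40))
        r, p = weight_correlation(df, "metric")
        assert abs(r) < 0.35  # null at n=40: |r| beyond this is ~2.2 sigma

    def test_configured_weight_pause_coupling_recovered(self, wt8):
        import dataclasses

        coupled = dataclasses.replace(wt8, pause_weight_corr=0.8)
        rng = np.random.default_rng(9)
        animals = [draw_animal(coupled, rng) for _ in range(120)]
        df = self._summary(
            [a.weight for a in animals], [a.intra_pause_mean for a in animals]
        )
        r, p = weight_correlation(df, "metric")
        assert r < -0.5
        assert p < 1e-3


class TestBenjaminiHochberg:
    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(10)
        p = rng.uniform(0, 1, 25)
        ours = benjamini_hochberg(p)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(ours, ref)
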