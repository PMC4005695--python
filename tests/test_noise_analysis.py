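import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from seq2abundance.noise_analysis import (
    NoiseRecord,
    bh_fdr,
    coefficient_of_variation,
    correlation_report,
    make_noise_records,
    mann_whitney,
    noise_differential,
    partial_correlation,
    quartile_noise_groups,
    significance_stars,
)

from conftest import exact_mw_p


class TestCoV:
    def test_direct_formula(self):
        assert coefficient_of_variation(4.0, 4.0) == 0.5

    def test_zero_variance(self):
        assert coefficient_of_variation(10.0, 0.0) == 0.0

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            coefficient_of_variation(0.0, 1.0)


def records_from(means, covs):
    return make_noise_records(
        [f"g{i}" for i in range(len(means))], means, covs=covs
    )


class TestNoiseDifferential:
    def test_constant_cov_gives_zero(self):
        recs = records_from(np.arange(1.0, 21.0), [0.7] * 20)
        out = noise_differential(recs, window=5)
        assert all(r.noise_differential == 0 for r in out)

    def test_hand_median(self):
        recs = records_from([1, 2, 3, 4, 5], [0.5, 0.5, 0.9, 0.5, 0.5])
        out = noise_differential(recs, window=5)
        nds = [r.noise_differential for r in out]
        assert nds == pytest.approx([0, 0, 0.4, 0, 0])

    def test_input_order_preserved(self):
        recs = records_from([5, 1, 3, 2, 4], [0.5] * 5)
        out = noise_differential(recs, window=3)
        assert [r.gene_id for r in out] == [r.gene_id for r in recs]

    def test_planted_offsets_recovered(self):
        """CoV = sqrt(1/mu) exactly plus delta on 10% of genes: the noise
        differential recovers delta and nulls stay near zero."""
        for seed in (1, 2, 3, 4, 5):
            rng = np.random.default_rng(seed)
            n = 1000
            mu = 10 ** rng.uniform(0, 4, n)
            delta = np.zeros(n)
            planted = rng.choice(n, size=100, replace=False)
            delta[planted] = 0.3
            cov = np.sqrt(1.0 / mu) + delta
            out = noise_differential(records_from(mu, cov), window=51)
            nd = np.array([r.noise_differential for r in out])
            assert abs(nd[planted].mean() - 0.3) < 0.05
            nulls = np.setdiff1d(np.arange(n), planted)
            assert np.median(np.abs(nd[nulls])) < 0.02

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            noise_differential(records_from([1, 2, 3, 4], [1] * 4), window=4)


class TestQuartileGroups:
    def test_octile_split(self):
        recs = [
            NoiseRecord(f"g{i}", 1.0, 1.0, 1.0, float(i)) for i in range(1, 9)
        ]
        labels = quartile_noise_groups(recs)
        assert list(labels[:2]) == ["low_nd"] * 2
        assert list(labels[-2:]) == ["high_nd"] * 2

    def test_all_equal_all_mid(self):
        recs = [NoiseRecord(f"g{i}", 1.0, 1.0, 1.0, 0.5) for i in range(8)]
        assert set(quartile_noise_groups(recs)) == {"mid"}


class TestMannWhitney:
    def test_worked_exact_example(self):
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(2 / 6)

    def test_identical_samples(self):
        a = [1.0, 2.0, 3.0]
        u, p = mann_whitney(a, a)
        assert u == len(a) ** 2 / 2
        assert p == 1.0

    def test_exact_path_matches_independent_oracle(self):
        rng = np.random.default_rng(14)
        for _ in range(15):
            n1 = int(rng.integers(1, 6))
            n2 = int(rng.integers(1, 13 - n1))
            a = rng.normal(size=n1)
            b = rng.normal(size=n2) + rng.normal()
            _, p = mann_whitney(a, b)
            assert p == pytest.approx(exact_mw_p(a, b), abs=1e-12)

    def test_large_sample_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(21)
        a = rng.normal(size=40)
        b = rng.normal(0.5, 1, size=35)
        _, p = mann_whitney(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(1, 10, size=20)
        b = rng.uniform(2, 12, size=18)
        u1, p1 = mann_whitney(a, b)
        u2, p2 = mann_whitney(np.log(a), np.log(b))
        assert u1 == u2 and p1 == p2

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestPartialCorrelation:
    def test_uncorrelated_control_reduces_to_plain_r(self):
        n = 400
        rng = np.random.default_rng(9)
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        # control constructed orthogonal to both x and y
        z = rng.normal(size=n)
        z -= np.polyval(np.polyfit(x, z, 1), x)
        z -= np.polyval(np.polyfit(y, z, 1), y)
        r, _ = partial_correlation(x, y, z)
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=0.02)

    def test_degenerate_control_returns_zero(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        r, p = partial_correlation(x, y, x)
        assert r == 0.0

    def test_matches_residual_regression_oracle(self):
        rng = np.random.default_rng(30)
        for method in ("pearson", "spearman"):
            x = rng.normal(size=50)
            y = 0.4 * x + rng.normal(size=50)
            z = 0.5 * x + rng.normal(size=50)
            if method == "spearman":
                xs, ys, zs = (sps.rankdata(v) for v in (x, y, z))
            else:
                xs, ys, zs = x, y, z
            rx = xs - np.polyval(np.polyfit(zs, xs, 1), zs)
            ry = ys - np.polyval(np.polyfit(zs, ys, 1), zs)
            oracle = np.corrcoef(rx, ry)[0, 1]
            r, _ = partial_correlation(x, y, z, method=method)
            assert r == pytest.approx(oracle, abs=1e-10)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        x, y, z = rng.normal(size=(3, 20))
        r1, p1 = partial_correlation(x, y, z)
        r2, p2 = partial_correlation(y, x, z)
        assert r1 == pytest.approx(r2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            partial_correlation([1, 2, 3, 4], [1, 2, 3, 4], [1, 2, 3])


class TestBHFDR:
    def test_hand_triple(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.1]), [0.03, 0.03, 0.1])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.37])[0] == 0.37

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=30)
        assert np.all(bh_fdr(p) >= p - 1e-15)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        p = rng.uniform(size=25)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_fdr(p), ref)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_order_preserving_and_bounded(self, ps):
        p = np.asarray(ps)
        adj = bh_fdr(p)
        assert np.all((adj >= 0) & (adj <= 1))
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


def test_significance_stars_thresholds():
    assert significance_stars(0.2) == ""
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.009) == "**"
    assert significance_stars(0.0005) == "***"


def test_correlation_report_shape(small_bundle):
    import pandas as pd

    df = small_bundle.feature_table.data
    X = df[["cai", "sd_best_score", "tir_fold_dg"]]
    y = small_bundle.response
    rep = correlation_report(X, y, df["mrna_level"])
    assert set(rep.columns) >= {"r", "partial_r", "p_adj", "stars"}
    assert len(rep) == 3
    assert (rep["p_adj"] >= rep["p"] - 1e-15).all()
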