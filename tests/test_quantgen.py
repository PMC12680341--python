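"""QST, Weir-Cockerham FST (with an independent brute-force oracle),
permutation thresholds, transgression ratios and SMA regression."""

import numpy as np
import pytest
from scipy import optimize

import phenospace as ps


# ---------------------------------------------------------------------------
# independent brute-force Weir-Cockerham implementation (per-SNP loop,
# scalar arithmetic straight from the published component definitions)
# ---------------------------------------------------------------------------

def wc_fst_brute(dosage, groups):
    groups = np.asarray(groups)
    labels = np.unique(groups)
    out = np.empty(dosage.shape[1])
    for j in range(dosage.shape[1]):
        n_i, p_i, h_i = [], [], []
        for lab in labels:
            col = dosage[groups == lab, j]
            col = col[~np.isnan(col)]
            if col.size == 0:
                continue
            n_i.append(col.size)
            p_i.append(col.sum() / (2 * col.size))
            h_i.append(np.mean(col == 1.0))
        r = len(n_i)
        n_i, p_i, h_i = map(np.asarray, (n_i, p_i, h_i))
        nbar = n_i.mean()
        n_sum = n_i.sum()
        nc = (n_sum - (n_i**2).sum() / n_sum) / (r - 1)
        pbar = (n_i * p_i).sum() / n_sum
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / n_sum
        if pbar <= 0 or pbar >= 1:
            out[j] = np.nan
            continue
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        denom = a + b + c
        out[j] = a / denom if denom != 0 else np.nan
    return out


class TestQst:
    def test_equal_group_means_give_zero(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(5.0, 1.0, 200)
        groups = np.repeat(np.arange(10), 20)
        q = ps.estimate_qst(vals, groups, n_boot=50, seed=2)
        assert q.qst < 0.1
        assert q.interval[0] <= q.qst <= q.interval[1]

    def test_equal_variance_components_recover_half(self):
        """30 groups x 20, V_among = V_within = 1 -> QST near 0.5."""
        qs = []
        for s in range(10):
            rng = np.random.default_rng(100 + s)
            gm = rng.normal(0, 1, 30)
            vals = np.concatenate([g + rng.normal(0, 1, 20) for g in gm])
            qs.append(ps.estimate_qst(vals, np.repeat(np.arange(30), 20), n_boot=20, seed=s).qst)
        assert np.mean(qs) == pytest.approx(0.5, abs=0.05)

    def test_zero_within_variance_gives_one(self):
        vals = np.repeat([1.0, 2.0, 3.0], 5)
        q = ps.estimate_qst(vals, np.repeat(list("abc"), 5), n_boot=20, seed=3)
        assert q.qst == pytest.approx(1.0)

    def test_singleton_group_dropped_with_warning(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0, 99.0])
        groups = np.array(["a", "a", "b", "b", "c"])
        with pytest.warns(UserWarning, match="size 1"):
            q = ps.estimate_qst(vals, groups, n_boot=20, seed=4)
        assert np.isfinite(q.qst)

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            ps.estimate_qst(np.arange(6.0), np.repeat("a", 6), n_boot=10)


class TestWcFst:
    def test_fixed_difference_gives_theta_one(self):
        dosage = np.vstack([np.full((20, 1), 2.0), np.full((20, 1), 0.0)])
        groups = np.repeat(["a", "b"], 20)
        assert ps.wc_fst(dosage, groups)[0] == pytest.approx(1.0)

    def test_null_mean_near_zero(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0.1, 0.9, 2000)
        dosage = 2.0 * (rng.random((90, 2000)) < p)
        theta = ps.wc_fst(dosage, np.repeat(list("abc"), 30))
        assert abs(np.nanmean(theta)) < 0.01

    def test_matches_brute_force_oracle(self):
        """Vectorized estimator equals scalar component formulas to 1e-10."""
        rng = np.random.default_rng(8)
        p = rng.uniform(0.05, 0.95, 50)
        dosage = rng.choice([0.0, 1.0, 2.0], size=(60, 50), p=[0.4, 0.2, 0.4])
        dosage[rng.random(dosage.shape) < 0.05] = np.nan
        groups = rng.choice(list("abcd"), 60)
        ours = ps.wc_fst(dosage, groups)
        brute = wc_fst_brute(dosage, groups)
        assert np.allclose(ours, brute, atol=1e-10, equal_nan=True)

    def test_monomorphic_snp_flagged_nan(self):
        dosage = np.column_stack([np.full(40, 2.0), np.tile([0.0, 2.0], 20)])
        theta = ps.wc_fst(dosage, np.repeat(["a", "b"], 20))
        assert np.isnan(theta[0]) and np.isfinite(theta[1])

    def test_all_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            ps.wc_fst(np.full((10, 3), 2.0), np.repeat(["a", "b"], 5))


class TestPermutationThreshold:
    def test_null_exceedance_calibrated(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0.05, 0.95, 2000)
        dosage = 2.0 * (rng.random((120, 2000)) < p)
        groups = np.repeat(list("abc"), 40)
        theta = ps.wc_fst(dosage, groups)
        thr = ps.fst_permutation_threshold(dosage, groups, n_perm=200, seed=10)
        exceed = np.mean(theta[~np.isnan(theta)] > thr)
        assert exceed == pytest.approx(0.05, abs=0.02)

    def test_structured_data_exceeds_heavily(self, fast_dataset):
        g0 = fast_dataset.g0
        theta = ps.wc_fst(g0, g0.group)
        thr = ps.fst_permutation_threshold(g0, g0.group, n_perm=100, seed=11)
        assert np.mean(theta[~np.isnan(theta)] > thr) > 0.3

    def test_threshold_monotone_in_percentile(self):
        rng = np.random.default_rng(12)
        dosage = 2.0 * (rng.random((60, 300)) < 0.4)
        groups = np.repeat(["a", "b"], 30)
        t90 = ps.fst_permutation_threshold(dosage, groups, n_perm=50, pct=90, seed=13)
        t99 = ps.fst_permutation_threshold(dosage, groups, n_perm=50, pct=99, seed=13)
        assert t99 >= t90

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError, match="n_perm"):
            ps.fst_permutation_threshold(np.zeros((4, 2)), np.array(["a", "a", "b", "b"]), n_perm=5)


class TestNeutralFst:
    def test_median_of_significant(self):
        assert ps.neutral_fst(np.array([0.2, 0.4, 0.6, 0.01]), 0.1) == pytest.approx(0.4)

    def test_single_significant_value(self):
        assert ps.neutral_fst(np.array([0.01, 0.5]), 0.4) == pytest.approx(0.5)

    def test_result_at_least_threshold(self):
        rng = np.random.default_rng(14)
        thetas = rng.uniform(0, 0.5, 500)
        thr = 0.25
        assert ps.neutral_fst(thetas, thr) >= thr

    def test_none_significant_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            ps.neutral_fst(np.array([0.1, 0.2]), 0.5)


class TestTransgression:
    def test_identical_distributions_give_unit_ratio(self):
        vals = np.random.default_rng(15).normal(10, 2, 200)
        t = ps.transgression_ratio(vals, vals)
        assert t.ratio == pytest.approx(1.0)

    def test_doubled_spread_doubles_ratio(self):
        g0 = np.random.default_rng(16).normal(10, 1, 500)
        m = g0.mean()
        f2 = m + 2 * (g0 - m)  # same mean, exactly doubled SD
        t = ps.transgression_ratio(f2, g0)
        assert t.ratio == pytest.approx(2.0, rel=1e-9)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            ps.transgression_ratio(np.array([-1.0, 1.0]), np.array([1.0, 2.0]))

    def test_regime_ordering_on_simulation(self, fast_matrix):
        """Stabilizing traits transgress (>1) and more than divergent ones."""
        g0 = fast_matrix[fast_matrix["generation"] == "G0"]
        f2 = fast_matrix[fast_matrix["generation"] == "F2"]
        stab = ps.transgression_ratio(f2["ldmc"].to_numpy(), g0["ldmc"].to_numpy())
        div = ps.transgression_ratio(f2["flowering_time"].to_numpy(), g0["flowering_time"].to_numpy())
        assert stab.ratio > 1.0
        assert div.ratio < stab.ratio


def sma_loss(params, x, y):
    """SMA objective: sum of triangle areas between points and the line."""
    a, b = params
    dy = y - (a + b * x)
    dx = x - (y - a) / b
    return np.sum(np.abs(dy * dx))


class TestSmaRegression:
    def test_exact_line(self):
        x = np.linspace(0, 10, 20)
        fit = ps.sma_regression(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_axis_swap_inverts_slope(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=100)
        y = 1.5 * x + rng.normal(0, 0.5, 100)
        f_xy = ps.sma_regression(x, y)
        f_yx = ps.sma_regression(y, x)
        assert f_xy.slope == pytest.approx(1.0 / f_yx.slope)

    def test_matches_numeric_minimizer(self):
        """SMA closed form agrees with brute-force minimization of the
        product-of-deviations criterion."""
        rng = np.random.default_rng(18)
        x = rng.normal(size=60)
        y = 0.8 * x + rng.normal(0, 0.7, 60)
        fit = ps.sma_regression(x, y)
        res = optimize.minimize(
            sma_loss, x0=[fit.intercept + 0.1, fit.slope * 1.1], args=(x, y),
            method="Nelder-Mead", options={"xatol": 1e-12, "fatol": 1e-12, "maxiter": 20000},
        )
        assert res.x[1] == pytest.approx(fit.slope, abs=1e-6)
        assert res.x[0] == pytest.approx(fit.intercept, abs=1e-6)

    def test_negative_correlation_gives_negative_slope(self):
        rng = np.random.default_rng(19)
        x = rng.normal(size=80)
        y = -2 * x + rng.normal(0, 0.3, 80)
        fit = ps.sma_regression(x, y)
        assert fit.slope < 0
        assert fit.pvalue < 1e-6

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            ps.sma_regression(np.ones(5), np.arange(5.0))
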