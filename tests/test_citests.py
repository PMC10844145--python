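"""Conditional-independence tests: closed-form oracles, invariances,
permutation-scheme calibration."""

import numpy as np
import pytest
from scipy import stats

import boldcausal as bc
from boldcausal.citests import (
    CITestSpec,
    auto_block_length,
    block_shuffle_indices,
    cmi_knn,
    distance_correlation,
    local_permutation_indices,
)


def _pearson(a, b):
    return float(np.corrcoef(a, b)[0, 1])


# -- partial correlation ---------------------------------------------------

def test_parcorr_identical_columns_statistic_one(rng):
    x = rng.standard_normal(300)
    data = np.column_stack([x, x])
    res = bc.parcorr_test(data, CITestSpec(i=0, j=1, lag=0, n_permutations=99, seed=0))
    assert res.statistic == pytest.approx(1.0, abs=1e-12)


def test_parcorr_common_cause_partial_correlation_vanishes(rng):
    n = 4000
    w = rng.standard_normal(n)
    x = w + rng.standard_normal(n)
    y = w + rng.standard_normal(n)
    data = np.column_stack([x, y, w])
    res = bc.parcorr_test(
        data, CITestSpec(i=0, j=1, lag=0, Z=[(2, 0)], n_permutations=199, seed=1)
    )
    # precision-matrix oracle: exact partial correlation is 0
    assert abs(res.statistic) < 3 / np.sqrt(n)
    assert abs(np.corrcoef(res.residual_i, data[:, 2])[0, 1]) < 1e-10


def test_parcorr_matches_closed_form_gaussian_triple(rng):
    n = 4000
    cov = np.array([[1.0, 0.6, 0.5], [0.6, 1.0, 0.4], [0.5, 0.4, 1.0]])
    data = rng.multivariate_normal(np.zeros(3), cov, size=n)
    res = bc.parcorr_test(
        data, CITestSpec(i=0, j=1, lag=0, Z=[(2, 0)], n_permutations=199, seed=2)
    )
    expected = (0.6 - 0.5 * 0.4) / np.sqrt((1 - 0.25) * (1 - 0.16))
    assert abs(res.statistic - expected) < 3 / np.sqrt(n)


def test_parcorr_too_small_sample_raises(rng):
    data = rng.standard_normal((3, 3))
    with pytest.raises(ValueError, match="n_effective"):
        bc.parcorr_test(data, CITestSpec(i=0, j=1, lag=0, Z=[(2, 0)], n_permutations=99))


def test_parcorr_and_gpdc_affine_scale_invariance(rng):
    n = 400
    data = rng.standard_normal((n, 3))
    data[:, 1] += 0.5 * data[:, 0]
    scaled = data * np.array([3.0, -0.2, 10.0]) + np.array([5.0, -1.0, 0.0])
    for fn in (bc.parcorr_test, bc.gpdc_test):
        a = fn(data, CITestSpec(i=0, j=1, lag=0, Z=[(2, 0)], n_permutations=99, seed=3,
                                method="gpdc" if fn is bc.gpdc_test else "parcorr",
                                gp_optimize=False))
        b = fn(scaled, CITestSpec(i=0, j=1, lag=0, Z=[(2, 0)], n_permutations=99, seed=3,
                                  method="gpdc" if fn is bc.gpdc_test else "parcorr",
                                  gp_optimize=False))
        assert abs(abs(a.statistic) - abs(b.statistic)) < 1e-6


def test_cmiknn_exact_monotone_invariance(rng):
    n = 400
    x = rng.standard_normal(n)
    y = x + rng.standard_normal(n)
    data = np.column_stack([x, y])
    warped = np.column_stack([np.exp(x), np.tanh(y) ** 3])
    sa = bc.cmiknn_test(data, CITestSpec(i=0, j=1, lag=0, method="cmiknn",
                                         n_permutations=99, seed=4))
    sb = bc.cmiknn_test(warped, CITestSpec(i=0, j=1, lag=0, method="cmiknn",
                                           n_permutations=99, seed=4))
    assert sa.statistic == pytest.approx(sb.statistic, abs=1e-12)
    assert sa.p_value == sb.p_value


# -- distance correlation / GPDC -------------------------------------------

def test_distance_correlation_self_is_one(rng):
    x = rng.standard_normal(150)
    assert distance_correlation(x, x) == pytest.approx(1.0, abs=1e-12)


def test_distance_correlation_matches_naive_double_sum(rng):
    """V-statistic dcor equals the O(n^2) double-sum definition to 1e-10."""
    n = 150
    x = rng.standard_normal(n)
    y = x**2 + 0.5 * rng.standard_normal(n)

    def naive(u, v):
        A = np.abs(u[:, None] - u[None, :])
        B = np.abs(v[:, None] - v[None, :])
        Ac = A - A.mean(0) - A.mean(1)[:, None] + A.mean()
        Bc = B - B.mean(0) - B.mean(1)[:, None] + B.mean()
        dcov2 = (Ac * Bc).sum() / n**2
        dvx = (Ac * Ac).sum() / n**2
        dvy = (Bc * Bc).sum() / n**2
        return np.sqrt(dcov2 / np.sqrt(dvx * dvy))

    assert distance_correlation(x, y) == pytest.approx(naive(x, y), abs=1e-10)


def test_gpdc_detects_quadratic_dependence_invisible_to_pearson(rng):
    n = 500
    x = rng.standard_normal(n)
    y = x**2
    data = np.column_stack([x, y])
    res = bc.gpdc_test(data, CITestSpec(i=0, j=1, lag=0, method="gpdc",
                                        n_permutations=199, seed=5))
    assert abs(_pearson(x, y)) < 3 / np.sqrt(n)
    assert res.statistic > 0.3
    assert res.p_value < 0.01


def test_gpdc_conditional_null_calibrated_on_nonlinear_confounder():
    """X and Y both driven by sin(Z): given Z the GP residuals are
    independent, so the test should be non-significant at 0.01 in >= 95%
    of replicates."""
    nonsig = 0
    reps = 60
    for r in range(reps):
        rng = np.random.default_rng([77, r])
        z = rng.uniform(-3, 3, 250)
        x = np.sin(z) + 0.3 * rng.standard_normal(250)
        y = np.sin(z) + 0.3 * rng.standard_normal(250)
        data = np.column_stack([x, y, z])
        res = bc.gpdc_test(
            data,
            CITestSpec(i=0, j=1, lag=0, Z=[(2, 0)], method="gpdc",
                       n_permutations=99, seed=r, gp_restarts=0),
        )
        nonsig += res.p_value > 0.01
    assert nonsig / reps >= 0.95


# -- kNN conditional mutual information ------------------------------------

def test_cmi_near_zero_for_independent_uniforms(rng):
    u = rng.random(1000)
    v = rng.random(1000)
    assert abs(cmi_knn(u, v, None, k=100)) < 0.05


def test_cmiknn_p_values_uniform_under_independence():
    """Kolmogorov-Smirnov check of the permutation p-value distribution on
    independent pairs (full permutation loop, no sequential stopping)."""
    ps = []
    for r in range(200):
        rng = np.random.default_rng([55, r])
        data = rng.random((300, 2))
        res = bc.cmiknn_test(
            data, CITestSpec(i=0, j=1, lag=0, method="cmiknn",
                             n_permutations=99, seed=r, early_stop=False),
        )
        ps.append(res.p_value)
    assert stats.kstest(ps, "uniform").pvalue > 0.05


def test_cmi_matches_gaussian_closed_form():
    """Mean estimate over independent draws within 0.03 nats of the
    bivariate-Gaussian closed form at n = 2000 (sampling noise of a single
    draw is itself ~0.015)."""
    n, rho = 2000, 0.6
    estimates = []
    for r in range(4):
        rng = np.random.default_rng([8, r])
        a = rng.standard_normal(n)
        b = rho * a + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        au = stats.rankdata(a) / (n + 1)
        bu = stats.rankdata(b) / (n + 1)
        estimates.append(cmi_knn(au, bu, None, k=30))
    expected = -0.5 * np.log(1 - rho**2)
    assert np.mean(estimates) == pytest.approx(expected, abs=0.03)


def test_cmiknn_detects_multiplicative_noise():
    """Heteroscedastic dependence with Pearson correlation ~ 0 is detected
    in >= 90% of replicates."""
    hits = 0
    reps = 10
    for r in range(reps):
        rng = np.random.default_rng([66, r])
        x = rng.standard_normal(2000)
        y = (1 + np.abs(x)) * rng.standard_normal(2000)
        assert abs(_pearson(x, y)) < 0.08
        res = bc.cmiknn_test(
            np.column_stack([x, y]),
            CITestSpec(i=0, j=1, lag=0, method="cmiknn", n_permutations=199,
                       seed=r, max_samples=500),
        )
        hits += res.p_value < 0.01
    assert hits / reps >= 0.9


def test_cmiknn_k_too_large_raises(rng):
    data = rng.random((80, 2))
    with pytest.raises(ValueError, match="10\\*k"):
        bc.cmiknn_test(data, CITestSpec(i=0, j=1, lag=0, method="cmiknn",
                                        n_permutations=99, knn=20, max_samples=None))


# -- permutation machinery -------------------------------------------------

def test_block_shuffle_indices_are_permutations(rng):
    idx = block_shuffle_indices(103, 10, rng)
    assert sorted(idx) == list(range(103))


def test_local_permutation_preserves_neighborhoods(rng):
    z = np.sort(rng.random(200))[:, None]
    perm = local_permutation_indices(z, rng, k_perm=5)
    assert sorted(perm) != list(perm)  # actually permuted
    # donors come from close Z-neighborhoods
    assert np.abs(z[perm, 0] - z[:, 0]).max() < 0.2


def test_permutation_null_extreme_rank():
    """Perfectly correlated pair: p = 1/200 with 199 permutations."""
    x = np.arange(200, dtype=float)
    p = bc.permutation_null(
        x, x, lambda a, b: _pearson(a, b), scheme="block_shuffle",
        n_permutations=199, block_length=10, seed=0,
    )
    assert p == pytest.approx(1 / 200)


def test_permutation_null_calibrated_on_white_noise():
    ps = []
    for r in range(200):
        rng = np.random.default_rng([99, r])
        a, b = rng.standard_normal((2, 150))
        ps.append(bc.permutation_null(a, b, lambda u, v: _pearson(u, v),
                                      n_permutations=99, block_length=5, seed=r))
    assert 0.45 < np.mean(ps) < 0.55


def test_block_shuffle_controls_autocorrelation_inflation():
    """Independent AR(1) phi = 0.9 pairs: naive (block length 1) permutation
    inflates the rejection rate; the automatic block length keeps it near
    the nominal 1% level."""
    from boldcausal.benchmarks import _ar1

    rej = {1: 0, None: 0}
    reps = 150
    for r in range(reps):
        rng = np.random.default_rng([111, r])
        a = _ar1(600, 0.9, rng)
        b = _ar1(600, 0.9, rng)
        for bl in rej:
            res = bc.parcorr_test(
                np.column_stack([a, b]),
                CITestSpec(i=0, j=1, lag=0, n_permutations=199, seed=r, block_length=bl),
            )
            rej[bl] += res.p_value <= 0.01
    assert rej[None] / reps <= 0.02
    assert rej[1] > rej[None]
    assert rej[1] / reps > 0.05


def test_auto_block_length_grows_with_autocorrelation():
    from boldcausal.benchmarks import _ar1

    rng = np.random.default_rng(7)
    white = rng.standard_normal(1000)
    ar = _ar1(1000, 0.9, rng)
    assert auto_block_length(white) <= 3
    assert auto_block_length(ar) > auto_block_length(white)


def test_citest_spec_invariants():
    with pytest.raises(ValueError):
        CITestSpec(i=0, j=1, lag=1, Z=[(0, 1)])
    with pytest.raises(ValueError):
        CITestSpec(i=0, j=1, lag=0, Z=[(1, 0)])
    with pytest.raises(ValueError):
        CITestSpec(i=0, j=1, lag=3, tau_max=2)
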