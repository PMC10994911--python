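"""Density estimation and KL-divergence similarity.

Closed-form oracle: for two equal-variance Gaussians N(mu1, s^2), N(mu2, s^2)
the symmetric KL divergence is ((mu1 - mu2) / s)^2.
"""

import numpy as np
import pytest

from suscnet import (
    KDEConfig,
    SusceptibilityROISamples,
    build_susceptibility_matrix,
    estimate_pdf,
    isj_bandwidth,
    klse,
    read_matrix,
    silverman_bandwidth,
    symmetric_kl,
    write_matrix,
)
from suscnet.errors import DegenerateDistributionError, InsufficientSampleError


def _samples(rng, mu=0.0, sigma=1.0, n=20000):
    return rng.normal(mu, sigma, size=n)


def _exact_gaussian(rng, mu, n):
    """Gaussian draw standardized to exact sample mean/SD, so the
    closed-form oracle is not blurred by Monte-Carlo moment error."""
    z = rng.normal(size=n)
    return mu + (z - z.mean()) / z.std()


def test_kde_matches_standard_normal_density_at_zero(rng):
    p = estimate_pdf(_samples(rng, n=100_000))
    at0 = p.density[np.argmin(np.abs(p.grid))]
    assert at0 == pytest.approx(1.0 / np.sqrt(2 * np.pi), rel=0.02)


@pytest.mark.parametrize("draw", ["normal", "lognormal", "uniform", "tiny"])
def test_density_integrates_to_one(rng, draw):
    x = {
        "normal": rng.normal(3.0, 0.5, 500),
        "lognormal": rng.lognormal(0.0, 0.6, 800),
        "uniform": rng.uniform(-2, 2, 300),
        "tiny": rng.normal(0.0, 1.0, 12),
    }[draw]
    p = estimate_pdf(x)
    assert np.trapezoid(p.density, p.grid) == pytest.approx(1.0, abs=2e-3)
    assert np.all(p.density >= p.floor * 0.999)
    assert np.all(np.diff(p.grid) > 0)


def test_duplicating_samples_leaves_isj_density_unchanged(rng):
    x = _samples(rng, n=500)
    p1 = estimate_pdf(x)
    p2 = estimate_pdf(np.concatenate([x, x]))
    # ISJ uses the unique-value count, so the bandwidth and density agree
    assert p2.bandwidth == pytest.approx(p1.bandwidth, rel=1e-12)
    np.testing.assert_allclose(p1.density, p2.density, rtol=1e-9)


def test_silverman_is_count_sensitive(rng):
    x = _samples(rng, n=200)
    h1 = silverman_bandwidth(x)
    h2 = silverman_bandwidth(np.concatenate([x, x]))
    assert h2 < h1  # n**(-1/5) shrinkage


def test_insufficient_or_degenerate_samples_raise(rng):
    with pytest.raises(InsufficientSampleError):
        estimate_pdf(rng.normal(size=5))
    with pytest.raises(DegenerateDistributionError):
        estimate_pdf(np.full(50, 1.3))
    p = estimate_pdf(np.full(50, 1.3), degenerate_policy="delta")
    assert "degenerate_delta" in p.flags
    assert np.trapezoid(p.density, p.grid) == pytest.approx(1.0, abs=2e-3)


def test_symmetric_kl_is_zero_for_identical_estimate(rng):
    p = estimate_pdf(_samples(rng, n=500))
    assert symmetric_kl(p, p) == 0.0
    assert klse(p, p) == 1.0


@pytest.mark.parametrize("offset", [0.0, 0.5, 1.0, 2.0])
def test_symmetric_kl_matches_gaussian_closed_form(rng, offset):
    p = estimate_pdf(_exact_gaussian(rng, 0.0, 100_000))
    q = estimate_pdf(_exact_gaussian(rng, offset, 100_000))
    expected = offset**2
    assert symmetric_kl(p, q) == pytest.approx(expected, abs=max(0.02 * expected, 0.005))


def test_symmetric_kl_is_exactly_symmetric(rng):
    p = estimate_pdf(_samples(rng, mu=0.0, n=2000))
    q = estimate_pdf(_samples(rng, mu=0.7, n=1500))
    assert symmetric_kl(p, q) == symmetric_kl(q, p)


def test_klse_decreases_monotonically_with_divergence(rng):
    base = estimate_pdf(_samples(rng, n=20000))
    sims = [
        klse(base, estimate_pdf(_samples(rng, mu=off, n=20000)))
        for off in (0.3, 0.8, 1.5)
    ]
    assert sims[0] > sims[1] > sims[2] > 0.0
    assert all(s <= 1.0 for s in sims)


def test_klse_of_unit_divergence_is_inverse_e(rng):
    p = estimate_pdf(_exact_gaussian(rng, 0.0, 100_000))
    q = estimate_pdf(_exact_gaussian(rng, 1.0, 100_000))
    # D_KL ~ 1 here, so KLSE ~ 1/e
    assert klse(p, q) == pytest.approx(np.exp(-1.0), rel=0.02)


def test_quadrature_converges_under_grid_doubling(rng):
    p = estimate_pdf(_samples(rng, n=5000))
    q = estimate_pdf(_samples(rng, mu=0.8, n=5000))
    d512 = symmetric_kl(p, q, grid_points=512)
    d1024 = symmetric_kl(p, q, grid_points=1024)
    assert abs(d1024 - d512) / d512 < 0.005


def test_divergence_is_shift_invariant(rng):
    x = _samples(rng, n=3000)
    y = _samples(rng, mu=0.6, n=2500)
    d0 = symmetric_kl(estimate_pdf(x), estimate_pdf(y))
    shift = 37.5
    d1 = symmetric_kl(estimate_pdf(x + shift), estimate_pdf(y + shift))
    assert d1 == pytest.approx(d0, rel=1e-6)


def test_isj_bandwidth_scales_with_data_scale(rng):
    x = _samples(rng, n=5000)
    assert isj_bandwidth(3.0 * x) == pytest.approx(3.0 * isj_bandwidth(x), rel=1e-6)


# ---------------------------------------------------------------------------
# Whole-subject matrices
# ---------------------------------------------------------------------------

def _roi_samples(rng, means, n=200):
    return SusceptibilityROISamples(
        subject_id="s0",
        region_values={r + 1: rng.normal(m, 1.0, size=n) for r, m in enumerate(means)},
    )


def test_identical_region_multisets_give_all_ones_matrix(rng):
    vals = rng.normal(size=150)
    s = SusceptibilityROISamples(
        subject_id="s0", region_values={1: vals, 2: vals.copy(), 3: vals.copy()}
    )
    mat = build_susceptibility_matrix(s)
    np.testing.assert_allclose(mat.values, np.ones((3, 3)), atol=1e-12)


def test_matrix_entries_equal_pairwise_klse_calls(rng, fast_kde):
    s = _roi_samples(rng, [0.0, 0.4, 1.0, 1.7, 2.1])
    mat = build_susceptibility_matrix(s, fast_kde)
    pdfs = {
        r: estimate_pdf(v, grid_points=fast_kde.grid_points)
        for r, v in s.region_values.items()
    }
    for i, ri in enumerate(s.region_ids):
        for j, rj in enumerate(s.region_ids):
            if i == j:
                assert mat.values[i, j] == 1.0
            else:
                assert mat.values[i, j] == pytest.approx(
                    klse(pdfs[ri], pdfs[rj], grid_points=fast_kde.grid_points),
                    rel=1e-12,
                )
    # invariants: symmetric, off-diagonal in (0, 1]
    np.testing.assert_array_equal(mat.values, mat.values.T)
    off = mat.values[np.triu_indices(5, 1)]
    assert np.all((off > 0) & (off <= 1))


def test_region_order_permutation_permutes_matrix(rng, fast_kde):
    means = [0.0, 0.5, 1.2, 2.0]
    s = _roi_samples(rng, means)
    mat = build_susceptibility_matrix(s, fast_kde)
    # relabel regions 1..4 -> 4..1 (same value bags, reversed ids)
    s_perm = SusceptibilityROISamples(
        subject_id="s0",
        region_values={5 - r: v for r, v in s.region_values.items()},
    )
    mat_perm = build_susceptibility_matrix(s_perm, fast_kde)
    np.testing.assert_allclose(mat_perm.values, mat.values[::-1, ::-1], rtol=1e-12)


def test_degenerate_region_aborts_with_region_named(rng):
    s = SusceptibilityROISamples(
        subject_id="subj",
        region_values={1: rng.normal(size=100), 2: np.full(100, 2.0)},
    )
    with pytest.raises(DegenerateDistributionError, match="region 2"):
        build_susceptibility_matrix(s)
    mat = build_susceptibility_matrix(s, KDEConfig(degenerate_policy="delta"))
    assert 0 < mat.values[0, 1] <= 1


def test_matrix_roundtrip_preserves_values_and_metadata(tmp_path, rng, fast_kde):
    s = _roi_samples(rng, [0.0, 1.0, 2.0])
    mat = build_susceptibility_matrix(s, fast_kde)
    path = tmp_path / "mat.tsv"
    write_matrix(mat, path)
    back = read_matrix(path)
    assert back.subject_id == mat.subject_id
    assert back.region_ids == mat.region_ids
    np.testing.assert_array_equal(back.values, mat.values)
    assert back.meta["kde_config"]["grid_points"] == fast_kde.grid_points
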