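"""Rate-to-fluctuation quotients: closed forms, limits, bounds, extrema."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from itrfluct.entropy import DomainError, shannon_h
from itrfluct.markov import MarkovParams, from_s_and_p10, itr, sigma, variance
from itrfluct.quotients import (
    UndefinedCaseError,
    count_local_extrema,
    curve,
    q_sigma,
    q_sigma_boundary_limit,
    q_sigma_bounds,
    q_sigma_center,
    q_variance,
    q_variance_boundary_limit,
    solve_critical_s0,
    solve_sigma_lt_itr_threshold,
)

# 40-digit oracle values
QS_05_02 = 1.6037487377513792  # sqrt(1.5) H(0.2) + sqrt(2/3) H(0.3)
TWO_H_QUARTER = 1.6225562489182657
QV_05_02 = 3.2736384026028936
S_STAR = 1.7235252269268052
BOUNDS_19 = (0.4943647627749308, 0.5727939142319123)
VARIANTS = ["shannon", "taylor10", "unimodal", "unimodal_root"]


@pytest.mark.parametrize(
    "s, p10, variant, expected",
    [
        (1.0, 0.5, "shannon", 2.0),
        (0.5, 0.25, "shannon", TWO_H_QUARTER),
        (0.5, 0.2, "shannon", QS_05_02),
    ],
)
def test_q_sigma_values(s, p10, variant, expected):
    assert q_sigma(s, p10, variant) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "s, p10, variant, expected",
    [
        (1.0, 0.5, "shannon", 4.0),
        (0.5, 0.2, "unimodal", 3.0),  # constant 4s(2-s)
        (0.5, 0.2, "shannon", QV_05_02),
    ],
)
def test_q_variance_values(s, p10, variant, expected):
    assert q_variance(s, p10, variant) == pytest.approx(expected, abs=1e-12)


def test_quotients_agree_with_source_ratios():
    """Closed forms reproduce ITR/sigma and ITR/V from the source module."""
    rng = np.random.default_rng(11)
    for _ in range(50):
        s = rng.uniform(0.05, 1.95)
        lo, hi = max(0.0, s - 1.0), min(1.0, s)
        p10 = rng.uniform(lo + 0.01, hi - 0.01)
        params = from_s_and_p10(s, float(p10))
        assert q_sigma(s, p10) == pytest.approx(itr(params) / sigma(params), abs=1e-12)
        assert q_variance(s, p10) == pytest.approx(
            itr(params) / variance(params), abs=1e-12
        )
        # Q_V * sigma = Q_sigma pointwise
        assert q_variance(s, p10) * sigma(params) == pytest.approx(
            q_sigma(s, p10), abs=1e-12
        )


@pytest.mark.parametrize("variant", VARIANTS)
def test_symmetry_about_midpoint(variant):
    """Q(p) = Q(s-p) for both quotients, every variant, random draws."""
    rng = np.random.default_rng(5)
    for _ in range(200):
        s = rng.uniform(0.05, 1.95)
        lo, hi = max(0.0, s - 1.0), min(1.0, s)
        p10 = rng.uniform(lo + 1e-3, hi - 1e-3)
        assert q_sigma(s, p10, variant) == pytest.approx(
            q_sigma(s, s - p10, variant), abs=1e-9
        )
        assert q_variance(s, p10, variant) == pytest.approx(
            q_variance(s, s - p10, variant), abs=1e-9
        )


@pytest.mark.parametrize(
    "s, variant, expected",
    [(1.0, "shannon", 2.0), (0.5, "shannon", TWO_H_QUARTER), (1.0, "unimodal", 2.0)],
)
def test_q_sigma_center(s, variant, expected):
    assert q_sigma_center(s, variant) == pytest.approx(expected, abs=1e-12)
    if 0 < s < 2:
        assert q_sigma_center(s, variant) == pytest.approx(
            q_sigma(s, s / 2, variant), abs=1e-12
        )


@pytest.mark.parametrize(
    "s, variant, expected",
    [
        (0.5, "shannon", 0.0),
        (0.5, "unimodal", 0.0),
        (0.5, "unimodal_root", 2.0 * math.sqrt(0.5)),
        (0.5, "taylor10", math.inf),
        (1.5, "shannon", math.sqrt(2.0)),  # H(0.5)/sqrt(0.5)
        (1.5, "unimodal", math.sqrt(2.0)),
    ],
)
def test_q_sigma_boundary_limit(s, variant, expected):
    lim = q_sigma_boundary_limit(s, variant)
    assert lim == pytest.approx(expected, abs=1e-9)
    if math.isfinite(lim) and s > 1:
        # the closed form matches near-boundary evaluation
        assert q_sigma(s, 1.0 - 1e-8, variant) == pytest.approx(lim, abs=1e-3)
        assert q_sigma(s, s - 1.0 + 1e-8, variant) == pytest.approx(lim, abs=1e-3)


@pytest.mark.parametrize(
    "s, variant, expected",
    [
        (0.5, "shannon", math.inf),
        (0.5, "taylor10", math.inf),
        (0.5, "unimodal_root", math.inf),
        (0.5, "unimodal", 4.0 * 0.5 * 1.5),  # the constant curve's value
        (1.5, "shannon", 3.0),  # 1.5 * H(0.5) / 0.5
        (1.5, "unimodal", 3.0),  # 4s(2-s)
    ],
)
def test_q_variance_boundary_limit(s, variant, expected):
    lim = q_variance_boundary_limit(s, variant)
    assert lim == pytest.approx(expected, abs=1e-9)
    if s > 1:
        assert q_variance(s, 1.0 - 1e-8, variant) == pytest.approx(lim, abs=1e-3)


def test_boundary_limit_undefined_at_s_one():
    with pytest.raises(UndefinedCaseError):
        q_sigma_boundary_limit(1.0)
    with pytest.raises(UndefinedCaseError):
        q_variance_boundary_limit(1.0)


def test_taylor_boundary_limit_reflects_positive_endpoint():
    """The Taylor truncation's q_sigma blows up at the case-A boundary."""
    vals = [q_sigma(0.5, eps, "taylor10") for eps in (1e-3, 1e-5, 1e-7)]
    assert vals[0] < vals[1] < vals[2]  # increasing without bound


def test_q_sigma_bounds_case_b():
    lo, hi = q_sigma_bounds(1.5)
    assert lo == pytest.approx(math.sqrt(2.0), abs=1e-9)
    assert hi == pytest.approx(2.0 * shannon_h(0.75), abs=1e-12)
    lo9, hi9 = q_sigma_bounds(1.9)
    assert (lo9, hi9) == pytest.approx(BOUNDS_19, abs=1e-9)
    with pytest.raises(DomainError):
        q_sigma_bounds(0.9)


def test_q_sigma_bounds_contain_curve():
    """Every interior value lies in [H(s-1)/sqrt(s-1), 2H(s/2)] for s in (1,2)."""
    rng = np.random.default_rng(17)
    for s in rng.uniform(1.01, 1.99, size=50):
        lo, hi = q_sigma_bounds(float(s))
        grid = np.linspace(s - 1 + 1e-4, 1 - 1e-4, 101)
        vals = q_sigma(float(s), grid, "shannon")
        assert np.all(vals >= lo - 1e-9)
        assert np.all(vals <= hi + 1e-9)


def test_case_a_collapse_and_blowup():
    """For s < 1: Q_sigma -> 0 monotonically at the boundary, Q_V -> inf."""
    eps = np.array([1e-2, 1e-3, 1e-4, 1e-5, 1e-6, 1e-7, 1e-8])
    qs = np.array([q_sigma(0.5, e) for e in eps])
    # decay is ~ sqrt(eps) log(1/eps): monotone, small but not yet tiny at 1e-8
    assert np.all(np.diff(qs) < 0) and qs[-1] < 0.005
    qv = np.array([q_variance(0.5, e) for e in eps])
    # logarithmic divergence: each decade toward the boundary adds
    # ~ s*log2(10) ~ 1.66, without saturating
    assert np.all(np.diff(qv) > 1.5)
    assert qv[-1] > qv[0] + 6 * 1.5


def test_boundary_p10_rejected_with_guidance():
    with pytest.raises(DomainError, match="limit"):
        q_sigma(0.5, 0.0)
    with pytest.raises(DomainError):
        q_variance(1.5, 1.0)


def test_critical_s0_is_four_thirds():
    res = solve_critical_s0(1e-10)
    assert round(res.value, 2) == 1.33
    assert res.value == pytest.approx(4.0 / 3.0, abs=1e-12)
    assert res.residual < 1e-10
    assert res.bracket[0] <= res.value <= res.bracket[1]


def test_sigma_lt_itr_threshold():
    res = solve_sigma_lt_itr_threshold(1e-9)
    assert res.value >= 1.7
    assert res.value == pytest.approx(S_STAR, abs=1e-9)
    assert shannon_h(res.value - 1.0) / math.sqrt(res.value - 1.0) == pytest.approx(
        1.0, abs=1e-9
    )
    # below the threshold the whole curve stays above 1
    grid_min = np.min(q_sigma(1.5, np.linspace(0.5 + 1e-6, 1 - 1e-6, 1001)))
    assert grid_min > 1.0
    assert grid_min == pytest.approx(math.sqrt(2.0), abs=1e-2)


def _center_curvature(s: float, h: float = 1e-4) -> float:
    c = q_variance(s, s / 2)
    return (q_variance(s, s / 2 + h) - 2 * c + q_variance(s, s / 2 - h)) / h**2


def test_qv_center_curvature_flips_near_s_143():
    """The center of Q_V turns from local min to local max at s ~ 1.4307."""
    assert _center_curvature(1.42) > 0
    assert _center_curvature(1.44) < 0
    # and it does NOT flip at the boundary-crossing parameter 4/3
    assert _center_curvature(4.0 / 3.0 - 0.05) > 0
    assert _center_curvature(4.0 / 3.0 + 0.05) > 0


def test_curve_construction_and_symmetry():
    c = curve(0.5, "shannon", "sigma", 101)
    assert len(c.grid) == 101
    mid = len(c.grid) // 2
    assert c.grid[mid] == pytest.approx(0.25)
    assert c.values[mid] == pytest.approx(TWO_H_QUARTER, abs=1e-9)
    assert c.values[mid] == c.values.max()
    np.testing.assert_allclose(c.values, c.values[::-1], atol=1e-9, rtol=0)


def test_curve_forces_odd_grid():
    c = curve(0.8, "shannon", "sigma", 100)
    assert len(c.grid) % 2 == 1
    assert c.grid[len(c.grid) // 2] == pytest.approx(0.4)


def test_unimodal_variance_curve_is_constant():
    for s in (0.3, 0.7, 1.2, 1.8):
        c = curve(s, "unimodal", "variance", 101)
        np.testing.assert_allclose(c.values, 4 * s * (2 - s), atol=1e-12, rtol=0)
        assert count_local_extrema(c) == 0
    # while the Shannon curve genuinely varies
    c = curve(0.7, "shannon", "variance", 101)
    assert np.ptp(c.values) > 0.1


@pytest.mark.parametrize(
    "s, kind, expected",
    [
        (0.5, "sigma", 1),  # single maximum at s/2
        (1.3, "variance", 3),  # center min flanked by two maxima
        (1.5, "variance", 1),  # monotone rise to the center maximum
    ],
)
def test_extremum_counts(s, kind, expected):
    assert count_local_extrema(curve(s, "shannon", kind, 1001)) == expected


def test_curve_serialization_round_trip(tmp_path):
    c = curve(1.5, "shannon", "variance", 51)
    path = tmp_path / "curve.tsv"
    c.to_table(path)
    data = np.loadtxt(path, comments="#", usecols=(0, 1), delimiter="\t")
    np.testing.assert_allclose(data[:, 0], c.grid, rtol=1e-9)
    np.testing.assert_allclose(data[:, 1], c.values, rtol=1e-9)
    header = path.read_text().splitlines()[0]
    assert header.startswith("#") and "s=1.5" in header


@settings(derandomize=True, max_examples=100)
@given(
    s=st.floats(min_value=0.1, max_value=1.9),
    frac=st.floats(min_value=0.05, max_value=0.95),
)
def test_quotient_product_identity_property(s, frac):
    """Q_V * sigma == Q_sigma across the whole parameter plane."""
    lo, hi = max(0.0, s - 1.0), min(1.0, s)
    p10 = lo + frac * (hi - lo)
    params = from_s_and_p10(s, p10)
    assert q_variance(s, p10) * sigma(params) == pytest.approx(
        q_sigma(s, p10), rel=1e-10
    )
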