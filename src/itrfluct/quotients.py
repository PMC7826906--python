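"""Quotients of transmission rate by fluctuation: Q_sigma and Q_V.

At fixed jumping parameter ``s`` the two-state source is parametrized by
``p10`` alone, and the ratios of rate to fluctuation have closed forms:

    Q_sigma(s, p) = sqrt((s-p)/p) * f(p) + sqrt(p/(s-p)) * f(s-p)   (ITR/sigma)
    Q_V(s, p)     = s * [ f(p)/p + f(s-p)/(s-p) ]                   (ITR/V)

with ``f`` an entropy variant.  Both are symmetric about the midpoint
``p = s/2``.  Their boundary behavior splits into two regimes:

* case A, ``s < 1`` (admissible ``p in (0, s)``): Q_sigma collapses to 0 at
  the boundary while Q_V blows up, so the center is a max of Q_sigma and a
  min of Q_V;
* case B, ``s > 1`` (``p in (s-1, 1)``): both stay finite, giving the
  two-sided bound ``H(s-1)/sqrt(s-1) <= Q_sigma <= 2 H(s/2)``, and Q_V can
  develop three interior extrema.

Two critical parameters follow: ``s0`` (exactly 4/3), defined by
``s H(s-1)/(s-1) = 4 H(s/2)``, where the common boundary limit of Q_V
crosses its center value; and ``s*`` (~1.72), the upper end of the regime
where the case-B infimum of Q_sigma stays >= 1, i.e. where fluctuation
never exceeds transmission rate.

The fine structure of Q_V in case B: its center curvature is
``2s g''(s/2)`` with ``g(p) = H(p)/p``, which changes sign at
``s = 2p* ~ 1.4307`` (``g''(p*) = 0``).  Below that the center is a local
minimum flanked by two maxima (three interior extrema); above it the curve
rises monotonically from the boundary limit to a single center maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .entropy import DomainError, EntropyVariant, evaluate, shannon_h
from .markov import admissible_p10_interval

__all__ = [
    "QuotientCurve",
    "CriticalResult",
    "q_sigma",
    "q_variance",
    "q_sigma_center",
    "q_sigma_boundary_limit",
    "q_sigma_bounds",
    "q_variance_boundary_limit",
    "solve_critical_s0",
    "solve_sigma_lt_itr_threshold",
    "curve",
    "count_local_extrema",
]

#: default inset from the interval endpoints when sampling curves; the
#: quotients are 0/0 forms at the exact endpoints
DEFAULT_EPSILON = 1e-6


class UndefinedCaseError(ValueError):
    """A boundary-limit operation was asked for the s = 1 knife edge."""


def _as_variant(variant) -> EntropyVariant:
    return variant if isinstance(variant, EntropyVariant) else EntropyVariant(str(variant))


def _check_interior(s: float, p10) -> None:
    lo, hi = admissible_p10_interval(s)
    arr = np.atleast_1d(np.asarray(p10, dtype=float))
    if np.any(arr <= lo) or np.any(arr >= hi):
        raise DomainError(
            f"p10 must lie strictly inside ({lo:g}, {hi:g}) for s = {s:g}; "
            "use the boundary-limit operations for endpoint values"
        )


def q_sigma(s: float, p10, variant: EntropyVariant | str = "shannon"):
    """Rate-to-standard-deviation quotient at fixed ``s``.

    ``sqrt((s-p)/p) f(p) + sqrt(p/(s-p)) f(s-p)``; accepts scalar or array
    ``p10`` strictly inside the admissible interval.
    """
    variant = _as_variant(variant)
    _check_interior(s, p10)
    p = np.asarray(p10, dtype=float)
    q = s - p
    val = np.sqrt(q / p) * evaluate(variant, p) + np.sqrt(p / q) * evaluate(variant, q)
    return float(val) if np.isscalar(p10) else val


def q_variance(s: float, p10, variant: EntropyVariant | str = "shannon"):
    """Rate-to-variance quotient ``s [f(p)/p + f(s-p)/(s-p)]`` at fixed ``s``.

    Satisfies ``q_variance * sigma = q_sigma`` pointwise.
    """
    variant = _as_variant(variant)
    _check_interior(s, p10)
    p = np.asarray(p10, dtype=float)
    q = s - p
    val = s * (evaluate(variant, p) / p + evaluate(variant, q) / q)
    return float(val) if np.isscalar(p10) else val


def q_sigma_center(s: float, variant: EntropyVariant | str = "shannon") -> float:
    """Value ``2 f(s/2)`` of Q_sigma at the symmetry point ``p10 = s/2``.

    For ``s <= 1`` this is the maximum of the curve; it peaks at 2 over all
    ``s`` (attained at s = 1, the fair Bernoulli source).
    """
    if not 0.0 < s < 2.0:
        raise DomainError(f"s must lie in (0, 2); got {s!r}")
    return 2.0 * float(evaluate(_as_variant(variant), s / 2.0))


def q_sigma_boundary_limit(s: float, variant: EntropyVariant | str = "shannon") -> float:
    """Common limit of Q_sigma as ``p10`` approaches either interval endpoint.

    For ``s > 1`` the limit is ``sqrt(s-1) f(1) + f(s-1)/sqrt(s-1)``, which
    is ``f(s-1)/sqrt(s-1)`` for every variant vanishing at 1.  For ``s < 1``
    the limit depends on the variant's behavior at 0: it is 0 for shannon
    and unimodal, ``2 sqrt(s)`` for unimodal_root, and +inf for the Taylor
    truncation (whose endpoint value is positive).
    """
    variant = _as_variant(variant)
    if not 0.0 < s < 2.0:
        raise DomainError(f"s must lie in (0, 2); got {s!r}")
    if s == 1.0:
        raise UndefinedCaseError(
            "s = 1 separates the two boundary regimes; the limit is the "
            "case-A mechanism value 0"
        )
    if s > 1.0:
        f1 = float(evaluate(variant, 1.0))
        return math.sqrt(s - 1.0) * f1 + float(evaluate(variant, s - 1.0)) / math.sqrt(s - 1.0)
    # case A: behavior of sqrt(s/p) * f(p) as p -> 0+
    if variant.kind in ("shannon", "unimodal"):
        return 0.0
    if variant.kind == "unimodal_root":
        return 2.0 * math.sqrt(s)
    return math.inf  # taylor truncation: f(0) > 0


def q_sigma_bounds(s: float) -> tuple[float, float]:
    """Two-sided bound ``[H(s-1)/sqrt(s-1), 2 H(s/2)]`` on Q_sigma, case B.

    Valid for ``1 < s < 2`` with the Shannon entropy; every interior value
    of the quotient lies between the boundary limit and the center value,
    yielding the rate estimate ``lower * sigma <= ITR <= upper * sigma``.
    """
    if not 1.0 < s < 2.0:
        raise DomainError(f"the two-sided bound requires 1 < s < 2; got {s!r}")
    return (shannon_h(s - 1.0) / math.sqrt(s - 1.0), 2.0 * shannon_h(s / 2.0))


def q_variance_boundary_limit(s: float, variant: EntropyVariant | str = "shannon") -> float:
    """Common boundary limit of Q_V.

    For ``s > 1``: ``s [f(1) + f(s-1)/(s-1)]``, i.e. ``s f(s-1)/(s-1)`` for
    variants vanishing at 1.  For ``s < 1`` the quotient diverges (+inf) for
    every variant except the unimodal map, whose Q_V is the constant
    ``4 s (2 - s)``.
    """
    variant = _as_variant(variant)
    if not 0.0 < s < 2.0:
        raise DomainError(f"s must lie in (0, 2); got {s!r}")
    if s == 1.0:
        raise UndefinedCaseError("s = 1 separates the two boundary regimes")
    if s > 1.0:
        f1 = float(evaluate(variant, 1.0))
        return s * (f1 + float(evaluate(variant, s - 1.0)) / (s - 1.0))
    if variant.kind == "unimodal":
        return 4.0 * s * (2.0 - s)
    return math.inf


@dataclass(frozen=True)
class CriticalResult:
    """Root of a defining transcendental equation, with solver evidence."""

    value: float
    residual: float
    bracket: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.bracket
        if not lo <= self.value <= hi:
            raise ValueError("root escaped its bracket")


def _bisect_root(func, lo: float, hi: float, tolerance: float) -> CriticalResult:
    """Bracketing root find refined until ``|func| < tolerance``."""
    if tolerance <= 0.0:
        raise DomainError("tolerance must be positive")
    if func(lo) * func(hi) > 0:
        raise RuntimeError(f"no sign change on bracket ({lo}, {hi})")
    root = brentq(func, lo, hi, xtol=1e-15, rtol=8.9e-16)
    residual = abs(func(root))
    if residual >= tolerance:
        raise RuntimeError(
            f"root residual {residual:g} did not reach tolerance {tolerance:g}"
        )
    return CriticalResult(value=float(root), residual=residual, bracket=(lo, hi))


def solve_critical_s0(tolerance: float = 1e-10) -> CriticalResult:
    """Critical jumping parameter where Q_V's boundary limit meets its center.

    Root in (1, 2) of ``s H(s-1)/(s-1) - 4 H(s/2) = 0``: below the root the
    center value of Q_V lies under the boundary limit, above it over.  The
    root is exactly 4/3 (the equation reduces to ``4 H(1/3) = 4 H(2/3)``
    there), printing as 1.33.  Note the center's own curvature does not
    change sign here but at ~1.4307 (see the module docstring).
    """
    def g(s: float) -> float:
        return s * shannon_h(s - 1.0) / (s - 1.0) - 4.0 * shannon_h(s / 2.0)

    return _bisect_root(g, 1.0 + 1e-6, 2.0 - 1e-6, tolerance)


def solve_sigma_lt_itr_threshold(tolerance: float = 1e-10) -> CriticalResult:
    """Upper end ``s*`` of the regime where the case-B floor of Q_sigma is >= 1.

    Root in (1.2, 2) of ``H(s-1)/sqrt(s-1) = 1``.  For ``1 < s < s*`` (apart
    from a thin layer at s -> 1+ where the floor dips below 1) the
    transmission rate exceeds the fluctuation level sigma regardless of how
    the transition probabilities split ``s``.
    """
    def g(s: float) -> float:
        return shannon_h(s - 1.0) / math.sqrt(s - 1.0) - 1.0

    return _bisect_root(g, 1.2, 2.0 - 1e-6, tolerance)


@dataclass(frozen=True)
class QuotientCurve:
    """A sampled quotient curve at fixed ``s``.

    The grid spans the open admissible interval inset by ``epsilon`` at each
    end and always has an odd number of points so the midpoint ``s/2`` is
    sampled exactly.
    """

    s: float
    variant: EntropyVariant
    quotient_kind: str
    grid: np.ndarray
    values: np.ndarray
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        if self.quotient_kind not in ("sigma", "variance"):
            raise ValueError(f"unknown quotient kind {self.quotient_kind!r}")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        lo, hi = admissible_p10_interval(self.s)
        if self.grid[0] <= lo or self.grid[-1] >= hi:
            raise ValueError("grid must lie inside the open admissible interval")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("quotient values must be finite and nonnegative")

    def to_table(self, path, delimiter: str = "\t") -> None:
        """Write (p10, value, kind) rows with a commented provenance header."""
        header = (
            f"s={self.s!r} variant={self.variant.kind} "
            f"epsilon={self.epsilon!r} n_points={len(self.grid)}\n"
            f"p10{delimiter}value{delimiter}quotient_kind"
        )
        rows = np.rec.fromarrays(
            [self.grid, self.values, np.full(len(self.grid), self.quotient_kind)],
            names="p10,value,kind",
        )
        with open(path, "w") as fh:
            for line in header.split("\n"):
                fh.write(f"# {line}\n")
            for r in rows:
                fh.write(f"{r.p10:.10g}{delimiter}{r.value:.10g}{delimiter}{r.kind}\n")


def curve(
    s: float,
    variant: EntropyVariant | str = "shannon",
    quotient_kind: str = "sigma",
    n_points: int = 1001,
    epsilon: float = DEFAULT_EPSILON,
) -> QuotientCurve:
    """Sample Q_sigma or Q_V on a uniform grid over the admissible interval.

    ``n_points`` is forced odd so the symmetry point is a grid node.
    """
    if n_points < 3:
        raise DomainError("n_points must be >= 3")
    if quotient_kind not in ("sigma", "variance"):
        raise DomainError(f"unknown quotient kind {quotient_kind!r}")
    variant = _as_variant(variant)
    if n_points % 2 == 0:
        n_points += 1
    lo, hi = admissible_p10_interval(s)
    grid = np.linspace(lo + epsilon, hi - epsilon, n_points)
    func = q_sigma if quotient_kind == "sigma" else q_variance
    values = func(s, grid, variant)
    return QuotientCurve(
        s=s, variant=variant, quotient_kind=quotient_kind,
        grid=grid, values=np.asarray(values), epsilon=epsilon,
    )


def count_local_extrema(curve_obj: QuotientCurve) -> int:
    """Number of strict interior local extrema after plateau merging.

    Consecutive equal values are collapsed to one node; the outermost grid
    points are never counted.
    """
    vals = np.asarray(curve_obj.values, dtype=float)
    if len(vals) < 5:
        raise DomainError("curve must have at least 5 points")
    # steps below a few ulp of the curve scale count as plateau, so an
    # analytically constant curve is flat despite rounding jitter
    tol = 1e-12 * max(1.0, float(np.max(np.abs(vals))))
    d = np.diff(vals)
    signs = np.sign(d)
    signs[np.abs(d) <= tol] = 0
    signs = signs[signs != 0]
    if signs.size < 2:
        return 0
    return int(np.sum(signs[:-1] * signs[1:] < 0))
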