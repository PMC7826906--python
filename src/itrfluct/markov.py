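"""Two-state Markov information source: stationary law, rate, fluctuation.

A binary information source (a spike train encoded 0/1 per time bin) is
modeled as a two-state Markov chain with per-bin transition probabilities
``p10`` (0 -> 1) and ``p01`` (1 -> 0).  The column-stochastic transition
matrix is

    P = [[1 - p10, p01],
         [p10,     1 - p01]]

acting on column probability vectors, so state probabilities evolve as
``v_{n+1} = P v_n``.  The jumping parameter ``s = p01 + p10 = 2 - tr(P)``
measures the tendency to switch states: ``s = 1`` is the memoryless
(Bernoulli) case, ``s < 1`` persistent, ``s > 1`` anti-persistent.

For ``0 < s < 2`` the chain has the unique stationary law
``Peq(0) = p01/s, Peq(1) = p10/s``; its entropy rate (information
transmission rate, bits/symbol) is

    ITR = Peq(0) * H(p10) + Peq(1) * H(p01)

with H the binary Shannon entropy, or one of its polynomial surrogates from
:mod:`itrfluct.entropy`.  The fluctuation of the emitted 0/1 stream is
``sigma = sqrt(Peq(0) * Peq(1))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .entropy import DomainError, EntropyVariant, evaluate, shannon_h

__all__ = [
    "MarkovParams",
    "StationaryDist",
    "ProbVector",
    "DegenerateChainError",
    "from_s_and_p10",
    "admissible_p10_interval",
    "transition_matrix",
    "stationary_distribution",
    "master_step",
    "itr",
    "bernoulli_itr",
    "sigma",
    "variance",
    "capacity",
]


class DegenerateChainError(ValueError):
    """Raised for s = 0 (two absorbing states) or s = 2 (period-2 chain)."""


@dataclass(frozen=True)
class MarkovParams:
    """Transition probabilities of the two-state source.

    Attributes
    ----------
    p10
        Probability of a 0 -> 1 transition per time bin.
    p01
        Probability of a 1 -> 0 transition per time bin.
    s
        Derived jumping parameter ``p01 + p10``.
    """

    p10: float
    p01: float
    s: float = field(init=False)

    def __post_init__(self) -> None:
        for name in ("p10", "p01"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DomainError(f"{name} must lie in [0, 1]; got {v!r}")
        object.__setattr__(self, "s", self.p10 + self.p01)


@dataclass(frozen=True)
class StationaryDist:
    """Equilibrium occupation probabilities of states 0 and 1."""

    peq0: float
    peq1: float

    def __post_init__(self) -> None:
        if abs(self.peq0 + self.peq1 - 1.0) > 1e-12:
            raise ValueError("stationary probabilities must sum to 1")
        if not (0.0 <= self.peq0 <= 1.0 and 0.0 <= self.peq1 <= 1.0):
            raise ValueError("stationary probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class ProbVector:
    """State-probability column vector at one instant of the master equation."""

    pn0: float
    pn1: float

    def __post_init__(self) -> None:
        if self.pn0 < 0.0 or self.pn1 < 0.0:
            raise ValueError("probabilities must be nonnegative")
        if abs(self.pn0 + self.pn1 - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")


def admissible_p10_interval(s: float) -> tuple[float, float]:
    """Closed interval of valid ``p10`` at fixed ``s``: [0, s] or [s-1, 1]."""
    if not 0.0 < s < 2.0:
        raise DomainError(f"s must lie in (0, 2); got {s!r}")
    return (max(0.0, s - 1.0), min(1.0, s))


def from_s_and_p10(s: float, p10: float) -> MarkovParams:
    """Build the source from the jumping parameter and ``p10``.

    ``p01 = s - p10``; ``p10`` must lie in [0, s] when s <= 1 and in
    [s-1, 1] when s > 1 for both transition probabilities to be valid.
    """
    lo, hi = admissible_p10_interval(s)
    if not lo <= p10 <= hi:
        raise DomainError(
            f"p10 = {p10!r} outside the admissible interval "
            f"[{lo:g}, {hi:g}] for s = {s!r}"
        )
    return MarkovParams(p10=p10, p01=s - p10)


def transition_matrix(params: MarkovParams) -> np.ndarray:
    """Column-stochastic 2x2 transition matrix P (columns sum to 1)."""
    return np.array(
        [[1.0 - params.p10, params.p01], [params.p10, 1.0 - params.p01]]
    )


def _require_ergodic(params: MarkovParams) -> None:
    if params.s <= 0.0 or params.s >= 2.0:
        raise DegenerateChainError(
            f"s = {params.s:g}: the chain has no unique stationary "
            "distribution (s=0: absorbing states; s=2: period-2)"
        )


def stationary_distribution(params: MarkovParams) -> StationaryDist:
    """Unique fixed point of the master equation for ``0 < s < 2``."""
    _require_ergodic(params)
    return StationaryDist(peq0=params.p01 / params.s, peq1=params.p10 / params.s)


def master_step(dist: ProbVector, params: MarkovParams) -> ProbVector:
    """One master-equation update ``v -> P v``."""
    p0 = (1.0 - params.p10) * dist.pn0 + params.p01 * dist.pn1
    p1 = params.p10 * dist.pn0 + (1.0 - params.p01) * dist.pn1
    # renormalize away accumulated rounding so the invariant holds under iteration
    total = p0 + p1
    return ProbVector(pn0=p0 / total, pn1=p1 / total)


def itr(params: MarkovParams, variant: EntropyVariant | str = "shannon") -> float:
    """Information transmission rate ``Peq(0) f(p10) + Peq(1) f(p01)``.

    With the Shannon variant this is the exact entropy rate of the chain in
    bits per symbol; with a polynomial variant it is the analogous
    dimensionless quantity.
    """
    eq = stationary_distribution(params)
    if not isinstance(variant, EntropyVariant):
        variant = EntropyVariant(variant)
    return eq.peq0 * evaluate(variant, params.p10) + eq.peq1 * evaluate(
        variant, params.p01
    )


def bernoulli_itr(p: float) -> float:
    """Entropy rate ``H2(p)`` of the memoryless (s = 1) source, bits/symbol."""
    return shannon_h(p)


def sigma(params: MarkovParams) -> float:
    """Stationary standard deviation ``sqrt(Peq(0) Peq(1))`` of the 0/1 stream.

    Equals ``sqrt((s - p10) p10) / s``; at most 1/2, with equality iff the
    stationary law is uniform.
    """
    eq = stationary_distribution(params)
    return float(np.sqrt(eq.peq0 * eq.peq1))


def variance(params: MarkovParams) -> float:
    """Stationary variance ``Peq(0) Peq(1)`` of the emitted bits."""
    eq = stationary_distribution(params)
    return eq.peq0 * eq.peq1


def capacity(s: float) -> float:
    """Capacity ``1 - H2(s/2)`` of the symmetric channel with crossover s/2."""
    if not 0.0 < s < 2.0:
        raise DomainError(f"s must lie in (0, 2); got {s!r}")
    return 1.0 - shannon_h(s / 2.0)
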