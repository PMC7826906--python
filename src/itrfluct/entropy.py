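"""Binary entropy and its polynomial surrogates.

The entropy rate of a two-state Markov source is a stationary-weighted sum
of binary Shannon entropies of the transition probabilities.  To probe how
that rate behaves asymptotically it is useful to swap the Shannon entropy
``H2`` for smooth polynomial stand-ins that are close to it in sup norm:

* ``taylor10`` — the truncated power series of ``H2`` about p = 1/2,
  ``1 - (1/ln 4) * sum_{n=1..N} (1-2p)^{2n} / (n(2n-1))`` (default N = 10);
* ``unimodal`` — the logistic (unimodal) map ``U(p) = 4p(1-p)``;
* ``unimodal_root`` — its square root ``2*sqrt(p(1-p))``.

All four are symmetric about p = 1/2, peak there with value exactly 1, and
map [0, 1] into [0, 1] (up to the truncation residue of ``taylor10`` at the
endpoints, where the series converges slowly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EntropyVariant",
    "VARIANT_KINDS",
    "shannon_h",
    "taylor_h",
    "unimodal_u",
    "unimodal_root",
    "evaluate",
]

VARIANT_KINDS = ("shannon", "taylor10", "unimodal", "unimodal_root")

#: slack allowed before an out-of-domain probability raises instead of
#: being clamped — covers floating-point slop from upstream arithmetic
_CLAMP_TOL = 1e-12


class DomainError(ValueError):
    """A probability or parameter lies outside its admissible domain."""


@dataclass(frozen=True)
class EntropyVariant:
    """Selector for the entropy-like function used inside the rate formula.

    Parameters
    ----------
    kind
        One of ``"shannon"``, ``"taylor10"``, ``"unimodal"``,
        ``"unimodal_root"``.
    n_terms
        Number of series terms kept by ``taylor10`` (ignored otherwise).
    """

    kind: str = "shannon"
    n_terms: int = 10

    def __post_init__(self) -> None:
        if self.kind not in VARIANT_KINDS:
            raise ConfigurationError(
                f"unknown entropy variant {self.kind!r}; "
                f"expected one of {VARIANT_KINDS}"
            )
        if self.n_terms < 1:
            raise ConfigurationError("n_terms must be a positive integer")

    def __call__(self, p):
        return evaluate(self, p)


class ConfigurationError(ValueError):
    """An entropy-variant selector is malformed."""


def _check_prob(p, name: str = "p"):
    """Validate (arraywise) that ``p`` lies in [0, 1], clamping fp slop."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr < -_CLAMP_TOL) or np.any(arr > 1.0 + _CLAMP_TOL):
        bad = arr[(arr < -_CLAMP_TOL) | (arr > 1.0 + _CLAMP_TOL)]
        raise DomainError(
            f"{name} must lie in [0, 1]; got {float(np.ravel(bad)[0])!r}"
        )
    clipped = np.clip(arr, 0.0, 1.0)
    return clipped if arr.ndim else float(clipped)


def shannon_h(p):
    """Binary Shannon entropy ``H2(p) = -p log2 p - (1-p) log2 (1-p)`` in bits.

    Accepts scalars or arrays; endpoints return exactly 0 by the continuity
    convention ``0 * log2 0 = 0``.
    """
    p = _check_prob(p)
    arr = np.atleast_1d(np.asarray(p, dtype=float))
    out = np.zeros_like(arr)
    interior = (arr > 0.0) & (arr < 1.0)
    q = arr[interior]
    out[interior] = -q * np.log2(q) - (1.0 - q) * np.log2(1.0 - q)
    return float(out[0]) if np.isscalar(p) else out.reshape(np.shape(p))


def taylor_h(p, n_terms: int = 10):
    """Truncated Taylor series of ``H2`` about p = 1/2, in bits.

    ``1 - (1/ln 4) * sum_{n=1..n_terms} (1-2p)^{2n} / (n(2n-1))``.  The full
    series sums to ``H2``; truncation leaves a positive residue at p = 0, 1
    (about 0.0352 for 10 terms) because convergence is slowest there.
    """
    if n_terms < 1:
        raise DomainError("n_terms must be >= 1")
    p = _check_prob(p)
    x2 = (1.0 - 2.0 * np.asarray(p, dtype=float)) ** 2
    n = np.arange(1, n_terms + 1, dtype=float)
    # powers x2^n stacked over the last axis, summed with series weights
    terms = x2[..., None] ** n / (n * (2.0 * n - 1.0))
    result = 1.0 - terms.sum(axis=-1) / np.log(4.0)
    return float(result) if np.isscalar(p) else result


def unimodal_u(p):
    """Logistic (unimodal) map ``U(p) = 4p(1-p)``."""
    p = _check_prob(p)
    arr = np.asarray(p, dtype=float)
    result = 4.0 * arr * (1.0 - arr)
    return float(result) if np.isscalar(p) else result


def unimodal_root(p):
    """Square root of the unimodal map, ``2*sqrt(p(1-p))``."""
    p = _check_prob(p)
    arr = np.asarray(p, dtype=float)
    result = 2.0 * np.sqrt(arr * (1.0 - arr))
    return float(result) if np.isscalar(p) else result


def evaluate(variant: EntropyVariant, p):
    """Dispatch ``p`` through the function selected by ``variant``."""
    if not isinstance(variant, EntropyVariant):
        variant = EntropyVariant(str(variant))
    if variant.kind == "shannon":
        return shannon_h(p)
    if variant.kind == "taylor10":
        return taylor_h(p, variant.n_terms)
    if variant.kind == "unimodal":
        return unimodal_u(p)
    if variant.kind == "unimodal_root":
        return unimodal_root(p)
    raise ConfigurationError(f"unknown entropy variant {variant.kind!r}")
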