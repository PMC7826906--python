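# Methods

## Model and scope

The source is a time-homogeneous two-state Markov chain over the alphabet
{0, 1}, the standard binary encoding of a spike train at fixed time
resolution.  The column-stochastic transition matrix

    P = [[1 − p10, p01],
         [p10,     1 − p01]]

acts on column probability vectors (`v_{n+1} = P v_n`); this orientation is
used everywhere to avoid transposition bugs.  The jumping parameter
`s = p10 + p01 = 2 − tr P` together with `p10` determines the source
completely.  For `0 < s < 2` the unique stationary law is
`Peq(0) = p01/s`, `Peq(1) = p10/s`.  The degenerate endpoints are rejected
by every operation that needs the stationary law: `s = 0` has two absorbing
states and `s = 2` is the period-2 chain with an oscillating law; returning
one of several candidate "solutions" silently would be worse than an error.
Boundary transition probabilities (`p10 ∈ {0, 1}`) are allowed wherever the
formulas stay finite; there `σ = 0` and the quotients are handled as limits.

Fluctuation is measured on the emitted values {0, 1} themselves:
`σ = sqrt(Peq(0)·Peq(1))`, `V = σ²`.  No general-alphabet fluctuation is
implemented.

## Entropy variants

Four functions can serve as the `H` inside the rate formula:

| kind           | f(p)                                   | units  |
|----------------|----------------------------------------|--------|
| `shannon`      | −p log₂ p − (1−p) log₂ (1−p)           | bits   |
| `taylor10`     | 1 − (1/ln 4) Σₙ (1−2p)²ⁿ/(n(2n−1)), n ≤ 10 | bits |
| `unimodal`     | 4p(1−p)                                | —      |
| `unimodal_root`| 2√(p(1−p))                             | —      |

The Taylor truncation is taken about p = 1/2: the binary entropy is not
analytic at 0 or 1, so the expansion point is forced, and the resulting
curve matches the intended sup-norm approximation ("10 terms" is read as
ten series terms, i.e. polynomial degree 20).  Truncation leaves a positive
residue at the endpoints, `f(0) = f(1) = (2 ln 2 − Σ₁¹⁰ 1/(n(2n−1)))/ln 4 ≈
0.035167`; on [0.01, 0.99] the sup-norm distance to the Shannon entropy is
≈ 0.0132, and the unimodal map's is ≈ 0.1091 on all of [0, 1].  The
endpoint residue has real consequences downstream: the case-A boundary
limits of the quotients differ by variant (below).

`0·log₂0 = 0` by continuity; endpoint calls return exactly 0, never NaN.
Probabilities out of [0, 1] by ≤ 1e−12 (floating-point slop from upstream
arithmetic like `s − p`) are clamped; larger violations raise a domain
error naming the offending value.

## Quotients and their boundary structure

At fixed `s` the quotients `Q_σ = ITR/σ` and `Q_V = ITR/V` are evaluated in
the closed forms given in the README.  Both are 0/0 at the exact interval
endpoints, so sampled curves live on the open interval inset by a
configurable `epsilon` (default 1e−6) and the closed-form limit operations
supply endpoint values.  Grids always contain an odd number of points so
the symmetry point `p = s/2` is sampled exactly.

Boundary limits are computed per variant rather than assuming `f(0) = f(1) = 0`:

* `s > 1`, `p → 1⁻` (and its mirror): `Q_σ → √(s−1)·f(1) + f(s−1)/√(s−1)`
  and `Q_V → s·[f(1) + f(s−1)/(s−1)]`, which reduce to `f(s−1)/√(s−1)` and
  `s·f(s−1)/(s−1)` for variants vanishing at 1.
* `s < 1`, `p → 0⁺`: `Q_σ → 0` for `shannon`/`unimodal`, `2√s` for
  `unimodal_root`, and +∞ for `taylor10` (its positive endpoint residue is
  amplified by `√(s/p)`).  `Q_V → +∞` for every variant except `unimodal`,
  whose `Q_V` is identically `4s(2−s)`.

All finite limits are verified in the tests against direct evaluation at
distance 1e−8 from the boundary.

Critical parameters are roots of scalar monotone-crossing residuals, found
with `scipy.optimize.brentq` (bracketing, guaranteed convergence) on the
brackets (1+1e−6, 2−1e−6) for `s0` and (1.2, 2−1e−6) for `s*`, refined to
machine precision and validated against the caller's residual tolerance.
`s0` is exactly 4/3: at `s = 4/3` the defining equality reduces to
`4H(1/3) = 4H(2/3)`, true by symmetry of `H`.

### Extremum structure of Q_V, and two corrected claims

Write `g(p) = H(p)/p`, so `Q_V(p) = s·[g(p) + g(s−p)]` and the curvature at
the center is `2s·g''(s/2)`.  `g''` has a single sign change at
`p* ≈ 0.715332`, hence the center of `Q_V` switches from local minimum to
local maximum at `s = 2p* ≈ 1.430664` — not at `s0 = 4/3`.  Exact numerics
(grids up to 20001 points plus the near-boundary expansion) give, for the
Shannon variant in case B:

* `1 < s < 1.4307`: three interior extrema — a center minimum flanked by
  two maxima (e.g. `s = 1.3`: center `4H(0.65) ≈ 3.7363`, boundary limit
  `≈ 3.8189`, maxima near `p ≈ 0.333` and `0.967`);
* `s > 1.4307`: a single interior extremum — the curve rises monotonically
  from the boundary limit to the center maximum (e.g. `s = 1.5`: from 3.0
  to `4H(0.75) ≈ 3.2451`).

Two statements commonly made about this family do not survive exact
evaluation: that the center is a maximum below `s0` and a minimum above it
(the curvature is positive on both sides of 4/3; what flips at `s0` is
whether the center value lies below or above the boundary limit), and that
the three-extrema shape is visible at `s = 1.5` (it ends at ≈ 1.4307).  The
acceptance-style tests assert the conventional statements and are left
failing by design, with the correct behavior pinned by separate tests.

A related caveat near `s → 1⁺`: the case-B floor `H(s−1)/√(s−1)` dips
below 1 (e.g. ≈ 0.81 at `s = 1.01`), so the guarantee `σ < ITR` on
`1 < s < s*` is not uniform in that thin layer.  The package exposes both
the floor function and the threshold `s*` so users can see this directly.

Extremum counting works on the sampled grid: steps below `1e−12 ×` the
curve scale are treated as plateau (so the analytically constant unimodal
`Q_V` counts zero extrema despite rounding jitter), runs of equal values
are merged, and sign changes of consecutive increments are counted;
outermost points are never extrema.  The 1001-point default resolves the
shallow case-B features; note that for `s` very close to 1 the two
off-center maxima sit in a boundary layer thinner than the default
`epsilon = 1e−6` inset and are deliberately not chased.

## Simulator and estimators

Trajectories are drawn by sampling the initial state from the stationary
law and then alternating sojourn times, which for a two-state chain are
exactly geometric (parameter = probability of leaving the current state).
This is distributionally identical to bin-by-bin stepping, fully
vectorized, and reproducible: the same `(params, n, seed)` always yields
the same bits (numpy `default_rng`; the seed is recorded on the
trajectory and in all reports).  Absorbing corner cases (`p10 = 0` or
`p01 = 0`) are handled explicitly.

Rate estimation is the raw plug-in route: overlapping length-L words
(overlap maximizes data use), empirical word frequencies, Shannon entropy
`Ĥ(Z^L)`, and either `Ĥ(Z^L)/L` (`block_average`, the finite-L rate, an
overestimate for autocorrelated sources and decreasing in L) or
`Ĥ(Z^L) − Ĥ(Z^{L−1})` (`conditional`, which converges much faster for
Markov sources and is the default).  No bias correction (Miller–Madow,
NSB, CTW) is applied — the estimators implement the plain definitions.
Unobserved words contribute zero by the `0·log 0` convention.  Requests
with `n < 2^L` are a hard error; `n < 50·2^L` warns, and the automatic L
choice takes the largest L with `n ≥ 50·2^L`, capped at 12, which keeps
plug-in bias below the tolerances used in the closure checks at `n = 10^6`.

Calibration of those tolerances is empirical: for `(p10, p01) = (0.2, 0.3)`
at `n = 10^6`, a 20-seed pilot gave maximum absolute deviations ≈ 0.0018
(conditional ITR, L = 10) and ≈ 0.0004 (RMS), so the suite asserts 0.01 and
0.005 — roomy but meaningful.  The closure checks validate the algebra of
the closed forms, the simulator, and the estimators against each other;
they do not address real spike recordings, whose binning, nonstationarity
and refractory structure are outside this package's scope.

## Problem sizes

Defaults used by the tests and the reproduction script: 1001-point curve
grids (20001 for the fine-structure checks), 1999-point `s` grid for the
global maximum, `n = 10^6` bins and 20 seeds for Monte-Carlo closure,
100 random draws for fixed-point and symmetry properties.  All are desk
scale: the full suite runs in a few seconds.

## Known limitations

* Only two-state, discrete-time, stationary sources; no multi-state or
  continuous-time generalizations, and no fitting to experimental data.
* The polynomial entropy family is fixed; Rényi/Tsallis entropies are not
  implemented.
* Empirical estimates carry plug-in bias at small `n/2^L`; the package
  warns rather than corrects.
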