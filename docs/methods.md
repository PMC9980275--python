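# Methods

## Model

The package represents a symbol stream twice, as paired populations indexed
by a rate constant `s` (the "Laplace space") and by a preferred delay `τ*`
(the "inverse space").

**Past.** For each symbol the past state holds `F-(s) = Σ_j e^{-s(t-t_j)}`
over a geometric grid of N rate constants from `smax` down to `smin`
(`make_s_grid` uses `numpy.geomspace`, so both endpoints are exact and the
step ratio r is constant to machine precision). Presenting a symbol adds 1
at every `s` (the transform of an impulse at the present); the passage of
time multiplies each component by `e^{-s·dt}`. Both operations are exact in
`dt`, so the state after any event sequence equals the closed form
(`closed_form_past`), which the property tests verify to 1e-10 over random
interleavings. An exact `s = 0` channel (the plain impulse count) rides
along with the grid and is used wherever a zero-frequency (probability)
readout is required exactly.

**Future.** The predicted future is a list of delta sources
`(symbol, p, τ_rem)` rendered as `Σ p·e^{-s·τ_rem}`. Approaching the
present corresponds to multiplying the rendered vector by `e^{+s·dt}`;
because that literal update is numerically explosive, the sources are
stored and the rendering recomputed — the literal identity is asserted
step-by-step in the tests instead of being iterated. A prediction has
reached the present when its rendered value at `smax` (the proxy for
`s → ∞`) exceeds a fraction ε of its weight; it is then removed in full and
emitted as an arrival event. Arrivals not matched by an observation within
one `Δt` are retagged "not symbols"; they are logged but neither learn nor
predict. Whole sources are removed at the boundary (the general
partial-removal case for non-delta futures is deliberately out of scope).

**Inverse space.** `post_inverse` implements the Post approximation
`f̃(τ*) = [(-1)^k / k!] s^{k+1} F^{(k)}(s)` with `s = k/τ*`, so
`τ*_n = k/s_n` inherits the log spacing of the grid. The k-th derivative is
estimated by k repeated three-point central differences taken along the
uniform log-s axis and converted by the chain rule `dF/ds = (dF/dn)/(s ln
r)`. We also provide the quadratic-exact non-uniform stencil
(`log_grid_derivative(..., method="nonuniform")`), but under repeated
application on a geometric grid its truncation errors compound to ~8%
relative error at a delta input's peak (k = 4, N = 64), whereas the
log-axis scheme stays near 2%; the inverse transform therefore uses the
log-axis scheme. For a delta at lag `τ0` the kernel peaks at
`τ* = τ0·k/(k+1)` and depends on `s·τ0` only, so its full width at half
maximum is constant in grid-index units — the bump translates rigidly along
the log-time axis. Finite-difference ringing below zero is clipped (the
fields model firing rates), with the largest clipped magnitude available as
a diagnostic; the outer `k/2 + 1` points per edge are excluded from peak
statistics.

**Associative memory.** On each presentation of a symbol, at every
forgetting rate ρ on the grid: connections *from* it (it as source) decay
by ρ; connections *to* it increment by `(1-ρ)·F-(s)`. Decay is applied
before increment (the order only matters for self-pairs, which the
simulator never produces because prediction, learning and encoding happen
in that order within a presentation). In the ρ → 1 steady state
`M_yx(s) = P(y|x)·E[e^{-s·τ_xy}]`; `steady_state_oracle` evaluates this
exactly for fixed, discrete-uniform and gamma lags and is the independent
check on the learned weights. The predecessor weights `M̄_xy` decay on the
*present* symbol's column and carry a mirrored `-s` half learned from a
within-trial growing trace `Σ e^{+s(t-t_j)}`; entries whose exponent would
exceed 30 are NaN-masked and excluded downstream (within a bounded trial
`E[e^{+sτ}]` is finite, but not representable at large `s·τ`).

**Contingency.** The direct curve `M_zy(+s)` and the mediated product
`M_zx(+s)·M̄_xy(-s)` store the transforms of `τ_xz - τ_xy` and of the
convolution `τ_xz * (-τ_xy)` respectively; they are equal iff the lags are
independent across trials. The divergence statistic is the maximum of
|log(direct/mediated)| over valid grid points, with both curves floored at
1e-12. Valid points are those with finite mirrored entries *and* where both
curves retain at least 5% of their maximum: because both curves are built
from the same ρ-weighted trials, their sampling fluctuations cancel to
first order in `s × (lag spread)`, and the log-ratio only becomes
noise-dominated deep in the exponential tail — the 5% relative floor cuts
the comparison off before that happens. Credit goes to the mediator when
the divergence is within tolerance (default 0.05, matched to the trained
oracle error bound), to the candidate otherwise, and is indeterminate on
untrained rows. The `s = 0` (associative) comparison uses the smallest grid
`s` as a proxy, with bias `|e^{-smin·τ} - 1| ≤ smin·τ_max` per factor
(< 2% per factor for single-digit lags on the default grid); note the
temporal route's mediated value reads `M̄` at `-s` and so sits a factor
`e^{+2·smin·τ_xy}` above the associative proxy.

**Trial history.** With a continuum of ρ, each weight equals
`(1-ρ)·Σ_i ρ^i h[i] e^{-s τ[i]}` — the Z-transform of its own trial history
— and `ztransform_forward` reproduces the learned weight to 1e-12 as an
executable identity. Inversion is by non-negative least squares against the
design `A[m,i] = (1-ρ_m)ρ_m^i` (histories are non-negative and sparse,
where NNLS is reliable); the design's condition number is reported because
the numerical rank of the geometric design is ~12 on a 24–32 point ρ grid,
so recovery is trustworthy for sparse histories (the tests verify ≥95% of
mass within ±1 lag for up to 5 pairings in a 20-trial horizon) and
degrades for dense ones and under measurement noise. The final decoded lag
absorbs all history beyond the horizon and is excluded from history
correlations. The three-point history correlation decodes `M_zy(ρ, s=0)`
and `M̄_xy(ρ, s=0)` over a shared horizon and correlates the lag weights; a
raw-profile variant (`use_decoded=False`) is available. Because dense
Bernoulli histories exceed the design's resolution, the null distribution
of this correlation is wide; the robust signature is the paired comparison
(conjunctive world above its matched null), which is what the tests assert.
History images divide out `(1-ρ)` via the design matrix and unfold a weight
into (trial lag × log time).

## Simulator

Schedules are declarative: per symbol, an occurrence probability (marginal
or conditional on other symbols that trial) and a lag distribution drawn
relative to an anchor (trial start or another symbol). Timing dependencies
are expressed through anchoring — chaining z on y makes `τ_xz = τ_xy +
τ_yz` trial by trial, anchoring z on x draws it independently. Each symbol
occurs at most once per trial and generation is a pure function of the
seed. Trials are rendered `span + iti` apart with the inter-trial interval
floored at `10/smin` so the past state's carryover between trials is
`< e^{-10}` even without reset.

The driver applies, within each presentation: predict (probe `M` with the
present symbol and inject delta sources, decoded by an exact-on-exponentials
log-linear fit, with an optional sampling mode for multi-modal rows), then
learn, then encode. States evolve exactly between events; boundary arrivals
are emitted at the first `Δt` multiple after threshold crossing, which is
identical to literal `Δt` stepping (stepping is still available for
per-step snapshot logging). Per-trial past/anti-trace reset is on by
default — it realizes the long-ITI limit exactly at desk scale — and can be
switched off.

## Parameter defaults

| parameter | default | units | rationale |
|---|---|---|---|
| `Δt` | 0.1 | time | duration of the "present"; quantizes only event emission |
| `smax` | 10 | 1/time | of order `1/Δt` |
| `smin` | 0.01 | 1/time | `1/smin` exceeds any demo delay; sets the s≈0 proxy bias |
| N | 64 | — | dense enough that the k=4 Post kernel spans ~9 indices |
| k | 4 | — | Post order: sharpness vs differentiation noise |
| ε | 0.5 | — | boundary threshold as a fraction of source weight |
| ρ grid | 24 values, `1-ρ` geometric 0.5 → 0.002 | — | spans trial horizons from ~2 to ~500 trials |
| horizon | 20 | trials | `ρ^horizon` spans > 2 decades across the grid |
| ITI | 1000 | time | `10/smin` floor |

Study-condition defaults (trial counts, probabilities, lags) live in
`laplacemem.demos`; the closed-form comparisons use n = 2000–5000 trials
with ρ = 0.99–0.995, where the exponentially weighted estimates have
relative standard errors of a few percent (the EWMA's variance factor is
`(1-ρ)/(1+ρ)` regardless of n, so precision is set by ρ, not by running
longer).

## What the generator does and does not emulate

The simulator produces Poisson-free, noiseless impulse observations on a
discrete-trial scaffold: symbols are binary events with exact times, at
most one occurrence per trial, and stationary statistics. It does not
emulate firing-rate noise, overlapping or continuous stimuli, within-trial
repeats, non-stationary contingencies, or subjective-time modulation (the
time-flow factors are fixed at ±1). Passing tests therefore demonstrate the
algebraic and statistical properties of the representations — transform
identities, recovery of probabilities and lag distributions, detection of
timing dependence, history decoding — not robustness to biological noise;
the conditioning surfaced by the decoder (and the record of masked
mirrored entries) indicates where real-data noise would bite first.

## Known limitations

- The mirrored `-s` axis is representable only up to `s·T_trial ≤ 30`;
  contingency comparisons silently lose large-s points for long trials
  (they are excluded from the divergence, never imputed).
- One estimator cannot make `E[e^{-sτ}]` precise at large `s` relative to
  the lag scale: the EWMA's relative error grows like the inverse of the
  retained tail mass. Curve recovery statements are therefore phrased
  against the curve's maximum.
- NNLS history decoding resolves sparse histories; dense histories collapse
  onto the design's ~12-dimensional identifiable subspace.
- Boundary handling removes whole delta sources; distributed (non-delta)
  futures would need partial subtraction, which is out of scope.
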