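# Methods

## The null model and the test

The data unit is a *point field*: the positions of all tracked organisms in
one video frame, affinely normalized from the physical channel extents onto
the unit square.  Normalization always uses the configured channel bounds —
never per-frame minima/maxima, which would rescale each frame differently
and corrupt the time evolution of the statistic.  Each frame is projected
onto its two coordinate marginals: the **cross** axis runs across the three
fluid bands (the direction in which a loaded chemical creates structure),
the **long** axis runs along the channel and serves as a negative control.

The null hypothesis for a 1-D marginal is a homogeneous Poisson process:
counts in disjoint subsets are independent and Poisson with mean
proportional to subset length; the intensity estimate on the unit interval
is simply the total count `n`.  Partitioning `[0,1]` into `k` equal cells
gives quadrat counts `N_1..N_k`, i.i.d. Poisson(n/k) under the null, and the
dispersion index

    I = (k-1) S² / N̄ = Σᵢ (Nᵢ - N̄)² / N̄

is approximately χ²(k−1).  Conventions, fixed after the following
considerations:

* `S²` uses divisor `k−1` (unbiased sample variance).  This makes `I` the
  classical index-of-dispersion / Poisson goodness-of-fit statistic whose
  χ²(k−1) null distribution the rejection rule invokes.
* The two-sided rejection rule uses the `α/2` and `1−α/2` χ²(k−1) quantiles
  with *strict* inequalities; a statistic exactly on a bound is classified
  `consistent`.  Verdicts: `clustered` above the upper bound, `regular`
  below the lower bound.
* Partition cells are half-open `[i/k, (i+1)/k)` with the last cell closed
  at 1.  No boundary convention is canonical; half-open cells avoid double
  counting, and closing at 1 keeps boundary points.  Cell indices are
  computed as `floor(x·k)`; with this form the refinement identity (counts
  at `k` equal pairwise sums of counts at `2k`) holds *exactly* in floating
  point, which the property tests assert.
* Default `α = 0.05`, reported per test.  **No multiple-testing correction**
  is applied across partition scales or frames; the sweep over `k`
  (default 5..25) is a robustness display, not a family of independent
  tests, and rejection rates aggregated over frames must be read
  accordingly.
* Default `k` range 5..25: at the assay's ~200 organisms per frame the
  per-cell expectation stays ≥ 8, where the χ² approximation to the Poisson
  dispersion statistic is reliable.  Frames with `n < 2·max(k)` are analyzed
  but flagged with a log warning rather than refused.
* Empty frames produce report rows with verdict `undefined` and NaN
  statistics — never silent omission.
* The statistic is computed with correctly-rounded summation (`math.fsum`),
  making it exactly invariant under permutations of the count vector.

The **chemotactic index** is reported alongside: the in-band vs out-of-band
*density* ratio `(N_in/|B|) / (N_out/(1−|B|))` for the loaded band `B`
(default the central third).  Area normalization makes the uniform-field
value 1 for any band geometry; the head-count-only ratio would not have a
geometry-free reference value.  A field entirely inside the band returns
`inf` as an explicit sentinel.

The per-frame test conditions on the observed `n` (organisms, not a random
Poisson total), so the quadrat counts are multinomial rather than Poisson;
the dispersion statistic is then exactly the classical χ² goodness-of-fit
statistic for uniformity, with the same χ²(k−1) reference distribution.
The type-I calibration checks cover both regimes (Poisson-sampled fields
and fixed-n simulator frames).

## Synthetic data

Two Poisson generators provide exact null and alternative fields:
homogeneous (count ~ Poisson(λ), positions i.i.d. uniform) and
inhomogeneous by thinning — candidates at the dominating rate `λ_max`
retained at `x` with probability `λ(x)/λ_max`.  The thinning sampler
validates at run time that the supplied intensity is nonnegative and really
is dominated by its declared bound.

The assay simulator is a biased random walk, the agent-level counterpart of
the Keller–Segel drift–diffusion description.  Per Euler–Maruyama step of
size `dt`, an agent's cross coordinate advances by `χ ∂c/∂x dt` plus a
N(0, 2D·dt) increment; the long coordinate gets the diffusion term only;
both coordinates are folded back into [0,1] by reflection (the channel is
closed on the observation timescale, so reflection conserves agents — the
population density `u` is never represented).  The chemical concentration
`c(x)` is a *static* smoothed indicator of the loaded band: error-function
edges of width `σ`, scaled so the band-center value equals the amplitude,
with an analytic gradient; `σ = 0` degenerates to a sharp indicator with
zero gradient everywhere.  The smoothing width stands in for lateral
diffusion of the chemical after flow stops; an optional linear growth
`σ(t) = σ + rate·t` is available (default off), as is a phenomenological
short-range wall-attraction drift for wall-accumulation peaks (default
off — that phenomenon is occasional, not systematic).  Reproducibility: the
master seed is expanded through `SeedSequence.spawn` into one independent
noise stream per agent, so output is independent of agent iteration order.

### Parameter defaults (unit-interval lengths, seconds)

| parameter | default | rationale |
|---|---|---|
| `n_agents` | 200 | per-frame head count of the assay |
| `D` | 5·10⁻³ unit²/s | cross-axis relaxation time 1/(Dπ²) ≈ 20 s: a centrally released population homogenizes over tens of seconds, matching the control phenomenology |
| `χ` | ±1.5·10⁻² (presets) | with amplitude 1 this sets χc/D = 3, a stationary density ∝ e³ᶜ with ≈ 80% of agents in the band — visible aggregation within ~15 s and decisive clustered verdicts inside the two-minute horizon |
| `σ` | 0.1 | band edges blurred over ~10% of the channel width, a plausible post-flow lateral spread |
| `dt` | 0.05 s | drift per step ≪ edge width; noise per step ≈ 0.022 units |
| horizon | 120 s, 1 frame/s | two-minute video sampled at one analysis frame per second |

`D` and `χ` for real organisms are not identifiable from position snapshots
alone (that requires controlled gradients); these defaults are a
calibration of the emulation, not measurements.

Scenario presets: `control` (χ=0, released in the middle third),
`attractant` (χ>0, uniform start), `repellent` (χ<0, uniform start); any
field can be overridden per run.

### What the simulator does and does not emulate

It reproduces the *statistical structure* the analysis assumes: frame-wise
point fields with ~200 points, a cross axis that is (control) transiently
inhomogeneous, (attractant) increasingly band-concentrated, or (repellent)
band-depleted, and a long axis that is uniform throughout.  It does **not**
model run-and-tumble ciliary mechanics, hydrodynamic wall drag, gravitaxis,
chemical consumption, or inter-agent interaction.  Passing tests therefore
certify the analysis pipeline and the drift–diffusion phenomenology — not
organism-level behavioral realism.  Whether the empirical asymmetry between
attractant filling and repellent emptying time courses emerges from a
symmetric-χ walk is an open experiment; no test asserts it.

## Statistical test design in the suite

* Type-I calibration: 1000 independent Poisson(200) fields; the k=10,
  α=0.05 rejection fraction must lie in [0.03, 0.07] (χ² approximation
  plus binomial Monte-Carlo error).
* The simulator-null calibration uses the final frames of 1000 independent
  short runs rather than consecutive frames of one run: frames within a run
  are autocorrelated (cross-axis mixing time ≈ 1/(Dπ²) ≈ 20 s), and the
  tight binomial band is only valid for independent tests.
* The long-axis rejection rate of the control emulation *is* aggregated
  over correlated frames (100 runs × 121 frames); its acceptance band
  [0.02, 0.08] comes from the effective sample size ≈ 100 runs × (120 s /
  20 s mixing) ≈ 600 independent tests (±3 binomial SD ≈ ±0.027).
* Mirror-experiment monotonicity (attractant in-band fraction rising,
  repellent falling, in Monte-Carlo mean) is asserted on checkpoints in the
  transient window t = 0–12 s, where per-checkpoint increments (~0.1)
  dominate Monte-Carlo noise (~0.005); near stationarity increments vanish
  and strict monotonicity of a Monte-Carlo mean is not a model property.
* The mean-squared-displacement check (MSD ≈ 2Dt within 10%) is restricted
  to √(2Dt) < 0.2 with a middle-third start, before wall reflections
  depress the apparent displacement.
* χ² quantiles are cross-checked against an independent oracle: numerical
  inversion of the regularized incomplete gamma function by root bracketing,
  sharing no code path with the quantile implementation.

## Numerical and I/O conventions

* Position files: delimited ASCII, canonical header `frame,time,x,y`
  (`x` = cross, `y` = long), comma or whitespace sniffed automatically;
  headerless files accepted with a user-supplied column order, timestamps
  falling back to `frame/fps`.  Coordinates are parsed with full-precision
  `float()` (pandas' fast parser can be one ulp off) so write→read
  round-trips are bit-exact; empty frames round-trip via a marker line with
  blank coordinates.  Unparseable lines, missing values, non-monotone times
  and out-of-bounds coordinates are reported with file line numbers.
* Reports are long-format (tidy) CSV — one row per frame × axis × k — from
  which all figures are derived views.
* Problem sizes in the test suite and acceptance script (1000 fields for
  calibration/power, 100 runs per scenario emulation, two-minute horizons)
  were chosen so each study resolves its acceptance band with ≥3σ margin
  while a full run of everything stays in the low minutes on one CPU.

## Known limitations

* The χ²(k−1) approximation degrades for per-cell expectations below ~5;
  the package warns but does not refuse.
* Uncorrected multiple testing across k and frames means family-wise error
  is larger than α; consumers aggregating verdicts should account for it.
* The tolerant reader covers delimited frame/x/y layouts only; exotic
  tracking formats need a pre-conversion step.
* The simulator's Euler scheme is first-order; with default parameters the
  per-step drift (≤ 3.5·10⁻³) and noise (2.2·10⁻²) are small relative to
  the profile's edge width (0.1), which keeps discretization bias well
  below sampling noise, but very large `χ·dt` would require a smaller step.
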