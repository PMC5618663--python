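# Methods

This note documents the models implemented in `rsfpkit`, the defaults of
the synthetic-data generator, the numerical choices inside the fits, and
what the tests do and do not demonstrate.

## Photoswitching model

A negative-switching RSFP ensemble under cyan (reading/off-switching)
illumination is modeled as two emissive species, A (fast-switching) and B
(slow-switching), each decaying mono-exponentially to its own residual
plateau. Within one off half-cycle:

    F(t) = a·[(1 − f_A)·e^(−k_A·t) + f_A]
         + b·[(1 − f_B)·e^(−k_B·t) + f_B] + c

- `k_A > k_B > 0` (s⁻¹) — off-switching rate constants. The strict ordering
  is an identifiability convention that prevents label switching.
- `f_A, f_B ∈ [0, 1)` — residual on-fractions: the fraction of each
  species' fluorescence that survives complete off-switching. `f_A`
  defaults to 0 (species A switches off completely) but is fittable;
  `f_B > 0` is what produces a nonzero per-cycle baseline.
- `c ≥ 0` — constant background, shared across cycles.

This is the minimal form consistent with two observations: single-cycle
decays need at least two exponentials, and off-switching does not reach
zero. Stretched exponentials and distributed-rate models are deliberately
out of scope.

Violet half-cycles are modeled as complete, instantaneous on-switching of
the surviving population: repeated-switching protocols drive on-switching
to saturation before reading the on level, so the within-half-cycle
on-switching kinetics carry no information the analysis uses. A finite
on-rate (`k_on`) is available as a generator option, default off.

## Population dynamics across cycles

Interconversion and photodestruction operate on a much slower clock than
the within-cycle decay, so the cycle index `n` is used as the time variable
and all rates are per-cycle and dimensionless:

    da/dn = −(k_AB + k_dA)·a
    db/dn =  k_AB·a − k_dB·b

with `k_AB` the light-driven A→B interconversion rate and `k_dA`, `k_dB`
the photodestruction rates. Writing α = k_AB + k_dA, the closed form is

    a(n) = a₀·e^(−α·n)
    b(n) = b₀·e^(−k_dB·n) + a₀·k_AB·(e^(−k_dB·n) − e^(−α·n))/(α − k_dB)

with the analytic limit `a₀·k_AB·n·e^(−α·n)` when α = k_dB; the switch
happens at |α − k_dB| < 1e−9 to avoid catastrophic cancellation rather
than evaluating the generic expression near the pole. Back-conversion B→A
is assumed absent (`k_BA = 0`): the minimal model already reproduces the
characteristic rise-then-fall of species B, whose peak for b₀ = 0 sits at
n* = ln(α/k_dB)/(α − k_dB). A nonzero `k_BA` is accepted as an explicit
option and handled by numerical integration.

Consequences used as checks: a(n)+b(n) is conserved when both destruction
rates vanish; a(n) is strictly decreasing whenever α > 0; b(n) is unimodal
when b₀ = 0 and both k_AB, k_dB > 0.

The per-cycle baseline (maximally off-switched frame) equals
`a(n)·S_A(T) + b(n)·S_B(T) + c ≈ b(n)·f_B + c` once the fast species has
fully decayed within the half-cycle — so the rising baseline is explained
by accumulation of the partially-switching species B, with no separate
non-switching state.

## Global fitting

All off half-cycles of an experiment are fitted jointly: one shared
(k_A, k_B, f_A, f_B, c), per-cycle amplitudes (aₙ, bₙ) ≥ 0. The problem is
separable, and is solved variable-projection style: for each candidate set
of nonlinear parameters the amplitudes are obtained by non-negative linear
least squares per cycle, and only the 4 (or 5, with f_A) nonlinear
parameters are iterated. Because every cycle shares the same within-cycle
time grid, the 2×2 Gram matrix of the two basis decays is common to all
cycles, and the per-cycle non-negative solves reduce to a vectorized 2×2
solve with an exact two-variable active-set fallback (verified against
`scipy.optimize.nnls` in the tests). A 500-cycle fit therefore costs a
4-parameter `least_squares` problem instead of a ~1000-parameter one and
runs in well under a second.

Numerical choices:

- Ordering k_A > k_B is enforced by parameterizing k_B = ρ·k_A with
  ρ ∈ (10⁻⁶, 0.999) under box bounds (equivalent to a sigmoid
  reparameterization, with simpler gradients). ρ > 0.9 triggers a
  rate-degeneracy warning: the amplitudes are then ill-determined.
- Initialization: single-cycle fits of the first cycle (dominated by A →
  seeds k_A) and the last cycle (dominated by B → seeds k_B); the f_B seed
  is the last cycle's plateau ratio; c seeds at half the global minimum.
  For off half-cycles shorter than 8 frames, log-linear regression slopes
  replace the single-cycle fits.
- Tolerances: `scipy.optimize.least_squares` with ftol 1e−10, xtol 1e−12,
  up to 500 outer iterations; convergence status, residual norm and
  iteration count are recorded in every `FitResult`. Non-convergence is
  flagged, never silent.
- Least squares is unweighted across cycles and frames.
- Model order selection (1 vs 2 species) uses the small-sample-corrected
  AIC on the residual sum of squares, counting all free parameters
  including the profiled linear ones.

Population-dynamics fitting minimizes joint least squares over both
amplitude trajectories, initialized by log-linear regression on a(n) (for
α and a₀), the tail of b(n) (for k_dB), and b(0) (for b₀), with α split
evenly between k_AB and k_dA at the start.

## Stabilization accounting

Faster off-switching shortens the time a molecule spends absorbing photons
per off half-cycle. With residual fraction f and half-cycle duration T the
relative photon dose is D(k) = (1−f)(1−e^(−kT))/k + f·T, so switching
speed alone predicts a destruction-rate ratio D(k_free)/D(k_fusion)
between two constructs. The observed fold-stabilization of the fast state
is k_dA,free / k_dA,fusion; the quotient of observed over expected is
reported as intrinsic stabilization. Similarly, an off-rate increase is
decomposed into an absorption factor (ε₇.₄ ratio, which already folds in
the pKa change) and an intrinsic factor (the remainder).

## Spectroscopy conventions

- Titration fits: A(pH) = A_min + (A_max − A_min)/(1 + 10^(hill·(pKa − pH))),
  Hill coefficient free with initialization 1 (the shape is only known to
  be sigmoidal). pKa is the inflection point. Data whose absorbance is
  nearly constant over the sampled range (span < 5% of the maximum), or a
  fitted midpoint outside the sampled range, set a failure flag — no
  silent extrapolation.
- ε_on = ε₇.₄·(1 + 10^(pKa − pH)) at pH 7.4: the measured coefficient
  divided by the anionic occupancy.
- Ward's method is implemented in its concentration-cancelling ratio form
  ε = ε_ref·A_native/A_denatured; the denatured-chromophore reference
  extinction is an explicit input, not a hard-coded constant.
- Extinction coefficients are carried in L mol⁻¹ cm⁻¹ internally and
  rendered in units of 10³ in reports.
- All reported percents and scaled brightness values are rounded
  half-away-from-zero to integers, and percent changes of brightness are
  computed on the integer-scaled values — the convention that reproduces
  published characterization tables of this kind self-consistently.

## Synthetic-data generator: what it emulates

The generator reproduces the statistical structure the analysis stages
assume, with every random draw flowing from one seeded
`numpy.random.Generator` per invocation (identical config + seed ⇒
byte-identical output).

Reference protocols:

- Cultured-cell repeated switching: 500 cycles of 25 on + 25 off periods
  of 100 ms (one frame per period).
- Colony switching: a single 20 on / 40 off / 20 on cycle of 30 s periods.
- Thermal recovery: sampling every 30 s over 10 min (21 samples including
  t = 0).

Reference ground truth (`default_truth`): k_A = 6 s⁻¹, k_B = 1 s⁻¹,
f_A = 0, f_B = 0.15, c = 0.02; per-cycle k_AB = 0.006, k_dA = k_dB = 0.004,
a₀ = 1, b₀ = 0.05. The off-rates were chosen so that the fast species
completes its decay within a few frames while the slow species approaches
its residual plateau near the end of the 2.5 s off half-cycle. The latter
is not cosmetic: the residual fraction f_B is a measurable quantity only
if the plateau is actually approached within the window — it is read from
the maximally off-switched frame — and when it is not (e.g. k_B·T ≪ 1),
the (k_B, f_B, c) likelihood becomes nearly flat and no fitting method can
separate them. The population rates put the slow-species peak near cycle
150 and the on-level half-point near cycle 190, i.e. visible dynamics
within a 500-cycle experiment.

Noise: expected signal (plus a camera background of 0.05) is
Poisson-sampled at `shot_scale` = 1000 photons per intensity unit and
carries additive Gaussian read noise of σ = 0.01 — an EMCCD-like
approximation. `shot_scale = 0` disables shot noise.

Experimental unit: repeated-switching assays fit the *average* trace over
a field of expressing cells, so the reference experiment
(`reference_field_experiment`) simulates 20 cells with lognormal (σ = 0.3)
expression scatter and analyses their mean; single traces are available
for noise-sensitivity work.

Colony images are rendered as hard-edged disks (non-overlapping by
default) on a uniform background. There is no optical PSF, no gain
register model, no drift and no per-molecule stochasticity — ensemble
rates only. Passing round-trip tests therefore demonstrate correctness of
the estimators under the assumed model, not robustness to optical
artifacts, cell movement or model misspecification in real recordings.

## Problem sizes used in the test suite

Recovery checks run at the sizes that make their claims meaningful while
keeping the suite quick: the noiseless and default-noise global-fit
recoveries use the full 500-cycle protocol; replicate-spread checks use 20
seeds at 120–150 cycles; the two-construct fold-stabilization recovery
uses 20 seeds × 2 constructs at 100 cycles, where the threefold k_dA
difference is already well expressed.

## Known limitations

- The per-cycle clock lumps all interconversion and destruction into the
  cycle as a whole; on- and off-half-cycle contributions are not separated,
  and violet-driven interconversion is not distinguished from cyan-driven.
- `f_B` is defined as the residual *fluorescence* fraction of species B;
  if the underlying quantity is a population fraction the two coincide
  only up to a brightness factor absorbed into the amplitudes.
- The photon-dose stabilization estimate is a proxy, not a microscopic
  photobleaching model.
- Per-cycle amplitude uncertainties are not propagated into the
  population-dynamics fit (unweighted second stage).
- Touching colonies are not split (no watershed); overlapping disks are
  only rendered if explicitly configured.
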