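# Methods

## Task geometry and conventions

The color wheel holds `n_colors = 64` hues; color index 1 sits at angle 0 and
angles grow counterclockwise in steps of 2π/64, so index i maps to
(i−1)·2π/64.  Signed report errors live in (−π, π] with counterclockwise
displacement positive; the literature reports clockwise/counterclockwise
deviations without fixing a sign, so the convention is fixed here once and
used everywhere.  A peck exactly on a wedge boundary belongs to the lower
index (deterministic tie-break; the underlying assignment rule used with
touchscreen data is nearest wedge center).  The graded reward is 3 pellets on
the exact color, 2 within ±1, 1 within ±3, 0 beyond; uniform guessing
therefore scores 7/64 ≈ 10.9 % in the full range, 3/64 ≈ 4.7 % in the inner
range and 1/64 ≈ 1.6 % exactly.  Delay classes map to 0.45 s
("simultaneous" — the target is re-shown inside the wheel, approximating
undelayed estimation), 1.2 s (short) and 3.2 s (long); the mapping is
configurable.

Trial tables are UTF-8 TSV, one row per completed trial.  `response_angle`
is the peck angle on the *rotated* wheel; subtracting `wheel_rotation`
recovers the reported color angle.  Validation enforces the schema row-wise
(load-1 trials carry no non-target and no cue, delay durations match their
class, the response index is the nearest wedge) and reports offending row
numbers.

## Synthetic data generator

The generator emulates the study conditions: targets (and non-targets under
load 2) i.i.d. uniform over the 64 hues, the nine trial types drawn with
configurable weights (uniform by default), wheel rotation uniform on
[0, 2π).  Responses are drawn per trial: with probability `p_guess(load)` a
uniform guess; otherwise with probability `p_swap` (load 2 only) the
*non-target* is remembered, else the target; the remembered item is
integrated by Euler-Maruyama (`dt = 0.01 s`, small enough that integrator
bias is far below every test tolerance at the gains and noise levels used)
through a 1-s encoding phase and the trial's delay with phase- and
load-specific β, σ.  The default ground truth uses a six-attractor landscape
(the basis projection of −sin 6θ, normalized to max |G| = 1) with
β_enc = 1.2 s⁻¹, σ_enc = 0.25/0.35 rad·s^(−1/2) (load 1/2),
β_mem = 0.6/0.8 s⁻¹, σ_mem = 0.35/0.5 rad·s^(−1/2), p_swap = 0.1 and
p_guess = 0.05/0.1 — a regime that reproduces the qualitative behavioral
phenomenology (performance falling along the demand diagonal, clustered
response frequencies, rising bias and falling precision).  The 800-ms sample
display and 200-ms cue are not separately simulated: encoding is the model's
1-s encoding phase.  Duplicate target/non-target draws are permitted; the
swap branch then coincides with the target branch.

Serial dependence is injected post hoc as a bounded first-harmonic shift
toward the previous target, `gain · sin(Δ)` with Δ the previous-minus-current
target angle — the simplest generative form that yields a peaked,
antisymmetric bias curve.  The generator does **not** emulate session or
subject random effects, reaction times, motivational drift, or perceptual
confounds (luminance differences between rendered hues); passing tests
demonstrate internal consistency of the estimators on the assumed generative
family, not robustness to those real-data features.

## Behavioral statistics

Performance matrices give per-(load condition × delay) proportions of
responses within each accuracy window; empty cells are flagged missing rather
than zero.  Bias is |circular mean| of signed errors and precision is
1/circular SD (circular SD = √(−2 ln R̄)) minus the Monte-Carlo expectation
of 1/circular SD for matched-n uniform samples (200 draws, fixed internal
seed 12345), so chance-level responding scores ≈ 0.  Degenerate all-equal
samples report precision at a documented cap (10³) with a flag.  Both
measures are computed per target color and averaged (per-color grouping is
the default; groups with fewer than two trials are skipped), matching the
per-color analysis convention.

Hodges-Ajne uses the exact tail (n − 2m)·C(n, m)/2^(n−1), evaluated in log
space, while m < n/3; beyond that a 10⁴-draw uniform-resampling estimate is
used.  Cochran's Q with a vanishing denominator (every block constant) is
returned as Q = 0, p = 1 with a degeneracy flag, since the numerator also
vanishes.  The two-way ANOVA runs on per-session cell proportions (the unit
of replication is a design choice documented here; trial-level binary
outcomes are an alternative the data format supports) via OLS with
interaction, and partial ω² per term is (SS − df·MS_err)/(SS + (N − df)·MS_err),
clipped at zero only for reporting.  Friedman uses average-rank tie
correction and Kendall's W = χ²/(n(k−1)).  The serial-bias curve smooths
signed error over the previous-target offset with a von Mises kernel
(κ = 16, about a 20° half-width — the estimator in the literature is not
specified, so a standard circular kernel regression is used) and reports the
peak of the antisymmetrized curve.

## Mixture model

Errors are modelled as pT·VM(e; 0, κ) + pN·VM(e_nontarget; 0, κ) + pU/2π with
a single κ shared by the two von Mises components, fitted by EM: closed-form
weight updates, κ by Newton inversion of A(κ) = I₁/I₀ from the Best-Fisher
starting values, capped at 10⁴ for degenerate data.  Convergence is a
relative log-likelihood change below 1e−8 or 500 iterations; five restarts
from stratified Dirichlet starting weights (seeded) guard against local
optima; log-likelihood monotonicity is asserted in the tests on every fit.
When no trial carries a non-target the pN component is forced to zero.  Swap
errors are quantified two ways — the mixture weight pN and the fraction of
trials whose posterior responsibility favors the non-target component — since
published swap frequencies do not state which convention they use.

## Per-color Gaussian tuning

For each target color, per-session response fractions over the 64 colors are
averaged and circularly shifted so the target sits at position 33, then fit
by nonlinear least squares with y = a·exp(−((x−b)/c)²) + d from starting
values a = 1, b = 33, c = 1, d = mean fraction over the 30 farthermost colors;
a, c, d are constrained non-negative (sign constraints are not stated in the
source analysis; unconstrained fits can invert the Gaussian on noisy
histograms).  The x-axis is linear index space, not circular — edge effects
are minimal because the histogram is re-centered.  Adjusted R² (n = 64,
p = 4) measures goodness of fit.  Colors near repellers have bimodal
histograms the single Gaussian cannot represent; their fits collapse toward
zero-variance spikes, so analyses of the coefficient landscape filter to fits
with positive adjusted R².

## Fokker-Planck engine

The drift basis consists of 12 von Mises derivative bumps centered 2π/12
apart with concentration κ* chosen so each bump's circular SD equals the
spacing (R̄ = exp(−s²/2), κ* = A⁻¹(R̄), computed numerically); columns are
unit-normalized on the grid.  The gain/weight-norm degeneracy is resolved at
reporting time by rescaling to max |G| = 1 with β carrying all gain.

The propagator discretizes the Fokker-Planck operator on a periodic
cell-centered grid with Scharfetter-Gummel (exponentially fitted) fluxes.
The resulting rate matrix is a Markov generator — off-diagonal rates
non-negative, columns summing to zero — so the matrix exponential is a
stochastic matrix: mass conservation, positivity and the semigroup property
hold to machine precision, and there is no time step and hence no CFL
stability constraint to refine.  With σ = 0 the scheme degrades gracefully to
pure upwind advection.  The 128-cell default grid (finer than the 64 stimulus
wedges, cheap to exponentiate) resolves densities at the study's parameter
scales to TV ≲ 0.01 against 2×10⁵-sample Euler-Maruyama histograms; strongly
advection-dominated transients (β ≳ 2 with σ ≲ 0.3 at sub-second times) or
near-deterministic stationary peaks a few cells wide are the known resolution
limit, and accuracy-critical comparisons run the same engine on a 3× finer
grid aggregated back to the 128-bin histogram.

## Drift-diffusion likelihood, fitting and model comparison

One matrix exponential per (phase, load, delay) maps *every* initial cell to
its final distribution at once, so a single pair of propagators per condition
yields the response density for all 64 target bins; per-trial densities are
read off by periodic linear interpolation at the reported angle and floored
at 1e−12.  Simultaneous-cue trials are excluded (ambiguous load), and 0.45-s
"simultaneous"-delay trials are excluded by default (their treatment in
delayed-estimation fits is ambiguous since the target is visible; a flag
includes them with delay 0.45 s), leaving four modeled conditions.  A single
drift field is shared across loads; β and σ are per phase × load; p_guess is
per load and p_swap a single load-2 parameter.

Fitting minimizes the joint NLL by L-BFGS-B with finite-difference gradients
(the objective is smooth in all parameters; propagators are memoized so
perturbing one parameter recomputes only the affected matrices), σ
log-parameterized, β ≥ 0 (drift sign lives in the weights), mixture weights
bounded in [10⁻⁴, 0.45].  Up to 3000 trials per load × delay condition are
subsampled with a seeded generator; restarts (default 5; 2 in the acceptance
runs, which proved sufficient at these problem sizes) start from jittered
heuristic initial points.  Variants (`no_encoding_drift`, `no_memory_drift`,
`pure_diffusion`) zero the corresponding gains and drop them from the search.
Cross-validation stratifies fold assignment by condition, trains each variant
on k−1 folds and scores held-out NLL; fold fits warm-start from the
full-data solution of the same variant, which shortens optimization without
leaking any held-out information.  All seeds (subsampling, restarts, folds)
are recorded in the fit report.

Attractors are negative-slope zero crossings of β·G located by a dense
8192-point sign-change scan with linear root refinement; positive-slope roots
are repellers.  β = 0 yields an empty set by definition.

## Problem sizes and limitations

The acceptance runs use 20 mixture-recovery replicates at n = 5000, 2×10⁵
Monte-Carlo samples per Fokker-Planck comparison point on a 3 × 3 × 2
(β, σ, t) grid, 3000 trials per modeled condition for the drift-diffusion
recovery, and a 20,000-trial dataset for the behavioral signatures — sizes at
which every recovery criterion is comfortably identified while a full run
stays around ten minutes on one CPU.  Known limitations: the engine's
spatial-resolution limit above; encoding-phase and memory-phase drift are
only weakly separable when delays are short relative to encoding; the
per-color Gaussian is misspecified at repeller colors by construction; and
statistics are within-subject — no hierarchical pooling across subjects is
attempted.
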