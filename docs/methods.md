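# Methods

## The synthetic cohort and what it emulates

The generator produces the full crossover design — 30 participants × 3
conditions (sham, motor-cortex tDCS, DLPFC tDCS) × 3 sprint phases — as
4-channel sEMG plus one phase velocity per trial, 270 cells in total.

**Common-drive model.** Only target coherence levels are specified for the
cohort, not a generative mechanism, so coherent muscle pairs are built from a
shared neural-drive abstraction: per muscle pair and band, a band-limited
unit-variance Gaussian drive `s` (white noise through a 4th-order Butterworth
band-pass, one independent drive per (pair, band) so bands are separately
controllable) is mixed into both channels as

    x = κ·s + √(1−κ²)·e₁,    y = κ·s + √(1−κ²)·e₂,

with `e₁, e₂` independent and identically band-limited. Because drive and
noise then share the same in-band spectrum, the magnitude-squared coherence
in the band is κ⁴ exactly, and a target *t* is achieved by κ = t^(1/4)
(verified by simulation to ±0.05 on 60 s signals). Targets are taken from the
reported per-cell band-coherence means; one reported value (TA–GL γ, 60–100 m,
motor-cortex condition: 1.10) exceeds the mathematical maximum of 1 for
magnitude-squared coherence, so all targets are clamped at 0.95 — the
discrepancy is documented here, not resolved.

**Additional realism.** Channels carry independent broadband (20–450 Hz)
background noise at relative amplitude 0.3 (electrode/instrumentation noise;
small enough to dilute band coherence by < 0.02), and a per-trial, per-channel
lognormal gain jitter (σ = 0.1, ~10 % amplitude variability, the order of
inter-trial sEMG amplitude variation). Phase durations derive from phase
distance ÷ per-cell mean velocity (e.g. 30 m / 11.59 m s⁻¹ ≈ 2.59 s), so
trial lengths are realistic for spectral estimation (~9–14 Welch segments).

**Velocities.** Two modes. *Table* mode (default for the statistics stage)
draws from the per-cell (mean, SD), truncated at ±3 SD, plus a participant
random intercept (SD 0.2 m/s) so participant-grouped cross-validation is
meaningful. *Formula* mode (default for model-recovery work) evaluates the
packaged closed-form equation on the realized features and adds Gaussian
noise (SD 0.15 m/s).

**What passing tests do not show.** The generator is stationary Gaussian
within a trial: no bursting motor-unit structure, no movement artifacts, no
heart-rate contamination, no within-trial nonstationarity, no cross-pair
coupling, and features vary across cells mainly through duration, gain and
coherence targets. Recovery results on this cohort demonstrate estimator
correctness, not performance on real sprint EMG.

## EMG features

Band-pass 20–450 Hz (4th-order Butterworth, zero-phase forward–backward —
the de-facto sEMG standard; the effective order is doubled by filtfilt),
full-wave rectification, 50 ms centred moving-RMS with shrinking windows at
the edges (no padding, so no fabricated data at phase boundaries). iEMG is
the rectangle-rule integral of the rectified *unsmoothed* signal (the
conventional definition); RMS and the median frequency are computed on the
filtered, unrectified signal (rectification distorts the spectrum). MF uses
Welch PSD (0.5 s Hann, 50 % overlap; a single periodogram if the span is
shorter), restricted to 20–450 Hz, with the half-mass point interpolated
linearly inside the crossing bin (bin mass treated as uniform over the bin
width). Spans shorter than 0.5 s raise an error (MF unreliable).

## Intermuscular coherence

The stationary Welch estimator `|Sxy|²/(Sxx·Syy)` with Hann windows, 0.5 s
segments, 50 % overlap; the sprint phase is the time resolution. Bands are
half-open ([8,15), [15,30), [30,50) Hz) so the 15 and 30 Hz bins are not
double-counted; the γ band is 30–50 Hz. Pairs RA–BF and TA–GL are computed.
Zero-power bins map to coherence 0 (logged) so band averages are always
defined. Significance: a fixed 0.5 flag by default (configurable), plus the
analytic 95 % independence limit 1 − 0.05^(1/(L−1)) for L segments. The
estimator has the usual 1/L bias under independence; at trial length
(L ≈ 9–14) band estimates carry ±0.1–0.15 spread, which is why calibration
checks use 60 s signals.

## The spline network

Widths [9,5,3,1]. Inputs are min-max scaled to [0,1] per feature (scaler
fitted on the training fold only and serialized with the model); hidden node
values are clamped to [0,1] before the next spline layer; values outside the
domain are clamped with a logged warning. Each edge is a uniform cubic
B-spline with G knot intervals (G+3 basis functions; the headline grid is 5
and the sweep covers {3,5,10,20,50,100}). The basis is the standard cardinal
cubic (partition of unity, C², centre value 2/3 — all verified numerically
and against an independent B-spline implementation). There is no residual
base activation: edges are pure splines.

**Objective.** With targets standardized internally (the model stores the
affine output transform), the loss is

    MSE + λ·(μ₁·Σ‖Φ‖₁ + μ₂·S),   λ = 0.01, μ₁ = 1, μ₂ = 10,

where ‖Φ‖₁ is the per-edge coefficient L1 norm and S is the attribution
entropy *across* each layer's edges (p ∝ per-edge L1 norm). The
standardization makes these weights scale-free; with raw m/s targets the
penalty would swamp the MSE. An alternative reading of the entropy — per
edge over its own squared coefficients — is exposed as the diagnostic
`edge_entropy` but is not used in training: at these weights it contributes
up to ~130 to a unit-variance objective and provably collapses the fit
(measured train R² 0.49 vs 0.77 without it), which is incompatible with the
fit quality this architecture is known to reach.

**Initialisation.** Normal(0, 0.1) noise around an identity-preserving ramp
(Greville abscissae ÷ fan-in, so each node starts near the mean of its
inputs). A zero-mean init leaves about half of all activation mass clamped
at 0, where gradients vanish; the ramp removes that failure mode while
keeping the stochastic component the stated N(0, 0.1).

**Optimization.** 20 outer L-BFGS steps, each up to 20 internal iterations
(strong-Wolfe line search, history 10), analytic gradients throughout
(spline derivatives in closed form; the L1 term uses the sign subgradient
with sign(0)=0; entropy probabilities are floored at 1e-12 inside the log).
The per-step loss trajectory is non-increasing by the line-search guarantee;
non-finite losses abort with a diagnostic.

**Pruning and refitting.** Edge importance is the coefficient L1 norm scaled
by the edge's output standard deviation on the training inputs, normalized
by the layer maximum; edges at or below 0.2 on that [0,1] attribution scale
are masked, and nodes left without active incoming or outgoing edges are
removed (to a fixed point). The forward pass of a pruned model equals the
unpruned forward with masked coefficients set to zero, exactly. Because
pruning removes compensating wiggle, the surviving edges are refit; prune →
refit repeats until the masks stop changing (at most 3 rounds). The whole
path runs from 3 random restarts and the candidate with the lowest penalized
*training* objective is kept — model selection never sees held-out data.

**Symbolic compression.** Each surviving edge, sampled at its realized node
inputs, is refit as c·g(a·x+b)+d for g in {x, x², exp, log, sin, const}:
inner parameters by coarse grid search refined with local least squares,
outer (c, d) in closed form; sin is canonicalized to a ≥ 0, c ≥ 0,
b ∈ [0, 2π). Selection minimises mse/var + λc·C(g) with C(g) the number of
free parameters and λc = 0.02 by default — the BIC scale ln(n)/n at n ≈ 270.
A near-constant edge maps to 'const'; a log argument that goes non-positive
is a domain error at evaluation. With multiple layers the result is a nested
closed form (single-layer models flatten to an additive equation); the
equation string renders either. The packaged reference equation ships as a
single-layer additive SymbolicModel fixture.

## Statistics

Classical one-way repeated-measures ANOVA per outcome: SS decomposition with
df = (k−1), (k−1)(n−1); Greenhouse–Geisser ε from the double-centred
condition covariance (clipped to [1/(k−1), 1]); both uncorrected and
GG-corrected p are always reported, and the headline p follows the
conditional rule (GG only when Mauchly p < 0.05, via pingouin's Mauchly
test). Partial η² = SS_effect/(SS_effect+SS_error), and
`partial_eta_from_f` exposes the back-computation F·df₁/(F·df₁+df₂) so
printed (F, df) triplets convert directly to effect sizes. Degenerate
all-equal inputs return F = 0, η² = 0 rather than NaN. Post hocs are paired
t-tests with Bonferroni correction capped at 1; Shapiro–Wilk screening is
advisory (violations are logged, the pipeline proceeds). Two-sided α = 0.05
throughout. The hand-rolled ANOVA is cross-checked in the tests against both
a brute-force sums-of-squares oracle (to 1e-10) and pingouin.

A note on degrees of freedom: the reported analyses print F(2,27) where a
30-participant × 3-condition within-subject design yields F(2,58). The
module reports the standard dfs; `partial_eta_from_f` reproduces the printed
effect sizes from the printed triplets as stated, without endorsing the df
bookkeeping. The origin of df_error = 27 is not modelled.

## Cross-validation and the grid sweep

Folds are grouped by participant (each participant's 9 rows are correlated;
row-level splits would leak) — 3 folds of 10 participants / 90 rows;
ungrouped mode exists behind a flag for comparison. Per fold: scaler fit on
the training fold, full fitting path, held-out R². The grid sweep trains one
model per grid value on a single grouped split and selects the minimum
validation MSE, ties toward the smaller grid. The report aggregates fold R²
by arithmetic mean and is byte-identical across reruns with the same config
and seed (no timestamps).

## Problem sizes used

Recovery and acceptance checks run at the design's natural size (270 rows);
calibration checks use 60 s signal pairs and 20 seeds; family-recovery
checks use n = 200 samples per edge and 10 seeds; the negative control uses
5 permutation seeds with a single restart (extra restarts only lower
training loss and cannot create held-out skill for permuted labels). The
worked example in the README uses a 12-participant cohort.

## Known limitations

- The generator's feature variance comes mostly from phase durations and
  gain jitter; with the closed-form outcome and noise SD 0.15 the
  population ceiling for held-out R² is ≈ 0.64, and its per-seed
  realization fluctuates by ±0.05–0.1 — fitted models track the
  refit-per-fold linear oracle to within ~0.03.
- The closed-form equation's two exponential terms have coefficients of
  order 1e-5–1e-6; over the coherence domain [0,1] they change the outcome
  by ~1e-4 m/s, three orders of magnitude below the 0.15 m/s observation
  noise, so they are not recoverable from formula-mode data at n = 270 —
  pruning correctly eliminates those inputs and recovery lands on the
  dominant iEMG term.
- Coherence is the stationary Welch estimator per phase; no time-resolved
  (wavelet) variant, no EEG–EMG (corticomuscular) coherence, no
  directionality.
- No MVC normalization, onset detection, or EMG decomposition; no
  biophysical muscle or tDCS field modelling.
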