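# Methods

This note records the model assumptions, parameter choices and numerical
decisions behind the package, and what the synthetic-data tests do and do
not establish about real recordings.

## Shape model

Poses are `(11, 3)` landmark arrays, flattened landmark-major
(`x0 y0 z0 x1 ...`). Training aligns annotated poses by generalized
Procrustes superimposition with the scale fixed to 1 (rotation +
translation only), initialized at the first pose, iterated until the mean
pose changes by < 1e-8 RMS (max 50 iterations). Probabilistic PCA on the
aligned poses yields the mean pose, K orthonormal eigenposes, eigenvalues
and an isotropic residual σ². Two conventions matter:

* **Eigenvalues are shape-score variances**, i.e. the sample eigenvalue
  minus σ² (the PPCA generative parameterization), not the raw data
  eigenvalue. This is what the ridge penalty α Σ bᵢ²/λᵢ assumes and what
  makes planted-variance recovery unbiased.
* **Explained-variance fractions** divide by the total sample variance
  (retained + residual), so they sum to ≤ 1.

K defaults to 3 for the behavioral read-out (Bar/Blr/Blu are always the
first three scores); a larger K for fitting is supported through
`train_ssm(n_eigenposes=...)`.

Full 3D Procrustes alignment absorbs the near-rigid component of each
deformation mode, so a model trained on aligned poses shows smaller
eigenvalues than the generative scores that produced unaligned data. This
is inherent to the alignment-then-PCA recipe, affects real and synthetic
training identically, and is internally consistent with the fit.

## Robust pose fit

The cost C(b, R, T) = σ⁻²‖X − (X̄ + Σ bᵢPᵢ)R − T‖² + α Σ bᵢ²/λᵢ (α = 0.01)
is minimized over valid landmarks by exact alternation: given b, the
optimal (R, t) is a closed-form rigid alignment; given (R, t), b is a
closed-form ridge solve. Iteration stops when the cost decreases by less
than 1e-10 (max 300 iterations) — tight enough that on random instances
the solution matches a 20-restart Nelder-Mead search to ≈ 1e-9.

**Rotation parameterization.** R defaults to yaw-only (rotation about the
vertical). Pitch- and roll-like deformations then remain in shape space,
where the behavioral read-out expects them (body arch as an eigenpose
score rather than a body rotation). A free 3D rotation is available via
`rotation="full"`.

**Outlier test degrees of freedom.** A frame is flagged when C exceeds
`chi2.ppf(p, dof)` with p = 0.99 by default. Because the minimization
absorbs q = 1 (yaw) + 3 (translation) + K (scores) degrees of freedom,
the converged cost of a clean frame follows approximately χ²(3·Np − q),
not χ²(3·Np); the default `dof_mode="effective"` uses 3·Np − q so that
clean frames are flagged at rate 1 − p (verified to sit inside the
binomial 99% CI at 10⁴ frames). `dof_mode="nominal"` (3·Np) is available;
it is conservative (flags clean frames at ≈ 1e-3 instead of 1e-2 at
p = 0.99) and shifts the precision/recall balance toward precision.

The outlier loop removes the valid landmark with the largest data-term
contribution (σ⁻² × its squared residual), refits, and stops when the
test passes or fewer than 6 landmarks would remain (then the frame is
flagged low-confidence). The corrected pose is always the model synthesis
at the final (b, R, t): every landmark gets a coordinate. Frames with
fewer than 4 triangulated landmarks are imputed from the prior (b = 0 at
the last known rotation/translation) and flagged.

## Behavioral state

Hel is the elevation (deg) of the neck→nose vector above horizontal; Hlr
the signed horizontal angle between the body midline (tail-base→neck) and
the neck→nose vector, positive leftward (both conventions are internal
choices; the underlying angle definitions leave the reference plane and
midline unspecified). Bar/Blr/Blu are the first three fit scores, Re is
t_z. Consecutive-frame differences are assigned to the later frame, so
the first frame of each epoch is masked — this is the single consistent
reading of "difference between two consecutive frames" that leaves epoch
starts undefined. Posture derivatives are scaled by the frame rate
(units/s); Lc and OM are raw per-step displacements. OM sums the
per-landmark displacement over all 11 landmarks; a mean instead of a sum
differs by a constant and is erased by the z-scoring that precedes every
coupling analysis. Zero-variance variables are zero-filled and flagged.

The variable-grouping analysis discretizes each z-scored variable into 5
quantile bins, computes bias-corrected pairwise MI (diagonal = entropies)
and clusters the matrix with WPGMA linkage on the dissimilarity
d = 1 − MI/max(off-diagonal MI), with negative corrected MI clipped at 0
for clustering only.

## Information estimation

Variables are quantile-discretized (stable-rank tie-breaking; fewer
distinct values than bins reduces the bin count with a warning). Spike
counts enter MI as integers top-coded at their 99th percentile to bound
the state space. The plug-in MI is computed on the full data and on 10
random subsets each at one-half and one-quarter of the samples; a
quadratic in inverse sample size through the three points, evaluated at
zero, is the corrected estimate. Since the extrapolation is linear in the
entropies, extrapolating MI directly equals extrapolating H(R) and H(R|S)
separately. Calibration: the binary symmetric channel (flip 0.11,
n = 10⁴) is recovered within 0.02 bits of its 0.500-bit closed form;
independent 5×5 data sit within 0.02 bits of zero; the correction lowers
the mean absolute null error at every n ∈ {250, 1000, 4000}.

Pair-versus-single comparisons estimate MI2 from the joint (a, b) label
and the single-variable control as the larger of the pair MI with either
variable's time order shuffled, both corrected identically.

## Cross-correlation and coherence

Cross-correlograms use 0.0667 s bins over ±2 s (61 lags), mean-removed
per epoch, normalized per lag by the overlap and the product of epoch
SDs (a Pearson-style normalization; values clipped to [−1, 1]), and
averaged over epochs weighted by epoch length. Positive lag means
spiking follows behavior.

The null permutes the order of the count epochs against the fixed
behavior, 1000 times. Count/behavior epoch pairs of unequal length are
truncated to the shorter; all pairwise epoch curves are precomputed so a
permutation is a weighted average — this is what makes thousands of
permutations per unit affordable. Significance requires some lag outside
the [0.0005, 0.9995] quantiles of the null. Those quantiles are taken
over the **pooled** null values (permutations × lags) by default: a
per-lag quantile cannot resolve past ≈ 1/(n_perm + 1) per tail with 1000
permutations, which would roughly double the intended per-lag level and
push the familywise rate over the nominal ≈ 6% (61 correlated tests at
0.001 two-sided). The pooled band achieves the nominal tail and measured
familywise rates of ≈ 3%. `band_mode="per-lag"` restores the literal
per-lag reading.

Coherence is Welch MSC (nperseg = 64 at 15 Hz), epoch-averaged with
length weights; the null is mean ± 2 SD over 100 random circular shifts
of the variable within epochs. A ±2 SD band on a skewed statistic leaves
a few percent single-tail exceedance under the null — tests therefore
check exceedance fractions averaged over units.

## Prediction and condition comparison

Encoding/decoding uses gradient-boosted trees (learning rate 0.025, 500
rounds, max depth 3, γ = 1, subsample 1, CPU histogram method; Poisson
log-likelihood objective for counts, squared error otherwise), training
on the first half of the bins in temporal order and reporting Pearson r
on the second half. The shift control swaps the two halves of the
feature series, destroying the association while preserving within-half
autocorrelation. Cross-condition stability concatenates each unit's Bar
and OM correlograms, correlates them across conditions per unit, and
compares the mean against 10,000 random unit re-pairings.

## Unit typing

Each unit's mean firing rate over the joint 5×5 quantile grid of
(Bar, OM) is z-scored with the occupied-cell statistics; cells with fewer
than 5 samples are imputed with the unit's mean rate and marked. Units
pair into a graph when the Spearman correlation of their flattened
z-grids strictly exceeds the median off-diagonal correlation (≈ half of
all pairs connect by construction). Community detection is recursive
leading-eigenvector modularity bisection with the generalized modularity
matrix on subgraphs; zero eigenvector components join the positive group;
recursion stops when the leading eigenvalue is non-positive or the split
would not increase Q. Each accepted bisection is fine-tuned by greedy
single-node swaps — the Kernighan–Lin-style stage of the published
leading-eigenvector method; without it the plain bisection matches the
exhaustive-search bipartition on only ≈ 76% of small random graphs versus
≈ 95% with it, so refinement is on by default (`refine=False` disables
it). The community with the higher mean z-rate in the top body-arch
quantile is "look-up"; a single-community result is "unclassified".

## Synthetic sessions

The generator produces the study conditions, not a tunable benchmark:
15 Hz frames in 15–24 s epochs separated by 30–40 s gaps; four cameras at
azimuths 0/90/180/270°, elevation 30°, ~60 cm from the arena centre
(focal length 1500 px); 11-landmark poses synthesized exactly through the
built-in three-eigenpose mouse model (arch, left/right bend, lunge;
λ = (1.0, 0.5, 0.25) cm², σ² = 0.02 cm²).

Kinematics: shape scores follow an Ornstein–Uhlenbeck process (τ = 0.6 s,
stationary SD 0.8·√λ, clipped at ±3√λ) whose target is displaced along
the arch (+2√λ₁) and lunge (−0.8√λ₃) modes during rearing bouts (Poisson
onsets at 0.05 Hz, 2 s); locomotion bouts (0.1 Hz, 3 s) move the body
centre at 8 cm/s along a random-walk heading inside a 30 cm arena; the
body-centre height tracks 2 cm + 0.4·b₁ (+2 cm while rearing). Two
structural features give the simulated behavior the dependence structure
that real bout-organized behavior shows and that the variable-grouping
analysis expects: (i) a slow log-normal *activity level* (τ = 1.5 s,
log-SD 1.0), boosted during bouts, multiplies every increment and — by
scaling the OU mean-reversion and noise together (speed-up capped at
2.4², keeping the discretization stable) — speeds posture dynamics up
without widening the posture range, so all movement magnitudes co-vary
while posture levels do not inherit the envelope; (ii) a slow common
drift (τ = 6 s, weight 0.9) shared across all shape-score targets couples
the postures to one another. With these defaults the pairwise-MI
dendrogram's top split separates the six postures from the eight
movements, and the spectrum of the behavioral drive is concentrated below
~2 Hz.

Observations: pinhole projections plus isotropic Gaussian pixel noise
(default 2 px); an `outlier_rate` fraction is displaced by 20–40× the
noise SD in a random direction, a `missing_rate` fraction is dropped;
the corruption log records every injected entry exactly.

Spikes: per-bin rate exp(b₀ + β_ud·Bar_z + β_om·OM_z) with z-scored
ground-truth covariates (optionally delayed), Poisson counts, uniform
spike times within bins; log-rates above 20 raise an error. The default
population is half look-up (β_ud = +0.5), half look-down (−0.5), all
motion-excited (β_om = 0.5) at a 5 Hz baseline — generative coefficients
a Poisson GLM recovers within ±20% at 10⁴ bins.

**What the synthetic tests do not show.** The generator has no 2D
detector confusions beyond noise/outliers/missing (no identity swaps, no
confidence-correlated errors), no camera miscalibration, rigid-landmark
geometry (no soft-tissue deformation off the model manifold), Poisson
firing (no refractoriness, bursting or adaptation), and log-linear tuning
with at most a pure delay. Passing tests demonstrate correctness and
calibration of the estimators under the assumed model class, not
robustness to every failure mode of real tracking or real spike trains.

## Problem sizes and determinism

Test and acceptance runs use desk-scale sizes chosen for a single CPU:
clean-frame χ² calibration at 2.5×10³ frames in the test suite and 10⁴
in the acceptance script; cross-correlogram false-positive calibration at
400 (tests) / 3000 (script) null units of a 300 s session; encoding
orderings over 20 (tests) / 50 (script) seeded sessions of 240 s;
community recovery on 60 units over a 600 s session; modularity oracle on
200 random graphs of ≤ 12 nodes. All stochastic stages are seeded;
`run_pipeline` reruns are byte-identical, and `scripts/acceptance.py`
derives every draw from its `--seed`.

## Known limitations

Per-frame fitting has no temporal smoothing prior (deliberate: the
correction is per-frame), so isolated frames with < 4 landmarks fall back
to the model prior. The yaw-only default misestimates genuinely rolled
poses (climbing on walls). Quantile discretization with heavy ties splits
tied values across bins by rank; entropy estimates on near-constant
variables are then rank artifacts (flagged). The epoch-permutation null
assumes epochs are exchangeable units; slow drift across a session
violates this and would inflate significance for any method of this
family.
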