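# Methods

This note documents the models behind `colonydrift`, the parameter choices
that matter, what the synthetic generators do and do not emulate, and the
numerical decisions a maintainer would want to know.

## The windowed, detrended MSD statistic

**Model.** A lineage at the colony front is represented by its tracer-bead
trajectory, an ordered set of 2-D positions with cumulative arclength s.
For a window length L, every sample index l opens a window containing the
samples with s_j − s_l ≤ L. Within each admitted window a line of best fit
is computed and the window's value is the mean of the squared deviations
Δw² of its samples from that line — the discretization of the window
integral (1/L)∫(Δw)²dL′, adequate because samples are roughly equally
spaced in arclength when the front advances steadily. The per-trajectory
MSD(L) is the unweighted mean over windows with SEM taken across windows;
trajectories are then combined per L by inverse-variance weighting, the
combined curve is fitted to A·L^β by weighted least squares in log-log
coordinates (delta-method errors, σ_log = σ/MSD), and the fit is evaluated
at the reference scale L = 50 µm.

**Line of best fit.** The default is the total-least-squares (principal
axis) line with perpendicular deviations. The window value is then the
smallest eigenvalue of the window's 2×2 coordinate covariance, which makes
the statistic exactly invariant under rigid rotations and translations and
covariant under similarity scaling (MSD(L) → c²·MSD(cL)). Ordinary least
squares of y on x with vertical deviations is selectable (`mode="ols"`)
for comparison; it agrees with TLS when trajectories run mostly along one
axis but is not rotation-invariant.

**Window admission.** A window needs ≥ 3 samples and must span at least
0.8·L (`coverage`); a window length "fits" a trajectory only if the total
arclength reaches L. A trajectory contributes to the combined curve at a
given L only when it admits ≥ 2 windows (one window has no SEM).

**Numerics.** Per-window moments come from prefix sums of (x, y, x², y²,
xy) accumulated in 80-bit extended precision, so the closed-form eigenvalue
agrees with an explicit per-window eigendecomposition to well below 1e-9
relative while the whole grid (200 window lengths × all window starts)
remains O(n) per length. Tiny negative eigenvalues from rounding are
clamped to zero.

**Trajectory combination.** The fixed-effects prescription w_i = 1/SEM_i²
with propagated error (Σw)^(−1/2) is exact when the per-trajectory SEM
captures all the scatter. For window lengths approaching the trajectory
length, however, the windows within one trajectory overlap almost
completely: the SEM collapses while the trajectory-to-trajectory scatter
(a few effective degrees of freedom of the underlying process) explodes,
and pure 1/SEM² weights then systematically favor low-MSD trajectories,
flattening the combined curve and corrupting the fitted exponent. The
default combination is therefore a random-effects (DerSimonian–Laird)
weighting w_i = 1/(SEM_i² + τ²), with τ² the moment estimate of the
between-trajectory variance: it reduces to the fixed weighting when
trajectories agree (small L) and to the unbiased unweighted mean when they
do not (large L). The fixed rule remains available via
`aggregate_msd(..., weighting="fixed")`. With random effects the pipeline
recovers generator exponents β ∈ {0.8, 1.0, 1.33} to within ±0.03 at the
design scale (50 trajectories of 1200 µm); with the fixed rule the
recovered exponent is biased low by 0.3–0.7 under the same conditions.

**Reference value and QC.** MSD(50 µm) = A·50^β. Its error is half the
difference between the evaluations at the jointly +1σ- and −1σ-shifted
log-log coefficients ("bounded coefficients"); a per-coefficient envelope
(half-range over the four sign combinations) is selectable. Filtering
rules: window lengths reached by < 5 trajectories are dropped; colonies
with < 5 usable window lengths fail the fit (`too_few_windows`); reference
values whose error is ≥ half the value fail QC. All thresholds are
arguments with these defaults.

**Plate normalization and replicates.** Colony MSD(50 µm) is divided by
the inverse-variance weighted mean of the wild-type colonies on the same
plate (8 wild-type wells per plate in the emulated layout); the ratio
error combines both relative errors in quadrature, which a 10⁵-draw
Monte-Carlo check confirms to ~10% accuracy in the regime of interest.
Strains keep an inverse-variance weighted mean over ≥ 2 clean replicates
(configurable); the reported error is the SEM of the replicate values.
Colonies are excluded with recorded reasons (`sectored` for diverging
trajectory pairs indicating a beneficial bulge, `no_wt`,
`too_few_windows`, QC failure) — exclusion reasons are data columns, not
log lines.

**Distribution comparison.** Knockout vs wild-type relative-MSD
distributions are compared by the two-sided two-sample KS test, group
means/variances/medians, and the median shift 1 − median_KO/median_WT with
a seeded percentile-bootstrap CI (default 10,000 resamples). The
percentile bootstrap of a median ratio is known to undercover slightly
(~94% at nominal 95% in our calibration runs at n = 191 vs 45).

## Synthetic generators

The generators produce data with exactly the statistical structure the
analysis assumes; their defaults are the design conditions used throughout
the tests.

* **Lineage wandering** is a fractional Brownian motion in (arclength,
  transverse) coordinates with Hurst index β/2, synthesized exactly by
  Cholesky factorization of the fBm covariance (≤ 4096 samples per
  trajectory), so Var[w(s+ℓ)−w(s)] = A·ℓ^β holds by construction.
  Defaults: 50 trajectories, 1200 µm at 2 µm steps, β = 1.33, A = 0.5 —
  transverse fluctuations of a few µm over tens of µm of front advance,
  the scale observed for bacterial colony lineages. Radial bending of real
  colonies is deliberately omitted: the statistic is computed in a locally
  detrended frame, so only the transverse fluctuation law matters.
* **Sector coarsening** places an even number of boundaries (alternating
  color labels) on a ring of radius R0 = 1 mm and advances the front to
  Rf = 4 mm in 5-µm radial steps; each boundary's arc position takes an
  independent Gaussian increment of variance 2·D_b·dr while inflation
  dilutes angular density. Adjacent boundaries that cross annihilate in
  pairs, resolved left-to-right in angular order (including the 0/2π seam)
  until all circular gaps are positive — a deterministic, seed-stable
  tie-break. Boundary parity is conserved; the preserved fraction is the
  surviving one-color sector count over n_boundaries/2.
* **Establishment** evolves a sector half-width X by dX = s·dr +
  N(0, 2·D_b·dr), absorbing at X ≤ 0 and establishing at X ≥ X_est = 50 µm
  (or by surviving 3 mm of growth). X0 defaults to 1.7 µm — one effective
  cell width, √(length·width) for E. coli. p_est carries a Wilson 95%
  binomial interval. Establishment rises with s and falls with D_b, and
  the preserved diversity fraction falls monotonically with D_b and is
  better described by c/√noise than by a straight line — the pipeline
  tests these *relationships*; no microscopic constant linking bead MSD
  amplitude to boundary diffusion is asserted, because the two are treated
  as one tunable noise scale.
* **Bead imaging** renders isotropic Gaussian spots (σ = 1.5 px, peak
  1000 counts over a 100-count background → peak/background 11) at
  subpixel ground-truth positions on a 512×512 px field, ~250 beads, one
  frame per 10 min for 12 h, with Gaussian shot-like noise of sd
  photon_noise·√signal. Pixel centers sit at integer coordinates, origin
  top-left, x right / y down. Beads outside the field are absent from the
  frame, not an error.
* **Plate effects** multiply strain effects (positive by construction —
  hence multiplicative log-normal plate factors, matching the ratio
  normalization) by a per-plate log-normal factor and 10% Gaussian
  measurement noise; every plate carries 8 wild-type wells and each strain
  appears on 3 distinct plates.
* **Trait tables** draw four colony-level traits from a correlated
  Gaussian (area–depth −0.4, area–roughness +0.4, matching the observed
  signs) and five cell-level traits independently; the response is a
  sparse linear combination of the colony traits (coefficients 0.40,
  −0.25, 0.30, 0.15) plus Gaussian noise of sd 0.3. These defaults give a
  regime where 5-fold cross-validated Lasso recovers the true support
  reliably at n = 200 while a pure-noise response yields a near-empty one.

What the generators do **not** emulate: nutrient fields, mechanical
single-cell interactions, realistic colony-edge morphology, focus drift,
uneven illumination, or bead loss into the colony bulk. Passing tests
therefore demonstrate correctness of the estimators under the stated
stochastic models, not robustness to every imaging artifact of real data.

## Tracking

Detection takes local maxima above threshold (5-px footprint) and refines
them by background-subtracted center of mass within 4 px (background =
median of the window border); a noiseless isolated spot is localized to
< 0.001 px and realistic fields to ~0.04 px RMSE. Detections closer than
`min_separation` (default 10 px ≈ two refinement radii) are crowd-flagged:
a neighbor inside the refinement window contaminates the centroid, the
same failure mode as overcrowded beads in the experiment. Tracks containing
crowded detections carry a `crowded` QC flag and are excluded from
fidelity statements. Two true beads closer than the spot size merge into a
single detection that cannot be flagged from one frame; this resolution
limit is inherited from the optics being emulated.

Coarse flow between consecutive frames is estimated per 64-px patch from
the circular FFT cross-correlation peak with 1-D parabolic subpixel
refinement, followed by universal-outlier validation (vectors deviating
from their 3×3 neighborhood median by more than 2 px + 2·MAD are replaced
by that median) — textureless patches otherwise produce noise vectors.
Linking advects each open track by the bilinearly interpolated flow and
assigns candidates within `max_disp` of the prediction greedily,
shortest link first, with ties broken on coordinates so the result is
invariant to detection order. There is no gap closing: a missed detection
terminates the track — conservative, biasing toward shorter tracks rather
than wrong links. Greedy assignment (not global optimization) is adequate
at ~250 beads/field, where the mean neighbor distance (~16 px) far exceeds
the per-frame motion.

## Sector estimators and collision geometry

The inoculum front holds N_front = π·d/a cells (d = inoculum diameter,
a = 1.7 µm effective cell size — circumference over cell width, the only
reading of "initial number at the front" that yields a count along a
front). Fraction of diversity preserved f = n_sectors/(N_front/2); the
half accounts for same-color neighbors. Establishment probability
p_est = N_sectors/N₀ with N₀ = N_front × resistant fraction; p_est > 1 is
possible under counting noise and warns rather than clamps.

The collision boundary between colonies expanding at speeds v₁, v₂
(k = v₂/v₁) from inocula d apart is modeled as the equal-arrival-time
locus — the Apollonius circle of radius R = d·k/|k²−1|, straight at k = 1.
The inverse, k = (d + √(d² + 4R²))/(2R), gives the fitness coefficient
s = k − 1 with the sign set by which colony the arc bows into. R < d/2
would imply k > 1 + √2 and is flagged as an inconsistent observation. The
published assays compute curvature-to-fitness through the same geometric
family; only the self-consistency of this forward/inverse pair is
guaranteed here.

## Trait inference

Partial correlation residualizes both variables on the controls (with
intercept) and correlates the residuals, p from Student's t on n − 2 − k
degrees of freedom; it equals the inverse-correlation-matrix formula to
machine precision and reduces exactly to Pearson for an empty control set.
Lasso selection standardizes predictors, picks the penalty by 5-fold
cross-validated MSE with seeded shuffled folds (CV-minimum rule; the
sparser 1-SE rule is selectable), and reports standardized coefficients,
the support, and in-sample R². Measurement errors on traits are not
propagated (no errors-in-variables treatment); this is a known limitation.
Term (gene-set) shift tests offer two permutation nulls, recorded in the
output: means of random same-size strain subsets ("does this term differ
from random knockouts?") or two-sample permutation against wild-type
replicate values. P-values are two-sided with the add-one correction
(p ≥ 1/(n_perm + 1), floor n_perm ≥ 1000) and Benjamini–Hochberg adjusted
across terms.

## Problem sizes

Default verification scales, chosen as the smallest at which each property
is cleanly measurable: 20 trajectories (≤ 200 points) for oracle
agreement; 50 × 1200 µm trajectories per exponent-recovery case; 50
strains × 3 plates × 3 replicates for plate-effect removal; 200 seeds per
boundary-diffusion value over a 5-value sweep; 2000 trials per
establishment grid point; one 30-frame, 250-bead rendered stack for
tracking fidelity; 20 repeats of n = 200 trait tables for Lasso recovery;
100 terms × 2000 permutations and 100–200 bootstrap-coverage repeats for
calibration.

## Known limitations

* The random-effects trajectory combination is the package's resolution of
  a bias intrinsic to SEM weighting over overlapping windows; with very
  few trajectories (< ~5) τ² is itself noisy and the combined error can be
  underestimated.
* The fitted amplitude A is systematically below the generator's fBm
  amplitude because local detrending removes intra-window fluctuation; the
  exponent, and ratios of MSD(50 µm) between colonies, are the meaningful
  outputs.
* Merged bead spots (closer than the PSF) are unresolvable and yield a
  single detection between the true positions.
* The establishment simulator treats the sector half-width as a 1-D biased
  walk; sector–sector interactions and coalescence are outside its scope.
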