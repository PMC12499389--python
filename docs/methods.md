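# Methods

`boldslope` implements a lifespan analysis of the spectral content of
resting-state BOLD fluctuations at the cortical-parcel level, together with
a synthetic cohort generator that reproduces the statistical structure the
analysis is designed to detect. This note documents the models, the
numerical choices, and what the synthetic conditions do and do not show
about real data.

## Spectral slope estimation

BOLD power spectra are approximately 1/f-like: log power decreases roughly
linearly with frequency over the infra-slow band, sitting on a flat
(thermal/motion) noise floor. The spectral slope

SS = −d log₁₀ S(f) / df  over f ∈ [0.015, 0.145] Hz

indexes the predominance of slow over fast activity (units: log₁₀-power per
Hz; typical cortical values here are of order 5–20). Log base 10 is fixed by
convention in this package — the base rescales SS but affects no comparison.

Because high-motion frames must be excluded, the PSD is estimated by the
Wiener–Khinchin route rather than a direct FFT:

1. **Censored autocovariance.** After demeaning over valid frames, for each
   1-based lag m the raw sum Σ xₜ·xₜ₊ₘ₋₁ runs over pairs in which both
   frames are valid, with n the number of such pairs. The scaled lag
   q = (m−1)·TR/30 (the 30 s constant is a fixed normalization) enters a
   Gaussian taper, giving the adjusted value raw·exp(−q²/2)/n. Lags with no
   valid pair get 0 and are flagged. With an all-valid mask this reduces
   bit-for-bit to the ordinary biased-pair estimator times the taper.
2. **Cosine transform.** S(f) = TR·[a(1) + 2·Σₘ₌₂ a(m)·cos(2π f (m−1) TR)]
   on the grid fⱼ = j/(2·n_freq·TR), j = 0…n_freq, with n_freq = 256
   (guarantees ≥ 5 in-band points for TR ≤ 4 s). The default maximum lag is
   where the taper falls below 10⁻³ (q ≈ 3.72, about 112 s), capped at one
   less than the series length: later lags contribute nothing.
3. **Flooring.** Lag-window estimates can go slightly negative; values are
   floored at 10⁻¹² times the spectral maximum before logging and flagged.
   The floor caps a semilog fit at roughly 12 decades across the 0.13 Hz
   band, so pathological fits are bounded near SS ≈ 95; with the default
   cohort fewer than 1 % of subject×parcel fits are affected.
4. **Slope fit.** OLS of log₁₀ power on raw frequency over the in-band grid;
   SS is the negative of the fitted slope. The alternative log–log
   (power-law) fit is available for model comparison; on the synthetic
   spectra (semilog by construction) the semilog R² dominates, mirroring
   the model-form choice the analysis assumes.

The estimator is amplitude-invariant (SS(c·x) = SS(x)) and calibrated:
white-noise series give mean SS statistically indistinguishable from 0, and
spectral-synthesis inputs with target slope s are recovered with bias well
below 5 % (Gaussian-in-frequency smoothing by the lag taper multiplies an
exponential spectrum by a constant, so the semilog slope is preserved
exactly until band-edge and floor effects enter).

## Lifespan GAMs

Per parcel, SS is modeled as a generalized additive model with a penalized
thin-plate regression spline of age (basis dimension k = 4, REML-selected
smoothing) and linear sex and head-motion covariates, fitted with mgcv via
an Rscript worker (one invocation fits all parcels). The reduced model is
the covariates-only OLS fit. Effect summaries:

* **p_age** — mgcv's standard approximate test for penalized smooths.
  Simulation (200 null parcels at n = 455) shows the raw p-values are
  uniform to KS precision and BH at q = 0.05 controls the false-discovery
  proportion.
* **ΔR²** — R²(full) − R²(reduced) with R² = 1 − RSS/TSS for both models
  ("explained variance" made explicit). A planted effect holding 10 % of
  response variance is recovered with mean ΔR² ≈ 0.10 and |bias| < 0.03.

Smooths for plotting/clustering are predicted with covariates at their
column means (reference levels are otherwise arbitrary and unstated in
common practice). Parcels to exclude (e.g., susceptibility-affected
regions) enter as an explicit id list, not a recomputation.

## Trajectory clustering

Fitted age smooths of FDR-significant parcels are mean-centered per row —
not variance-scaled — so the *shape* (decline onset) rather than the
amplitude of decline drives clustering; this choice is configurable.
Fuzzy c-means uses a fuzzifier of 5 (deliberately soft memberships),
Euclidean distance, tolerance 10⁻⁵ on the objective, and at most 10 000
iterations, initialized from a seeded random row-stochastic membership
matrix. A point at zero distance from one or more centers splits its mass
evenly over them. Clusters are canonically reordered by descending
winner-take-all size (cluster 1 = majority family). The cluster count is
chosen by the mean silhouette of winner-take-all labels over candidates
2–15; candidates that are infeasible or collapse to a single non-empty
cluster score −1.

The RSN correspondence index is Σₚ rsn_probᵣ(p)·u_c(p), normalized within
each cluster to sum to 1 over networks so clusters of different sizes are
comparable (the normalization is otherwise under-determined).

On cleanly planted two-family trajectories the silhouette selects N = 2 and
the partition is seed-stable (ARI = 1). On the full default cohort the
choice between N = 2 and larger counts can be marginal: the generator's
decline-rate topography adds continuous within-family amplitude variation,
and delayed-onset parcels have weaker total age effects and therefore lower
FDR survival at n = 200 — both features blur the family boundary in a way
a larger study would not.

## Spin permutation test

Spatial association between two parcel maps is Spearman correlation over
jointly non-missing parcels, with significance from random rotations of
the spherical parcel centroids: uniform SO(3) rotations from normalized
4-D Gaussian quaternions, applied directly to the left-hemisphere sphere
and x-mirrored to the right (each hemisphere is its own unit sphere).
After rotating the non-medial source parcels, any source whose rotated
position is nearest a medial-wall centroid is dropped; every surviving
non-medial target then takes the value of its nearest rotated source
(many-to-one collisions allowed), so rotated maps only permute and
duplicate original values. The one-sided p-value is
(#{null > ρ_obs} + 1)/(R + 1); the +1 keeps p positive (a two-sided option
exists but the one-sided "greater" convention is the default).

Calibration: on a single sphere the test rejects at 0.05–0.06 for α = 0.05
with moderately smooth Gaussian-random-field maps. Two subtleties matter
for synthetic geometries: (i) null maps must respect the hemisphere
structure — a field generated over the pooled 3-D coordinates of both
hemispheres couples left/right parcels through chance 3-D adjacency on the
shared shell, a dependence the mirrored-rotation null cannot reproduce and
which inflates rejections; the exchangeable null family is an independent
within-hemisphere field; (ii) extremely smooth maps (a handful of
effective degrees of freedom, e.g., pure linear fields) inflate any
parcel-level spin test at this parcel count, while smoother-than-calibrated
GRFs make it conservative. The calibration simulation uses
hemisphere-wise GRFs with kernel width 0.4 rad (measured rejection 0.055 at
α = 0.05; 0.02 at width 0.6).

## SS Youthful Index and white-matter correlates

The SSYI of a subject is the Spearman correlation between their SS map and
the parcel-wise mean map of subjects younger than 45 y; it is invariant to
any increasing transform of the subject's map. Outliers are subjects more
than 3 scaled MADs (1.4826·median absolute deviation, the Gaussian-
consistent scale) from the median SSYI across all subjects; with all values
equal nothing is flagged, and flags are affine-equivariant.

T2w volumes are z-scored voxelwise against a reference atlas (mean and sd
over subjects younger than 40 y; sd floored at 10⁻⁶). VLSM-style maps are
per-voxel Pearson correlations between normalized intensity and SSYI
across subjects, thresholded at two-sided p < 0.05 with no multiplicity
correction (exploratory); zero-variance voxels are excluded and flagged.
The FLWM summary statistic is the mean normalized intensity over the
significantly *negatively* correlated voxels (the direction of the planted
and expected effect; the unsigned mask is also written).

The outlier regression is a linear probability model (deliberately linear,
not logistic) of the binarized youthful status on age, grey-matter volume,
head motion, sex and FLWM T2w intensity, restricted to subjects older than
45 y. The response is coded 1 = retains the youthful pattern, so elevated
FLWM intensity among divergent subjects yields a negative FLWM
coefficient.

## Synthetic cohort

The generator defines the study conditions; defaults: 200 subjects, ages
uniform on 18–88 y, 100 parcels, 261 frames at TR = 1.97 s, 10 % frame
censoring (i.i.d. Bernoulli), 10 % divergent subjects among those older
than 45 y, and an age effect targeted at 10 % of slope variance.

* **Geometry** — a Fibonacci lattice per hemisphere on the unit sphere;
  parcels within a 25° cap around the medial pole are flagged medial wall;
  seven RSN probability fields are softmax kernels around mirrored seed
  directions and sum to 1 per parcel.
* **Baseline topography** — the youthful slope map is a smooth gradient on
  the sphere (mean 10, amplitude 4 plus a quadratic term and 0.5 sd
  scatter). The amplitude is set so that the across-parcel slope spread
  (sd ≈ 2.4) dominates single-run estimation noise (sd ≈ 1.2) at 100
  parcels, placing non-divergent SSYI near 0.77 ± 0.06 — the regime the
  index needs to be informative at this problem size.
* **Trajectories** — family 1 declines linearly from age 20; family 2
  (the 30 % of parcels with the highest combined AUD+CON+SAL probability)
  is flat until 50 y then declines steeply enough to reach the same total
  loss by the end of the range. The decline exponent is configurable
  (default linear — the shape within family 1 is not pinned by prior
  knowledge). Rates are modulated ±30 % per baseline z-score so steep
  youthful parcels flatten fastest, which induces the ΔR²–CMRGlc spatial
  correlation the association stage measures. The base rate is solved in
  closed form from the target variance fraction using the subject-offset
  sd (1.2), parcel jitter sd (0.3) and an assumed estimation-noise sd
  (1.0).
* **Timeseries** — random-phase spectral synthesis: the expected
  periodogram equals 10^(2 − s·f) plus a flat floor (default 0.1), so
  frames are Gaussian and the estimator's target is exact. Divergent
  subjects have their across-parcel slope profile randomly permuted over
  non-medial parcels — topography destroyed, marginal values preserved —
  which attacks the rank-based SSYI directly without changing magnitudes.
* **Metabolic maps** — CMRGlc is a sigmoidal transform of the baseline
  slope map plus Gaussian noise (sd 8; Spearman with the youthful map
  lands in 0.68–0.80 across seeds); CMRO₂ and CBF use sd 14 and 18,
  giving the expected ordering of correlation strengths.
* **T2w volumes** — 24³ grids (3 mm iso, RAS), pure noise (sd 5) outside a
  contiguous 6³ frontal-white-matter box; divergent subjects get a +10
  intensity shift inside it. The reference atlas comes from subjects
  younger than 40 y. Sex, motion and GMV are drawn independently of
  divergence status so the covariate terms of the outlier regression have
  a true null.

What the synthetic conditions do **not** emulate: hemodynamic response
shape, physiological (cardiac/respiratory) noise, burst-like motion
(censoring is i.i.d.; a contiguous-block option is out of scope), spatial
autocorrelation of estimation noise between parcels, surface meshes, and
any partial-volume structure in the volumes. Tests passing here therefore
demonstrate the correctness and calibration of the estimators and the
internal consistency of the pipeline — not performance on real scanner
data.

## Problem sizes and determinism

Defaults are chosen for a single-CPU workstation run: the full default
pipeline (200 subjects × 100 parcels, 10 000 rotations) completes in well
under a minute apart from the GAM stage's single Rscript call, and
simulation-based checks use 100–200 replicates. All randomness flows from
one integer seed through named SeedSequence streams; a rerun with the same
configuration is byte-identical (the manifest records a content hash of
every output and an overall run hash). Stage outputs are plain TSV/JSON
(NIfTI-1 for volumes), so any stage can be re-run on externally supplied
files in the documented schemas.
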