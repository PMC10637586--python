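# Methods

This note documents the models and procedures implemented in
`habitatomics`, the defaults and why they were chosen, what the synthetic
phantoms do and do not emulate, and the package's known limitations.

## The analysis pipeline

The pipeline targets a binary histopathological endpoint (here: LVSI,
lymphovascular space invasion) predicted from a single contrast-enhanced
T1-weighted MRI volume with a manually segmented tumour VOI per patient,
split into a training and an external test cohort.

**Geometry and grayscale.** Images are resampled to 1×1×3 mm (3rd-order
B-spline for the image, nearest-neighbour for the mask — the standard
radiomics pairing, preserving mask labels) and the VOI grayscale is min-max
rescaled to 0–255. The min/max are taken over VOI voxels only: normalising
on the whole field of view would let background air dominate the scale and
make habitats incomparable across patients. Min-max normalisation is a
known noise source — the per-patient scale and offset depend on the
extreme-intensity tails of the VOI — and this matters for what kinds of
label signal survive it (see the generator section).

**Per-voxel features.** Each VOI voxel carries its intensity V and the
local entropy H = −Σᵢ pᵢ log₂(pᵢ + ε) of the N_g-bin histogram of the
in-plane square window centred on it. Defaults: window radius 2 (5×5
pixels), N_g = 32 equal-width bins over [0, 255], ε = 10⁻¹²; the window is
clipped at image borders and counts every window pixel regardless of mask
membership. The stabiliser sits inside the logarithm (−Σ pᵢ log₂(pᵢ + ε))
so empty bins are harmless and H converges to the Shannon entropy as
ε → 0; placing ε outside the sum would leave log₂ 0 undefined. Entropy is
2D (slice-wise) because the through-plane spacing (3 mm) is three times
the in-plane spacing; a 3D window would mix anisotropic length scales.

**Choosing the number of habitats.** Voxels are pooled across training
patients (capped per patient, default 2000 per patient in the pipeline
config; 5000 items total in the consensus step), z-scored with the pooled
mean/SD, and consensus-clustered: for each k in 2…10, k-means (Lloyd's
algorithm with k-means++ seeding) is run on `n_reps` random item subsets
(default 1000 at 80%), and consensus(i,j) = co-clustered / co-sampled
counts. Two summaries are computed per k:

* the empirical CDF of consensus values and its area A(k), with the
  relative delta-area series Δ(k) = (A(k) − A(k−1))/A(k−1) — the classic
  consensus-clustering display;
* PAC(k), the proportion of ambiguous clustering: the fraction of
  consensus values strictly between 0.1 and 0.9.

The default decision rule is **PAC**: k* is the largest k with
PAC(k) ≤ 0.08, falling back to the smallest k when none qualifies. The
delta-area elbow (stop before the first Δ below a threshold) is available
as `selection_rule="delta_area"`, but it is *not* the default for a
structural reason worth recording: A(k) equals one minus the mean consensus,
which only tracks how many pairs are co-clustered, not whether assignments
are stable. Splitting one of k equal, perfectly stable clusters raises the
relative area by 1/(k²−1) (≈ 0.33 at k=2→3, 0.125 at 3→4) regardless of
whether any real structure was found, so no fixed delta-area threshold can
separate genuine sub-structure from stable-split combinatorics; on clean
three-cluster data the measured delta-area series decays smoothly
(≈ 0.49 / 0.21 / 0.13 / 0.07 …) for exactly this reason. PAC measures the
instability itself — clusterings at or below the true k are reproducible
across resamples (PAC ≲ 0.04 on design phantoms), while at k+1 the extra
centroid lands in a different cluster on each resample and PAC jumps
(≥ 0.11) — and is therefore the faithful automation of the visual rule of keeping
the finest clustering that is both well separated and reproducible. The
0.08 threshold sits in the middle of that measured gap and was fixed at
design time.

k-means itself is a purpose-built implementation (k-means++ seeding,
assignment-stability stopping, ≥10 restarts for patient segmentation, 1
restart inside the consensus resampling, 300 iteration cap): the consensus
stage runs tens of thousands of small fits, where the per-call overhead of
a general-purpose library estimator dominates the arithmetic by one to two
orders of magnitude. The implementation is cross-checked against
scikit-learn's KMeans and against an exhaustive-partition WCSS oracle in
the test suite.

**Per-patient segmentation and label alignment.** Each patient is
segmented at k* with k-means on the z-scored (V, H) features (cohort-level
scaler, 10 restarts, seeded), and clusters are renamed so habitat 1…k* is
ordered by ascending mean original-scale intensity. The ordering rule is a
convention — nothing in the clustering makes "habitat 2" of one patient
correspond to "habitat 2" of another — but it is deterministic, auditable,
and on phantoms it maps habitats to their generating compartments.
Patients with fewer voxels than k* are excluded and logged.

**Radiomics.** A native feature engine computes seven IBSI-style families:
first-order (18), shape (14), GLCM (24, symmetric co-occurrences averaged
over the 13 unique 3D directions at distance 1), GLRLM (16), GLSZM (16,
26-connected zones), NGTDM (5), GLDM (14, dependence = neighbours within
α = 0 gray levels, counted +1 so the dependence size is ≥ 1). Filtered
variants: Laplacian-of-Gaussian at σ ∈ {1, 2, 3} mm and the eight level-1
stationary-wavelet sub-bands (`coif1`, edge-padded to even dimensions).
Discretisation uses a fixed bin width (default 25 on the 0–255 scale,
≈ 10 bins) anchored at the region minimum, which makes every texture
feature invariant to adding a constant to the image. Degenerate regions
(a single occupied gray level) take conventional values (e.g. correlation
1, contrast 0) rather than NaN, and regions below 10 voxels are skipped
with a logged reason. With all filters and families enabled a region
yields 1130 features; the count is configuration-dependent and reported,
never asserted. Shape features are computed once per region from a
marching-cubes mesh; the binary mask is lightly Gaussian-smoothed
(σ = 1 voxel) before meshing because the raw staircase mesh overestimates
a sphere's surface by ~8% (sphericity 0.92 instead of 1.00); if smoothing
collapses a thin structure (mesh volume off by >25% from the voxel
volume), the raw mesh is used instead.

**Feature selection.** Four nested stages: (1) two-reader reproducibility,
keeping features with ICC(2,1) ≥ 0.75 (two-way random effects, absolute
agreement, single measurement — the common radiomics choice for two fixed
readers; undefined ICCs count as failures); (2) z-scoring with training
cohort mean/SD (population SD, ddof = 0); (3) greedy Pearson pruning at
|r| > 0.9, visiting columns by descending raw variance (ties by name) so
the more variable of a redundant pair survives; (4) L1-penalised logistic
regression with λ* minimising 5-fold cross-validated binomial deviance over
25 penalties, λ ∈ [0.1, 100] — weaker penalties approach the unpenalised
fit, which is never optimal for selection and makes the solver crawl on
separable data. Empty LASSO support falls back to the Pearson survivor set
with a warning.

**Models and evaluation.** One RBF-kernel SVM per region (whole tumour +
each habitat), hyperparameters from a seeded stratified 5-fold grid search
maximising AUC over C ∈ {0.1, 1, 10, 100} and γ = scale-heuristic ×
{0.1, 1, 10}; all regions share the seed so fold assignments are identical
and DeLong comparisons are paired. Probabilities come from explicit Platt
scaling fitted on out-of-fold decision values, with a monotonicity guard:
if the fitted sigmoid is decreasing in the margin (which happens when CV
margins are uninformative), it is refitted on the training margins so
probabilities can never anti-rank the SVM's own decision values. The
operating threshold is the Youden-optimal point of the training ROC,
applied unchanged to the test cohort. AUC uses the Mann-Whitney estimator
with DeLong structural-component variance (normal CI clipped to [0, 1];
perfectly ranked scores give SE 0); the paired DeLong test returns p = 1
for identical score vectors. Calibration is decile-binned observed vs
predicted frequency plus a logistic recalibration slope/intercept on
logit(score); decision curves report NB(t) = TP/n − (FP/n)·t/(1−t) against
treat-all and treat-none references.

**Clinical statistics.** 2×2 tables use Pearson chi-square *with* Yates
continuity correction — this choice reproduces the published 2×2 p-values
of the bundled cohort table to their printed precision, the uncorrected
statistic does not; r×c tables use the uncorrected statistic (df =
(r−1)(c−1)) with expected counts exposed so callers can fall back to
Fisher's exact test when any is < 5. The two-sample t defaults to pooled
variance (again matching the published continuous rows; Welch by flag) and
accepts printed mean ± SD summaries. Pooled stage-wise event rates use
exact rational arithmetic before rounding.

## The synthetic cohort generator

The generator is the package's study design: its defaults *are* the
conditions under which the acceptance properties are claimed.

**Phantom.** An ellipsoidal tumour (axes 15×13×16 mm) centred in a
48×48×16 grid at 1×1×3 mm, partitioned into three contiguous compartments
with volume fractions 0.40/0.33/0.27. The default geometry stacks the
compartments as **axial slabs** (whole slices, split at z-quantiles of the
mask volume, each habitat guaranteed ≥ 1 slice); concentric shells and
angular sectors are available as alternatives. Slabs are the default for a
reason tied to the entropy definition: the texture window is slice-wise,
so slab compartments never contaminate each other's windows. With shells
or sectors, the in-plane interface band (windows mixing two intensity
levels ~100 gray units apart) forms a coherent high-entropy arc in
(V, H) space that is itself a *stable* cluster — such phantoms are
honestly four-structured for these features (segmentation ARI saturates
around 0.86–0.94 and consensus clustering correctly prefers k = 4–5), and
would test the pipeline against a ground truth its own features cannot
express. Slab phantoms recover ARI ≈ 0.99 and the exact PAC signature.

**Intensity and texture.** Habitat means 30/128/228 with white Gaussian
noise of SD 8/16/32: the graded SDs give the three habitats distinct
entropy levels (≈ 1.9/2.9/3.9 bits at N_g = 32) while keeping intensity
separation above 3 pooled SDs. A per-habitat smoothing knob remains
(Gaussian-filtered noise rescaled to the same marginal SD, so smoothing
lowers local entropy without changing the histogram) and is exercised by
the monotone texture-response test, but defaults to 0.

**Between-patient variability and the label signal.** Per patient: habitat
means jitter with SD (4, 8, 4) — the extreme habitats are kept tighter
because they anchor the min-max normalisation, and anchor jitter is pure
noise for every downstream feature; habitat volume fractions jitter with
SD 0.15 (renormalised, floored at 0.08); tumour size scales by ±12%; and
habitat noise SDs jitter log-normally with σ = 0.15. Label-positive
patients have the **signal habitat's noise SD shifted by effect_size ×
0.15 in log units** (`signal_type="texture"`, the default; effect_size is
thus a standardised shift in units of the between-patient texture SD). A
mean-shift signal (`signal_type="mean"`, shift = effect_size ×
between-patient SD of the signal habitat) and the combination are also
available. Texture was chosen as the default signal channel deliberately:
a pure mean shift of the middle habitat is partly recoverable from
whole-tumour histogram *shape* statistics — the global median rides the
middle mode, and kurtosis/IMC-type features track mode positions scale-
free — which makes the habitat-vs-whole contrast a coin flip; a texture
shift is invariant to normalisation offset noise within the habitat, while
whole-tumour aggregates of it are masked by the other habitats'
independent texture jitter and by the fraction jitter. The signal habitat
defaults to 2 (middle intensity) because shifts in the extreme habitats
would be partially absorbed by the min-max anchors.

**Reader masks.** The second-reader mask applies seeded rounds of
one-voxel dilations/erosions to random boundary patches, one round per mm
of jitter; Dice against the first mask stays ≥ 0.85 at ≤ 2 mm on
tumours ≥ 20 mm. The analysis mask itself is the exact ellipsoid; the
perturbed mask exists for the ICC stage.

**What the phantoms do not emulate.** MRI physics (coil bias fields,
Rician noise), partial-volume mixing at habitat boundaries, anatomically
realistic habitat shapes (real perfusion habitats are not axial slabs),
multi-sequence acquisition, and inter-scanner variation. Passing the
phantom studies therefore demonstrates that the pipeline recovers the
structure it is designed to recover under controlled conditions — not that
habitat radiomics will show the same advantage on any particular clinical
dataset.

## Benchmark studies and problem sizes

The acceptance studies (in `habitatomics.benchmarks`, used by both the
test suite and `scripts/acceptance.py`) run at desk scale, chosen so the
full set completes in a few minutes on one CPU:

* habitat recovery: 20 patients, k = 3, mean per-patient ARI vs truth;
* consensus k selection: 20 runs × (20 patients × 100 voxels = 2000 pooled
  items, 200 resamples at 80%, k = 2…10);
* LASSO support recovery: 10 runs, n = 200, 5 informative (1 SD effect on
  the logit) + 95 noise features;
* null-label SVM: 5 runs, n = 200; the reported quantity is the
  cross-validated AUC of the *selected* hyperparameter configuration on
  fresh folds — the grid search's own best score is a maximum over the
  grid and is optimistically biased even under the null;
* habitat-vs-whole contrast: 10 replicates, n = 120 training / 60 test
  patients, effect 2 SD, with a reduced extraction configuration
  (original-image first-order + GLCM + GLDM) and the ICC stage disabled —
  the contrast under study is signal localisation, not reader
  reproducibility.

## Numerical choices and degenerate inputs

* Pooled/population SD (ddof = 0) everywhere a z-score is defined; the
  inverse transform is exact.
* Consensus entries for never-co-sampled pairs are undefined: excluded
  from the CDF/PAC with a warning.
* Zero-variance features: the voxel scaler and z-score stage raise, naming
  the feature; constant columns are dropped before z-scoring in the
  selection funnel (they carry no signal).
* Empty clusters during Lloyd iterations are re-seeded at the points
  farthest from their assigned centroids.
* Youden threshold: placed halfway between the optimal score and the next
  lower score (prediction is score ≥ threshold), clipped to (0, 1).
* DeLong with zero variance of the AUC difference returns p = 1.
* Fisher's two-sided p sums hypergeometric probabilities ≤ the observed
  table's probability (with a 1 + 10⁻¹² tolerance for ties).

## Known limitations

* The feature engine implements the IBSI-style definitions independently;
  exact numerical parity with any particular extractor's naming or
  aggregation variants is not a goal, and the per-configuration feature
  count (1130 with everything enabled) is reported rather than matched to
  any external count.
* The r×c Fisher exact test is not implemented (chi-square with an
  expected-count warning is used instead).
* Consensus clustering stores the full item×item matrices; at the default
  5000-item cap this costs ~100 MB per k. Reduce `max_items` on small
  machines.
* The delta-area k-selection rule is retained for display and comparison
  but, as derived above, is structurally unable to distinguish stable
  splits from real structure; use the PAC rule.
* Cross-patient habitat correspondence by intensity rank is a convention;
  if two habitats swap intensity order between patients the labels will
  follow intensity, not biology.
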