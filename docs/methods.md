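# Methods

## The delineation model

`tumorextent` treats tumor delineation as voxel-wise classification
against a within-subject normal reference. For each of six co-registered
parameter maps — post-gadolinium T1-weighted intensity (a.u.), baseline
T1 and T2 relaxation times (s), cerebral blood flow (mL/100 g/min),
cerebral blood volume (%), and apparent diffusion coefficient (μm²/ms) —
the mean and sample SD (n−1 denominator) are estimated over the
contralateral region: every brain voxel strictly beyond the midline on
the tumor-free side, excluding ventricles. The region is pooled across
slices and tissue classes; splitting it by slice or by gray/white matter
would shrink the sample or add partial-volume error at this resolution.
The midline is supplied per slice (as a column index) so tumor-induced
midline shift can be accounted for by the caller; the package does not
estimate it.

Seven abnormality channels are thresholded from the six maps (ADC
contributes separate high and low channels, which are mutually exclusive
at any voxel). Inequalities are strict — a voxel exactly at mean ± k·SD is
normal — because the rule is stated as "beyond k SD" and the boundary has
measure zero for continuous data. A reference SD of exactly zero is
degenerate; the channel is still computed (every deviation from the mean
triggers) and a warning is logged, so that noise-free synthetic edge cases
remain runnable.

The multimodal mask is `count(abnormal channels) ≥ min_count`, default 2.
The statistical rationale: for one channel at k = 1 a normal Gaussian
voxel is abnormal with probability Φ(−1) ≈ 0.159, so a *fixed pair* of
independent channels co-fires with probability ≈ 0.025 < 0.05. Note this
is a per-pair statement; the family-wise rate of "any ≥ 2 of 7" is much
higher (~0.31 for fully independent channels), which matters for the
phantom design below. Because adc_high and adc_low can never co-occur, the
ADC map can contribute at most one count to the decision.

Comparator delineations:

* **sd2** — post-Gd intensity > mean + 2 SD. Identically equal to the
  `postgd_high` channel at k = 2.
* **refined** — a fully parameterised morphology pipeline meant to mimic
  what a human does when cleaning a threshold map: threshold at
  mean + k·SD (default k = 2), morphological closing (ball radius
  1 voxel), keep the largest 26-connected component intersecting the
  tumor-side hemisphere, fill enclosed holes. Every step is logged and
  recorded on the output mask. These exact steps are this package's own
  definition; alternatives can be swapped in through `RefinedSettings`.
* **observer consensus** — voxels delineated by ≥ 2 observers (voxels
  marked by only a single observer are excluded).

## Evaluation

Scores are computed over the *valid domain only*: voxels with histologic
data. Sensitivity, specificity, accuracy, Jaccard and Youden
(Y = sens + spec − 1) follow the usual confusion-matrix definitions; any
zero denominator yields a missing value (NaN) and a log line rather than a
silent zero, because silent zeros corrupt downstream aggregation.
Interobserver agreement is summarised by pairwise Jaccard and percent
volume difference |V_i − V_j| / mean(V_i, V_j) × 100.

**Ablation importance** removes each channel in turn, recombines, and
records the signed change in sensitivity, specificity and accuracy.
Because the counting rule is monotone, removal can only lower sensitivity
and raise specificity. The "relative contribution" share is each channel's
accuracy drop floored at zero and normalised to sum to 1 — the floor-then-
normalise scheme is this package's fixed choice (raw signed deltas are
always retained in the output); ranks break ties by the fixed channel
order of the table above.

**Addition-order analysis** walks every permutation of the channels,
recording the accuracy after each addition (with fewer than `min_count`
channels added, the counting rule yields an empty mask, so the baseline is
the empty delineation's accuracy). Since accuracy depends only on the
*set* of channels present, the implementation precomputes accuracy for all
2^n subsets (128 for n = 7) and evaluates the 5040 orders by table lookup;
the naive per-order loop is retained in the test suite as the independent
oracle. Exhaustive enumeration is used up to 7 channels; beyond that a
seeded sample of orders is drawn.

**Occult-rim analysis** defines the rim as gold ∖ consensus, restricts the
evaluation domain to valid ∖ consensus, and re-runs both importance
analyses with the rim as the positive class. An empty rim is flagged and
the analyses skipped.

Group-level inference (ANOVA, post hoc tests, McNemar, random-effects
weighted means) is deliberately not implemented; the pipeline emits tidy
per-study tables for external statistical software.

## Histology processing

Binary stain masks (EpCAM, pimonidazole, cresyl violet, collagen IV)
arrive pre-registered to their image slice with a pixel size and an axial
position; manual anatomical matching and perspective de-warping are out of
scope. Each section is reduced to percent staining per voxel-sized block
(100 × positive/tissue pixels; blocks with no tissue are missing), the
sections falling within a slice are averaged ignoring missing values
(mean, not median), and voxels with at least one contributing tissue pixel
form the coverage mask. Voxels without coverage are excluded from every
downstream analysis. The gold standard marks a voxel tumor when
EpCAM > 0.001% or pimonidazole > 1% (strict inequalities); the thresholds
are fixed constants of the pipeline.

## Vessel morphometry

Connected components (8-connectivity, the standard choice for thin
curvilinear structures) smaller than 5 px or larger than 4000 px are
removed as noise and ventricle/artifact entities respectively — bounds are
strict, so 5 px and 4000 px components survive. Per component:

* `pixel_count`, and cross-sectional area = pixel_count × pixel_size²;
* skeleton by topology-preserving thinning (`skimage.morphology.thin`,
  which reduces a 3×3 square to a single pixel); in-plane length is the
  summed step length along the skeleton (1 px per 4-neighbour step, √2 per
  diagonal). For a w × L rectangle this lands in [L − w, L] px — the
  thinning consumes up to half the width at each end;
* central diameter = 2 × the maximum Euclidean distance-transform value on
  the skeleton, i.e. the widest inscribed circle at the medial axis. For a
  width-w bar this recovers w (even w) or w + 1 (odd w).

Both the diameter and the length definitions are explicit stand-ins fixed
by this package; per-window maps (area fraction, density in
components/mm², and centroid-assigned means of the morphometrics) use
centroid-in-window assignment to avoid double counting. The default window
maps one window to one MRI voxel footprint.

## The synthetic phantom

The generator produces the data the analysis assumes, not realistic MRI
physics. Defaults, chosen once to mirror a rodent brain-metastasis imaging
study:

* **Grid** 64 × 64 × 10 at 0.5 × 0.5 × 1 mm (a 32 mm field of view at
  matrix 64, 1 mm slices).
* **Normal tissue** i.i.d. Gaussian per modality: post-Gd 100 ± 10 a.u.,
  T1 1.8 ± 0.12 s, T2 0.045 ± 0.003 s, CBV 3.0 ± 0.4%, CBF
  120 ± 18 mL/100 g/min, ADC 0.75 ± 0.07 μm²/ms — plausible 9.4 T rodent
  values; only the shift/SD ratios matter to the method.
* **Tumor core**: ellipsoid (semi-axes 6 × 4 × 3 voxels, ~70 μL) in the
  left striatum-analogue, shifted by +3 SD (post-Gd), +2.5 (T1), −2.5
  (T2, CBV, CBF) and +2.5 (ADC). Effect signs are validated against the
  channel directions at spec construction.
* **Invasive rim**: a closed 1-voxel shell around the core with effects
  attenuated ×0.6 (≈1.5–1.8 SD) — abnormal enough that ≥ 2 channels fire
  with high probability, yet invisible to the simulated observers.
* **Observers** (4): the core eroded in-plane by 1 px (observers see and
  under-draw the enhancing core, missing the rim entirely) plus boundary
  jitter (each boundary voxel flipped with p = 0.1, per observer).
* **Histology**: per covered slice, 5 sections 200 μm apart for each of
  EpCAM/pimonidazole/cresyl violet, as Bernoulli pixel rasters at the
  region's staining level (EpCAM 0/2/20% and pimonidazole 0.2/3/15% for
  normal/rim/core — consistent with the gold-standard thresholds), with
  Poisson-placed missing-tissue blobs. Sections are emitted at 50 μm/px
  (configurable): they represent the already-downscaled masks the pipeline
  ingests, and stain fractions are scale-free, so nothing downstream
  changes; full-resolution 2 μm rasters would be 16,000² px per section
  for no statistical gain.
* **Histologic coverage** is narrow by design: the tumor plus a 1-voxel
  margin plus a contralateral reference patch (~100 μL). This mirrors
  studies where voxels lacking histology are excluded from all analyses
  and makes the valid domain hold tumor and normal tissue in comparable
  amounts. It is also why the method's evaluated volumes behave sensibly
  despite the ~31% any-2-of-7 noise coincidence rate: over a whole brain
  that rate would swamp the volume comparison, over the histology-valid
  domain it does not. The whole-brain multimodal mask is therefore *not* a
  meaningful volume estimate at k = 1 under independent noise — a real
  difference from in-vivo data, where cross-modality correlation of normal
  tissue suppresses coincidences.
* **Vessels**: per covered slice, rectangular tubes at 10 μm/px with
  region-dependent density and width (normal: dense and thin; rim/core:
  sparser and wider) plus sub-threshold speckles, with a per-tube ground
  truth table.

Everything is reproducible from one master seed via spawned child seeds,
all recorded in the manifest, and tumor placement is validated never to
cross into the contralateral region.

What passing tests on these phantoms shows: the thresholds implement the
stated tail probabilities; combination, evaluation and importance
machinery are exactly correct (brute-force-verified); and the pipeline
end-to-end reproduces the expected qualitative ordering (observers
under-estimate, the multimodal volume is closer to the histologic truth,
multimodal Youden exceeds observer Youden). What it does not show:
performance on real tissue, where noise is spatially correlated, modality
artifacts are structured, registration is imperfect, and contralateral
"normal" is itself heterogeneous.

## Numerical and design choices

* Missing data is NaN on disk (NIfTI-1), an unset `valid_mask` bit in
  memory; invalid voxels can never be abnormal and never enter statistics.
* Sample SD everywhere (reference is a finite-sample estimate).
* `ablation` / `addition-order` are exact, not sampled, for ≤ 7 channels.
* Telescoping of addition-order deltas holds to < 1e-12 (floating
  differences of accuracies), and is asserted, not assumed.
* Reference stats require ≥ 2 usable voxels per modality; an empty
  contralateral region raises a degenerate-reference error rather than
  returning NaNs.
* In `fit()`, channels are intersected with the brain mask, so extracranial
  voxels never count as abnormal.
* The refined pipeline unions the closing result with the original
  threshold mask so closing can only add, never remove, detections.

## Known limitations

* No registration or resampling: all volumes and masks must share one
  grid, and histology sections must arrive in-register with their slice.
* The "refined" comparator and the vessel diameter/length definitions are
  this package's explicit constructions, not reimplementations of any
  particular in-house original.
* The observer model is morphological (erosion + jitter); it does not
  model perceptual or experience effects.
* Gold-standard thresholds are fixed constants; no per-study calibration
  against contralateral staining intensity is performed.
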