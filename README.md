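# tumorextent

Voxel-wise multimodal MRI tumor delineation with histology-derived gold
standards, vessel morphometry, and modality-importance analysis.

Brain metastases are frequently under-delineated on single-modality
post-gadolinium T1-weighted MRI: independent observers draw the enhancing
core and miss an invasive rim that histology confirms is tumor, and local
relapse follows. `tumorextent` implements a simple, fully automated
alternative: classify each voxel against a patient- (or animal-) specific
*contralateral reference*, across six MRI parameters at once, and call a
voxel tumor when two or more parameters agree that it is abnormal.

The package is aimed at preclinical imaging groups who have co-registered
parameter maps plus sectioned histology, and at anyone who wants to
stress-test the method itself: a synthetic-phantom module generates whole
studies with known ground truth so that every stage of the pipeline can be
validated without any external data.

## The model

Let `μ_m`, `σ_m` be the mean and sample SD of modality `m` over the
contralateral region (all brain voxels beyond the midline on the tumor-free
side, excluding ventricles; pooled, not subdivided). A voxel with value
`x_m` is **abnormal** on a channel when it lies strictly beyond `k = 1` SD
in that channel's direction:

| channel       | rule                | physiology                      |
|---------------|---------------------|---------------------------------|
| `postgd_high` | `x > μ + kσ`        | contrast enhancement            |
| `t1_high`     | `x > μ + kσ`        | prolonged baseline T1 time      |
| `t2_low`      | `x < μ − kσ`        | shortened baseline T2 time      |
| `cbv_low`     | `x < μ − kσ`        | reduced cerebral blood volume   |
| `cbf_low`     | `x < μ − kσ`        | reduced cerebral blood flow     |
| `adc_high`    | `x > μ + kσ`        | elevated diffusion              |
| `adc_low`     | `x < μ − kσ`        | restricted diffusion            |

A voxel is **tumor** when at least `min_count = 2` channels are abnormal.
For a fixed pair of independent channels the chance that a normal Gaussian
voxel trips both is Φ(−1)² ≈ 0.025, keeping the per-pair false-positive
rate under α = 0.05.

Delineations are scored voxel-wise against a histologic gold standard
(tumor iff EpCAM staining > 0.001% or pimonidazole staining > 1%, averaged
from ~5 sections per 1 mm slice), over the voxels that have histologic
data. Alongside sensitivity, specificity, accuracy and Jaccard overlap
J = |A∩B|/|A∪B|, the **Youden index** Y = sensitivity + specificity − 1
summarises net benefit. Channel importance is measured by leave-one-out
ablation and by the accuracy gained as channels are added in every possible
order; the *occult rim* analysis (gold-standard tumor missed by observer
consensus) re-runs both with the consensus removed from the domain.

Also included: two automated single-modality comparators (a plain
mean + 2 SD threshold on post-Gd intensity and a "refined" morphology
pipeline), observer-consensus construction (≥ 2 of n observers), vessel
morphometry from collagen-IV masks (size filter, skeleton-based diameter /
length / density / area-fraction maps), and per-region histology summaries.

## Worked example

```python
import tumorextent as tx

phantom = tx.generate_phantom(tx.PhantomSpec(), seed=7)
results = tx.TumorDelineationModel.from_phantom(phantom).fit()
print(results.summary())
```

```
Multimodal tumor delineation
============================================================
grid: (64, 64, 10), voxel: 0.5 x 0.5 x 1.0 mm
threshold: mean ± 1 SD, tumor if ≥ 2 channels abnormal

Contralateral reference (mean, sample SD, n):
              mean       sd  n_voxels
modality
postgd_t1w   99.96    9.942     11212
t1_time      1.798   0.1212     11212
t2_time    0.04501 0.002997     11212
cbv          2.994   0.3996     11212
cbf          119.6    18.05     11212
adc         0.7494  0.07106     11212

Abnormal voxels per channel:
postgd_high    4178
t1_high        4168
t2_low         4090
cbv_low        4081
cbf_low        4070
adc_high       4127
adc_low        3624

Tumor volume: 1904.0 uL (7616 voxels)
```

The reference estimates recover the phantom's generating parameters
(e.g. CBF 119.6 ± 18.05 vs the true 120 ± 18 mL/100 g/min). The whole-brain
mask volume is large because, at ±1 SD, isolated noise voxels coincide on
two channels ~31% of the time; the method is meant to be read over the
histology-valid domain, where those coincidences are bounded and the tumor
dominates:

```python
epcam = tx.stack_to_volume(phantom.histology["epcam"])
pimo = tx.stack_to_volume(phantom.histology["pimonidazole"])
gold = tx.gold_standard_map(epcam, pimo)
valid = tx.coverage_union(epcam, pimo)

report = results.evaluate(gold, valid)
consensus = results.consensus_mask(phantom.observer_masks)
obs = tx.evaluate(consensus, gold, valid, phantom.geometry)
```

```
sensitivity=1.00 specificity=0.70 youden=0.70
multimodal volume=182.5 uL, gold-standard volume=126.2 uL
observer consensus: sensitivity=0.34 youden=0.34 volume=43.5 uL
```

On this phantom the multimodal rule finds every histologically confirmed
tumor voxel (including the rim the simulated observers never draw), its
volume is far closer to the gold standard than the observers' (182.5 vs
43.5 μL around a 126.2 μL truth), and its Youden index is twice theirs —
the qualitative behaviour the method is designed to deliver.

A thin CLI mirrors the library: `tumorextent make-phantom`,
`tumorextent delineate`, `tumorextent evaluate` (see `--help`).

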