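# sparseseg

Robust multi-modal 3D tumor-core segmentation when MRI sequences are
missing.

Clinical brain-tumor MRI stacks are often incomplete: the post-contrast
T1-weighted scan (T1c) is essentially always acquired, but one or more of
the secondary sequences (T1w, T2w, FLAIR) may be absent. A segmentation
network trained only on complete four-channel stacks degrades badly when a
channel it relies on is replaced by a zero-filled volume at inference.
`sparseseg` implements *sparsified training*: during training, each
secondary channel of every sampled patch stack is independently replaced by
zeros with probability *p* (default 0.2), after a missing-aware
normalization step, so that augmented-missing and originally-missing
channels are indistinguishable to the network. The model learns to extract
the missing sequence's information from the remaining channels.

The package contains, as importable library + thin CLI:

- a **dual-pathway patch-based 3D CNN** (DeepMedic-style): a
  normal-resolution pathway over a central crop and a subsampled pathway
  over the full window (mean-pooled by factor 3), valid 3×3×3 convolutions,
  1×1×1 "fully connected" layers and a two-class voxelwise classifier.
  The default preset maps a 57³ input window to a 9³ output patch through
  11 weighted layers; a `tiny` preset (27³ → 9³) trains in minutes on one
  CPU. Training minimizes a soft Dice loss with Adam under a stepped
  learning-rate schedule (0.001, halved every 5000 iterations up to 15 000
  and every 1500 after) and keeps the final-iteration weights.
  The network and its backpropagation are implemented in NumPy.
- **missing-aware normalization**: Nyúl-style percentile-landmark histogram
  standardization plus whitening to zero mean / unit variance over the
  brain mask — with zero-filled missing channels passing through bit-exactly
  unchanged, so a missing channel enters the network at the whitened mean of
  the available data.
- **evaluation metrics**: Dice `2·TP/(2·TP+FP+FN)`, sensitivity
  `TP/(TP+FN)`, and the undirected 95th-percentile Hausdorff distance
  (max of the two directed 95th percentiles over 6-connectivity boundary
  voxels, in mm, anisotropic spacing supported).
- an **experiment harness**: exhaustive simulation of all 2³ = 8 missing
  secondary-sequence patterns at inference, seed-matched model pairs,
  two-sided Wilcoxon signed rank tests on paired Dice scores (exact
  enumeration for n ≤ 25 without ties), and a single-family Bonferroni
  correction.
- a **synthetic phantom cohort generator**: seeded multi-channel 3D
  phantoms with an ellipsoidal brain, a deformed enhancing-rim + necrotic
  core tumor, cross-channel redundant appearance, smooth multiplicative
  bias fields, additive noise, and per-subject missing-sequence patterns,
  written as NIfTI files with a CSV manifest.

## Worked example

```python
from sparseseg import (PhantomConfig, generate_cohort_subjects,
                       fit_histogram_model, normalize_cohort,
                       NetConfig, TrainConfig, train,
                       MissingPattern, evaluate_model_under_patterns)

ph = PhantomConfig(seed=0)                      # 48^3, 1 mm, 4 channels
train_subjects = generate_cohort_subjects(ph, 8, force_complete=True)
test_subjects = generate_cohort_subjects(ph, 4, start_seed=100,
                                         force_complete=True)
hist = fit_histogram_model(train_subjects)
train_norm = normalize_cohort(train_subjects, hist)
test_norm = normalize_cohort(test_subjects, hist)

model, log = train(train_norm, NetConfig.tiny(),
                   TrainConfig.tiny(seed=1, iterations=200), sparsified=True)
table = evaluate_model_under_patterns(
    model, test_norm,
    patterns=[MissingPattern(frozenset()), MissingPattern(frozenset({"FLAIR"}))])
print(table.groupby("missing_pattern")[["dice", "sensitivity", "hd95"]].median())
```

prints (seed 0, one CPU):

```
                     dice  sensitivity      hd95
missing_pattern
FLAIR            0.916956     0.904447  1.258883
none             0.933447     0.979813  1.196751
```

i.e. the sparsified model's median test Dice barely moves when the FLAIR
analog is zeroed at inference (0.933 complete → 0.917), and the boundary
disagreement stays near 1.2 mm. A plain-trained twin collapses under the
same pattern (median Dice near 0 on most seeds, since a zeroed channel is
far outside its training distribution);
`examples/03_missing_pattern_study.py` runs that comparison with paired
statistics.

The same pipeline is available from the shell:

```bash
sparseseg synth --out-dir cohort --n-train 8 --n-val 2 --n-test 4 --seed 0
sparseseg train --manifest cohort/manifest.csv --model-out model --sparsified
sparseseg evaluate --manifest cohort/manifest.csv --model model --out metrics.csv
sparseseg run-experiment --seed 0 --out-dir report
```

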