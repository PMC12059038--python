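# slicemil

Semi-weakly supervised multi-instance learning for exam-level classification
of 3D medical image stacks.

## The problem

Exam-level labels ("this CT pulmonary angiogram contains an embolism") are
cheap — they can be pulled from radiology reports. Slice-level labels ("the
clot is visible on these axial slices") are expensive expert work. Between
the two extremes of *weak* supervision (exam labels only) and *strong*
supervision (every slice labeled) lies *semi-weak* supervision: all exam
labels plus an evenly spaced fraction `p` of each exam's slice labels, the
rest masked out of the loss. This package implements the full pipeline for
measuring how much slice-level annotation exam-level classification really
needs.

The model is a multi-instance sequence classifier: a per-slice CNN feature
extractor, batch normalization, three bidirectional LSTM layers aggregating
along the slice axis, per-slice sigmoid heads, and gated softmax attention
pooling (combined with slice-wise max pooling) feeding an exam-level
sigmoid head. The training objective is

    L = BCE(exam_prob, exam_label)
        + lambda * mean over visible slices of BCE(slice_prob_i, slice_label_i)

where the visible set at proportion `p` is `round_half_up(p * D)` indices
evenly spread over the exam's `D` slices. `p = 0` recovers the weak learner
and `p = 1` the strong learner.

Everything runs on CPU: the network layers (conv via im2col, LSTM,
attention, Adam) are built on a small numpy reverse-mode autodiff core that
ships with the package.

## What's in the box

| module | contents |
| --- | --- |
| `slicemil.synthetic` | phantom cohort generator (NIfTI + CSV I/O): ellipsoid "lungs", spherical central/peripheral lesions, exam/slice label consistency |
| `slicemil.preprocess` | lung-box VOI crop, HU windowing (700/100), trilinear standardization, 3-channel adjacent-slice stacking, augmentations |
| `slicemil.supervision` | label-consistency validation, even slice-label subsampling, loss masks, inverse-prevalence class weights |
| `slicemil.model` | backbone contract + tiny CNN default, BiLSTM-attention classifier, masked semi-weak loss |
| `slicemil.training` | weighted sampling, cosine-annealed Adam, early stopping, stratified k-fold CV |
| `slicemil.evaluation` | Mann-Whitney AUC, Youden threshold, confusion metrics, fast DeLong test + CIs, Wilson/exact binomial CIs, subtype subsets |
| `slicemil.experiment` | label-granularity sweep, threshold-transfer protocol, DeLong comparisons between proportions |
| `slicemil.autodiff`, `slicemil.nn` | the numpy autodiff core and layers |

## Worked example

```python
import numpy as np
from slicemil.evaluation import ConfusionCounts, confusion_metrics
from slicemil.supervision import class_weights, select_labeled_slices

# inverse-prevalence sampling weights for a 6958-exam training cohort
# with 2161 positives
w = class_weights(6958, 2161, 4797)
print(w.rounded(2))                     # (3.22, 1.45)

# evenly sampled slice labels: 200-slice exam at 27.5%
print(len(select_labeled_slices(200, 0.275)))   # 55

# diagnostic metrics from confusion counts (positive iff score >= threshold)
print(confusion_metrics(ConfusionCounts(tp=350, fn=88, tn=939, fp=67)))
# {'accuracy': 0.893, 'sensitivity': 0.799, 'specificity': 0.933,
#  'ppv': 0.839, 'npv': 0.914, 'f1': 0.819}
```

End-to-end on a phantom cohort:

```python
from slicemil.experiment import label_granularity_trend

aucs = label_granularity_trend(proportions=(0.0, 0.25, 1.0), seeds=(0, 1, 2))
# {0.0: [...], 0.25: [...], 1.0: [...]}  — held-out test AUC per seed at
# each supervision level; takes a few minutes per seed on one CPU
```

A CLI covers the same pipeline for shell use:

```bash
slicemil simulate --n-exams 60 --prevalence 0.3 --seed 7 --out cohort/
slicemil preprocess --in cohort/ --out processed/ --target-shape 16,48,48
slicemil train --data processed/ --proportion 0.25 --folds 2 --out run/
slicemil sweep --data processed/ --proportions 0,0.25,1.0 --out sweep/
```

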