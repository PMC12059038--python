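# Methods

## Supervision model

An exam is a stack of `D` axial slices with one binary exam label and `D`
binary slice labels, under the consistency rule *exam positive iff at least
one slice positive*. Exams violating the rule are excluded by
`supervision.validate_labels`, with the direction of the violation recorded
(`positive exam, no positive slices` / `negative exam, positive slices`);
we exclude rather than repair because the true location of the error is
unknowable from the labels alone.

Semi-weak supervision at proportion `p` keeps `n = round_half_up(p · D)`
slice labels visible and masks the rest from the loss. Visible indices are
`round_half_up(linspace(0, D−1, n))`: deterministic, endpoint-inclusive,
with consecutive gaps differing by at most one — the even spread a
radiologist would produce when asked to label a fixed fraction of an exam.
Rounding is half-up throughout; at `D = 200, p = 0.275` this yields 55
visible slices. The same mask is applied to negative exams even though
their slice labels are implied by the consistency rule, because the
annotation-cost scenario being modeled does not get those labels for free;
`reveal_negative_slices=True` switches to the optimistic variant.

## Model

Per-slice features come from a pluggable backbone; the default is a tiny
CNN (three stride-2 3×3 conv blocks, global average **and** max pooling
concatenated, linear projection). Max pooling is concatenated with average
pooling because the structures of interest occupy a few pixels; a pure
average pool dilutes them by the number of spatial cells. Features pass
through batch normalization, three bidirectional LSTM layers along the
slice axis (hidden 128 per direction at full scale, 32 in the desk-scale
configuration), a per-slice sigmoid head on the recurrent hidden states,
and gated tanh-scored softmax attention. The exam head reads the
attention-pooled state concatenated with the slice-wise max-pooled state.
The concatenation is a deliberate design choice: when the slice loss
dominates shared-trunk training, attention can stay diffuse for a long
time, and an exam head fed only the attention pool then sees a
near-uninformative average; the max-pool path keeps peak slice evidence
reachable regardless of the attention state.

The objective is

    L = BCE(exam) + λ · mean_{i: mask_i=1} BCE(slice_i)

with probabilities clipped to `[1e-7, 1 − 1e-7]` before the log. The slice
term averages over *visible* slices per exam (then over exams with at
least one visible slice), making its magnitude independent of `p` for
i.i.d. slice errors; with an all-zero mask it contributes neither value
nor gradient, so `p = 0` is exactly the weak learner. λ defaults to 1.

## Training

Class imbalance is handled by weighted random sampling with inverse
prevalence weights `w_c = n_total / n_c` (3.22 / 1.45 on a 6958-exam cohort
with 2161 positives), giving each epoch an expected 50/50 class mix. Adam
with a cosine-annealed learning rate
`lr(e) = lr_min + (lr_init − lr_min)(1 + cos(πe/T_max))/2`, batch size 16
(8 at desk scale), early stopping on validation exam AUC (patience 5 by
default; the monitored metric and patience are our choices), and
stratified k-fold CV with fold seed = master seed + fold index. All
stochastic components (init, sampler, augmentation, folds) draw from named
substreams of one master seed; two runs with the same seed produce
identical trajectories.

Training-time augmentation (horizontal flip, Gaussian noise of variance
0.004, optional rotation ≤ 10°, brightness/contrast ≤ 10%, blur) is
applied per exam with one geometric draw shared by all frames. At the
cohort sizes the phantom experiments use, fresh noise per epoch is the
main defense against the network memorizing per-exam noise signatures
instead of learning the lesion feature.

## Preprocessing

Fixed order: mask → tightest VOI crop → HU windowing → trilinear resize →
3-channel stacking. Windowing maps `[center − width/2, center + width/2]`
(default 700/100) linearly to `[0, 1]` with clipping. Resizing uses
align-corners trilinear interpolation (identity when shapes match); slice
labels follow the nearest source slice, which preserves at least one
positive output slice for any positive source. Adjacent-slice stacking
gives frame `i` the channels `(i−1, i, i+1)` with edge replication. The
full-scale target shape is (184, 256, 256); tests and the phantom
experiments use (16, 48, 48) so that a training run fits in seconds per
epoch on one CPU. In-plane resizing stretches to the target (no aspect
preservation).

## Phantom cohorts

The generator emulates the *label structure* of a CT pulmonary angiography
screening cohort: 30% positive exams; positives split 20/80 into central
(large, radius 6, central third of the in-plane mask extent) and
peripheral (small, radius 2, sphere centred 1–2 voxels of clearance from
the mask boundary) lesions; 1–3 lesions per positive exam; a slice is
positive iff ≥ 1 lesion voxel lies on it. The "lungs" are two axis-aligned
ellipsoids; HU values are soft tissue +40, lung −800, lesion +100, with
N(0, 20²) HU noise, so the default window renders lung black, background
mid-gray and lesions slightly brighter mid-gray. Peripheral lesion centres
require at least one lesion radius of interior clearance so that a labeled
lesion is never a one-voxel sliver clipped by the mask, which would leave
some positive slice labels with no visible evidence behind them. Each exam
draws from an RNG
substream keyed by (seed, exam index), so records are independent of
cohort size; cohorts are byte-identical across runs at a fixed seed.

What the phantoms do **not** model: vascular trees, contrast bolus
dynamics, breathing motion, scanner artifacts, inter-patient anatomical
variation (the mask is shared across exams). Passing the phantom
experiments therefore demonstrates that the pipeline's supervision
machinery behaves as designed — not clinical performance on real CTPA.

## Desk-scale label-granularity experiment

`experiment.label_granularity_trend` trains one model per (seed,
proportion) on 60-exam peripheral-lesion cohorts (32×64×64 voxels,
standardized to 16×48×48), split 50/20/30 into train/validation/test
stratified by exam label, 60 epochs of cosine-annealed Adam
(2e-3 → 1e-5), flip + noise augmentation, and reports the test exam AUC
per seed. Problem sizes were chosen so one training run takes well under
two minutes on a single CPU; at this scale single-split AUCs carry
sampling noise of roughly ±0.1, which is why trend conclusions use
seed-averaged margins rather than per-seed assertions.

## Evaluation protocol

Fold predictions are ensembled by per-exam arithmetic mean. The operating
threshold maximizes Youden's J = TPR − FPR over observed scores on a
designated tuning split (ties broken toward the smallest threshold,
favoring sensitivity) under the rule *positive iff score ≥ t*, and is then
applied frozen to test and external splits. AUC uses the Mann-Whitney
convention with its confidence interval from the fast (midrank) DeLong
variance; paired model comparisons use the DeLong test, with p = 1 by
convention for identical score vectors. Binomial metrics (accuracy,
sensitivity, specificity, PPV, NPV) get Wilson score intervals by default
(Clopper–Pearson via `method="exact"`); F1 is not a binomial proportion
and gets no interval. Reported fractions are rounded half-up to 3
decimals. Subtype reports evaluate all negatives plus central-only or
peripheral-only positives.

Numerical conventions worth knowing: `round_half_up(x) = floor(x + 0.5)`
with a 1e-9 guard against float representation just below a half;
degenerate confusion metrics (zero denominator) are `None`, not 0; the
DeLong variance falls back to p = 1 when either class has fewer than two
members.

## Known limitations

- The desk-scale cohorts are small enough that individual training runs
  are noisy; only seed-averaged comparisons are meaningful.
- The DeLong test is mildly liberal at n ≈ 60 (empirical size ≈ 0.055 at
  the 5% level), a known property of the asymptotic normal reference.
- The shared lung mask across phantom exams removes anatomical variation,
  making the task easier than real data in that one respect, while the
  tiny backbone and cohort sizes make it harder in others.
- Checkpoints store raw parameter arrays keyed by traversal order; they
  are not portable across architecture changes.
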