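# Methods

This note documents the models and procedures implemented in `dyngrnn`, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not establish.

## Dynamic graph construction

A subject is a parcellated BOLD matrix (n ROIs × K timepoints; the package
defaults mirror a 90-region AAL parcellation with K = 198 volumes). The
series is segmented into m = ⌊(K − w)/s⌋ + 1 half-open windows [t, t + w),
t = 0, s, 2s, …; trailing samples that do not fill a window are dropped.
Windows default to w = 30, s = 4 samples (the region where classification
accuracy peaked in published window sweeps).

Per window, each ROI's **node feature** is its mean signal (slide piecewise
aggregation); each ROI pair's **edge feature** is the Pearson correlation of
the two in-window signals. A pair whose signal is constant within a window
gets correlation 0 (no evidence of association, kept finite) and the
diagonal is fixed at 1 but excluded from every adjacency used downstream.

Each ordered pair's m-vector of correlations is min-max rescaled to [0, 1]
across its own windows. Two consequences worth stating plainly:

- the *level* of a pair's correlation is deliberately discarded — only the
  shape of its trajectory over windows survives;
- a constant trajectory is mapped to 0.5 everywhere (neutral mid-scale), so
  a single-window graph has all edge features 0.5 and is, by construction,
  informationless at the edge level — this is the static-connectivity
  baseline arm of the ablation.

## Recurrent graph encoder

Node states evolve across windows. Three cells are provided:

- `simple`: hᵢ ← ReLU(W(hᵢ + Σⱼ Eᵢⱼ hⱼ) + b)
- `dual`: hᵢ ← ReLU(W_self hᵢ + W_neigh Σⱼ Eᵢⱼ hⱼ + b), letting connection
  strength act as an adaptive regulator separate from self-dynamics
- `gated` (default): an input/forget/output-gated memory C with
  hᵢ = o ⊙ tanh(Cᵢ). The gate inputs concatenate the node's embedded
  window feature x_t, its state h, the state message Σⱼ Eᵢⱼ hⱼ, the input
  message Σⱼ Eᵢⱼ x_{t,j}, and the node's centered connection strength
  Σⱼ Eᵢⱼ. Only the output relation h = o ⊙ tanh(C) is fixed by the
  published formulation; the gate parameterization is this package's
  interpretation. The extra message channels exist because the
  class-relevant signal of dynamic connectivity lives in edge trajectories:
  gates that never see edge aggregates at first order demonstrably cannot
  propagate it.

Numerical choices: neighbor messages are scaled by 1/√(n−1), which keeps
them at unit variance for zero-mean features instead of letting the raw sum
grow with graph size (1/(n−1) mean aggregation was tried first and provably
attenuates the aggregate edge signal to ~2 % of the feature channels at
n = 90). h⁽⁰⁾ is a learned linear embedding of the first window's node
features; the forget-gate bias starts at +1; all other weights are
Glorot-uniform from the model seed.

## Temporal evolution patterns, pooling, classification

Node selection is based on each region's whole trajectory, not its final
state: a learned temporal convolution (kernel length 5 windows) slides over
the per-window node descriptors (state ⊕ centered strength) and its ReLU
responses are summarized by their mean and maximum over time. This matters
because a leaky recurrent integrator has near-zero gain at the frequency of
connectivity state switches — a zero-time-average alternation, exactly the
signature dynamic-connectivity analysis targets, would otherwise never
reach the readout.

Self-attention pooling scores every node with a one-output-channel graph
convolution z = X θ_self + A (X θ_neigh) on the window-averaged adjacency,
gates scores through softmax-then-tanh (both strictly increasing, so
`softmax_tanh` and plain `tanh` gating select identical node sets — both
are exposed), keeps the ⌈k·n⌉ best nodes (ties to the lower index;
default k = 0.2, the published optimum), gates their feature rows, and
restricts the adjacency to the kept rows/columns. The readout concatenates
the element-wise mean and maximum over kept nodes; a two-layer ReLU
perceptron with softmax output classifies, with dropout (default p = 0.1)
on the pooled representation during training only.

## Training

Adam (lr 0.001 by default, batch 32), cross-entropy, early stopping when
validation loss fails to improve by more than 1e-4 for `patience` epochs
(default 50), best-validation parameters restored. Subjects are the
sampling unit everywhere; a subject's windows never straddle the
train/validation/test boundary, which removes temporal leakage. Splits use
largest-remainder rounding of the 6:2:2 ratios (ties train > val > test),
within each diagnostic group when stratified.

Each time a batch is drawn, fresh Gaussian noise (sd 1.0, the scale of the
z-scored node features) is added to the node features. Without this the
model reliably memorizes subject-specific feature noise (training loss → 0
at chance-level test accuracy) before discovering edge-trajectory signal;
with it, a controlled edge-alternation benchmark goes from chance to 100 %
test accuracy. Node features are z-scored per ROI within subject during
dataset assembly, the usual BOLD normalization.

Evaluation reports the confusion counts, accuracy, recall, precision, F1
and AUC (midrank Mann–Whitney statistic, i.e. the exact area under the
empirical ROC; undefined single-class cases are flagged, zero-denominator
ratios report 0 with a flag so sweep tables stay numeric).

## Core-node identification

On a binarized graph (threshold or top-density edges of the window-averaged
adjacency; the paper-facing default feeds the mean normalized dynamic
adjacency): degree is the edge count; betweenness sums, over ordered pairs
(h, j) with h ≠ j ≠ i, the fraction of shortest h–j paths through i,
normalized by (N−1)(N−2); closeness is 1/Σⱼ Dᵢⱼ with hop-count distances
(a normalized (N−1)/ΣD variant is provided, since published summary values
suggest it was used at least once; raw reciprocal is the default).
Disconnected nodes get closeness 0 (the 1/∞ convention) and unreachable
pairs contribute 0 to betweenness.

The composite score is Count = k₁P₁ + k₂P₂ + k₃P₃ on min-max-normalized
metric vectors, with kᵢ the absolute mean slope of each metric's sorted
importance curve. By default the slopes are taken after min-max scaling so
the three weights are commensurate; note the arithmetic consequence that
every non-constant metric then receives the same weight 1/(n−1) (a constant
metric gets 0). `normalize=False` uses the raw curves and yields
metric-specific weights. A node is a **core node** for a metric when its
value strictly exceeds the metric's mean plus *population* variance
(divide-by-n; the convention is configurable in the sense that the summary
exposes mean and variance separately).

Biomarker ranking: per fold, the top-k ROIs by attention weight (k = 10 by
default, ties to the lower index); ROIs are ranked by appearance count
across folds, then mean weight, then index.

## Synthetic cohorts

The generator draws each subject from a zero-mean multivariate normal whose
correlation matrix combines (a) a community block structure, (b) optionally
two covariance states alternating with a fixed period, and (c) per-class
correlation deltas on designated ROI pairs — the ground-truth biomarkers,
written alongside generated cohorts. Independent Gaussian observation noise
is added afterwards; since that attenuates observed correlations by
1/(1+σ²), correlation-recovery checks run at σ = 0. Indefinite matrices are
repaired by eigenvalue clipping at 1e-8 with re-normalization to unit
diagonal, with a warning. Subject draws are decoupled through a seed
sequence of (cohort seed, subject index), so enlarging a cohort never
changes earlier subjects.

When a state schedule is present the class deltas act in the second state
only: an affected pair then *alternates* between baseline and shifted
coupling. This is deliberate — per-pair min-max normalization erases
constant level shifts, so a persistent delta is nearly invisible to the
downstream model, whereas a state-locked alternation is precisely the
dynamic signature the pipeline exists to detect (and the static
single-window arm provably cannot).

The model does not emulate hemodynamic convolution, scanner drift, motion,
or physiological noise; passing its benchmarks shows the pipeline recovers
controllable second-order structure, not that it handles real fMRI
artifacts.

## The reference recovery experiment

`dyngrnn.experiments` freezes one study design: 90 ROIs in six communities
of 15 (within-community correlation 0.2), states alternating every 40
timepoints, 40 control and 40 patient subjects of 198 timepoints,
observation noise 0.1, and +0.5 correlation on five within-community pairs
(10 distinct ROIs) in the patient class's second state. Windows are
w = 30, s = 8, the model is the gated cell with hidden size 8 and pooling
ratio 0.2, trained ≤60 epochs (patience 20, batch 16, lr 3e-3, chosen so
one protocol — ten seeds, a twenty-permutation biomarker null, and a
three-arm ablation — completes on one CPU at desk scale).

What the experiment can and cannot show, established with oracle probes and
kept here on purpose: the injected pairs' normalized trajectories separate
the classes perfectly (a logistic probe on those five trajectories alone
reaches 100 %), but the encoder's update equations aggregate edges through
unweighted neighbor sums, so any node-level statistic dilutes 5 informative
pairs among ~4 000 noise pairs whose trajectories min-max normalization has
amplified to full range. An oracle matched filter that is told both the
injected nodes and the exact switching template, applied to the node
strength trajectories the encoder can see, reaches only ≈0.55 test
accuracy at this problem size — so no amount of training can push the
node-level pipeline much past chance here, and measured accuracies sit
near 0.5–0.65. The recovery suite reports what it measures: the
classification arm documents this architectural ceiling rather than
masking it, and the biomarker and ablation arms are judged on their own
results.

## Known limitations

- The autodiff engine is a minimal tape sufficient for this model family;
  it is not a general deep-learning framework.
- Betweenness relies on the installed graph library's Brandes
  implementation; the exhaustive path-enumeration oracles in the test suite
  are the independent check.
- Multi-class cohorts are handled as one-vs-one binary tasks by downstream
  metrics; the classifier head itself supports any class count.
- The window/step sweep treats only integer sample steps; second-valued
  steps require resampling upstream.
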