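# dyngrnn

Dynamic functional brain-network analysis for parcellated resting-state
fMRI: build per-subject dynamic graphs from ROI BOLD time series, encode
them with an edge-weighted recurrent graph network, select key regions with
self-attention Top-K pooling, classify subjects, and identify hub/biomarker
regions with graph-centrality scores.

**Who it is for.** Researchers studying disorders such as mild cognitive
impairment and Alzheimer's disease from rs-fMRI, where the question is not
only *whether* groups can be separated but *which regions and connections*
carry the difference — and methods developers who need a fully synthetic,
ground-truth-controlled sandbox for dynamic-connectivity classifiers.

## The pipeline

Given a subject's ROI × time BOLD matrix (e.g., 90 AAL regions × 198
volumes), a sliding window of width *w* and step *s* cuts the series into

&nbsp;&nbsp;&nbsp;&nbsp;*m* = ⌊(*K* − *w*)/*s*⌋ + 1

slices. Node features are the per-window signal means (slide piecewise
aggregation, SPA); edge features are the windowed Pearson correlations
r<sub>ij</sub>[k], min-max normalized to [0, 1] along each pair's own
window axis. The recurrent encoder updates node states across windows —
e.g. the dual-weight cell

&nbsp;&nbsp;&nbsp;&nbsp;h<sub>i</sub><sup>(t)</sup> = ReLU(W<sub>self</sub> h<sub>i</sub><sup>(t−1)</sup> + W<sub>neigh</sub> Σ<sub>j</sub> E<sub>ij</sub><sup>(t−1)</sup> h<sub>j</sub><sup>(t−1)</sup> + b)

or a gated cell with memory, h = o ⊙ tanh(C). A learned temporal
convolution turns each node's state trajectory into an evolution-pattern
vector; a one-channel graph convolution scores nodes, softmax/tanh gating
and Top-⌈k·n⌉ selection pool the graph; a two-layer perceptron classifies.
Core nodes are identified from degree, betweenness and closeness
centrality and their slope-weighted composite Count = k₁P₁ + k₂P₂ + k₃P₃,
with a node called *core* when its importance strictly exceeds the metric's
mean plus variance.

See `docs/methods.md` for assumptions, parameter defaults and numerical
conventions.

## Worked example

Why sliding windows at all? `examples/03_dynamic_vs_static.py` generates a
two-ROI subject whose coupling alternates between r = 0.1 and r = 0.8 every
100 timepoints and prints:

```
true state correlations: 0.10 (state A) and 0.80 (state B)
static whole-series PCC: 0.440  <- sits between the states
per-window PCC (windows aligned with states):
  window  0 [   0: 100) state A: r = 0.084
  window  1 [ 100: 200) state B: r = 0.808
  window  2 [ 200: 300) state A: r = -0.036
  window  3 [ 300: 400) state B: r = 0.734
  ...
```

The whole-series (static) correlation, 0.44, blurs the two regimes; the
per-window trajectory recovers both — this is the information the dynamic
pipeline feeds to the recurrent encoder.

Core-node scoring (`examples/02_core_nodes.py`, a 30-node graph with two
planted hubs, binarized at 20 % density):

```
metric            mean  variance  threshold  core
degree           5.800    40.293     46.093     0
betweenness      0.029     0.010      0.039     2
closeness        0.020     0.000      0.020     2
count            0.011     0.001      0.012     2

core nodes by composite score: ['R00', 'R01']
```

Each metric's core threshold is its mean plus variance; the two planted
hubs are recovered by betweenness, closeness and the composite score
(degree's variance exceeds its range here, a known property of this
thresholding rule on heavy-tailed degree distributions).

The remaining examples cover graph construction
(`01_build_dynamic_graph.py`), end-to-end training
(`04_train_and_classify.py`) and biomarker frequency ranking across folds
(`05_biomarker_ranking.py`). A thin CLI mirrors the library:

```bash
dyngrnn synth --spec cohort.yaml --out data/
dyngrnn split --manifest data/manifest.tsv --ratios 0.6,0.2,0.2 --seed 1 --out splits/
dyngrnn build-network --in data/HC_0000.tsv --width 30 --step 4 --out graph.npz
dyngrnn centrality --in data/HC_0000.tsv --binarize density:0.2 --out report.tsv
dyngrnn train --train-manifest splits/train.tsv --val-manifest splits/val.tsv --out model.npz
dyngrnn evaluate --checkpoint model.npz --test-manifest splits/test.tsv
dyngrnn sweep-window --manifest data/manifest.tsv --widths 10,30,50,70 --steps 4,8 --out grid.tsv
```

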