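"""End-to-end: synthetic cohort -> dynamic graphs -> train -> evaluate.

A small two-class cohort (32 subjects, 10 ROIs) whose patient class carries
a dynamic connectivity effect on one ROI pair; trains the recurrent
graph classifier with attention pooling and prints test metrics.
Sized to finish in well under a minute.
"""

import numpy as np

from dyngrnn import (
    BlockStructure,
    ModelConfig,
    SlidingWindowConfig,
    SyntheticSpec,
    TrainConfig,
    generate_cohort_arrays,
    run_split_experiment,
)

spec = SyntheticSpec(
    n_rois=10, n_timepoints=160,
    n_subjects_per_class={"control": 16, "patient": 16},
    block_structure=BlockStructure.even(10, 2, within=0.2),
    state_period=40,
    class_effects={"patient": [(0, 3, 0.6)]},
    noise_sd=0.1, seed=1,
)
subjects = generate_cohort_arrays(spec)

result = run_split_experiment(
    subjects,
    SlidingWindowConfig(width=30, step=10),
    ModelConfig(hidden_dim=8, cell_variant="gated", pooling_ratio=0.4,
                dropout_p=0.1, seed=0),
    TrainConfig(batch_size=8, learning_rate=3e-3, max_epochs=80,
                patience=30, seed=0),
    split_seed=0, ratios=(0.5, 0.25, 0.25),
)

m = result["metrics"]
print(f"epochs run: {len(result['history'])}")
print(f"test accuracy : {m.accuracy:.3f}")
print(f"test AUC      : {m.auc:.3f}" if m.auc is not None else "AUC undefined")
print(f"recall {m.recall:.3f} | precision {m.precision:.3f} | F1 {m.f1:.3f}")
top = np.argsort(-result["node_weights"])[:3]
print("highest-attention ROIs on the test set:", [f"ROI_{i+1:03d}" for i in top])
print("The ground-truth effect sits on the pair (ROI_001, ROI_004). An AUC "
      "above 0.5 means the scorer ranks patients above controls; whether "
      "attention concentrates on the affected ROIs is exactly what the "
      "biomarker analysis (example 05) quantifies across folds.")
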