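"""Why sliding windows: state switching visible to dFC, blurred by sFC.

Generates a two-ROI subject whose coupling alternates between 0.1 and 0.8
every 100 timepoints, then compares the whole-series correlation (static
functional connectivity) with per-window correlations (dynamic FC).
"""

import numpy as np

from dyngrnn import (
    BlockStructure,
    SlidingWindowConfig,
    SyntheticSpec,
    generate_subject,
    windowed_pcc,
)

spec = SyntheticSpec(
    n_rois=2, n_timepoints=1200,
    n_subjects_per_class={"P": 1},
    block_structure=BlockStructure.even(2, 1, within=0.1),
    state_period=100,
    class_effects={"P": [(0, 1, 0.7)]},  # second state: 0.1 + 0.7 = 0.8
    noise_sd=0.0, seed=5,
)
ts = generate_subject(spec, "P", 0)

static = np.corrcoef(ts.data)[0, 1]
pcc = windowed_pcc(ts, SlidingWindowConfig(width=100, step=100))
traj = pcc[0, 1, :]

print(f"true state correlations: 0.10 (state A) and 0.80 (state B)")
print(f"static whole-series PCC: {static:.3f}  <- sits between the states")
print("per-window PCC (windows aligned with states):")
for k, r in enumerate(traj):
    print(f"  window {k:2d} [{100*k:4d}:{100*(k+1):4d}) state {'A' if k % 2 == 0 else 'B'}: r = {r:.3f}")
print("The window-level trajectory recovers both states; the static value "
      "blurs them — the information the dynamic pipeline is built to use.")
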