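"""Simulate a raw detector movie and detect single-electron clusters.

Generates a short synthetic pre-counting movie with the 120-kV detector
preset, finds the electron clusters, and reports the size-class mix and
how well detection recovered the known ground-truth events.
"""

import numpy as np

from lowvoltcount import DetectorModel, count_stack, generate_frame_stack, \
    position_error_stats
from lowvoltcount.cluster_detect import detect_stack
from lowvoltcount.synth_frames import PRESET_MODELS
from dataclasses import replace

model = replace(PRESET_MODELS["120kv"], dims=(192, 192))
stack, truth = generate_frame_stack(model, dose_rate=0.01, n_frames=20,
                                    seed=42)
print(f"simulated {stack.n_frames} frames, {truth.n_events} true electrons")

clusters = detect_stack(stack)
sizes = np.array([c.size for c in clusters])
print(f"detected {len(clusters)} clusters, mean size {sizes.mean():.2f} px")
for name, lo, hi in (("small", 1, 2), ("medium", 3, 4), ("large", 5, 999)):
    frac = np.mean((sizes >= lo) & (sizes <= hi))
    print(f"  {name:6s} ({lo}-{hi if hi < 999 else '+'} px): {frac:.1%}")

# count with the mass-centre filter and score against ground truth
_, events = count_stack(stack, "MCF", sr_factor=1)
stats = position_error_stats(events, truth)
print(f"MCF localization: RMSE {stats.rmse:.2f} px, "
      f"match rate {stats.match_rate:.1%}")
print("(RMSE well under a pixel: counting recovers sub-pixel positions; "
      "unmatched events are border or coincident arrivals)")
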