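"""Chemotaxis statistics for a simulated 3D-invasion cohort.

Simulates biased random walks toward a +y chemoattractant gradient, applies
the 3-timepoint track filter, and summarizes speed, straightness and the
parallel forward-motion index per condition.
"""

import pandas as pd

from vsmcquant import synthetic as syn
from vsmcquant import tracks as trk

conditions = {
    "control": syn.WalkModel(n_tracks=200, n_steps=72, step_sd=0.5, seed=1),
    "sEV": syn.WalkModel(
        n_tracks=200, n_steps=72, step_sd=0.5, drift=(0.0, 0.3), seed=2
    ),
}

metrics = []
for name, model in conditions.items():
    table = trk.filter_tracks_3d(syn.simulate_tracks(model))
    m = trk.track_metrics(table).assign(condition=name)
    metrics.append(m)
summary = trk.group_summary(pd.concat(metrics, ignore_index=True))

cols = ["condition", "n_tracks", "speed_mean", "straightness_mean",
        "parallel_fmi_mean", "parallel_fmi_sd"]
print(summary[cols].to_string(index=False, float_format=lambda v: f"{v:.4f}"))
# FMI near 0 = undirected migration; positive FMI = net movement toward the
# gradient. The drifted ("sEV") cohort shows directed invasion.

eligible = trk.proximity_exclusion([(0.0, 0.0), (30.0, 0.0), (100.0, 100.0)])
print(f"cells eligible for tracking (35 um exclusion): {list(eligible)}")
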