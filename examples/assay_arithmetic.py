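"""Closed-form assay computations: 2^-ddCt, bead capture, densitometry."""

import pandas as pd

from vsmcquant import omics

# qPCR: target Ct 25 in plaque vs 23 in intact tissue, housekeeping at 20
rows = []
for sample, group, target_ct in [("s1", "plaque", 25.0), ("s2", "intact", 23.0)]:
    rows.append((sample, "CD63", target_ct, group))
    rows += [(sample, hk, 20.0, group) for hk in omics.DEFAULT_HOUSEKEEPING]
ct = pd.DataFrame(rows, columns=["sample", "gene", "ct", "group"])
rel = omics.ddct(ct, target="CD63", group="plaque", calibrator="intact")
print(f"CD63 relative expression (2^-ddCt): {rel:.2f}")
# 0.25 = four-fold lower transcript level in plaque than intact tissue.

fold = omics.bead_fold_change(
    treatment=(1000.0, 50.0, 1e4), control=(500.0, 25.0, 1e4)
)
print(f"sEV secretion fold change (CD63 beads): {fold:.1f}")

wb = omics.densitometry_ratio(
    band_plaque=200.0, loading_plaque=100.0, band_intact=50.0, loading_intact=100.0
)
print(f"western-blot fold change (GAPDH-normalised): {wb:.1f}")
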