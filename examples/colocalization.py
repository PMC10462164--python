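"""Thresholded colocalization on a planted co-occupancy pair.

Builds a two-channel image where 30% of channel-1 pixels also carry
channel-2 signal, then computes the thresholded Manders split coefficients,
percent volume colocalised, and Pearson's r excluding zero-zero pixels.
"""

import numpy as np

from vsmcquant import coloc
from vsmcquant import synthetic as syn

ch1, ch2 = syn.make_cooccupancy_pair(0.30, shape=(400, 400), seed=4)
res = coloc.coloc_report(ch1, ch2, thresholds=(1.0, 1.0))

print(f"tM1 (ch1 signal co-occurring with ch2): {res.tM1:.3f}  (planted 0.30)")
print(f"tM2 (ch2 signal co-occurring with ch1): {res.tM2:.3f}")
print(f"percent volume ch1: {res.percent_volume_ch1:.1f}%")
print(f"Pearson r (zero-zero excluded): {res.pearson_above_threshold:.3f}")
# tM1 recovers the planted overlap fraction; tM2 differs because channel 2
# also has its own non-overlapping population.

# round-structure prefilter: keep disk-like objects, drop elongated ones
rows, cols = np.mgrid[0:120, 0:120]
mask = np.zeros((120, 120), dtype=bool)
for r, c in [(30, 30), (30, 90), (90, 30)]:
    mask |= (rows - r) ** 2 + (cols - c) ** 2 <= 8**2
mask[60:62, 20:100] = True  # elongated bar
kept, labels = coloc.round_structure_filter(mask)
print(f"round structures kept: {len(labels)} of 4 objects (the bar is dropped)")
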