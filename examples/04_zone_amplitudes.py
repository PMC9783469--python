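"""Arterial-distance zone analysis of pulsation amplitude.

Builds waveforms for gray-matter regions at four distance levels from an
arterial input (amplitude falling with distance), aggregates them per zone
and checks that the modulation amplitude decreases monotonically along the
arterial tree.
"""

import numpy as np
import pandas as pd

import brainbeat as bb
from brainbeat.roi import ZoneTable, zone_amplitudes_frame

rng = np.random.default_rng(0)
grid = bb.cycle_fraction_grid()

rows, labels, table_rows = [], [], []
for level, amp in enumerate([1.2, 0.9, 0.6, 0.4], start=1):
    table_rows.append((level, f"mca_level{level}", "MCA", level))
    for _ in range(40):
        w = amp * bb.waveform_template("artery", bb.TemplateParams(-0.15, 1.0, -1))(grid)
        rows.append(w + rng.normal(0, 0.05, grid.size))
        labels.append(level)

table = ZoneTable(pd.DataFrame(
    table_rows, columns=["label", "region_name", "artery", "distance_level"]
))
zones = bb.aggregate_zones(np.array(rows), np.array(labels), table)
print(zone_amplitudes_frame(zones).to_string(index=False))

report = bb.amplitude_gradient_test(zones)
print(f"\nMCA amplitudes non-increasing with distance: "
      f"{report['MCA']['non_increasing']}")
print()
print("Modulation amplitude (max - min of the zone-mean waveform, percent)")
print("falls along the arterial branch: regions closest to the arterial input")
print("pulse hardest, mirroring the distance-graded pulsatility in gray matter.")
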