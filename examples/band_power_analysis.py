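"""Rhythm-band power analysis of the two synthetic treatment-response classes.

Simulates a handful of windows per class and tabulates the average power
in the delta/theta/alpha/beta bands.  The treatment-resistant class is
generated with globally elevated band amplitudes, so every band should
show higher power, mirroring the spectral contrast that motivates using
frequency information as attention.
"""

import numpy as np
import pandas as pd

from gfacnn import SimConfig, band_power_table, simulate_dataset

N = 20
ds = simulate_dataset(N, N, SimConfig(), seed=0)

tables = {"responsive": [], "resistant": []}
for seg in ds.segments:
    tables[seg.label].append(band_power_table(seg))

rows = {}
for label, tabs in tables.items():
    # mean over windows and channels; powers scale with amplitude^2
    rows[label] = pd.concat(tabs).groupby(level=0).mean().mean(axis=0)
summary = pd.DataFrame(rows)
summary["resistant/responsive"] = summary["resistant"] / summary["responsive"]

print(f"mean band power over {N} windows per class (uV^2 per window)")
print(summary.round(1))
print()
print("The ratio column shows the resistant class's uniform power"
      " elevation (the generator's 1.6x amplitude gain squared ~ 2.56,"
      " diluted by the shared 1/f background).")
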