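"""From a rendered confocal stack to normalized embryo measurements.

Renders two-channel Z-stacks of Gaussian nuclear blobs (32 primary + 8
secondary cells per embryo) with per-embryo efficiency baked into both
channels, then runs the actual imaging pipeline: sum projection, polygon
ROI means, ratio, and per-replicate wildtype normalization.  The recovered
construct strength matches what was rendered.
"""

import numpy as np
import pandas as pd

from cisquant import (
    RenderCell,
    measure_embryo,
    normalize_experiment,
    render_stack,
    roi_mean,
    sum_project,
)

rng = np.random.default_rng(3)
rows = []
for construct, strength in (("WT", 1.0), ("MUT", 0.4)):
    for e in range(5):
        eff = float(rng.lognormal(0, 1))
        cells = []
        for i in range(40):
            lineage = "primary" if i < 32 else "secondary"
            x = 6 + 2.2 * i
            cells.append(
                RenderCell(
                    x=x, y=24 + 4 * np.sin(i / 4), z=4,
                    reporter=strength * 500 * eff * float(rng.lognormal(0, 0.3)),
                    control=700 * eff * float(rng.lognormal(0, 0.3)),
                    lineage=lineage,
                )
            )
        stack, rois, _ = render_stack(cells, shape=(8, 56, 104), sigma=0.9)
        m = measure_embryo(stack, rois, f"{construct}_{e}", "rep1", construct)
        rows.append(vars(m))

table = pd.DataFrame(rows)
norm = normalize_experiment(table, "WT")
print(norm.round(3).to_string(index=False))
print("\nmean normalized ratio by construct:")
print(norm.groupby("construct_id")["normalized_ratio"].mean().round(3))
print("\nThe MUT construct was rendered at 0.4x wildtype reporter output;")
print("sum projection conserves blob mass, the ROI mean divides out area,")
print("and the reporter/control ratio removes the per-embryo efficiency,")
print("so the normalized mean recovers ~0.4 despite >5-fold efficiency spread.")
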