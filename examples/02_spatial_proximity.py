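"""Test whether macrophages are direct neighbors of injured epithelium.

Simulates five segmented-cell sections (~20,000 cells each, 2 x 2 mm) in
which macrophages co-localize with the "PT Injury 2" state at a planted
direct-neighbor ratio of 2, computes co-occurrence curves on the 5-50 um
grid, and runs the one-sample t-test of the per-sample 25-um ratios
against 1 with BH correction.
"""

import numpy as np

from graftstates import cooccurrence_curve, direct_neighbor_test
from graftstates.simulate import default_config, simulate_spatial_sample

config = default_config(seed=1)
samples = [
    simulate_spatial_sample(config, f"section{i + 1}")[0] for i in range(5)
]

curve = cooccurrence_curve(
    samples[0], "PT Injury 2", "Macrophage", np.arange(5.0, 55.0, 5.0)
)
print("co-occurrence ratio vs distance (section1):")
for d, r in zip(curve.grid, curve.ratio):
    print(f"  <= {d:4.0f} um: {r:.2f}")
# the ratio decays toward 1 with distance: enrichment is local to the
# planted 25-um niches

result = direct_neighbor_test(
    samples,
    pairs=[("PT Injury 2", "Macrophage"), ("PT Healthy", "Macrophage")],
    threshold=25.0,
)
print("\ndirect-neighbor test (<= 25 um), allogeneic sections:")
print(result[["anchor", "query", "n_samples", "mean_ratio", "t", "p",
              "padj", "direction"]].round(4).to_string(index=False))
# the injured state shows ~2x enrichment; healthy tubule sits at ratio 1
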