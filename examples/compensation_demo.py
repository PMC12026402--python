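"""Estimate a spillover matrix from single-stain controls and apply it.

Fluorophore signal bleeding into neighbouring channels is estimated by
zero-intercept linear regression on single-stained control events, then
removed by right-multiplying each event's intensity vector with the
inverse spillover matrix.
"""

import numpy as np

from mkflow import apply_compensation, estimate_spillover
from mkflow.synthgen import generate_compensation_controls

markers = ["cd41", "cd45", "dump", "dna", "viability"]
true_spill = np.eye(5)
true_spill[0, 2] = 0.20          # 20% of CD41 signal leaks into the dump channel

controls = generate_compensation_controls(markers, true_spill,
                                          n_events=500, seed=3, noise="poisson")
estimated = estimate_spillover(controls)
print(f"true CD41→dump spillover:      0.200")
print(f"estimated from 500 events:     {estimated.matrix[0, 2]:.4f}")

compensated = apply_compensation(controls["cd41"], estimated)
leak_before = controls["cd41"]["intensity_dump"].median()
leak_after = compensated["intensity_dump"].median()
print(f"median dump-channel intensity of CD41 controls: "
      f"{leak_before:,.0f} → {leak_after:,.0f} after compensation")
print("\nAfter compensation the off-target channel of a single-stained "
      "control is consistent with zero — the leak has been removed.")
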