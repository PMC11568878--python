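"""Generate synthetic windows and quantify the planted signal.

Sweeps motif fidelity from the null (0.25, indistinguishable from
background) to exact (1.0) and prints the per-position class divergence
at the motif, showing what the classifier is asked to learn.
"""

import numpy as np

from nmsitekit import SyntheticSpec, generate, signal_check
from nmsitekit.windows import WINDOW_FLANK

for fidelity in (0.25, 0.5, 0.75, 1.0):
    spec = SyntheticSpec(n_pos=300, n_neg=300, motif_fidelity=fidelity, seed=7)
    windows = generate(spec)
    report = signal_check(windows, spec)
    start = WINDOW_FLANK + spec.motif_offset
    motif_div = report.divergence[start : start + len(spec.motif)].mean()
    print(
        f"fidelity {fidelity:.2f}: mean divergence at motif positions "
        f"{motif_div:.3f}, flagged positions {list(report.flagged_positions)}"
    )
print("Divergence is the total-variation distance between positive and negative")
print("base frequencies: ~0 at the null, rising monotonically to ~0.75 for the")
print("exact motif; flagged positions recover the planted offsets -3..+2.")
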