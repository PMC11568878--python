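"""Encode one 41-nt window into its three feature channels.

Builds a window around a candidate site, folds it with the builtin
base-pair-maximization backend, and prints the shapes plus a few
interpretable slices of each encoding.
"""

import numpy as np

from nmsitekit import extract_window, encode_window, z_curve_invert

sequence = "AUGGCUAGGACUGCCAUUGGACUGAAGCCAGUCCAAUGGCAGUCCUAGCCAU"
window = extract_window(sequence, position=22, seq_id="demo", label=1)
print(f"window  : {window.sequence}")
print(f"center  : {window.center_base} (position 21 of 41)")

bundle = encode_window(window)
print(f"one-hot : {bundle.one_hot.shape}, row 21 = {bundle.one_hot[20].tolist()}")
print(f"z-curve : {bundle.z_curve.shape}, final row (x,y,z) = {bundle.z_curve[-1].tolist()}")
counts = z_curve_invert(bundle.z_curve)[-1]
print(f"          inverts to base counts A,C,G,U = {counts.tolist()}")
pairs = int(bundle.pairing.sum()) // 2
print(f"pairing : {bundle.pairing.shape}, {pairs} base pairs in the folded window")
print("The one-hot row marks the center base; the final Z-curve row summarizes")
print("window composition (and inverts exactly); the pairing matrix is the")
print("secondary-structure channel the 2D branch of the model consumes.")
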