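"""Fold a hairpin-forming sequence with both structure backends.

The builtin Nussinov backend maximizes nested base pairs and is fully
deterministic; the ViennaRNA backend (used when RNAfold is installed)
returns the thermodynamic minimum-free-energy structure.
"""

import shutil

from nmsitekit import FoldConfig, fold, parse_dotbracket

seq = "GGGAGCUUCGGCUCCCAAAGGGAGCUUCGGCUCCCAAAGGG"  # two stable stems
db = fold(seq, FoldConfig(backend="builtin"))
print(f"sequence: {seq}")
print(f"builtin : {db}  ({len(parse_dotbracket(db))} pairs, pair-count maximum)")

if shutil.which("RNAfold"):
    db_v = fold(seq, FoldConfig(backend="vienna"))
    print(f"vienna  : {db_v}  ({len(parse_dotbracket(db_v))} pairs, MFE structure)")
else:
    print("vienna  : RNAfold not on PATH; skipping the thermodynamic backend")
print("Nussinov often pairs more bases than the MFE structure — it optimizes")
print("count, not energy — which is why it serves as the exactly-testable default.")
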