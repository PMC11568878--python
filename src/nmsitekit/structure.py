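"""RNA secondary structure: folding and dot-bracket parsing.

Two folding backends are provided behind one ``fold`` entry point:

* ``builtin`` — Nussinov base-pair maximization with a minimum-loop
  constraint and a deterministic traceback. Exactly testable and free of
  external dependencies; the default.
* ``vienna`` — minimum-free-energy folding through the ViennaRNA
  ``RNAfold`` executable when it is installed. Recommended for production
  use on real transcripts, since thermodynamic structures are closer to
  physiological folding than pair-count maximization.

Both emit nesting-only dot-bracket strings (no pseudoknots).
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field

import numpy as np

from nmsitekit.errors import (
    BackendUnavailableError,
    IllegalStructureCharacterError,
    UnbalancedStructureError,
)

__all__ = [
    "DEFAULT_ALLOWED_PAIRS",
    "FoldConfig",
    "parse_dotbracket",
    "nussinov_fold",
    "fold",
    "fold_windows",
    "write_structure_db",
    "read_structure_db",
]

#: Watson-Crick plus GU wobble.
DEFAULT_ALLOWED_PAIRS = frozenset({"AU", "UA", "GC", "CG", "GU", "UG"})


@dataclass(frozen=True)
class FoldConfig:
    """Folding options.

    min_loop is the minimum number of unpaired bases enclosed by a pair:
    positions i < j may pair only when j - i > min_loop. The default of 3
    is the standard hairpin-loop constraint.
    """

    backend: str = "builtin"
    min_loop: int = 3
    allowed_pairs: frozenset[str] = field(default=DEFAULT_ALLOWED_PAIRS)

    def __post_init__(self):
        if self.min_loop < 0:
            raise ValueError("min_loop must be >= 0")
        if self.backend not in ("builtin", "vienna", "external"):
            raise ValueError(f"unknown backend {self.backend!r}")


def parse_dotbracket(text: str) -> list[tuple[int, int]]:
    """Return the matched base pairs of a dot-bracket string.

    Pairs are 1-based (i, j) with i < j, emitted in stack-closure order
    (innermost pairs first among nested ones).
    """
    pairs: list[tuple[int, int]] = []
    stack: list[int] = []
    for idx, ch in enumerate(text, start=1):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise UnbalancedStructureError(f"unbalanced structure: surplus ')' at position {idx}")
            pairs.append((stack.pop(), idx))
        elif ch != ".":
            raise IllegalStructureCharacterError(f"illegal character {ch!r} at position {idx}")
    if stack:
        raise UnbalancedStructureError(f"unbalanced structure: {len(stack)} unmatched '('")
    return pairs


def _pairable(sequence: str, allowed: frozenset[str]) -> np.ndarray:
    """Boolean LxL matrix of which residue pairs are allowed (N never pairs)."""
    n = len(sequence)
    ok = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            ok[i, j] = sequence[i] + sequence[j] in allowed
    return ok


def nussinov_fold(sequence: str, config: FoldConfig | None = None) -> str:
    """Maximize the number of nested base pairs; return dot-bracket.

    Dynamic program over subsequence spans with traceback tie-breaking:
    leave position j unpaired when that attains the optimum, otherwise
    pair j with the smallest admissible partner i. This makes the output
    a deterministic function of the sequence alone.
    """
    cfg = config or FoldConfig()
    seq = sequence.upper().replace("T", "U")
    n = len(seq)
    if n == 0:
        return ""
    can_pair = _pairable(seq, cfg.allowed_pairs)
    ml = cfg.min_loop

    # dp[i, j] = max pairs in seq[i..j], 0-based inclusive
    dp = np.zeros((n + 1, n + 1), dtype=np.int32)
    for span in range(ml + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i, j - 1]  # j unpaired
            # j paired with some k in [i, j-ml-1]
            ks = np.nonzero(can_pair[i : j - ml, j])[0]
            if ks.size:
                ks = ks + i
                cand = np.where(ks > i, dp[i, np.maximum(ks - 1, 0)], 0) + dp[ks + 1, j - 1] + 1
                m = int(cand.max())
                if m > best:
                    best = m
            dp[i, j] = best

    struct = ["."] * n

    def traceback(i: int, j: int) -> None:
        while i < j:
            if dp[i, j] == dp[i, j - 1]:  # prefer unpaired j
                j -= 1
                continue
            target = dp[i, j]
            for k in range(i, j - ml):  # smallest partner first
                if not can_pair[k, j]:
                    continue
                left = dp[i, k - 1] if k > i else 0
                if left + dp[k + 1, j - 1] + 1 == target:
                    struct[k] = "("
                    struct[j] = ")"
                    if k > i:
                        # process the left span iteratively after the inner one
                        traceback(i, k - 1)
                    i, j = k + 1, j - 1
                    break
            else:  # pragma: no cover - DP and traceback disagree
                raise AssertionError("traceback failed to realize the DP optimum")

    traceback(0, n - 1)
    return "".join(struct)


def _vienna_available() -> bool:
    return shutil.which("RNAfold") is not None


def _vienna_fold(sequence: str) -> str:
    """MFE structure from the RNAfold executable."""
    proc = subprocess.run(
        ["RNAfold", "--noPS"],
        input=sequence + "\n",
        capture_output=True,
        text=True,
        check=True,
    )
    lines = [ln for ln in proc.stdout.splitlines() if ln.strip()]
    # second line: "structure (energy)"
    structure = lines[1].split()[0]
    if len(structure) != len(sequence):  # pragma: no cover - defensive
        raise RuntimeError("RNAfold returned a structure of unexpected length")
    return structure


def fold(sequence: str, config: FoldConfig | None = None) -> str:
    """Fold one sequence with the configured backend; output length = input length."""
    cfg = config or FoldConfig()
    if cfg.backend in ("vienna", "external"):
        if not _vienna_available():
            raise BackendUnavailableError("external backend requested but RNAfold is not on PATH")
        return _vienna_fold(sequence.upper().replace("T", "U"))
    return nussinov_fold(sequence, cfg)


def fold_windows(windows, config: FoldConfig | None = None) -> dict[str, str]:
    """Fold a collection of LabeledWindow, keyed by window_id."""
    cfg = config or FoldConfig()
    return {w.window_id: fold(w.sequence, cfg) for w in windows}


def write_structure_db(path, structures: dict[str, str]) -> None:
    """One record per line: ``window_id<TAB>dotbracket``."""
    with open(path, "w") as fh:
        for wid, db in structures.items():
            fh.write(f"{wid}\t{db}\n")


def read_structure_db(path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            wid, db = line.split("\t")
            parse_dotbracket(db)  # validate on read
            out[wid] = db
    return out
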