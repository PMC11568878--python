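"""Window extraction, negative sampling, splitting and stratification.

A sample is a 41-nt window centered on a candidate 2'-O-methylation
site (20 nt of flank on each side). Positives come from experimentally
verified site lists; negatives are windows centered on unmodified
residues sampled in the vicinity of each positive so that local sequence
composition is matched. All positions are 1-based and inclusive; the
window center is position ``flank + 1`` (= 21 of 41). T is normalized to
U and lowercase to uppercase on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from nmsitekit.errors import (
    AmbiguousCenterError,
    IllegalResidueError,
    InsufficientCandidatesError,
    NegativePoolExhaustedError,
    WindowOutOfBoundsError,
)

__all__ = [
    "WINDOW_FLANK",
    "WINDOW_LENGTH",
    "SiteRecord",
    "LabeledWindow",
    "DatasetSplit",
    "RatioSubset",
    "normalize_sequence",
    "extract_window",
    "sample_negatives",
    "split_dataset",
    "make_ratio_subsets",
    "stratify_by_center",
    "read_fasta",
    "read_sites_tsv",
    "write_windows_fasta",
    "write_windows_manifest",
    "read_windows_fasta",
]

WINDOW_FLANK = 20
WINDOW_LENGTH = 2 * WINDOW_FLANK + 1  # 41


@dataclass(frozen=True)
class SiteRecord:
    """One row of a site list: sequence id, 1-based position, optional label."""

    seq_id: str
    position: int
    label: str = "unknown"  # positive | negative | unknown

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.label not in ("positive", "negative", "unknown"):
            raise ValueError(f"unknown label {self.label!r}")


@dataclass(frozen=True)
class LabeledWindow:
    """A 41-nt window with binary label and provenance."""

    window_id: str
    sequence: str
    label: int
    origin: tuple[str, int]  # (seq_id, 1-based center position)

    def __post_init__(self):
        if len(self.sequence) != WINDOW_LENGTH:
            raise ValueError(
                f"window must be {WINDOW_LENGTH} nt, got {len(self.sequence)}"
            )
        if self.center_base == "N":
            raise AmbiguousCenterError("window center is N")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")

    @property
    def center_base(self) -> str:
        return self.sequence[WINDOW_FLANK]


@dataclass(frozen=True)
class DatasetSplit:
    """Train/validation/test partitions with imbalanced val and test."""

    train_pos: list[LabeledWindow]
    train_neg: list[LabeledWindow]
    val_pos: list[LabeledWindow]
    val_neg: list[LabeledWindow]
    test_pos: list[LabeledWindow]
    test_neg: list[LabeledWindow]
    seed: int

    @property
    def train(self) -> list[LabeledWindow]:
        return self.train_pos + self.train_neg

    @property
    def val(self) -> list[LabeledWindow]:
        return self.val_pos + self.val_neg

    @property
    def test(self) -> list[LabeledWindow]:
        return self.test_pos + self.test_neg


@dataclass(frozen=True)
class RatioSubset:
    """Training subset TS_k with negatives = k x positives."""

    ratio_k: int
    windows: list[LabeledWindow] = field(repr=False)


def normalize_sequence(sequence: str) -> str:
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - set("ACGUN")
    if bad:
        raise IllegalResidueError(f"illegal residue(s) {sorted(bad)}")
    return seq


def extract_window(
    sequence: str,
    position: int,
    flank: int = WINDOW_FLANK,
    seq_id: str = "seq",
    label: int = 0,
) -> LabeledWindow:
    """Cut the [position - flank, position + flank] window (1-based, inclusive).

    Windows that would run off either end are rejected, not padded.
    """
    seq = normalize_sequence(sequence)
    if not 1 <= position <= len(seq):
        raise WindowOutOfBoundsError(
            f"position {position} outside sequence of length {len(seq)}"
        )
    lo, hi = position - flank, position + flank
    if lo < 1 or hi > len(seq):
        raise WindowOutOfBoundsError(
            f"window [{lo}, {hi}] out of bounds for sequence of length {len(seq)}"
        )
    window = seq[lo - 1 : hi]
    if window[flank] == "N":
        raise AmbiguousCenterError(f"center residue at position {position} is N")
    return LabeledWindow(
        window_id=f"{seq_id}:{position}",
        sequence=window,
        label=label,
        origin=(seq_id, position),
    )


def sample_negatives(
    sequence: str,
    positive_positions: set[int],
    per_positive: int = 15,
    radius: int = 500,
    rng_seed: int = 0,
    flank: int = WINDOW_FLANK,
    seq_id: str = "seq",
    strict: bool = True,
) -> list[LabeledWindow]:
    """Draw negative windows near each positive site.

    For each positive position p, up to `per_positive` distinct centers are
    drawn uniformly without replacement from [p - radius, p + radius],
    excluding (a) centers whose window runs off the sequence, (b) any
    positive position, (c) N centers, and (d) centers already drawn for an
    earlier positive in this call. With strict=True an
    InsufficientCandidatesError is raised when a positive cannot be served
    in full; otherwise the shortfall is silently accepted.
    """
    if per_positive < 1:
        raise ValueError("per_positive must be >= 1")
    if radius < flank:
        raise ValueError(f"radius must be >= flank ({flank})")
    seq = normalize_sequence(sequence)
    rng = np.random.default_rng(rng_seed)
    taken: set[int] = set()
    out: list[LabeledWindow] = []
    for p in sorted(positive_positions):
        lo = max(p - radius, flank + 1)
        hi = min(p + radius, len(seq) - flank)
        candidates = [
            c
            for c in range(lo, hi + 1)
            if c not in positive_positions and c not in taken and seq[c - 1] != "N"
        ]
        if len(candidates) < per_positive and strict:
            raise InsufficientCandidatesError(
                f"positive at {p}: only {len(candidates)} valid negative centers "
                f"(requested {per_positive})",
                achieved=len(candidates),
            )
        k = min(per_positive, len(candidates))
        chosen = rng.choice(len(candidates), size=k, replace=False) if k else []
        for ci in sorted(int(c) for c in np.asarray(chosen)):
            center = candidates[ci]
            taken.add(center)
            out.append(extract_window(seq, center, flank=flank, seq_id=seq_id, label=0))
    return out


def split_dataset(
    positives: list[LabeledWindow],
    negatives: list[LabeledWindow],
    fractions: tuple[float, float, float] = (0.6, 0.1, 0.3),
    val_test_ratio: int = 10,
    seed: int = 0,
) -> DatasetSplit:
    """Partition into train/validation/test.

    Positives are shuffled and split by `fractions` with floor rounding;
    leftover positives go to train. Validation and test negatives are drawn
    to exactly `val_test_ratio` x their positive counts; all remaining
    negatives go to train.
    """
    rng = np.random.default_rng(seed)
    pos = [positives[i] for i in rng.permutation(len(positives))]
    neg = [negatives[i] for i in rng.permutation(len(negatives))]

    n = len(pos)
    n_train = int(fractions[0] * n)
    n_val = int(fractions[1] * n)
    n_test = int(fractions[2] * n)
    n_train += n - n_train - n_val - n_test  # remainder to train

    val_pos = pos[n_train : n_train + n_val]
    test_pos = pos[n_train + n_val :]
    train_pos = pos[:n_train]

    need = val_test_ratio * (len(val_pos) + len(test_pos))
    if len(neg) < need:
        raise NegativePoolExhaustedError(
            f"need {need} negatives for val/test at 1:{val_test_ratio}, have {len(neg)}"
        )
    n_val_neg = val_test_ratio * len(val_pos)
    n_test_neg = val_test_ratio * len(test_pos)
    val_neg = neg[:n_val_neg]
    test_neg = neg[n_val_neg : n_val_neg + n_test_neg]
    train_neg = neg[n_val_neg + n_test_neg :]

    return DatasetSplit(
        train_pos=train_pos,
        train_neg=train_neg,
        val_pos=val_pos,
        val_neg=val_neg,
        test_pos=test_pos,
        test_neg=test_neg,
        seed=seed,
    )


def make_ratio_subsets(
    train_pos: list[LabeledWindow],
    train_neg: list[LabeledWindow],
    seed: int = 0,
    max_ratio: int = 10,
) -> list[RatioSubset]:
    """Build the nested imbalance ladder TS_1 .. TS_max_ratio.

    All subsets share the full positive set; TS_k adds the first
    k x |positives| negatives of one fixed shuffle, so TS_(k-1)'s negatives
    are always a subset of TS_k's. The ladder is truncated (with a
    warning) when the negative pool cannot support the top rung.
    """
    import warnings

    rng = np.random.default_rng(seed)
    neg = [train_neg[i] for i in rng.permutation(len(train_neg))]
    n_pos = len(train_pos)
    top = max_ratio
    if len(neg) < max_ratio * n_pos:
        top = len(neg) // n_pos if n_pos else 0
        warnings.warn(
            f"negative pool supports ratios only up to 1:{top}; ladder truncated",
            stacklevel=2,
        )
    return [
        RatioSubset(ratio_k=k, windows=list(train_pos) + neg[: k * n_pos])
        for k in range(1, top + 1)
    ]


def stratify_by_center(windows) -> dict[str, list[LabeledWindow]]:
    """Partition windows by center base into the Am/Cm/Gm/Um strata."""
    strata: dict[str, list[LabeledWindow]] = {"A": [], "C": [], "G": [], "U": []}
    for w in windows:
        strata[w.center_base].append(w)
    return strata


# ---------------------------------------------------------------------------
# I/O

def read_fasta(path) -> dict[str, str]:
    """Multi-record FASTA to {id: normalized sequence}."""
    return {
        rec.id: normalize_sequence(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    }


def read_sites_tsv(path) -> list[SiteRecord]:
    """Site list TSV: ``seq_id<TAB>position[<TAB>label]``; '#' comments."""
    records: list[SiteRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed site line: {line!r}")
            label = parts[2] if len(parts) > 2 and parts[2] else "unknown"
            records.append(SiteRecord(seq_id=parts[0], position=int(parts[1]), label=label))
    return records


def write_windows_fasta(path, windows) -> None:
    """FASTA with header ``>window_id|origin_seq:pos|label``."""
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f">{w.window_id}|{w.origin[0]}:{w.origin[1]}|{w.label}\n{w.sequence}\n")


def read_windows_fasta(path) -> list[LabeledWindow]:
    out: list[LabeledWindow] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        wid, origin, label = rec.description.split("|")
        seq_id, pos = origin.rsplit(":", 1)
        out.append(
            LabeledWindow(
                window_id=wid,
                sequence=normalize_sequence(str(rec.seq)),
                label=int(label),
                origin=(seq_id, int(pos)),
            )
        )
    return out


def write_windows_manifest(path, windows) -> None:
    """TSV manifest: window_id, seq_id, position, center base, label."""
    with open(path, "w") as fh:
        fh.write("window_id\tseq_id\tposition\tcenter_base\tlabel\n")
        for w in windows:
            fh.write(
                f"{w.window_id}\t{w.origin[0]}\t{w.origin[1]}\t{w.center_base}\t{w.label}\n"
            )
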