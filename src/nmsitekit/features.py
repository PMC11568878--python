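"""Three-channel feature encoding of sequence windows.

Each 41-nt window is represented three ways before entering the network:

* **one-hot** — an L x 4 indicator matrix, column order (A, C, G, U);
  the ambiguous residue N maps to an all-zero row.
* **Z-curve** — the cumulative 3-D walk (x_n, y_n, z_n) of the sequence,
  where for the length-n prefix with cumulative base counts A_n, C_n,
  G_n, U_n:

      x_n = (A_n + G_n) - (C_n + U_n)    purine vs pyrimidine
      y_n = (A_n + C_n) - (G_n + U_n)    amino vs keto
      z_n = (A_n + U_n) - (G_n + C_n)    weak vs strong hydrogen bonding

  The mapping is invertible: the four cumulative counts are recovered
  exactly from (n, x_n, y_n, z_n), which `z_curve_invert` exploits.
* **pairing matrix** — a symmetric binary L x L matrix with 1 at (i, j)
  iff bases i and j are paired in the window's secondary structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from nmsitekit.errors import IllegalResidueError, InconsistentCoordinatesError
from nmsitekit.structure import FoldConfig, fold, parse_dotbracket

__all__ = [
    "FeatureBundle",
    "one_hot_encode",
    "z_curve_encode",
    "z_curve_invert",
    "pairing_matrix_from_structure",
    "encode_window",
    "encode_windows",
    "EncodedDataset",
    "save_encoded",
    "load_encoded",
]

_ONE_HOT = {
    "A": (1, 0, 0, 0),
    "C": (0, 1, 0, 0),
    "G": (0, 0, 1, 0),
    "U": (0, 0, 0, 1),
    "N": (0, 0, 0, 0),
}

# per-residue Z-curve step: delta(x, y, z); N advances nothing
_Z_STEP = {
    "A": (1, 1, 1),
    "C": (-1, 1, -1),
    "G": (1, -1, -1),
    "U": (-1, -1, 1),
    "N": (0, 0, 0),
}


@dataclass(frozen=True)
class FeatureBundle:
    """The three encodings of one window, sharing the same length L."""

    window_id: str
    one_hot: np.ndarray  # (L, 4) uint8
    z_curve: np.ndarray  # (L, 3) int32
    pairing: np.ndarray  # (L, L) uint8, symmetric

    def __post_init__(self):
        L = self.one_hot.shape[0]
        if self.z_curve.shape != (L, 3) or self.pairing.shape != (L, L):
            raise ValueError("encodings disagree on window length")


def _check_alphabet(sequence: str) -> str:
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - set("ACGUN")
    if bad:
        raise IllegalResidueError(f"illegal residue(s) {sorted(bad)} in sequence")
    return seq


def one_hot_encode(sequence: str) -> np.ndarray:
    """L x 4 indicator matrix, columns (A, C, G, U); N rows are all zero."""
    seq = _check_alphabet(sequence)
    return np.array([_ONE_HOT[ch] for ch in seq], dtype=np.uint8)


def z_curve_encode(sequence: str) -> np.ndarray:
    """L x 3 integer matrix; row n-1 holds (x_n, y_n, z_n) for prefix length n."""
    seq = _check_alphabet(sequence)
    if not seq:
        return np.zeros((0, 3), dtype=np.int32)
    steps = np.array([_Z_STEP[ch] for ch in seq], dtype=np.int32)
    return np.cumsum(steps, axis=0)


def z_curve_invert(coords: np.ndarray) -> np.ndarray:
    """Recover cumulative base counts (A_n, C_n, G_n, U_n) from Z-curve rows.

    Row n-1 of `coords` is (x_n, y_n, z_n); the algebraic inverse is

        A_n = (n + x + y + z) / 4      C_n = (n - x + y - z) / 4
        G_n = (n + x - y - z) / 4      U_n = (n - x - y + z) / 4

    (counts of N residues are implicitly n minus the sum of the four).
    """
    coords = np.asarray(coords)
    L = coords.shape[0]
    n = np.arange(1, L + 1)[:, None]
    x, y, z = coords[:, 0:1], coords[:, 1:2], coords[:, 2:3]
    counts4 = np.concatenate(
        [n + x + y + z, n - x + y - z, n + x - y - z, n - x - y + z], axis=1
    )
    if np.any(counts4 % 4 != 0) or np.any(counts4 < 0):
        raise InconsistentCoordinatesError(
            "coordinates do not invert to nonnegative integer base counts"
        )
    return (counts4 // 4).astype(np.int64)


def pairing_matrix_from_structure(dotbracket: str) -> np.ndarray:
    """Symmetric binary L x L matrix of the base pairs of a dot-bracket string."""
    L = len(dotbracket)
    m = np.zeros((L, L), dtype=np.uint8)
    for i, j in parse_dotbracket(dotbracket):
        m[i - 1, j - 1] = 1
        m[j - 1, i - 1] = 1
    return m


def encode_window(window, fold_config: FoldConfig | None = None, structure: str | None = None) -> FeatureBundle:
    """Build the FeatureBundle of one LabeledWindow.

    The pairing matrix comes from `structure` (dot-bracket) when given,
    otherwise from folding the window with `fold_config`.
    """
    db = structure if structure is not None else fold(window.sequence, fold_config)
    return FeatureBundle(
        window_id=window.window_id,
        one_hot=one_hot_encode(window.sequence),
        z_curve=z_curve_encode(window.sequence),
        pairing=pairing_matrix_from_structure(db),
    )


@dataclass
class EncodedDataset:
    """Stacked feature arrays for a window collection, ready for the model."""

    window_ids: list[str]
    one_hot: np.ndarray  # (n, L, 4)
    z_curve: np.ndarray  # (n, L, 3)
    pairing: np.ndarray  # (n, L, L)
    labels: np.ndarray  # (n,) int8

    def __len__(self) -> int:
        return len(self.window_ids)

    def subset(self, idx) -> "EncodedDataset":
        idx = np.asarray(idx)
        return EncodedDataset(
            window_ids=[self.window_ids[i] for i in idx],
            one_hot=self.one_hot[idx],
            z_curve=self.z_curve[idx],
            pairing=self.pairing[idx],
            labels=self.labels[idx],
        )


def encode_windows(
    windows,
    fold_config: FoldConfig | None = None,
    structures: dict[str, str] | None = None,
) -> EncodedDataset:
    """Encode a window collection into stacked arrays.

    `structures` maps window_id to a precomputed dot-bracket; windows
    absent from the map are folded on the fly.
    """
    windows = list(windows)
    bundles = [
        encode_window(
            w,
            fold_config=fold_config,
            structure=None if structures is None else structures.get(w.window_id),
        )
        for w in windows
    ]
    return EncodedDataset(
        window_ids=[w.window_id for w in windows],
        one_hot=np.stack([b.one_hot for b in bundles]).astype(np.uint8),
        z_curve=np.stack([b.z_curve for b in bundles]).astype(np.int32),
        pairing=np.stack([b.pairing for b in bundles]).astype(np.uint8),
        labels=np.array([w.label for w in windows], dtype=np.int8),
    )


def save_encoded(path, ds: EncodedDataset) -> None:
    """Lossless on-disk container (npz)."""
    np.savez_compressed(
        path,
        window_ids=np.array(ds.window_ids),
        one_hot=ds.one_hot,
        z_curve=ds.z_curve,
        pairing=ds.pairing,
        labels=ds.labels,
    )


def load_encoded(path) -> EncodedDataset:
    with np.load(path, allow_pickle=False) as z:
        return EncodedDataset(
            window_ids=[str(s) for s in z["window_ids"]],
            one_hot=z["one_hot"],
            z_curve=z["z_curve"],
            pairing=z["pairing"],
            labels=z["labels"],
        )
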