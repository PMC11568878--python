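"""End-to-end orchestration: data -> structures -> features -> CV -> ensemble -> report.

Also houses the prediction path (site list or sliding scan over a
transcript) and the on-disk ensemble artifact (five checkpoints plus
optimized weights).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from nmsitekit.ensemble import BOConfig, EnsembleWeights, optimize_weights, weighted_predict
from nmsitekit.errors import NmSiteKitError
from nmsitekit.features import EncodedDataset, encode_windows
from nmsitekit.metrics import MetricReport, compute_metrics
from nmsitekit.model import ModelConfig, NmSiteModel, load_model, save_model
from nmsitekit.structure import FoldConfig
from nmsitekit.training import FoldResult, LossConfig, TrainConfig, cross_validate
from nmsitekit.windows import (
    WINDOW_FLANK,
    LabeledWindow,
    extract_window,
    make_ratio_subsets,
    split_dataset,
)
from nmsitekit.synthetic import SyntheticSpec, generate

__all__ = [
    "EnsembleArtifact",
    "EndToEndResult",
    "calibrate_threshold",
    "end_to_end",
    "predict_windows",
    "scan_sequence",
    "write_manifest",
]


def calibrate_threshold(probabilities, labels) -> float:
    """MCC-maximizing classification threshold on a held-out set.

    Scans the midpoints between consecutive distinct predicted
    probabilities; ties resolve to the smallest optimal threshold.
    """
    from nmsitekit.metrics import confusion, mcc_from_counts

    p = np.asarray(probabilities, dtype=float)
    uniq = np.unique(p)
    candidates = np.concatenate([[0.5], (uniq[1:] + uniq[:-1]) / 2.0])
    best_t, best_mcc = 0.5, -np.inf
    for t in np.sort(candidates):
        m = mcc_from_counts(confusion(labels, p, threshold=t))
        if m > best_mcc + 1e-12:
            best_mcc, best_t = m, float(t)
    return best_t


@dataclass
class EnsembleArtifact:
    """Five trained fold models + ensemble weights + provenance.

    ``threshold`` is the classification cutoff calibrated on the unified
    validation set (0.5 when calibration is disabled).
    """

    models: list[NmSiteModel]
    weights: EnsembleWeights
    validation_mcc: float
    model_config: ModelConfig
    fold_config: FoldConfig
    threshold: float = 0.5

    def predict_proba(self, dataset: EncodedDataset) -> np.ndarray:
        per_model = np.stack([m.predict(dataset) for m in self.models])
        return weighted_predict(per_model, self.weights)

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for i, m in enumerate(self.models):
            save_model(outdir / f"fold{i}.npz", m)
        meta = {
            "weights": list(self.weights.weights),
            "validation_mcc": self.validation_mcc,
            "threshold": self.threshold,
            "model_config": asdict(self.model_config),
            "fold_config": {
                "backend": self.fold_config.backend,
                "min_loop": self.fold_config.min_loop,
                "allowed_pairs": sorted(self.fold_config.allowed_pairs),
            },
            "n_models": len(self.models),
        }
        (outdir / "ensemble.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, outdir) -> "EnsembleArtifact":
        outdir = Path(outdir)
        meta = json.loads((outdir / "ensemble.json").read_text())
        models = [load_model(outdir / f"fold{i}.npz") for i in range(meta["n_models"])]
        mc = meta["model_config"]
        for key in ("conv1d_channels", "conv2d_channels", "mlp_hidden_sizes"):
            mc[key] = tuple(mc[key])
        return cls(
            models=models,
            weights=EnsembleWeights(weights=tuple(meta["weights"])),
            validation_mcc=meta["validation_mcc"],
            model_config=ModelConfig(**mc),
            fold_config=FoldConfig(
                backend=meta["fold_config"]["backend"],
                min_loop=meta["fold_config"]["min_loop"],
                allowed_pairs=frozenset(meta["fold_config"]["allowed_pairs"]),
            ),
            threshold=meta.get("threshold", 0.5),
        )


@dataclass
class EndToEndResult:
    report: MetricReport
    artifact: EnsembleArtifact
    fold_results: list[FoldResult]
    test_probs: np.ndarray
    test_labels: np.ndarray


def end_to_end(
    spec: SyntheticSpec,
    ratio_k: int = 10,
    model_config: ModelConfig | None = None,
    loss_config: LossConfig | None = None,
    train_config: TrainConfig | None = None,
    fold_config: FoldConfig | None = None,
    bo_config: BOConfig | None = None,
    seed: int = 0,
    calibrate: bool = True,
) -> EndToEndResult:
    """Run the whole method on synthetic data, CPU-only.

    Stages: generate windows -> 60/10/30 split (validation and test at
    1:10) -> training subset at 1:ratio_k -> fold structures -> encode ->
    five-fold cross-validation -> Bayesian ensemble weighting on the
    unified validation set -> metric report on the independent test set.

    With ``calibrate`` (default) the classification threshold is also
    chosen on the unified validation set; the test partition is never
    touched before the final report.

    Defaults are the desk-scale protocol: the small model preset, a
    positive-class weight of 2.0 (selected on validation data, the same
    model-selection route the ratio/weight grid uses), and a 60-epoch
    cosine schedule with patience 10.
    """
    mcfg = model_config or ModelConfig.small()
    lcfg = loss_config or LossConfig(pos_weight=2.0)
    tcfg = train_config or TrainConfig(seed=seed, max_epochs=60, patience=10)
    fcfg = fold_config or FoldConfig()
    bcfg = bo_config or BOConfig(seed=seed)

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except NmSiteKitError as e:
            raise NmSiteKitError(f"stage {name}: {e}") from e

    windows = stage("synth", generate, spec)
    positives = [w for w in windows if w.label == 1]
    negatives = [w for w in windows if w.label == 0]
    split = stage("split", split_dataset, positives, negatives, seed=seed)
    subsets = stage("ratio", make_ratio_subsets, split.train_pos, split.train_neg, seed=seed)
    train_windows = subsets[ratio_k - 1].windows

    enc_train = stage("encode", encode_windows, train_windows, fold_config=fcfg)
    enc_val = stage("encode", encode_windows, split.val, fold_config=fcfg)
    enc_test = stage("encode", encode_windows, split.test, fold_config=fcfg)

    fold_results = stage(
        "train",
        cross_validate,
        enc_train,
        enc_val,
        model_config=mcfg,
        loss_config=lcfg,
        train_config=tcfg,
        k=tcfg.folds,
        seed=seed,
    )
    val_probs = np.stack([fr.val_probs for fr in fold_results])
    weights, val_mcc = stage("ensemble", optimize_weights, val_probs, enc_val.labels, bcfg)
    ens_val = weighted_predict(val_probs, weights)
    threshold = calibrate_threshold(ens_val, enc_val.labels) if calibrate else 0.5

    artifact = EnsembleArtifact(
        models=[fr.model for fr in fold_results],
        weights=weights,
        validation_mcc=val_mcc,
        model_config=mcfg,
        fold_config=fcfg,
        threshold=threshold,
    )
    test_probs = artifact.predict_proba(enc_test)
    report = compute_metrics(enc_test.labels, test_probs, threshold=threshold)
    return EndToEndResult(
        report=report,
        artifact=artifact,
        fold_results=fold_results,
        test_probs=test_probs,
        test_labels=np.asarray(enc_test.labels),
    )


def predict_windows(
    artifact: EnsembleArtifact, windows: list[LabeledWindow], threshold: float | None = None
) -> pd.DataFrame:
    """Score extracted windows; one row per window.

    The label column uses `threshold` when given, else the artifact's
    validation-calibrated threshold.
    """
    if not windows:
        raise NmSiteKitError("no eligible windows")
    if threshold is None:
        threshold = artifact.threshold
    enc = encode_windows(windows, fold_config=artifact.fold_config)
    probs = artifact.predict_proba(enc)
    return pd.DataFrame(
        {
            "window_id": [w.window_id for w in windows],
            "seq_id": [w.origin[0] for w in windows],
            "position": [w.origin[1] for w in windows],
            "center_base": [w.center_base for w in windows],
            "probability": probs,
            "label": (probs >= threshold).astype(int),
        }
    )


def scan_sequence(sequence: str, seq_id: str = "seq", flank: int = WINDOW_FLANK) -> list[LabeledWindow]:
    """All windows admitting a full flank on both sides, skipping N centers."""
    out = []
    for pos in range(flank + 1, len(sequence) - flank + 1):
        try:
            out.append(extract_window(sequence, pos, flank=flank, seq_id=seq_id))
        except NmSiteKitError:
            continue
    return out


def write_manifest(path, command: str, config: dict, seeds: dict, inputs: dict[str, Path] | None = None) -> None:
    """Reproducibility manifest: command, config snapshot, seeds, input checksums."""
    checksums = {}
    for name, p in (inputs or {}).items():
        checksums[name] = hashlib.sha256(Path(p).read_bytes()).hexdigest()
    manifest = {
        "command": command,
        "config": config,
        "seeds": seeds,
        "input_sha256": checksums,
        "package_version": "0.1.0",
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
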