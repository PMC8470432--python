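"""Readers and writers for traces, feature tables, PCA models and reports.

Everything is plain text: traces are CSV (columns ``time_s, X, Y, SUM``)
with a JSON sidecar carrying the label, signal id, sampling rate, seed and
particle parameters; a dataset directory is indexed by ``manifest.json``;
feature tables are CSV; PCA models and classification reports are JSON.
Floats are serialised with 17 significant digits so write-then-read
round-trips are bit-exact.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import ClassificationReport, FamilyReport, FoldResult, ModeComparison
from .features import ChannelPCA, PCAModel
from .trap_sim import CHANNEL_NAMES, QPDTrace

__all__ = [
    "TraceParseError",
    "write_trace",
    "read_trace",
    "write_dataset",
    "read_dataset",
    "write_features",
    "read_features",
    "pca_model_to_dict",
    "pca_model_from_dict",
    "report_to_dict",
    "comparison_to_dict",
    "sha256_file",
]

_FLOAT_FMT = "%.17g"


class TraceParseError(ValueError):
    pass


def _sidecar_path(trace_path: Path) -> Path:
    return trace_path.with_suffix(".json")


def write_trace(trace: QPDTrace, path: str | Path, extra_meta: dict | None = None) -> Path:
    """Write one trace as CSV plus JSON sidecar; returns the CSV path."""
    path = Path(path)
    n = trace.n_samples
    t = np.arange(n) / trace.sampling_rate
    df = pd.DataFrame(
        {"time_s": t, "X": trace.channels[0], "Y": trace.channels[1], "SUM": trace.channels[2]}
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    meta = {
        "label": trace.label,
        "signal_id": trace.signal_id,
        "sampling_rate_hz": trace.sampling_rate,
        "n_samples": n,
        "seed": trace.seed,
    }
    if extra_meta:
        meta.update(extra_meta)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_trace(path: str | Path) -> tuple[QPDTrace, dict]:
    """Read a trace CSV + sidecar; returns (trace, sidecar metadata)."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise TraceParseError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise TraceParseError(f"{path}: cannot parse CSV ({exc})") from exc
    expected = ["time_s", *CHANNEL_NAMES]
    if list(df.columns) != expected:
        raise TraceParseError(f"{path}: columns {list(df.columns)} != {expected}")
    if df.isna().any().any():
        bad = int(df.index[df.isna().any(axis=1)][0]) + 2  # header is line 1
        raise TraceParseError(f"{path}: NaN sample at line {bad}")
    if len(df) != meta["n_samples"]:
        raise TraceParseError(
            f"{path}: {len(df)} rows but sidecar declares {meta['n_samples']}"
        )
    trace = QPDTrace(
        channels=df[list(CHANNEL_NAMES)].to_numpy().T,
        sampling_rate=float(meta["sampling_rate_hz"]),
        label=meta["label"],
        signal_id=int(meta["signal_id"]),
        seed=int(meta.get("seed", 0)),
    )
    return trace, meta


def write_dataset(
    traces: Sequence[QPDTrace], out_dir: str | Path, extra_meta: dict | None = None
) -> Path:
    """Write every trace plus a manifest indexing the files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for trace in traces:
        name = f"trace_{trace.signal_id:04d}.csv"
        write_trace(trace, out_dir / name, extra_meta)
        entries.append(
            {"file": name, "label": trace.label, "signal_id": trace.signal_id}
        )
    manifest = out_dir / "manifest.json"
    manifest.write_text(json.dumps({"traces": entries}, indent=2))
    return manifest


def read_dataset(dataset_dir: str | Path) -> list[QPDTrace]:
    dataset_dir = Path(dataset_dir)
    manifest = dataset_dir / "manifest.json"
    if not manifest.exists():
        raise TraceParseError(f"missing dataset manifest {manifest}")
    index = json.loads(manifest.read_text())
    return [read_trace(dataset_dir / e["file"])[0] for e in index["traces"]]


def write_features(features: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    features.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


# ---------------------------------------------------------------------------
# PCA model serialisation
# ---------------------------------------------------------------------------


def pca_model_to_dict(model: PCAModel) -> dict:
    return {
        "fitted_on": model.fitted_on,
        "channels": [
            {
                "mean": ch.mean.tolist(),
                "components": ch.components.tolist(),
                "explained_variance_ratio": ch.explained_variance_ratio.tolist(),
                "explained_variance": ch.explained_variance.tolist(),
            }
            for ch in model.channels
        ],
    }


def pca_model_from_dict(d: dict) -> PCAModel:
    channels = tuple(
        ChannelPCA(
            mean=np.asarray(ch["mean"]),
            components=np.asarray(ch["components"]),
            explained_variance_ratio=np.asarray(ch["explained_variance_ratio"]),
            explained_variance=np.asarray(ch["explained_variance"]),
        )
        for ch in d["channels"]
    )
    return PCAModel(channels=channels, fitted_on=int(d["fitted_on"]))


# ---------------------------------------------------------------------------
# Report serialisation
# ---------------------------------------------------------------------------


def _fold_to_dict(r: FoldResult) -> dict:
    return {
        "fold_index": r.fold_index,
        "accuracy": r.accuracy,
        "confusion_counts": r.confusion_counts.tolist(),
        "chosen_params": {k: v for k, v in r.chosen_params.items()},
        "n_test": r.n_test,
    }


def report_to_dict(report: ClassificationReport) -> dict:
    fams = {}
    for name, rep in report.families.items():
        fams[name] = {
            "mean_accuracy": rep.mean_accuracy,
            "best_accuracy": rep.best_accuracy,
            "worst_accuracy": rep.worst_accuracy,
            "confusion_normalized": rep.confusion_normalized.tolist(),
            "folds": [_fold_to_dict(r) for r in rep.fold_results],
        }
    return {
        "channel_mode": report.channel_mode,
        "n_folds": report.n_folds,
        "class_labels": list(report.class_labels),
        "families": fams,
    }


def comparison_to_dict(cmp: ModeComparison) -> dict:
    return {
        "all_channels": report_to_dict(cmp.all_channels),
        "sum_only": report_to_dict(cmp.sum_only),
        "accuracy_delta": dict(cmp.accuracy_delta),
    }


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
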