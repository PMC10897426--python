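"""Tabular and JSON input/output.

CSV dialect is fixed: comma separator, '.' decimal, UTF-8, header
mandatory. Flow samples use columns ``sample_id,intensity`` (one event per
row); lineage tables use ``generation,cell_index,parent_index,outcome,
factor,activity``. JSON reports embed the seed, package version, the
resolved configuration, and its SHA-256 hash, so every artifact is
traceable; no timestamps are written, so repeated runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .mixture import FlowSample

__all__ = [
    "read_flow_csv",
    "write_flow_csv",
    "write_lineage_csv",
    "write_summary_csv",
    "write_json_report",
]

FLOW_COLUMNS = ("sample_id", "intensity")


def read_flow_csv(path) -> list[FlowSample]:
    """Read an event table into one FlowSample per distinct sample_id,
    preserving row order. Errors cite the offending file row (header is
    row 1) and column."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file does not exist: {path}")
    try:
        df = pd.read_csv(path, dtype={"sample_id": str}, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: file is empty") from None
    missing = [c for c in FLOW_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing required column(s) {missing}; header must contain "
            f"{list(FLOW_COLUMNS)}"
        )
    if len(df) == 0:
        raise ValidationError(f"{path}: no event rows")
    intensity = pd.to_numeric(df["intensity"], errors="coerce")
    bad = ~np.isfinite(intensity.to_numpy()) | (intensity.to_numpy() <= 0)
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 2  # +1 header, +1 one-based
        raise ValidationError(
            f"{path}: invalid intensity {df['intensity'].iloc[row - 2]!r} at row "
            f"{row}, column 'intensity' (must be a finite number > 0)"
        )
    samples = []
    for sid in df["sample_id"].unique():
        values = intensity[df["sample_id"] == sid].to_numpy(dtype=float)
        samples.append(FlowSample(str(sid), values))
    return samples


def write_flow_csv(samples, path) -> None:
    """Write one or more FlowSamples as an event table; values round-trip
    at full precision (shortest-repr floats)."""
    if isinstance(samples, FlowSample):
        samples = [samples]
    frames = [
        pd.DataFrame(
            {
                "sample_id": s.sample_id,
                # shortest-repr strings so values round-trip exactly
                "intensity": [repr(float(v)) for v in s.intensities],
            }
        )
        for s in samples
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_lineage_csv(dataset, path) -> None:
    """Write a LineageDataset's per-daughter table."""
    dataset.to_frame().to_csv(path, index=False)


def write_summary_csv(trajectory, path) -> None:
    """Write a trajectory's per-generation summary."""
    trajectory.summary().to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json_report(payload: dict, path, *, seed: int, config: dict | None = None) -> None:
    """Write a JSON report with provenance: seed, package version, resolved
    config and its SHA-256 hash. Deterministic byte layout (sorted keys,
    no timestamps)."""
    from . import __version__

    config = _jsonable(config or {})
    config_text = json.dumps(config, sort_keys=True)
    doc = {
        "seed": int(seed),
        "version": __version__,
        "config": config,
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        **_jsonable(payload),
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
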