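"""Readers and writers for recordings, grids and result tables.

The native on-disk recording format is a delimited channels x samples
matrix accompanied by a YAML side-car (same stem, ``.yaml``) holding the
sampling rate, channel ids, events and cohort fields, since a bare numeric
matrix cannot carry them.  EDF files are read through :mod:`mne` when it is
installed; EDF writing is not supported.

All numeric exports are plain comma-separated text with fixed column order
and ``NA`` sentinels for empty grid cells.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import Event, Recording

__all__ = [
    "write_recording",
    "read_recording",
    "write_grid",
    "read_grid",
    "write_report",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".yaml")


def write_recording(rec: Recording, path: str | Path, fmt: str = "%.6g") -> Path:
    """Write a recording as delimited matrix + YAML side-car metadata."""
    path = Path(path)
    np.savetxt(path, rec.signal, fmt=fmt, delimiter=",")
    meta = {
        "fs": float(rec.fs),
        "channels": [int(c) for c in rec.channels],
        "participant_id": rec.participant_id,
        "modality": rec.modality,
        "group": rec.group,
        "events": [
            {"label": ev.label, "time_ms": float(ev.time_ms), "clipped": bool(ev.clipped)}
            for ev in rec.events
        ],
        "meta": {k: v for k, v in rec.meta.items() if _yaml_safe(v)},
    }
    _sidecar(path).write_text(yaml.safe_dump(meta, sort_keys=False))
    return path


def _yaml_safe(v) -> bool:
    try:
        yaml.safe_dump(v)
        return True
    except yaml.YAMLError:
        return False


def read_recording(
    path: str | Path, fmt: str | None = None, n_channels_expected: int | None = None
) -> Recording:
    """Read a recording from delimited matrix + side-car, or from EDF.

    ``fmt`` is inferred from the suffix (``edf`` vs ``delimited``) when not
    given.  ``n_channels_expected`` (e.g. the layout's channel count) is
    checked against the file.
    """
    path = Path(path)
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "delimited"

    if fmt == "edf":
        rec = _read_edf(path)
    elif fmt == "delimited":
        try:
            signal = np.loadtxt(path, delimiter=",", ndmin=2)
        except ValueError as exc:
            raise ValueError(f"{path}: unparseable delimited matrix: {exc}") from exc
        meta_path = _sidecar(path)
        meta = yaml.safe_load(meta_path.read_text()) if meta_path.exists() else {}
        events = tuple(
            Event(e["label"], float(e["time_ms"]), bool(e.get("clipped", False)))
            for e in meta.get("events", [])
        )
        rec = Recording(
            signal=signal,
            fs=float(meta.get("fs", 1000.0)),
            channels=tuple(meta.get("channels", ())),
            events=events,
            participant_id=str(meta.get("participant_id", "")),
            modality=str(meta.get("modality", "")),
            group=str(meta.get("group", "")),
            meta=dict(meta.get("meta", {})),
        )
    else:
        raise ValueError(f"unknown recording format {fmt!r}")

    if n_channels_expected is not None and rec.n_channels != n_channels_expected:
        raise ValueError(
            f"{path}: {rec.n_channels} channels but layout expects {n_channels_expected}"
        )
    return rec


def _read_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the optional mne dependency") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return Recording(
        signal=raw.get_data() * 1e6,  # volts -> microvolts
        fs=float(raw.info["sfreq"]),
        meta={"source": str(path), "format": "edf"},
    )


def write_grid(grid: np.ndarray, path: str | Path) -> Path:
    """Write a scalp grid as CSV with ``NA`` at empty reference cells."""
    path = Path(path)
    frame = pd.DataFrame(grid)
    frame.to_csv(path, index=False, header=False, na_rep="NA")
    return path


def read_grid(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, header=None, na_values=["NA"]).to_numpy(dtype=float)


def write_report(report: dict, path: str | Path) -> Path:
    """Write a structured (JSON) machine-readable report."""
    path = Path(path)
    path.write_text(json.dumps(report, indent=2, default=str))
    return path
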