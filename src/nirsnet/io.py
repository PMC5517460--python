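"""Delimited-text file formats and atomic writes.

Recording format (TSV, one file per subject-run): comment header lines carry
the metadata, then one row per channel::

    # nirsnet-recording v1
    # subject=S01 run=1 species=HbO sampling_rate_hz=5.0
    # channels=CH01,CH02,...
    0.123<TAB>0.456<TAB>...

Connectivity matrices are square TSVs with a channel-id header row; sweep
results are long-format TSVs.  All writes go through a temp-file + rename so
interrupted runs never leave partial tables.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import HemodynamicRecording

__all__ = [
    "atomic_write_text",
    "write_recording",
    "read_recording",
    "write_matrix",
    "read_matrix",
    "write_table",
]

_MAGIC = "# nirsnet-recording v1"


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write text to `path` atomically (temp file in the same directory,
    then rename)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_recording(recording: HemodynamicRecording, path: str | Path) -> None:
    lines = [
        _MAGIC,
        f"# subject={recording.subject_id} run={recording.run_id} "
        f"species={recording.species} sampling_rate_hz={recording.sampling_rate_hz!r}",
        "# channels=" + ",".join(recording.channel_ids),
    ]
    for row in recording.data:
        lines.append("\t".join(repr(float(v)) for v in row))
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_recording(path: str | Path) -> HemodynamicRecording:
    """Read and validate a recording TSV; errors name the offending line."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such recording file: {path}")
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != _MAGIC:
        raise ValueError(f"{path}: missing '{_MAGIC}' header (line 1)")
    meta: dict[str, str] = {}
    channels: list[str] = []
    body_start = None
    for ln, line in enumerate(lines[1:], start=2):
        if line.startswith("# channels="):
            channels = line[len("# channels="):].split(",")
        elif line.startswith("#"):
            for tok in line[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
        else:
            body_start = ln
            break
    if "sampling_rate_hz" not in meta:
        raise ValueError(f"{path}: header missing sampling_rate_hz")
    if not channels:
        raise ValueError(f"{path}: header missing channel ids")
    if body_start is None:
        raise ValueError(f"{path}: no data rows")
    rows = []
    width = None
    for ln, line in enumerate(lines[body_start - 1:], start=body_start):
        if not line.strip():
            continue
        cells = line.split("\t")
        if width is None:
            width = len(cells)
        elif len(cells) != width:
            raise ValueError(
                f"{path}: ragged row at line {ln} "
                f"({len(cells)} cells, expected {width})")
        try:
            vals = [float(c) for c in cells]
        except ValueError as err:
            raise ValueError(f"{path}: non-numeric cell at line {ln}: {err}") from err
        for col, v in enumerate(vals):
            if np.isnan(v):
                raise ValueError(
                    f"{path}: NaN cell at line {ln}, column {col + 1}")
        rows.append(vals)
    data = np.asarray(rows, dtype=float)
    if data.shape[0] != len(channels):
        raise ValueError(
            f"{path}: {data.shape[0]} data rows but {len(channels)} channel ids")
    return HemodynamicRecording(
        subject_id=meta.get("subject", "S00"),
        run_id=meta.get("run", "1"),
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
        data=data,
        species=meta.get("species", "HbO"),
        channel_ids=channels,
    )


def write_matrix(m: np.ndarray, path: str | Path, channel_ids=None) -> None:
    """Square matrix as TSV with a channel-id header row."""
    m = np.asarray(m)
    n = m.shape[0]
    ids = channel_ids or [f"CH{i + 1:02d}" for i in range(n)]
    lines = ["\t".join(ids)]
    for row in m:
        lines.append("\t".join(repr(float(v)) for v in row))
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_matrix(path: str | Path):
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    ids = lines[0].split("\t")
    data = np.array([[float(c) for c in ln.split("\t")] for ln in lines[1:]])
    if data.shape != (len(ids), len(ids)):
        raise ValueError(f"{path}: matrix is not square against its header")
    return data, ids


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    atomic_write_text(path, df.to_csv(sep="\t", index=False))
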