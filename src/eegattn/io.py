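"""Plain-text readers/writers and manifest handling.

Recordings are single-column delimited text (one value per line) with a JSON
sidecar for the sampling rate and label metadata; windowed datasets are CSV
with one window per row and the state label in the last column; manifests are
CSV.  Numbers are serialized with 12 significant digits so write/read
round-trips are stable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import STATES, LabeledDataset, RawRecording, Sample

__all__ = [
    "ACTIVITIES",
    "read_recording",
    "write_recording",
    "read_windows_csv",
    "write_windows_csv",
    "read_manifest",
    "write_manifest",
    "write_score_report",
]

#: The seven recorded activities.
ACTIVITIES: tuple[str, ...] = (
    "drawing",
    "eating",
    "computer_exercises",
    "electronic_games",
    "reading",
    "toys",
    "television",
)

_FMT = "%.12g"


class ParseError(ValueError):
    pass


def write_recording(path: str | Path, recording: RawRecording) -> None:
    path = Path(path)
    np.savetxt(path, recording.signal, fmt=_FMT)
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump({"fs": recording.fs, "meta": recording.meta}, fh, indent=1)


def read_recording(path: str | Path, fs: float | None = None) -> RawRecording:
    """Read a one-value-per-line recording; a single header line is skipped.

    ``fs`` falls back to the JSON sidecar written alongside the recording.
    """
    path = Path(path)
    lines = path.read_text().strip().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty recording file")
    start = 0
    try:
        float(lines[0].split(",")[0])
    except ValueError:
        start = 1  # header line such as "value"
    values = []
    for i, line in enumerate(lines[start:], start=start + 1):
        token = line.split(",")[0].strip()
        if not token:
            continue
        try:
            values.append(float(token))
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric value on line {i}") from exc
    if not values:
        raise ParseError(f"{path}: no numeric data")

    meta: dict = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        side = json.loads(sidecar.read_text())
        meta = side.get("meta", {})
        if fs is None:
            fs = side.get("fs")
    if fs is None:
        raise ParseError(f"{path}: sampling rate not supplied and no sidecar")
    return RawRecording(signal=np.array(values), fs=float(fs), meta=meta)


def write_windows_csv(path: str | Path, dataset: LabeledDataset) -> None:
    n = dataset.samples[0].values.size
    df = pd.DataFrame(
        np.vstack([s.values for s in dataset.samples]),
        columns=[f"x{i}" for i in range(n)],
    )
    df["label"] = [s.label for s in dataset.samples]
    df.to_csv(path, index=False, float_format=_FMT)


def read_windows_csv(path: str | Path, fs: float = 512.0) -> LabeledDataset:
    """One window per row, numeric columns then a trailing label column."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected numeric columns plus a label column")
    labels = df.iloc[:, -1].astype(str)
    values = df.iloc[:, :-1]
    try:
        mat = values.to_numpy(dtype=float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric window values") from exc
    bad = [i for i, lab in enumerate(labels) if lab not in STATES]
    if bad:
        raise ParseError(
            f"{path}: unknown state label in row(s) {bad[:5]}; "
            f"expected one of {STATES}"
        )
    samples = [
        Sample(values=mat[i], label=labels.iloc[i], meta={"row": i})
        for i in range(mat.shape[0])
    ]
    return LabeledDataset(samples=samples, fs=fs)


def write_manifest(path: str | Path, entries: list[dict]) -> None:
    pd.DataFrame(entries).to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"path", "participant", "activity", "state"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: manifest missing columns {sorted(missing)}")
    return df


def write_components_csv(
    path: str | Path, components: list[np.ndarray], names: list[str] | tuple
) -> None:
    """Dump a decomposition (EMD or SSA), one named component per column."""
    if len(components) != len(names):
        raise ValueError("one name per component required")
    pd.DataFrame(
        np.column_stack(components), columns=list(names)
    ).to_csv(path, index=False, float_format=_FMT)


def read_components_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_score_report(path: str | Path, report) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=1)
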