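"""Readers and writers for plain-text signal and result files.

Two on-disk signal layouts are supported: single-channel ASCII files with one
numeric sample per line (the common distribution format for short EEG
segments, 173.61 Hz by default), and delimited multichannel tables with one
column per channel (long-term multichannel records, e.g. 256 Hz).  Feature
tables and window matrices are written as CSV so that plots and classification
consume the same interchange files.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .classify import CVReport
from .types import Signal, WindowMatrix

__all__ = [
    "read_bonn_ascii",
    "write_bonn_ascii",
    "read_multichannel_csv",
    "write_multichannel_csv",
    "write_window_matrix_csv",
    "write_feature_csv",
    "write_cv_report_json",
]

DEFAULT_SEGMENT_RATE = 173.61  # Hz, single-channel short-segment convention

PathLike = Union[str, Path]


def read_bonn_ascii(path: PathLike, label: Optional[str] = None,
                    sample_rate: float = DEFAULT_SEGMENT_RATE) -> Signal:
    """Read a one-sample-per-line ASCII segment file into a Signal.

    Blank lines are ignored; any non-numeric line raises with its line number.
    """
    path = Path(path)
    samples = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            token = line.strip()
            if not token:
                continue
            try:
                samples.append(float(token))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {token!r} on line {lineno}"
                ) from None
    if not samples:
        raise ValueError(f"{path}: file contains no samples")
    return Signal(samples=np.array(samples), sample_rate=sample_rate,
                  label=label, source_id=path.name)


def write_bonn_ascii(signal: Signal, path: PathLike) -> None:
    """Write a Signal as one sample per line (full repr precision)."""
    path = Path(path)
    with path.open("w") as fh:
        for v in signal.samples:
            fh.write(f"{float(v)!r}\n")


def read_multichannel_csv(path: PathLike, sample_rate: float,
                          label: Optional[str] = None,
                          delimiter: str = ",") -> list[Signal]:
    """Read a rectangular delimited table as one Signal per column.

    A non-numeric first row is treated as a header of channel names;
    otherwise channels are named ``ch1..chK``.  Ragged rows raise with the
    offending row number.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        rows = [r for r in reader if r]
    if not rows:
        raise ValueError(f"{path}: file contains no data")
    header: Optional[list[str]] = None
    try:
        [float(v) for v in rows[0]]
    except ValueError:
        header = [h.strip() for h in rows[0]]
        rows = rows[1:]
        if not rows:
            raise ValueError(f"{path}: header but no data rows")
    ncol = len(rows[0])
    data = np.empty((len(rows), ncol))
    offset = 2 if header is not None else 1
    for i, r in enumerate(rows):
        if len(r) != ncol:
            raise ValueError(
                f"{path}: ragged row {i + offset}: expected {ncol} fields, "
                f"got {len(r)}"
            )
        try:
            data[i] = [float(v) for v in r]
        except ValueError:
            raise ValueError(
                f"{path}: non-numeric value in row {i + offset}"
            ) from None
    names = header if header is not None else [f"ch{j + 1}" for j in range(ncol)]
    return [
        Signal(samples=data[:, j], sample_rate=sample_rate, label=label,
               source_id=f"{path.name}:{names[j]}")
        for j in range(ncol)
    ]


def write_multichannel_csv(signals: Sequence[Signal], path: PathLike,
                           channel_names: Optional[Sequence[str]] = None) -> None:
    """Write equal-length signals as columns of a CSV with a header row."""
    lengths = {len(s) for s in signals}
    if len(lengths) != 1:
        raise ValueError(f"signals have unequal lengths: {sorted(lengths)}")
    if channel_names is None:
        channel_names = [f"ch{j + 1}" for j in range(len(signals))]
    data = np.column_stack([s.samples for s in signals])
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(channel_names)
        for row in data:
            writer.writerow([repr(float(v)) for v in row])


def write_window_matrix_csv(wm: WindowMatrix, path: PathLike) -> None:
    """Write a window matrix for inspection: one row per window, then
    label / source_id / window_index columns."""
    df = pd.DataFrame(wm.rows,
                      columns=[f"s{j + 1}" for j in range(wm.window_length)])
    df["label"] = [("" if lab is None else lab) for lab in wm.row_labels]
    df["source_id"] = [org[0] for org in wm.row_origins]
    df["window_index"] = [org[1] for org in wm.row_origins]
    df.to_csv(path, index=False)


def write_feature_csv(X: np.ndarray, labels: Sequence, source_ids: Sequence,
                      window_indices: Sequence, path: PathLike) -> None:
    """Write per-window features: source_id, window_index, f1..fd, label."""
    X = np.asarray(X, dtype=float)
    cols: dict = {
        "source_id": list(source_ids),
        "window_index": list(window_indices),
    }
    for j in range(X.shape[1]):
        cols[f"f{j + 1}"] = [repr(float(v)) for v in X[:, j]]
    cols["label"] = [("" if lab is None else lab) for lab in labels]
    pd.DataFrame(cols).to_csv(path, index=False)


def write_cv_report_json(report: CVReport, path: PathLike) -> None:
    Path(path).write_text(report.to_json() + "\n")
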