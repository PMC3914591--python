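"""Core domain containers shared across the package.

A :class:`Signal` is a uniformly sampled one-dimensional amplitude sequence
(e.g. one EEG channel or one recorded segment).  A :class:`WindowMatrix` is
the windows-as-rows embedding of one or more signals: each row is one
length-``l`` window, optionally labelled with the class of the signal it came
from.  Window indices are reported 1-based throughout, matching the usual
convention for moving-window embeddings in the signal-processing literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = ["Signal", "WindowMatrix", "OVERLAPPING", "NONOVERLAPPING"]

OVERLAPPING = "overlapping"
NONOVERLAPPING = "nonoverlapping"


@dataclass
class Signal:
    """A labelled, uniformly sampled 1-D signal.

    Parameters
    ----------
    samples : array-like of float
        Amplitude values in arbitrary units (e.g. µV), in temporal order.
    sample_rate : float
        Sampling rate in samples/second; must be positive.
    label : str, optional
        Class identifier, or ``None`` for an unlabelled (test) signal.
    source_id : str
        Free-text provenance (file name, channel, hour, ...).
    """

    samples: np.ndarray
    sample_rate: float
    label: Optional[str] = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.samples.size < 1:
            raise ValueError("Signal must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(
                f"Signal {self.source_id!r} contains non-finite samples"
            )
        if not (self.sample_rate > 0):
            raise ValueError(f"sample_rate must be > 0, got {self.sample_rate}")

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return len(self) / self.sample_rate


@dataclass
class WindowMatrix:
    """Windows-as-rows embedding of one or more signals.

    ``rows`` is an ``m × l`` matrix whose ``w``-th row holds one window of
    length ``l``.  ``row_labels`` carries the class of the originating signal
    per row (``None`` if unlabelled) and ``row_origins`` records, per row, the
    ``(source_id, window_index)`` pair with a 1-based window index.
    """

    rows: np.ndarray
    window_length: int
    mode: str
    row_labels: list = field(default_factory=list)
    row_origins: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        if self.rows.ndim != 2:
            raise ValueError("rows must be a 2-D matrix")
        if self.rows.shape[1] != self.window_length:
            raise ValueError(
                f"rows have {self.rows.shape[1]} columns but window_length is "
                f"{self.window_length}"
            )
        if self.rows.shape[0] < 1:
            raise ValueError("WindowMatrix needs at least one row")
        if self.mode not in (OVERLAPPING, NONOVERLAPPING):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.row_labels:
            self.row_labels = [None] * self.n_windows
        if not self.row_origins:
            self.row_origins = [("", w + 1) for w in range(self.n_windows)]
        if len(self.row_labels) != self.n_windows:
            raise ValueError("row_labels length must match the number of rows")
        if len(self.row_origins) != self.n_windows:
            raise ValueError("row_origins length must match the number of rows")

    @property
    def n_windows(self) -> int:
        return int(self.rows.shape[0])

    def labels_array(self) -> np.ndarray:
        return np.asarray(self.row_labels, dtype=object)


def as_signals(arrays: Sequence[np.ndarray], sample_rate: float,
               labels: Sequence[Optional[str]],
               source_ids: Sequence[str]) -> list[Signal]:
    """Bundle raw arrays into :class:`Signal` objects (convenience helper)."""
    return [
        Signal(a, sample_rate=sample_rate, label=lab, source_id=sid)
        for a, lab, sid in zip(arrays, labels, source_ids)
    ]
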