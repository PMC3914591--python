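"""Moving-window embeddings of 1-D signals.

Two embeddings are provided.  The *non-overlapping* embedding partitions a
length-``N`` signal into ``m = floor(N / l)`` disjoint consecutive blocks of
length ``l`` — window ``w`` (1-based) covers samples ``(w-1)·l + 1 .. w·l`` —
and is the embedding the classification pipeline uses: rows are far less
cross-correlated than in the classical trajectory matrix, which benefits the
covariance eigendecomposition downstream.  The *overlapping* (Hankel /
trajectory) embedding of singular spectrum analysis, with ``N - l + 1`` rows
shifted by one sample each, is kept for comparison studies of the redundancy
argument.

Training matrices for multiple labelled signals are built by concatenating the
per-signal non-overlapping embeddings and randomly permuting the rows, so that
consecutive windows of one signal are not adjacent in the training matrix.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .types import NONOVERLAPPING, OVERLAPPING, Signal, WindowMatrix

__all__ = [
    "embed_nonoverlapping",
    "embed_overlapping",
    "stack_training_matrix",
]

logger = logging.getLogger(__name__)


def _check_window_length(window_length: int, n_samples: int) -> None:
    if not isinstance(window_length, (int, np.integer)) or isinstance(window_length, bool):
        raise TypeError(f"window_length must be an integer, got {window_length!r}")
    if window_length < 1 or window_length > n_samples:
        raise ValueError(
            f"window_length must be in [1, {n_samples}] (signal length), "
            f"got {window_length}"
        )


def embed_nonoverlapping(signal: Signal, window_length: int) -> WindowMatrix:
    """Partition ``signal`` into consecutive disjoint windows of ``window_length``.

    Returns a matrix with ``m = floor(N / l)`` rows; any trailing ``N mod l``
    samples are discarded (with a logged warning), since the embedding assumes
    the signal length is a whole number of windows.
    """
    l = int(window_length)
    n = len(signal)
    _check_window_length(l, n)
    m = n // l
    tail = n - m * l
    if tail:
        logger.warning(
            "discarding %d trailing samples of %r (N=%d not divisible by l=%d)",
            tail, signal.source_id, n, l,
        )
    rows = signal.samples[: m * l].reshape(m, l)
    return WindowMatrix(
        rows=rows,
        window_length=l,
        mode=NONOVERLAPPING,
        row_labels=[signal.label] * m,
        row_origins=[(signal.source_id, w + 1) for w in range(m)],
    )


def embed_overlapping(signal: Signal, window_length: int) -> WindowMatrix:
    """Build the Hankel trajectory matrix: all ``N - l + 1`` unit-shift windows."""
    l = int(window_length)
    n = len(signal)
    _check_window_length(l, n)
    m = n - l + 1
    rows = np.lib.stride_tricks.sliding_window_view(signal.samples, l).copy()
    assert rows.shape == (m, l)
    return WindowMatrix(
        rows=rows,
        window_length=l,
        mode=OVERLAPPING,
        row_labels=[signal.label] * m,
        row_origins=[(signal.source_id, w + 1) for w in range(m)],
    )


def stack_training_matrix(signals: Sequence[Signal], window_length: int,
                          shuffle_seed: int) -> WindowMatrix:
    """Stack non-overlapping embeddings of labelled signals into one matrix.

    All signals are embedded with :func:`embed_nonoverlapping`, concatenated,
    and the rows randomly permuted with ``shuffle_seed`` so that windows of
    one signal are scattered through the matrix.  Labels and origins travel
    with their rows.  At least two distinct labels are required, since the
    matrix exists to train a classifier.
    """
    if not signals:
        raise ValueError("no signals given")
    labels = {s.label for s in signals}
    if len(labels) < 2:
        raise ValueError("classification requires >= 2 groups "
                         f"(got labels {sorted(map(str, labels))})")
    parts = [embed_nonoverlapping(s, window_length) for s in signals]
    rows = np.vstack([p.rows for p in parts])
    row_labels = [lab for p in parts for lab in p.row_labels]
    row_origins = [org for p in parts for org in p.row_origins]
    rng = np.random.default_rng(shuffle_seed)
    perm = rng.permutation(rows.shape[0])
    return WindowMatrix(
        rows=rows[perm],
        window_length=int(window_length),
        mode=NONOVERLAPPING,
        row_labels=[row_labels[i] for i in perm],
        row_origins=[row_origins[i] for i in perm],
    )
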