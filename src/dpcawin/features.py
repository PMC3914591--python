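"""Per-window feature vectors: FFPC and PCPEM schemes.

FFPC ("first few principal components") keeps only the leading PC scores of a
window — by default the first three, giving a 3-D feature vector.  PCPEM
("PCs plus energy measure") replaces the last retained score with the window's
energy in PC space,

    E(w) = sum_{v=1}^{t} score_v(w)^2,

by default the first two scores plus the energy, again 3-D.  The energy sum is
truncated at ``t = floor(l/2)`` by default; with ``t = l`` it equals the
squared Euclidean norm of the centred window (Parseval), and it is invariant
to the eigenvector sign convention.  Energy carries squared-amplitude units
while scores carry amplitude units, so PCPEM vectors are usually z-scored
before nearest-neighbour classification (see :mod:`dpcawin.classify`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .pca import ProjectedWindow

__all__ = [
    "FFPC",
    "PCPEM",
    "FeatureVector",
    "EnergyMeasure",
    "ffpc_features",
    "energy_measure",
    "pcpem_features",
    "default_truncation",
]

FFPC = "FFPC"
PCPEM = "PCPEM"

DEFAULT_N_COMPONENTS = 3  # FFPC: PCs 1-3
DEFAULT_N_PCS = 2         # PCPEM: PCs 1-2 + energy


@dataclass
class FeatureVector:
    """Low-dimensional descriptor of one window under one scheme."""

    values: np.ndarray
    scheme: str
    window_index: int = 0
    source_id: str = ""
    label: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size < 1:
            raise ValueError("feature vector must have at least one entry")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")
        if self.scheme not in (FFPC, PCPEM):
            raise ValueError(f"unknown scheme {self.scheme!r}")


@dataclass
class EnergyMeasure:
    """PC-space energy of one window: sum of the first ``truncation`` squared scores."""

    value: float
    truncation: int


def default_truncation(window_length: int) -> int:
    """Half the window length: sufficient in practice for a discriminative energy."""
    return max(1, window_length // 2)


def _check_range(name: str, value: int, upper: int) -> None:
    if not 1 <= value <= upper:
        raise ValueError(f"{name} must be in [1, {upper}], got {value}")


def ffpc_features(projected: ProjectedWindow,
                  n_components: int = DEFAULT_N_COMPONENTS) -> FeatureVector:
    """First ``n_components`` PC scores of the window, in PC order."""
    l = projected.scores.size
    _check_range("n_components", n_components, l)
    return FeatureVector(
        values=projected.scores[:n_components],
        scheme=FFPC,
        window_index=projected.window_index,
        source_id=projected.source_id,
    )


def energy_measure(projected: ProjectedWindow,
                   truncation: Optional[int] = None) -> EnergyMeasure:
    l = projected.scores.size
    if truncation is None:
        truncation = default_truncation(l)
    _check_range("truncation", truncation, l)
    value = float(np.sum(projected.scores[:truncation] ** 2))
    return EnergyMeasure(value=value, truncation=truncation)


def pcpem_features(projected: ProjectedWindow,
                   n_pcs: int = DEFAULT_N_PCS,
                   truncation: Optional[int] = None) -> FeatureVector:
    """First ``n_pcs`` scores concatenated with the truncated PC-space energy."""
    l = projected.scores.size
    _check_range("n_pcs", n_pcs, l)
    e = energy_measure(projected, truncation)
    return FeatureVector(
        values=np.concatenate([projected.scores[:n_pcs], [e.value]]),
        scheme=PCPEM,
        window_index=projected.window_index,
        source_id=projected.source_id,
    )


# ---------------------------------------------------------------------------
# vectorised variants used by the evaluation pipeline

def ffpc_matrix(scores: np.ndarray, n_components: int = DEFAULT_N_COMPONENTS) -> np.ndarray:
    """FFPC features for an ``(n, l)`` score matrix; returns ``(n, n_components)``."""
    _check_range("n_components", n_components, scores.shape[1])
    return scores[:, :n_components].copy()


def pcpem_matrix(scores: np.ndarray, n_pcs: int = DEFAULT_N_PCS,
                 truncation: Optional[int] = None) -> np.ndarray:
    """PCPEM features for an ``(n, l)`` score matrix; returns ``(n, n_pcs + 1)``."""
    l = scores.shape[1]
    _check_range("n_pcs", n_pcs, l)
    if truncation is None:
        truncation = default_truncation(l)
    _check_range("truncation", truncation, l)
    energy = np.sum(scores[:, :truncation] ** 2, axis=1, keepdims=True)
    return np.hstack([scores[:, :n_pcs], energy])


def energy_matrix(scores: np.ndarray, truncation: Optional[int] = None) -> np.ndarray:
    """Energy-only 1-D feature for an ``(n, l)`` score matrix; returns ``(n, 1)``."""
    l = scores.shape[1]
    if truncation is None:
        truncation = default_truncation(l)
    _check_range("truncation", truncation, l)
    return np.sum(scores[:, :truncation] ** 2, axis=1, keepdims=True)
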