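"""1-NN classification of window features and k-fold cross-validated accuracy.

The classifier is deliberately minimal: a query window receives the label of
its nearest training window under Euclidean distance, with ties broken by the
smallest training-set index.  Accuracy is estimated by stratified k-fold
cross-validation over windows; the reported score is the fraction of all
held-out windows (all classes pooled) that are correctly labelled, aggregated
as mean ± standard deviation over folds.

:func:`evaluate_pipeline` runs the full chain — non-overlapping embedding,
PCA, feature scheme, 1-NN — with the PCA model refitted inside each fold on
the training-fold windows only, so held-out windows never influence the basis
they are projected onto.  A per-segment majority-vote accuracy (one vote per
source signal) is computed as a secondary metric.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold

from . import features as feat
from .pca import fit_pca, project_rows
from .types import NONOVERLAPPING, Signal, WindowMatrix
from .windowing import embed_nonoverlapping

__all__ = [
    "LabeledFeatureSet",
    "CVReport",
    "predict_1nn",
    "kfold_accuracy",
    "evaluate_pipeline",
    "energy_baseline",
]


@dataclass
class LabeledFeatureSet:
    """A bag of same-scheme, same-dimension feature vectors with labels."""

    X: np.ndarray          # (n, d)
    labels: np.ndarray     # (n,) object array of class identifiers
    scheme: str
    source_ids: Optional[np.ndarray] = None  # (n,) provenance, optional

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (n_vectors, d)")
        self.labels = np.asarray(self.labels, dtype=object).ravel()
        if self.labels.size != self.X.shape[0]:
            raise ValueError("labels length must match number of vectors")
        if self.source_ids is not None:
            self.source_ids = np.asarray(self.source_ids, dtype=object).ravel()

    @classmethod
    def from_vectors(cls, vectors: Sequence[feat.FeatureVector]) -> "LabeledFeatureSet":
        if not vectors:
            raise ValueError("no feature vectors given")
        schemes = {v.scheme for v in vectors}
        if len(schemes) != 1:
            raise ValueError(f"mixed schemes in one feature set: {sorted(schemes)}")
        dims = {v.values.size for v in vectors}
        if len(dims) != 1:
            raise ValueError(f"mixed dimensions in one feature set: {sorted(dims)}")
        return cls(
            X=np.vstack([v.values for v in vectors]),
            labels=np.array([v.label for v in vectors], dtype=object),
            scheme=vectors[0].scheme,
            source_ids=np.array([v.source_id for v in vectors], dtype=object),
        )

    @property
    def d(self) -> int:
        return int(self.X.shape[1])


@dataclass
class CVReport:
    """Per-fold and aggregated cross-validation accuracy.

    ``mean_accuracy`` and ``sd_accuracy`` (sample standard deviation, ddof=1)
    are recomputable from ``fold_accuracies``.  ``confusion_totals`` maps each
    true label to correct/incorrect window counts summed over all folds.
    ``config_echo`` records every parameter that determined the run.
    """

    fold_accuracies: list
    mean_accuracy: float
    sd_accuracy: float
    confusion_totals: dict
    config_echo: dict
    segment_fold_accuracies: list = field(default_factory=list)

    @classmethod
    def from_folds(cls, fold_accuracies: Sequence[float], confusion: dict,
                   config_echo: dict,
                   segment_fold_accuracies: Sequence[float] = ()) -> "CVReport":
        accs = [float(a) for a in fold_accuracies]
        return cls(
            fold_accuracies=accs,
            mean_accuracy=float(np.mean(accs)),
            sd_accuracy=float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
            confusion_totals=confusion,
            config_echo=dict(config_echo),
            segment_fold_accuracies=[float(a) for a in segment_fold_accuracies],
        )

    def to_json(self) -> str:
        payload = {
            "fold_accuracies": self.fold_accuracies,
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "confusion_totals": self.confusion_totals,
            "config_echo": self.config_echo,
            "segment_fold_accuracies": self.segment_fold_accuracies,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def to_csv_row(self) -> dict:
        """Flat one-row mapping for assembling results tables across runs."""
        row = {
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
        }
        row.update({f"fold_{i + 1}": a for i, a in enumerate(self.fold_accuracies)})
        row.update(self.config_echo)
        return row


# ---------------------------------------------------------------------------
# 1-NN

def _predict_batch(X_train: np.ndarray, y_train: np.ndarray,
                   X_query: np.ndarray) -> np.ndarray:
    """Nearest-neighbour labels for each query row.

    argmin over the distance matrix returns the earliest index on ties,
    which is the documented deterministic tie-break.
    """
    d = cdist(X_query, X_train, metric="euclidean")
    nearest = np.argmin(d, axis=1)
    return y_train[nearest]


def predict_1nn(train: LabeledFeatureSet, query: feat.FeatureVector):
    """Label of the training vector nearest to ``query`` (Euclidean)."""
    if train.X.shape[0] == 0:
        raise ValueError("empty training set")
    q = np.asarray(query.values, dtype=float).ravel()
    if q.size != train.d:
        raise ValueError(
            f"query has dimension {q.size} but training set has {train.d}"
        )
    return _predict_batch(train.X, train.labels, q[None, :])[0]


# ---------------------------------------------------------------------------
# cross-validation

def _standardizer(X_train: np.ndarray):
    """Per-dimension z-scoring fitted on training features only."""
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return lambda X: (X - mu) / sd


def _check_fold_feasibility(labels: np.ndarray, k: int) -> None:
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    uniq, counts = np.unique(labels.astype(str), return_counts=True)
    if uniq.size < 2:
        raise ValueError("classification requires >= 2 groups")
    short = counts < k
    if short.any():
        bad = {u: int(c) for u, c in zip(uniq[short], counts[short])}
        raise ValueError(
            f"labels with fewer than k={k} members: {bad}; use a smaller k"
        )


def _confusion_update(confusion: dict, y_true: np.ndarray,
                      y_pred: np.ndarray) -> None:
    for t, p in zip(y_true, y_pred):
        entry = confusion.setdefault(str(t), {"correct": 0, "incorrect": 0})
        entry["correct" if t == p else "incorrect"] += 1


def kfold_accuracy(features: LabeledFeatureSet, k: int, seed: int,
                   standardize: bool = False) -> CVReport:
    """Stratified k-fold 1-NN accuracy of a pre-computed feature set.

    Folds partition the windows (every window in exactly one test fold),
    stratified by label, shuffled with ``seed``.  Standardization, if on, is
    fitted on the training folds only.
    """
    _check_fold_feasibility(features.labels, k)
    y = features.labels
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_accs = []
    confusion: dict = {}
    for train_idx, test_idx in skf.split(features.X, y.astype(str)):
        Xtr, Xte = features.X[train_idx], features.X[test_idx]
        if standardize:
            z = _standardizer(Xtr)
            Xtr, Xte = z(Xtr), z(Xte)
        pred = _predict_batch(Xtr, y[train_idx], Xte)
        fold_accs.append(float(np.mean(pred == y[test_idx])))
        _confusion_update(confusion, y[test_idx], pred)
    echo = {
        "scheme": features.scheme,
        "d": features.d,
        "k": k,
        "seed": seed,
        "standardize": bool(standardize),
    }
    return CVReport.from_folds(fold_accs, confusion, echo)


def _fold_features(rows: np.ndarray, train_idx: np.ndarray,
                   test_idx: np.ndarray, window_length: int, scheme: str,
                   n_components: int, n_pcs: int,
                   truncation: Optional[int]):
    """Fit PCA on training-fold rows, derive scheme features for both splits."""
    train_wm = WindowMatrix(rows=rows[train_idx], window_length=window_length,
                            mode=NONOVERLAPPING)
    model = fit_pca(train_wm)
    s_train = project_rows(model, rows[train_idx])
    s_test = project_rows(model, rows[test_idx])
    if scheme == feat.FFPC:
        return feat.ffpc_matrix(s_train, n_components), feat.ffpc_matrix(s_test, n_components)
    if scheme == feat.PCPEM:
        return (feat.pcpem_matrix(s_train, n_pcs, truncation),
                feat.pcpem_matrix(s_test, n_pcs, truncation))
    if scheme == "ENERGY":
        return (feat.energy_matrix(s_train, truncation),
                feat.energy_matrix(s_test, truncation))
    raise ValueError(f"unknown scheme {scheme!r}")


def _segment_majority(y_true, y_pred, sources) -> float:
    """Fraction of segments whose window-vote majority label is correct."""
    correct = total = 0
    for sid in np.unique(sources.astype(str)):
        mask = sources.astype(str) == sid
        preds, counts = np.unique(y_pred[mask].astype(str), return_counts=True)
        voted = preds[np.argmax(counts)]  # earliest label wins ties
        correct += int(voted == str(y_true[mask][0]))
        total += 1
    return correct / total


def _run_windowed_cv(signals: Sequence[Signal], window_length: int,
                     scheme: str, k: int, seed: int,
                     n_components: int, n_pcs: int,
                     truncation: Optional[int],
                     standardize: Optional[bool]) -> CVReport:
    if standardize is None:
        standardize = scheme == feat.PCPEM  # energy units dominate otherwise
    parts = [embed_nonoverlapping(s, window_length) for s in signals]
    rows = np.vstack([p.rows for p in parts])
    labels = np.array([lab for p in parts for lab in p.row_labels], dtype=object)
    sources = np.array([org[0] for p in parts for org in p.row_origins],
                       dtype=object)
    _check_fold_feasibility(labels, k)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_accs, seg_accs = [], []
    confusion: dict = {}
    for train_idx, test_idx in skf.split(rows, labels.astype(str)):
        Xtr, Xte = _fold_features(rows, train_idx, test_idx, window_length,
                                  scheme, n_components, n_pcs, truncation)
        if standardize:
            z = _standardizer(Xtr)
            Xtr, Xte = z(Xtr), z(Xte)
        pred = _predict_batch(Xtr, labels[train_idx], Xte)
        fold_accs.append(float(np.mean(pred == labels[test_idx])))
        seg_accs.append(_segment_majority(labels[test_idx], pred,
                                          sources[test_idx]))
        _confusion_update(confusion, labels[test_idx], pred)
    d = {feat.FFPC: n_components, feat.PCPEM: n_pcs + 1, "ENERGY": 1}[scheme]
    echo = {
        "window_length": int(window_length),
        "scheme": scheme,
        "d": d,
        "n_components": n_components if scheme == feat.FFPC else None,
        "n_pcs": n_pcs if scheme == feat.PCPEM else None,
        "truncation": (truncation if truncation is not None
                       else feat.default_truncation(window_length)),
        "k": k,
        "seed": seed,
        "standardize": bool(standardize),
    }
    return CVReport.from_folds(fold_accs, confusion, echo, seg_accs)


def evaluate_pipeline(signals: Sequence[Signal], window_length: int,
                      scheme: str, k: int = 10, seed: int = 0,
                      n_components: int = feat.DEFAULT_N_COMPONENTS,
                      n_pcs: int = feat.DEFAULT_N_PCS,
                      truncation: Optional[int] = None,
                      standardize: Optional[bool] = None) -> CVReport:
    """End-to-end cross-validated accuracy of the windowed DPCA pipeline.

    Signals are embedded with non-overlapping windows; within each fold the
    PCA basis is fitted on the training-fold windows only, features of both
    splits are derived from that basis, and 1-NN accuracy is measured on the
    held-out windows.  ``standardize`` defaults to on for PCPEM (mixed units)
    and off for FFPC.
    """
    if scheme not in (feat.FFPC, feat.PCPEM):
        raise ValueError(f"scheme must be {feat.FFPC!r} or {feat.PCPEM!r}, "
                         f"got {scheme!r}")
    return _run_windowed_cv(signals, window_length, scheme, k, seed,
                            n_components, n_pcs, truncation, standardize)


def energy_baseline(signals: Sequence[Signal], window_length: int,
                    k: int = 10, seed: int = 0,
                    truncation: Optional[int] = None) -> CVReport:
    """Diagnostic 1-D baseline: 1-NN on the PC-space energy alone.

    Useful as a contrast when classes differ in spectral structure but not in
    power — the energy coordinate then carries no class information.
    """
    return _run_windowed_cv(signals, window_length, "ENERGY", k, seed,
                            n_components=1, n_pcs=1, truncation=truncation,
                            standardize=False)
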