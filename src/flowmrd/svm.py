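"""Per-patient RBF-SVM: (C, γ) grid search, model fit, MRD prediction.

A soft-margin binary SVM with radial-basis-function kernel
``K(u, v) = exp(-γ ||u - v||²)`` is trained per patient on the scaled
training set (diagnosis blasts = 1, pooled donors = 0).  (C, γ) are chosen
by exhaustive search over a log2 lattice, scoring each pair by k-fold
cross-validated classification accuracy with seeded, label-stratified fold
assignment; ties go to the smaller C (better generalization), then the
smaller γ.  MRD on a follow-up specimen is quantified as the percentage of
events the model classifies leukemic.

The fitted classifier is reduced to its support vectors, dual coefficients
and intercept, so a trained :class:`PatientModel` is self-contained: it
embeds the scaling range and predicts with a plain kernel evaluation that
is identical before and after text serialization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .fcs import EventMatrix
from .training import ScalingRange, TrainingSet, apply_scaling

_MODEL_MAGIC = "flowmrd-model-v1"


@dataclass(frozen=True)
class GridSearchConfig:
    """Log2 lattice and cross-validation settings for the (C, γ) search.

    Defaults span C = 2^-5 … 2^15 and γ = 2^3 … 2^-15 in log2 steps of 2,
    wide enough to contain optima from heavily regularized to nearly
    hard-margin fits; 5 folds.
    """

    log2C: tuple[float, float, float] = (-5, 15, 2)
    log2gamma: tuple[float, float, float] = (3, -15, -2)
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.log2C[2] == 0 or self.log2gamma[2] == 0:
            raise ValueError("grid steps must be nonzero")
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")

    @staticmethod
    def _lattice(start: float, stop: float, step: float) -> np.ndarray:
        n = int(np.floor((stop - start) / step + 1e-9)) + 1
        if n < 1:
            raise ValueError(f"empty lattice ({start}, {stop}, {step})")
        return start + step * np.arange(n)

    def c_values(self) -> np.ndarray:
        return 2.0 ** self._lattice(*self.log2C)

    def gamma_values(self) -> np.ndarray:
        return 2.0 ** self._lattice(*self.log2gamma)


@dataclass(frozen=True)
class ModelParams:
    """Chosen kernel parameters and the CV accuracy that selected them."""

    C: float
    gamma: float
    cv_accuracy: float  # percent in [0, 100]

    def __post_init__(self) -> None:
        if not self.C > 0 or not self.gamma > 0:
            raise ValueError("C and gamma must be positive")


def stratified_folds(flags: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Assign each event a fold id in [0, n_folds), stratified by label.

    Within each label the (seeded) shuffled indices are dealt round-robin,
    so every fold sees both labels whenever each label has >= n_folds
    events.  Deterministic given (flags, n_folds, seed).
    """
    rng = np.random.default_rng(seed)
    fold = np.empty(len(flags), dtype=np.int64)
    for lab in np.unique(flags):
        idx = np.flatnonzero(flags == lab)
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % n_folds
    return fold


def cv_accuracy(features: np.ndarray, flags: np.ndarray, C: float, gamma: float,
                folds: np.ndarray) -> float:
    """K-fold cross-validated accuracy (percent) of an RBF-SVM at (C, γ).

    Accuracy is pooled over folds (total correct / total events), matching
    the classic cross-validation accuracy a grid search reports.
    """
    correct = 0
    for k in np.unique(folds):
        test = folds == k
        clf = SVC(C=C, gamma=gamma, kernel="rbf", cache_size=256)
        clf.fit(features[~test], flags[~test])
        correct += int((clf.predict(features[test]) == flags[test]).sum())
    return 100.0 * correct / len(flags)


def grid_search(ts: TrainingSet, cfg: GridSearchConfig = GridSearchConfig()) -> ModelParams:
    """Exhaustive (C, γ) search maximizing cross-validated accuracy.

    The training set must already be scaled and contain both labels.  Fold
    assignment is fixed across the whole lattice so grid points are compared
    on identical splits.  Ties are broken toward smaller C, then smaller γ.
    """
    labs = np.unique(ts.flags)
    if len(labs) < 2:
        raise ValueError("grid search needs both labels (0 and 1) present")
    if ts.n < cfg.n_folds:
        raise ValueError(f"only {ts.n} events for {cfg.n_folds} folds")
    folds = stratified_folds(ts.flags, cfg.n_folds, cfg.seed)
    best: ModelParams | None = None
    for C in np.sort(cfg.c_values()):
        for gamma in np.sort(cfg.gamma_values()):
            acc = cv_accuracy(ts.features, ts.flags, float(C), float(gamma), folds)
            if best is None or acc > best.cv_accuracy:
                best = ModelParams(C=float(C), gamma=float(gamma), cv_accuracy=acc)
    assert best is not None
    return best


@dataclass
class PatientModel:
    """An individual-specific classifier with its embedded scaling range.

    Prediction is ``sign(Σ_i a_i K(sv_i, x) + b)`` over the stored support
    vectors — deterministic, self-contained, and identical across
    save/load.
    """

    params: ModelParams
    range: ScalingRange
    channels: list[str]
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float

    def __post_init__(self) -> None:
        if len(self.channels) != self.range.n_channels:
            raise ValueError("channel list must match scaling-range dimensionality")
        if self.support_vectors.shape[1] != len(self.channels):
            raise ValueError("support vectors must match channel count")

    def decision_function(self, X_scaled: np.ndarray) -> np.ndarray:
        """Signed distance to the separating surface, positive = leukemic."""
        out = np.empty(len(X_scaled))
        chunk = 16384
        sv = self.support_vectors
        sv_sq = np.einsum("ij,ij->i", sv, sv)
        for a in range(0, len(X_scaled), chunk):
            x = X_scaled[a : a + chunk]
            d2 = (
                np.einsum("ij,ij->i", x, x)[:, None] + sv_sq[None, :] - 2.0 * x @ sv.T
            )
            K = np.exp(-self.params.gamma * np.clip(d2, 0.0, None))
            out[a : a + chunk] = K @ self.dual_coef + self.intercept
        return out

    def predict(self, X_scaled: np.ndarray) -> np.ndarray:
        """Per-event label in {0, 1} on already-scaled features."""
        return (self.decision_function(X_scaled) > 0).astype(np.int64)


def train_model(ts: TrainingSet, params: ModelParams, rng: ScalingRange,
                channels: Sequence[str] | None = None) -> PatientModel:
    """Fit the soft-margin RBF-SVM at (C, γ) on the scaled training set."""
    if len(np.unique(ts.flags)) < 2:
        raise ValueError("training needs both labels (0 and 1) present")
    if not np.isfinite(ts.features).all():
        raise ValueError("training features must be finite")
    clf = SVC(C=params.C, gamma=params.gamma, kernel="rbf", cache_size=512)
    clf.fit(ts.features, ts.flags)
    # libsvm orders binary classes [0, 1]: decision > 0 predicts class 1
    assert list(clf.classes_) == [0, 1]
    return PatientModel(
        params=params,
        range=rng,
        channels=list(channels if channels is not None else ts.channels),
        support_vectors=np.asarray(clf.support_vectors_, dtype=np.float64),
        dual_coef=np.asarray(clf.dual_coef_[0], dtype=np.float64),
        intercept=float(clf.intercept_[0]),
    )


@dataclass
class MRDResult:
    """Per-event predictions and the residual leukemic-cell percentage."""

    labels: np.ndarray
    leukemic_fraction: float  # percent
    n_events: int

    def __post_init__(self) -> None:
        recomputed = 100.0 * float(np.sum(self.labels == 1)) / max(self.n_events, 1)
        if abs(recomputed - self.leukemic_fraction) > 1e-9:
            raise ValueError("leukemic_fraction inconsistent with labels")


def predict_mrd(model: PatientModel, specimen: EventMatrix) -> MRDResult:
    """Quantify MRD as the percentage of specimen events classified leukemic.

    The specimen is restricted to the model's channels, scaled with the
    embedded saved range, and classified event by event.
    """
    if specimen.n_events == 0:
        raise ValueError(f"specimen {specimen.specimen_id!r} has no events")
    X = specimen.select(model.channels)
    labels = model.predict(apply_scaling(X, model.range))
    frac = 100.0 * float(labels.sum()) / len(labels)
    return MRDResult(labels=labels, leukemic_fraction=frac, n_events=len(labels))


def render_prediction(specimen: EventMatrix, result: MRDResult,
                      channel_pair: tuple[str, str]) -> pd.DataFrame:
    """Scatter-plot table of (x, y, label) triples on raw intensities.

    Label 1 marks predicted leukemic events (conventionally drawn red) and
    0 normal events (blue); columns are the requested channels' original,
    unscaled intensities.
    """
    x_name, y_name = channel_pair
    return pd.DataFrame({
        x_name: specimen.column(x_name),
        y_name: specimen.column(y_name),
        "label": result.labels,
    })


# ---------------------------------------------------------------------------
# Versioned text persistence

def save_model(model: PatientModel, path: str | Path) -> Path:
    doc = {
        "format": _MODEL_MAGIC,
        "params": {"C": model.params.C, "gamma": model.params.gamma,
                   "cv_accuracy": model.params.cv_accuracy},
        "range": {"mins": list(model.range.mins), "maxs": list(model.range.maxs),
                  "lo": model.range.lo, "hi": model.range.hi},
        "channels": model.channels,
        "support_vectors": model.support_vectors.tolist(),
        "dual_coef": model.dual_coef.tolist(),
        "intercept": model.intercept,
    }
    Path(path).write_text(json.dumps(doc))
    return Path(path)


def load_model(path: str | Path) -> PatientModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != _MODEL_MAGIC:
        raise ValueError(f"{path}: not a flowmrd model file")
    return PatientModel(
        params=ModelParams(**doc["params"]),
        range=ScalingRange(mins=tuple(doc["range"]["mins"]),
                           maxs=tuple(doc["range"]["maxs"]),
                           lo=doc["range"]["lo"], hi=doc["range"]["hi"]),
        channels=list(doc["channels"]),
        support_vectors=np.array(doc["support_vectors"], dtype=np.float64),
        dual_coef=np.array(doc["dual_coef"], dtype=np.float64),
        intercept=float(doc["intercept"]),
    )
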