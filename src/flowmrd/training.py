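"""Per-patient training-set assembly, stratified subsampling, and range scaling.

The training set for a patient's individual model is the vertical
concatenation of the diagnosis blast events (flag 1, leukemic) and pooled
healthy-donor events (flag 0, normal), restricted to the configured feature
channels.  Because SVM training time grows with training size, the set is
subsampled to 10^4 events by stratified random sampling; strata are the
source files (patient + each donor), which preserves the leukemic:normal
ratio and donor balance.  Per-stratum quotas are the exact largest-remainder
apportionment of the target size by stratum size.

Scaling mirrors the classic ``svm-scale`` workflow: per-channel (min, max)
are fitted on the training features, mapped affinely onto a target interval
(default [-1, 1]), persisted as a plain-text range file, and re-applied
unchanged to follow-up specimens at prediction time.  Out-of-range test
values extrapolate linearly — no clipping — so the transform stays affine
and invertible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .fcs import EventMatrix
from .synth import largest_remainder

_RANGE_MAGIC = "# flowmrd range v1"
_TRAIN_MAGIC = "# flowmrd training v1"


@dataclass
class TrainingSet:
    """Labeled training events: features, 0/1 flags, and per-event source files."""

    features: np.ndarray
    flags: np.ndarray
    sources: np.ndarray
    channels: list[str]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.flags = np.asarray(self.flags, dtype=np.int64)
        self.sources = np.asarray(self.sources, dtype=object)
        n = len(self.features)
        if len(self.flags) != n or len(self.sources) != n:
            raise ValueError("features, flags and sources must have equal length")
        if not np.isin(self.flags, (0, 1)).all():
            raise ValueError("flags must be 0 (normal) or 1 (leukemic)")

    @property
    def n(self) -> int:
        return len(self.features)


@dataclass(frozen=True)
class ScalingRange:
    """Per-channel training (min, max) plus the affine target interval."""

    mins: tuple[float, ...]
    maxs: tuple[float, ...]
    lo: float = -1.0
    hi: float = 1.0

    def __post_init__(self) -> None:
        if len(self.mins) != len(self.maxs):
            raise ValueError("mins and maxs must have equal length")
        if any(a > b for a, b in zip(self.mins, self.maxs)):
            raise ValueError("each channel must satisfy min <= max")
        if not self.lo < self.hi:
            raise ValueError("target interval requires lo < hi")

    @property
    def n_channels(self) -> int:
        return len(self.mins)


def build_training_set(blasts: EventMatrix, donors: Sequence[EventMatrix],
                       channels: Sequence[str]) -> TrainingSet:
    """Assemble the labeled training set: diagnosis blasts = 1, donor events = 0.

    Feature columns follow the requested channel order regardless of each
    source file's own column order.  Raises ``KeyError`` naming the file and
    channel if any input lacks a requested channel.
    """
    if blasts.n_events == 0:
        raise ValueError("blast matrix is empty; a training set needs leukemic events")
    donors = list(donors)
    if not donors or all(d.n_events == 0 for d in donors):
        raise ValueError("need at least one nonempty donor specimen")
    channels = list(channels)
    feats = [blasts.select(channels)]
    flags = [np.ones(blasts.n_events, dtype=np.int64)]
    sources = [np.full(blasts.n_events, blasts.specimen_id or "blasts", dtype=object)]
    for k, d in enumerate(donors):
        feats.append(d.select(channels))
        flags.append(np.zeros(d.n_events, dtype=np.int64))
        sources.append(np.full(d.n_events, d.specimen_id or f"donor-{k}", dtype=object))
    return TrainingSet(features=np.vstack(feats), flags=np.concatenate(flags),
                       sources=np.concatenate(sources), channels=channels)


def stratified_sample(ts: TrainingSet, n: int, seed: int) -> TrainingSet:
    """Subsample ``n`` events by stratified random sampling over source files.

    Per-stratum quotas are the largest-remainder apportionment of ``n`` by
    stratum size; events within each stratum are drawn uniformly without
    replacement.  When ``n`` is at least the total size the set is returned
    unchanged (original order).
    """
    strata, first = np.unique(ts.sources, return_index=True)
    strata = strata[np.argsort(first)]  # order of first appearance
    if n < len(strata):
        raise ValueError(f"n={n} is smaller than the number of strata ({len(strata)})")
    if n >= ts.n:
        return ts
    sizes = np.array([(ts.sources == s).sum() for s in strata])
    quotas = largest_remainder(sizes, n)
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    for s, q in zip(strata, quotas):
        idx = np.flatnonzero(ts.sources == s)
        chosen.append(rng.choice(idx, size=int(q), replace=False))
    keep = np.sort(np.concatenate(chosen))
    return TrainingSet(features=ts.features[keep], flags=ts.flags[keep],
                       sources=ts.sources[keep], channels=list(ts.channels))


def fit_scaling(ts: TrainingSet, lo: float = -1.0, hi: float = 1.0) -> ScalingRange:
    """Fit per-channel (min, max) on the training features."""
    if ts.n == 0:
        raise ValueError("cannot fit a scaling range on an empty training set")
    return ScalingRange(mins=tuple(ts.features.min(axis=0)),
                        maxs=tuple(ts.features.max(axis=0)), lo=lo, hi=hi)


def apply_scaling(X: np.ndarray, rng: ScalingRange) -> np.ndarray:
    """Map features affinely onto the target interval using the saved range.

    ``x' = lo + (hi - lo) * (x - min) / (max - min)`` per channel; values
    outside the training range extrapolate linearly (no clipping); a
    degenerate channel (min == max) maps to ``lo``.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != rng.n_channels:
        raise ValueError(
            f"feature matrix has {X.shape[1] if X.ndim == 2 else '?'} columns, "
            f"range has {rng.n_channels}"
        )
    mins = np.asarray(rng.mins)
    span = np.asarray(rng.maxs) - mins
    out = np.full_like(X, rng.lo, dtype=np.float64)
    ok = span > 0
    out[:, ok] = rng.lo + (rng.hi - rng.lo) * (X[:, ok] - mins[ok]) / span[ok]
    return out


def invert_scaling(Xs: np.ndarray, rng: ScalingRange) -> np.ndarray:
    """Invert :func:`apply_scaling` on channels with min < max."""
    mins = np.asarray(rng.mins)
    span = np.asarray(rng.maxs) - mins
    out = np.asarray(Xs, dtype=np.float64).copy()
    ok = span > 0
    out[:, ok] = mins[ok] + (out[:, ok] - rng.lo) * span[ok] / (rng.hi - rng.lo)
    out[:, ~ok] = mins[~ok]
    return out


# ---------------------------------------------------------------------------
# Plain-text persistence (range file and training file)

def save_range(rng: ScalingRange, path: str | Path) -> Path:
    path = Path(path)
    lines = [_RANGE_MAGIC, f"target {rng.lo:.17g} {rng.hi:.17g}"]
    for i, (a, b) in enumerate(zip(rng.mins, rng.maxs), start=1):
        lines.append(f"{i} {a:.17g} {b:.17g}")
    path.write_text("\n".join(lines) + "\n")
    return path


def load_range(path: str | Path) -> ScalingRange:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].strip() != _RANGE_MAGIC:
        raise ValueError(f"{path}: not a flowmrd range file")
    _, lo, hi = lines[1].split()
    mins, maxs = [], []
    for ln in lines[2:]:
        if not ln.strip():
            continue
        _, a, b = ln.split()
        mins.append(float(a))
        maxs.append(float(b))
    return ScalingRange(mins=tuple(mins), maxs=tuple(maxs), lo=float(lo), hi=float(hi))


def save_training(ts: TrainingSet, path: str | Path) -> Path:
    """Persist a training set as label + indexed features (sparse text rows)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_TRAIN_MAGIC + "\n")
        fh.write("# channels " + ",".join(ts.channels) + "\n")
        for flag, row, src in zip(ts.flags, ts.features, ts.sources):
            feats = " ".join(f"{j + 1}:{v:.17g}" for j, v in enumerate(row))
            fh.write(f"{flag} {feats} # {src}\n")
    return path


def load_training(path: str | Path) -> TrainingSet:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].strip() != _TRAIN_MAGIC:
        raise ValueError(f"{path}: not a flowmrd training file")
    channels = lines[1].removeprefix("# channels ").split(",")
    flags, rows, sources = [], [], []
    for ln in lines[2:]:
        if not ln.strip():
            continue
        body, _, src = ln.partition(" # ")
        parts = body.split()
        flags.append(int(parts[0]))
        rows.append([float(p.split(":", 1)[1]) for p in parts[1:]])
        sources.append(src)
    return TrainingSet(features=np.array(rows), flags=np.array(flags),
                       sources=np.array(sources, dtype=object), channels=channels)
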