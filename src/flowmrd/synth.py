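"""Seeded synthetic cytometry specimens for end-to-end testing.

Generates mixtures of multichannel event populations — compact Gaussian
clusters in linear intensity space, optionally correlated across channels —
with a spiked leukemic ("blast") population at a known fraction.  Per-
population event counts are the exact largest-remainder apportionment of
``n_events`` by fraction, so ground-truth fractions are deterministic and
any tolerance in downstream tests is attributable to the classifier, not
the generator.  Negative draws are truncated at zero.

This emulates the structure the MRD pipeline consumes — a dominant normal
marrow background plus a rare CD7+/CD117+ blast cluster at a known spike-in
fraction — not cytometry physics: doublets, debris, autofluorescence and
spectral spillover are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .fcs import ChannelInfo, EventMatrix

#: Default 4-fluorescence + scatter panel (CD7-FITC, CD117-PE, HLA-DR-APC,
#: CD45-PE-Cy7 plus forward/side scatter).
DEFAULT_CHANNELS: tuple[str, ...] = ("FSC", "SSC", "CD7", "CD117", "HLA-DR", "CD45")

#: Population name that counts as leukemic in truth labels.
BLAST = "blast"


def largest_remainder(weights: Sequence[float], n: int) -> np.ndarray:
    """Apportion ``n`` items to ``weights`` by the largest-remainder method.

    Returns integer counts summing exactly to ``n``.  Quotas are
    ``n * w / sum(w)``; each weight gets the floor of its quota and the
    leftover items go to the largest fractional remainders (ties broken by
    position, earlier first).
    """
    w = np.asarray(weights, dtype=np.float64)
    if w.ndim != 1 or len(w) == 0 or (w < 0).any():
        raise ValueError("weights must be a nonempty 1-D array of nonnegative numbers")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights must not all be zero")
    quota = n * w / total
    counts = np.floor(quota).astype(np.int64)
    short = n - int(counts.sum())
    if short:
        frac = quota - counts
        order = np.lexsort((np.arange(len(w)), -frac))
        counts[order[:short]] += 1
    return counts


@dataclass(frozen=True)
class PopulationSpec:
    """One event population: a (possibly correlated) Gaussian cluster.

    ``location`` and ``spread`` are per-channel center and standard
    deviation in arbitrary linear intensity units; ``correlation`` is an
    optional symmetric positive-semidefinite channel-correlation matrix.
    """

    name: str
    fraction: float
    location: tuple[float, ...]
    spread: tuple[float, ...]
    correlation: tuple[tuple[float, ...], ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"population {self.name!r}: fraction must be in [0,1]")
        if len(self.location) != len(self.spread):
            raise ValueError(f"population {self.name!r}: location/spread length mismatch")
        if any(s < 0 for s in self.spread):
            raise ValueError(f"population {self.name!r}: spreads must be >= 0")

    def covariance(self) -> np.ndarray:
        s = np.asarray(self.spread, dtype=np.float64)
        if self.correlation is None:
            return np.diag(s**2)
        corr = np.asarray(self.correlation, dtype=np.float64)
        if corr.shape != (len(s), len(s)) or not np.allclose(corr, corr.T):
            raise ValueError(f"population {self.name!r}: correlation must be symmetric k x k")
        if np.linalg.eigvalsh(corr).min() < -1e-9:
            raise ValueError(f"population {self.name!r}: correlation is not positive semidefinite")
        return np.outer(s, s) * corr


@dataclass(frozen=True)
class SyntheticSpec:
    """A full specimen recipe: populations, event count, seed, channel panel."""

    populations: tuple[PopulationSpec, ...]
    n_events: int
    seed: int
    channels: tuple[str, ...] = DEFAULT_CHANNELS

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if not self.populations:
            raise ValueError("need at least one population")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")
        total = sum(p.fraction for p in self.populations)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"population fractions sum to {total}, not 1")
        for p in self.populations:
            if len(p.location) != len(self.channels):
                raise ValueError(
                    f"population {p.name!r} has {len(p.location)} channels, "
                    f"specimen has {len(self.channels)}"
                )


@dataclass
class LabeledSpecimen:
    """A simulated specimen with per-event ground-truth population labels."""

    events: EventMatrix
    truth_labels: np.ndarray
    spiked_fraction: float

    def __post_init__(self) -> None:
        if len(self.truth_labels) != self.events.n_events:
            raise ValueError("truth_labels length must equal n_events")


def _draw(pop: PopulationSpec, count: int, rng: np.random.Generator) -> np.ndarray:
    if count == 0:
        return np.empty((0, len(pop.location)))
    loc = np.asarray(pop.location, dtype=np.float64)
    cov = pop.covariance()
    # eigendecomposition factor handles zero-spread channels and PSD
    # correlation without a Cholesky failure
    vals, vecs = np.linalg.eigh(cov)
    factor = vecs * np.sqrt(np.clip(vals, 0.0, None))
    z = rng.standard_normal((count, len(loc)))
    return np.clip(loc + z @ factor.T, 0.0, None)


def _make_matrix(parts: list[np.ndarray], labels: list[str],
                 counts: np.ndarray, spec_channels: tuple[str, ...],
                 specimen_id: str, leukemic_name: str) -> LabeledSpecimen:
    values = np.vstack(parts)
    truth = np.repeat(np.asarray(labels, dtype=object), counts)
    channels = [ChannelInfo(short_name=c, range=float(max(values[:, j].max(initial=1.0), 1.0)))
                for j, c in enumerate(spec_channels)]
    em = EventMatrix(values=values, channels=channels, specimen_id=specimen_id)
    spiked = float(np.sum(truth == leukemic_name)) / len(truth)
    return LabeledSpecimen(events=em, truth_labels=truth, spiked_fraction=spiked)


def simulate_specimen(spec: SyntheticSpec, leukemic_name: str = BLAST,
                      specimen_id: str = "") -> LabeledSpecimen:
    """Simulate one specimen from its recipe.

    Deterministic given the spec: identical spec + seed produce identical
    matrices; population counts carry no sampling noise.
    """
    counts = largest_remainder([p.fraction for p in spec.populations], spec.n_events)
    rng = np.random.default_rng(spec.seed)
    parts = [_draw(p, int(c), rng) for p, c in zip(spec.populations, counts)]
    return _make_matrix(parts, [p.name for p in spec.populations], counts,
                        spec.channels, specimen_id or f"synthetic-{spec.seed}",
                        leukemic_name)


def spike_mrd(normal: SyntheticSpec, blast: PopulationSpec, fraction: float,
              n_events: int, seed: int, specimen_id: str = "") -> LabeledSpecimen:
    """Simulate a follow-up MRD specimen with a known spiked blast fraction.

    The leukemic event count is ``round(fraction * n_events)``; the normal
    populations are rescaled to fill the remainder.  ``spiked_fraction`` on
    the result records the realized (post-rounding) fraction.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("spike fraction must be in [0,1]")
    n_blast = int(round(fraction * n_events))
    normal_pops = [p for p in normal.populations if p.name != blast.name]
    counts = largest_remainder([p.fraction for p in normal_pops], n_events - n_blast) \
        if n_events > n_blast else np.zeros(len(normal_pops), dtype=np.int64)
    rng = np.random.default_rng(seed)
    all_pops = list(normal_pops) + [blast]
    all_counts = np.append(counts, n_blast)
    parts = [_draw(p, int(c), rng) for p, c in zip(all_pops, all_counts)]
    return _make_matrix(parts, [p.name for p in all_pops], all_counts,
                        normal.channels, specimen_id or f"followup-{seed}",
                        blast.name)


# ---------------------------------------------------------------------------
# Canonical synthetic study: one AML patient panel with a CD7+/CD117+ LAIP

def blast_population(fraction: float, separation_sd: float = 6.0) -> PopulationSpec:
    """The leukemic blast cluster: CD7+/CD117+/HLA-DR+ with dim CD45.

    The blast cluster shares the lymphocyte scatter profile (so light
    scatter alone cannot identify it) and is offset from the lymphocyte
    center by ``separation_sd`` standard deviations (pooled spread 30
    intensity units) on each of the three LAIP markers CD7, CD117 and
    HLA-DR, plus a fixed 2-SD CD45-dim shift.  ``separation_sd`` is thus a
    single knob for classifier difficulty: at 6 the immunophenotype is
    cleanly aberrant, at 0 it nearly coincides with normal lymphocytes.
    """
    s = 30.0
    return PopulationSpec(
        name=BLAST,
        fraction=fraction,
        # FSC, SSC, CD7, CD117, HLA-DR, CD45
        location=(300.0, 150.0, 80.0 + separation_sd * s, 60.0 + separation_sd * s,
                  100.0 + separation_sd * s, 640.0),
        spread=(s,) * 6,
    )


def normal_populations(total_fraction: float = 1.0) -> tuple[PopulationSpec, ...]:
    """Normal marrow background: lymphocytes and a myeloid/granulocyte cluster."""
    return (
        PopulationSpec(
            name="lymphocyte",
            fraction=0.55 * total_fraction,
            location=(300.0, 150.0, 80.0, 60.0, 100.0, 700.0),
            spread=(30.0,) * 6,
        ),
        PopulationSpec(
            name="myeloid",
            fraction=0.45 * total_fraction,
            location=(600.0, 500.0, 60.0, 120.0, 80.0, 450.0),
            spread=(30.0,) * 6,
        ),
    )


def donor_spec(seed: int, n_events: int = 100_000) -> SyntheticSpec:
    """A healthy-donor specimen: normal populations only."""
    return SyntheticSpec(populations=normal_populations(), n_events=n_events, seed=seed)


def diagnosis_spec(seed: int, n_events: int = 100_000, blast_fraction: float = 0.5,
                   separation_sd: float = 6.0) -> SyntheticSpec:
    """A diagnosis specimen: dominant blast population over normal background."""
    pops = (blast_population(blast_fraction, separation_sd),) + \
        normal_populations(1.0 - blast_fraction)
    return SyntheticSpec(populations=pops, n_events=n_events, seed=seed)


def followup_specimen(fraction: float, seed: int, n_events: int = 100_000,
                      separation_sd: float = 6.0,
                      specimen_id: str = "") -> LabeledSpecimen:
    """A follow-up MRD specimen with a known spiked blast fraction."""
    base = donor_spec(seed=seed, n_events=n_events)
    return spike_mrd(base, blast_population(0.0, separation_sd), fraction,
                     n_events, seed, specimen_id=specimen_id)


# ---------------------------------------------------------------------------
# Plain-text spec files

def load_spec(path: str | Path) -> SyntheticSpec:
    """Load a :class:`SyntheticSpec` from a YAML recipe file."""
    raw = yaml.safe_load(Path(path).read_text())
    pops = tuple(
        PopulationSpec(
            name=p["name"],
            fraction=float(p["fraction"]),
            location=tuple(float(v) for v in p["location"]),
            spread=tuple(float(v) for v in p["spread"]),
            correlation=tuple(tuple(float(x) for x in row) for row in p["correlation"])
            if p.get("correlation") else None,
        )
        for p in raw["populations"]
    )
    return SyntheticSpec(
        populations=pops,
        n_events=int(raw["n_events"]),
        seed=int(raw["seed"]),
        channels=tuple(raw.get("channels", DEFAULT_CHANNELS)),
    )


def save_labels(specimen: LabeledSpecimen, path: str | Path) -> Path:
    """Write the truth-label sidecar CSV (event_index,label)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("event_index,label\n")
        for i, lab in enumerate(specimen.truth_labels):
            fh.write(f"{i},{lab}\n")
    return path
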