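"""Conventional manual MRD analysis: 2-D gates combined by logical AND.

A gate is a region — axis-aligned rectangle or simple polygon — on a pair
of channels; an event passes a gate if its point lies inside or on the
boundary of the region (boundary-inclusive, so events exactly on a gate
edge resolve deterministically).  The gated leukemic-cell fraction is the
percentage of events passing every gate in the set, mirroring the
"P1 AND P2 AND P3" convention of clinical immunophenotyping software.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import shapely

from .fcs import EventMatrix


@dataclass(frozen=True)
class Gate:
    """A named 2-D region on a channel pair.

    Exactly one of ``rect`` (xmin, xmax, ymin, ymax) or ``vertices``
    (ordered polygon vertices, >= 3, non-self-intersecting) must be given.
    """

    name: str
    x_channel: str
    y_channel: str
    rect: tuple[float, float, float, float] | None = None
    vertices: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if (self.rect is None) == (self.vertices is None):
            raise ValueError(f"gate {self.name!r}: give exactly one of rect or vertices")
        if self.rect is not None:
            xmin, xmax, ymin, ymax = self.rect
            if xmin > xmax or ymin > ymax:
                raise ValueError(f"gate {self.name!r}: rectangle bounds must be ordered")
        else:
            assert self.vertices is not None
            if len(self.vertices) < 3:
                raise ValueError(f"gate {self.name!r}: polygon needs >= 3 vertices")
            poly = shapely.Polygon(self.vertices)
            if not poly.is_valid:
                raise ValueError(f"gate {self.name!r}: polygon is self-intersecting or degenerate")

    @classmethod
    def rectangle(cls, name: str, x_channel: str, y_channel: str,
                  xmin: float, xmax: float, ymin: float, ymax: float) -> "Gate":
        return cls(name=name, x_channel=x_channel, y_channel=y_channel,
                   rect=(xmin, xmax, ymin, ymax))

    @classmethod
    def polygon(cls, name: str, x_channel: str, y_channel: str,
                vertices: Sequence[tuple[float, float]]) -> "Gate":
        return cls(name=name, x_channel=x_channel, y_channel=y_channel,
                   vertices=tuple((float(x), float(y)) for x, y in vertices))


@dataclass(frozen=True)
class GateSet:
    """An ordered list of gates combined by logical AND."""

    gates: tuple[Gate, ...]

    def __post_init__(self) -> None:
        if not self.gates:
            raise ValueError("a gate set needs at least one gate")


def apply_gate(events: EventMatrix, gate: Gate) -> np.ndarray:
    """Boolean per-event mask: True iff the event lies in or on the gate region."""
    x = events.column(gate.x_channel)
    y = events.column(gate.y_channel)
    if gate.rect is not None:
        xmin, xmax, ymin, ymax = gate.rect
        return (x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)
    poly = shapely.Polygon(gate.vertices)
    pts = shapely.points(np.column_stack([x, y]))
    return shapely.covers(poly, pts)


def gated_fraction(events: EventMatrix, gates: GateSet) -> float:
    """Percentage of events passing the AND of all gates."""
    if events.n_events == 0:
        raise ValueError(f"specimen {events.specimen_id!r} has no events")
    mask = np.ones(events.n_events, dtype=bool)
    for g in gates.gates:
        mask &= apply_gate(events, g)
    return 100.0 * float(mask.sum()) / events.n_events


# ---------------------------------------------------------------------------
# Plain-text gate files
#
#   # flowmrd gates v1
#   rect P1 CD7 CD117 200 900 200 900
#   poly P2 SSC CD45 100 150 400 150 250 500

_GATE_MAGIC = "# flowmrd gates v1"


def save_gates(gates: GateSet, path: str | Path) -> Path:
    path = Path(path)
    lines = [_GATE_MAGIC]
    for g in gates.gates:
        if g.rect is not None:
            coords = " ".join(f"{v:.17g}" for v in g.rect)
            lines.append(f"rect {g.name} {g.x_channel} {g.y_channel} {coords}")
        else:
            assert g.vertices is not None
            coords = " ".join(f"{x:.17g} {y:.17g}" for x, y in g.vertices)
            lines.append(f"poly {g.name} {g.x_channel} {g.y_channel} {coords}")
    path.write_text("\n".join(lines) + "\n")
    return path


def load_gates(path: str | Path) -> GateSet:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].strip() != _GATE_MAGIC:
        raise ValueError(f"{path}: not a flowmrd gate file")
    gates: list[Gate] = []
    for ln in lines[1:]:
        if not ln.strip() or ln.startswith("#"):
            continue
        kind, name, xc, yc, *coords = ln.split()
        vals = [float(v) for v in coords]
        if kind == "rect":
            if len(vals) != 4:
                raise ValueError(f"{path}: rect {name} needs 4 coordinates")
            gates.append(Gate.rectangle(name, xc, yc, *vals))
        elif kind == "poly":
            if len(vals) % 2 or len(vals) < 6:
                raise ValueError(f"{path}: poly {name} needs >= 3 (x, y) pairs")
            gates.append(Gate.polygon(name, xc, yc, list(zip(vals[::2], vals[1::2]))))
        else:
            raise ValueError(f"{path}: unknown gate kind {kind!r}")
    return GateSet(gates=tuple(gates))
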