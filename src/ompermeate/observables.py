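"""Equilibrium-trajectory observables.

Crossing-event bookkeeping on membrane-normal traces (full membrane
transits, leaflet exchanges, glycan entries), periodic-boundary
unwrapping, and acyl-tail order parameters −S_CD from C–H bond vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .synthetic import COMPARTMENTS, BondVectorSet, ToyTrace

__all__ = [
    "CrossingReport",
    "unwrap_trace",
    "wrap_z",
    "classify_and_count",
    "order_parameter",
]

DEFAULT_HYSTERESIS = 2.0  # Å


@dataclass
class CrossingEvent:
    kind: str  # full_crossing | leaflet_exchange | glycan_entry
    t_start: float
    t_end: float
    direction: int  # +1 toward +z, -1 toward -z

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "t_start": self.t_start,
            "t_end": self.t_end,
            "direction": self.direction,
        }


@dataclass
class CrossingReport:
    """Per-molecule event list plus per-frame compartment labels."""

    molecule_id: int
    events: list = field(default_factory=list)
    compartment_series: list = field(default_factory=list)

    def count(self, kind: str) -> int:
        return sum(1 for e in self.events if e.kind == kind)

    def to_dict(self) -> dict:
        return {
            "molecule_id": self.molecule_id,
            "events": [e.to_dict() for e in self.events],
            "counts": {
                k: self.count(k)
                for k in ("full_crossing", "leaflet_exchange", "glycan_entry")
            },
        }


def wrap_z(z: np.ndarray, box_z: float) -> np.ndarray:
    """Wrap a continuous z series into [−box_z/2, box_z/2)."""
    return (np.asarray(z, dtype=float) + box_z / 2.0) % box_z - box_z / 2.0


def unwrap_trace(trace: ToyTrace) -> np.ndarray:
    """Undo periodic wrapping by accumulating minimal-image increments.

    Valid when the true per-frame motion is smaller than half the box;
    a residual jump larger than box_z/2 after unwrapping indicates an
    undersampled trace and triggers a warning.  The returned series
    equals the original continuous path up to a constant multiple of
    the box length.
    """
    z = np.asarray(trace.z, dtype=float)
    dz = np.diff(z)
    dz -= trace.box_z * np.round(dz / trace.box_z)
    # a minimal-image step near box_z/2 is ambiguous: the true motion
    # cannot be distinguished from a wrap, so the trace is undersampled
    if np.any(np.abs(dz) > 0.45 * trace.box_z):
        warnings.warn(
            "frame-to-frame jump near half the box length after unwrapping: "
            "trace may be undersampled",
            RuntimeWarning,
            stacklevel=2,
        )
    return np.concatenate([[z[0]], z[0] + np.cumsum(dz)])


def _label(z: float, b_lo: float, b_mid: float, b_hi: float) -> str:
    if z < b_lo:
        return "inner solution"
    if z < b_mid:
        return "core"
    if z < b_hi:
        return "glycan"
    return "outer solution"


def classify_and_count(
    trace: ToyTrace,
    boundaries: tuple[float, float, float] | None = None,
    hysteresis: float = DEFAULT_HYSTERESIS,
    unwrap: bool = True,
) -> CrossingReport:
    """Label compartments frame-by-frame and count crossing events.

    A hysteresis band suppresses boundary flicker: the molecule must
    penetrate ``hysteresis`` Å past a boundary before its compartment
    label switches.  Events:

    * ``full_crossing`` — solution-to-opposite-solution traversal that
      passed through both the core and the glycan region;
    * ``leaflet_exchange`` — crossing of the core midplane (with the
      same hysteresis margin);
    * ``glycan_entry`` — entry into the glycan region from a solution
      compartment.
    """
    if boundaries is None:
        boundaries = trace.region_boundaries
    b_lo, b_mid, b_hi = boundaries
    if not b_lo < b_mid < b_hi:
        raise ValueError(
            f"boundaries must be ordered inner solution < core < glycan < "
            f"outer solution along z, got {boundaries}"
        )
    if hysteresis < 0:
        raise ValueError("hysteresis must be >= 0")
    z = unwrap_trace(trace) if unwrap else np.asarray(trace.z, dtype=float)
    t = trace.times
    midplane = 0.5 * (b_lo + b_mid)
    bounds = (b_lo, b_mid, b_hi)

    labels = []
    ci = COMPARTMENTS.index(_label(z[0], b_lo, b_mid, b_hi))
    visited_since_solution: set[str] = set()
    last_solution = COMPARTMENTS[ci] if ci in (0, 3) else None
    last_solution_t = t[0]
    side = 1 if z[0] >= midplane else -1
    report = CrossingReport(molecule_id=trace.molecule_id)
    for i, zi in enumerate(z):
        # compartment switches require penetrating `hysteresis` Å past
        # the separating boundary; loop to allow multi-compartment jumps
        while ci < 3 and zi >= bounds[ci] + hysteresis:
            ci += 1
        while ci > 0 and zi <= bounds[ci - 1] - hysteresis:
            ci -= 1
            if COMPARTMENTS[ci] == "glycan" and last_solution == "outer solution" \
                    and "glycan" not in visited_since_solution:
                report.events.append(
                    CrossingEvent("glycan_entry", last_solution_t, t[i], -1)
                )
        current = COMPARTMENTS[ci]
        labels.append(current)

        if current in ("core", "glycan"):
            visited_since_solution.add(current)
        if current.endswith("solution"):
            if (
                last_solution is not None
                and current != last_solution
                and {"core", "glycan"} <= visited_since_solution
            ):
                report.events.append(
                    CrossingEvent(
                        "full_crossing",
                        last_solution_t,
                        t[i],
                        1 if current == "outer solution" else -1,
                    )
                )
            last_solution = current
            last_solution_t = t[i]
            visited_since_solution = set()
        # leaflet exchange with the same hysteresis margin about the midplane
        if side > 0 and zi < midplane - hysteresis:
            report.events.append(CrossingEvent("leaflet_exchange", t[i], t[i], -1))
            side = -1
        elif side < 0 and zi > midplane + hysteresis:
            report.events.append(CrossingEvent("leaflet_exchange", t[i], t[i], 1))
            side = 1
    report.events.sort(key=lambda e: (e.t_end, e.t_start))
    report.compartment_series = labels
    return report


def order_parameter(vectors: BondVectorSet) -> float:
    """Acyl-tail order parameter −S_CD = −⟨3cos²θ_CH − 1⟩/2.

    θ_CH is the angle between each C–H bond vector and the membrane
    normal; the average runs over the supplied set (one carbon index
    and leaflet).  Lies in [−1, 0.5]: −1 for bonds parallel to the
    normal, 0.5 for perpendicular, 0 for an isotropic distribution.
    """
    v = vectors.vectors
    if v.size == 0:
        raise ValueError("empty bond-vector set")
    n = vectors.normal / np.linalg.norm(vectors.normal)
    cos_t = v @ n
    return float(-np.mean(3.0 * cos_t**2 - 1.0) / 2.0)
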