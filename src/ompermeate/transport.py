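"""Whole-cell steady-state flux from serial membrane permeabilities.

A gram-negative cell presents two membranes in series; at steady state
the flux across each equals the flux across the whole envelope, so the
total permeability coefficient is the harmonic combination

    Pm_t = Pm_o · Pm_i / (Pm_o + Pm_i),

and the net inward molar flux across a surface of area A under a
concentration difference Δc is J = Pm_t · A · Δc.  Units: Pm in cm/s,
A in μm², concentrations in mM; J is reported in fmol/s and molecules/s.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import AVOGADRO, MM_TO_MOL_PER_CM3, MOL_TO_FMOL, UM2_TO_CM2

__all__ = [
    "TransportSystem",
    "serial_permeability",
    "steady_state_flux",
    "rod_surface_area",
    "classify_limiting_membrane",
]


@dataclass
class TransportSystem:
    """Two-membrane cell model with boundary concentrations.

    Pm_o, Pm_i : outer/inner membrane permeability coefficients, cm/s.
    area : permeating surface area, μm².
    c_out, c_in : external and internal compound concentrations, mM.
    """

    Pm_o: float
    Pm_i: float
    area: float
    c_out: float
    c_in: float = 0.0

    def __post_init__(self) -> None:
        if self.Pm_o < 0 or self.Pm_i < 0:
            raise ValueError("permeability coefficients must be >= 0")
        if self.area <= 0:
            raise ValueError("area must be positive")
        if self.c_out < 0 or self.c_in < 0:
            raise ValueError("concentrations must be >= 0")

    @property
    def Pm_t(self) -> float:
        return serial_permeability(self.Pm_o, self.Pm_i)


def serial_permeability(Pm_o: float, Pm_i: float) -> float:
    """Total permeability of two membranes in series (harmonic combination).

    Equals half of either coefficient when the two are equal, and is
    limited by the smaller one otherwise.  Both zero returns 0 with a
    warning (fully impermeable envelope).
    """
    if Pm_o < 0 or Pm_i < 0:
        raise ValueError("permeability coefficients must be >= 0")
    if Pm_o == 0 and Pm_i == 0:
        warnings.warn(
            "both membranes impermeable: total permeability is 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    if math.isinf(Pm_o):
        return Pm_i
    if math.isinf(Pm_i):
        return Pm_o
    return Pm_o * Pm_i / (Pm_o + Pm_i)


def steady_state_flux(
    system: TransportSystem, Pm_t: float | None = None
) -> dict:
    """Net inward steady-state flux J = Pm_t · A · (c_out − c_in).

    ``Pm_t`` defaults to the system's serial combination; passing it
    explicitly supports the common approximation of using the limiting
    membrane's coefficient directly.  Returns the flux in mol/s,
    fmol/s, and molecules/s.
    """
    pm = system.Pm_t if Pm_t is None else Pm_t
    j_mol = (
        pm
        * system.area
        * UM2_TO_CM2
        * (system.c_out - system.c_in)
        * MM_TO_MOL_PER_CM3
    )
    return {
        "mol_per_s": j_mol,
        "fmol_per_s": j_mol * MOL_TO_FMOL,
        "molecules_per_s": j_mol * AVOGADRO,
    }


def rod_surface_area(
    length: float, diameter: float, convention: str = "lateral"
) -> float:
    """Surface area (μm²) of a rod-shaped cell.

    ``lateral`` (default) is the open cylinder π·d·L — the convention
    that gives 1.25 μm² for a 1 μm × 0.4 μm rod.  ``spherocylinder``
    adds hemispherical caps (π·d·L + π·d²), ``capped`` adds flat disk
    ends (π·d·L + π·d²/2).
    """
    if length < 0 or diameter < 0:
        raise ValueError("dimensions must be nonnegative")
    lateral = math.pi * diameter * length
    if convention == "lateral":
        return lateral
    if convention == "spherocylinder":
        return lateral + math.pi * diameter**2
    if convention == "capped":
        return lateral + math.pi * diameter**2 / 2.0
    raise ValueError(f"unknown area convention {convention!r}")


def classify_limiting_membrane(
    table: pd.DataFrame,
    class_column: str = "class",
) -> tuple[pd.DataFrame, dict]:
    """Tag each compound by its rate-limiting membrane and build class CDFs.

    ``table`` needs columns ``compound``, ``logPm_o``, ``logPm_i`` and
    optionally a lignin-type class column (H/G/S/C/other).  A compound
    is OM-limited when logPm_o < logPm_i, IM-limited when greater, and
    ``comparable`` on exact ties.  Rows with a missing inner-membrane
    value are skipped with a warning.  The second return value maps each
    class to the sorted (logPm_o − logPm_i) values with their empirical
    cumulative probabilities.
    """
    required = {"compound", "logPm_o", "logPm_i"}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise ValueError(f"table missing columns: {sorted(missing_cols)}")
    rows = []
    for _, row in table.iterrows():
        lo, li = row["logPm_o"], row["logPm_i"]
        if pd.isna(li) or pd.isna(lo):
            warnings.warn(
                f"compound {row['compound']!r} missing a membrane value; skipped",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        if not (np.isfinite(lo) and np.isfinite(li)):
            raise ValueError(
                f"non-finite log-permeability for {row['compound']!r}"
            )
        if lo < li:
            tag = "OM-limited"
        elif lo > li:
            tag = "IM-limited"
        else:
            tag = "comparable"
        rows.append(
            {
                "compound": row["compound"],
                "class": row.get(class_column, "other"),
                "logPm_o": lo,
                "logPm_i": li,
                "delta_log": lo - li,
                "limiting": tag,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["compound", "class", "logPm_o", "logPm_i", "delta_log", "limiting"],
    )
    cdfs = {}
    for cls, grp in out.groupby("class"):
        vals = np.sort(grp["delta_log"].to_numpy())
        cdfs[cls] = {
            "delta_log": vals.tolist(),
            "cumulative": ((np.arange(vals.size) + 1) / vals.size).tolist(),
        }
    return out, cdfs
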