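"""Tabulated profiles along the membrane normal (free energy, diffusivity)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class Profile:
    """A tabulated function of membrane-normal position ξ.

    ``values`` are kcal/mol for ``kind='free_energy'`` and Å²/ns for
    ``kind='diffusivity'``.  ``sd`` is an optional pointwise uncertainty
    in the same units.  NaN values mark masked (unsampled) grid points;
    masked points are excluded from fitting, never imputed.  ``fit`` is
    a smooth callable over the grid span, populated by
    :func:`ompermeate.permeability.spline_fit`.
    """

    grid: np.ndarray  # Å, strictly increasing
    values: np.ndarray
    kind: str = "free_energy"
    sd: np.ndarray | None = None
    fit: object = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape != self.values.shape:
            raise ValueError("grid and values must have the same shape")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if self.kind not in ("free_energy", "diffusivity"):
            raise ValueError(f"unknown profile kind {self.kind!r}")
        if self.kind == "diffusivity" and np.any(self.values[self.mask] < 0):
            raise ValueError("diffusivity values must be nonnegative")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.grid.shape:
                raise ValueError("sd must match grid shape")

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask of unmasked (finite) grid points."""
        return np.isfinite(self.values)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.grid[0]), float(self.grid[-1])

    def copy(self, **updates) -> "Profile":
        fields = {
            "grid": self.grid.copy(),
            "values": self.values.copy(),
            "kind": self.kind,
            "sd": None if self.sd is None else self.sd.copy(),
            "fit": self.fit,
            "meta": dict(self.meta),
        }
        fields.update(updates)
        return Profile(**fields)

    def __call__(self, xi):
        """Evaluate the smooth fit (falls back to linear interpolation)."""
        if self.fit is not None:
            return self.fit(xi)
        m = self.mask
        return np.interp(xi, self.grid[m], self.values[m])

    # -- I/O ---------------------------------------------------------

    def to_csv(self, path) -> None:
        """Write as CSV with columns xi_angstrom, value[, sd]."""
        cols = {"xi_angstrom": self.grid, "value": self.values}
        if self.sd is not None:
            cols["sd"] = self.sd
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, kind: str = "free_energy") -> "Profile":
        df = pd.read_csv(path)
        cols = list(df.columns)
        grid = df[cols[0]].to_numpy(dtype=float)
        values = df[cols[1]].to_numpy(dtype=float)
        sd = df[cols[2]].to_numpy(dtype=float) if len(cols) > 2 else None
        return cls(grid=grid, values=values, sd=sd, kind=kind)


def read_profile(path, kind: str = "free_energy") -> Profile:
    return Profile.from_csv(Path(path), kind=kind)
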