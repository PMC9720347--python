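"""Ground-truth free-energy / diffusivity landscapes for synthetic data.

A :class:`LandscapeSpec` holds an analytic (or tabulated) free-energy
profile G(ξ) in kcal/mol and diffusivity profile D(ξ) in Å²/ns over a
reaction-coordinate domain in Å.  It is the "answer key" for recovery
tests: the Langevin generator samples from it, and the reconstruction
chain (WHAM → diffusivity → permeability) is judged against it.

Supported free-energy forms
---------------------------
``flat``              G ≡ offset (default 0).
``harmonic``          G = ½ k (ξ − center)².
``gaussian_barriers`` sum of Gaussians: Σ h_i exp(−(ξ−c_i)²/(2σ_i²));
                      negative heights encode wells.  This is the shape
                      used to emulate asymmetric two-leaflet landscapes.
``tabulated``         cubic-spline interpolation of (xi, g) tables.

Supported diffusivity forms
---------------------------
``constant``   D ≡ value.
``piecewise``  plateau values joined by smooth tanh ramps (so that the
               spurious-drift term D′ of the Itô Langevin integrator is
               well defined); emulates an aqueous plateau ≈ 80 Å²/ns
               with interfacial minima.
``tabulated``  cubic-spline interpolation, derivative by centered finite
               differences (step 1e-4 Å).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline

from .constants import beta

_FD_STEP = 1e-4  # Å, centered-difference step for tabulated derivatives

G_FORMS = ("flat", "harmonic", "gaussian_barriers", "tabulated")
D_FORMS = ("constant", "tabulated", "piecewise")


@dataclass
class LandscapeSpec:
    """Ground-truth G(ξ) and D(ξ) over a reaction-coordinate domain.

    Parameters
    ----------
    name : str
        Label for the landscape (appears in file metadata).
    g_form, d_form : str
        Analytic form tags, see module docstring.
    g_params, d_params : dict
        Parameters of the respective forms (kcal/mol, Å, Å²/ns).
    domain : (float, float)
        Reaction-coordinate interval [ξ_lo, ξ_hi] in Å.
    periodic : bool
        Whether ξ is treated as periodic over the domain.
    temperature : float
        Temperature in K used when sampling from the landscape.
    """

    name: str
    g_form: str = "flat"
    g_params: dict = field(default_factory=dict)
    d_form: str = "constant"
    d_params: dict = field(default_factory=dict)
    domain: tuple[float, float] = (-35.0, 65.0)
    periodic: bool = False
    temperature: float = 310.0

    def __post_init__(self) -> None:
        lo, hi = self.domain
        if not hi > lo:
            raise ValueError(f"domain must be nonempty, got {self.domain}")
        if self.g_form not in G_FORMS:
            raise ValueError(f"unknown g_form {self.g_form!r}")
        if self.d_form not in D_FORMS:
            raise ValueError(f"unknown d_form {self.d_form!r}")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        self._g_spline = None
        self._d_spline = None
        if self.g_form == "tabulated":
            xi = np.asarray(self.g_params["xi"], dtype=float)
            g = np.asarray(self.g_params["g"], dtype=float)
            self._g_spline = CubicSpline(xi, g)
        if self.d_form == "tabulated":
            xi = np.asarray(self.d_params["xi"], dtype=float)
            d = np.asarray(self.d_params["d"], dtype=float)
            if np.any(d <= 0):
                raise ValueError("tabulated diffusivity must be positive")
            self._d_spline = CubicSpline(xi, d)
        # validate positivity / finiteness on a dense probe grid
        probe = np.linspace(lo, hi, 501)
        gv = self.free_energy(probe)
        dv = self.diffusivity(probe)
        if not np.all(np.isfinite(gv)):
            raise ValueError("free energy is not finite everywhere on domain")
        if not np.all(dv > 0):
            raise ValueError("diffusivity must be positive everywhere on domain")

    # -- free energy -------------------------------------------------

    def free_energy(self, xi):
        """G(ξ) in kcal/mol (vectorized)."""
        xi = np.asarray(xi, dtype=float)
        if self.g_form == "flat":
            return np.full_like(xi, float(self.g_params.get("offset", 0.0)))
        if self.g_form == "harmonic":
            k = float(self.g_params["k"])
            c = float(self.g_params.get("center", 0.0))
            return 0.5 * k * (xi - c) ** 2
        if self.g_form == "gaussian_barriers":
            g = np.full_like(xi, float(self.g_params.get("offset", 0.0)))
            for h, c, s in self._gaussians():
                g = g + h * np.exp(-((xi - c) ** 2) / (2.0 * s * s))
            return g
        return self._g_spline(xi)

    def free_energy_grad(self, xi):
        """dG/dξ in kcal/mol/Å (vectorized)."""
        xi = np.asarray(xi, dtype=float)
        if self.g_form == "flat":
            return np.zeros_like(xi)
        if self.g_form == "harmonic":
            k = float(self.g_params["k"])
            c = float(self.g_params.get("center", 0.0))
            return k * (xi - c)
        if self.g_form == "gaussian_barriers":
            dg = np.zeros_like(xi)
            for h, c, s in self._gaussians():
                dg = dg - h * (xi - c) / (s * s) * np.exp(
                    -((xi - c) ** 2) / (2.0 * s * s)
                )
            return dg
        return (self._g_spline(xi + _FD_STEP) - self._g_spline(xi - _FD_STEP)) / (
            2.0 * _FD_STEP
        )

    def _gaussians(self):
        p = self.g_params
        return zip(p["heights"], p["centers"], p["widths"])

    # -- diffusivity -------------------------------------------------

    def diffusivity(self, xi):
        """D(ξ) in Å²/ns (vectorized)."""
        xi = np.asarray(xi, dtype=float)
        if self.d_form == "constant":
            return np.full_like(xi, float(self.d_params.get("value", 80.0)))
        if self.d_form == "piecewise":
            return self._piecewise_d(xi)
        return self._d_spline(xi)

    def diffusivity_grad(self, xi):
        """dD/dξ in Å²/ns/Å (vectorized)."""
        xi = np.asarray(xi, dtype=float)
        if self.d_form == "constant":
            return np.zeros_like(xi)
        if self.d_form == "piecewise":
            return self._piecewise_d_grad(xi)
        return (self._d_spline(xi + _FD_STEP) - self._d_spline(xi - _FD_STEP)) / (
            2.0 * _FD_STEP
        )

    def _piecewise_d(self, xi):
        # plateau values v_0..v_n joined at edges e_1..e_n by tanh ramps
        p = self.d_params
        values = np.asarray(p["values"], dtype=float)
        edges = np.asarray(p["edges"], dtype=float)
        w = float(p.get("smooth", 1.0))
        d = np.full_like(xi, values[0])
        for e, v_prev, v_next in zip(edges, values[:-1], values[1:]):
            d = d + 0.5 * (v_next - v_prev) * (1.0 + np.tanh((xi - e) / w))
        return d

    def _piecewise_d_grad(self, xi):
        p = self.d_params
        values = np.asarray(p["values"], dtype=float)
        edges = np.asarray(p["edges"], dtype=float)
        w = float(p.get("smooth", 1.0))
        dd = np.zeros_like(xi)
        for e, v_prev, v_next in zip(edges, values[:-1], values[1:]):
            dd = dd + 0.5 * (v_next - v_prev) / w / np.cosh((xi - e) / w) ** 2
        return dd

    # -- derived quantities ------------------------------------------

    def boltzmann_density(self, xi):
        """Unnormalized stationary density exp(−βG(ξ)) at ``temperature``."""
        return np.exp(-beta(self.temperature) * self.free_energy(xi))

    def analytic_permeability(self, xi_lo=None, xi_hi=None, n=20001):
        """Reference Pm in cm/s by dense trapezoid of exp(βG)/D (Å/ns → ×10)."""
        from .constants import ANG_PER_NS_TO_CM_PER_S

        lo = self.domain[0] if xi_lo is None else xi_lo
        hi = self.domain[1] if xi_hi is None else xi_hi
        grid = np.linspace(lo, hi, n)
        integrand = np.exp(beta(self.temperature) * self.free_energy(grid)) / (
            self.diffusivity(grid)
        )
        resistance = np.trapezoid(integrand, grid)  # ns/Å
        return ANG_PER_NS_TO_CM_PER_S / resistance

    # -- (de)serialization -------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "g_form": self.g_form,
            "g_params": _jsonable(self.g_params),
            "d_form": self.d_form,
            "d_params": _jsonable(self.d_params),
            "domain": list(self.domain),
            "periodic": self.periodic,
            "temperature": self.temperature,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LandscapeSpec":
        return cls(
            name=d["name"],
            g_form=d["g_form"],
            g_params=d.get("g_params", {}),
            d_form=d["d_form"],
            d_params=d.get("d_params", {}),
            domain=tuple(d["domain"]),
            periodic=bool(d.get("periodic", False)),
            temperature=float(d.get("temperature", 310.0)),
        )

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "LandscapeSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _jsonable(params: dict) -> dict:
    out = {}
    for k, v in params.items():
        if isinstance(v, np.ndarray):
            out[k] = v.tolist()
        elif isinstance(v, (list, tuple)):
            out[k] = [float(x) for x in v]
        else:
            out[k] = v
    return out


def two_barrier_landscape(
    span: float = 22.0,
    barrier_heights: tuple[float, float] = (3.0, 2.0),
    well_depth: float = -2.0,
    d_value: float = 50.0,
    temperature: float = 310.0,
    name: str = "two-barrier",
) -> LandscapeSpec:
    """Asymmetric two-barrier landscape over [−span/2, span/2].

    Two Gaussian barriers of unequal height flank a central well,
    mimicking the shape of a solute free-energy profile across an
    asymmetric bilayer (interfacial barriers, favourable core) at a
    reduced reaction-coordinate span suitable for desk-scale sampling.
    """
    half = span / 2.0
    return LandscapeSpec(
        name=name,
        g_form="gaussian_barriers",
        g_params={
            "heights": [barrier_heights[0], well_depth, barrier_heights[1]],
            "centers": [-0.5 * half, 0.0, 0.5 * half],
            # narrow enough that G is flat (solution-like) at the edges
            "widths": [0.08 * span, 0.12 * span, 0.08 * span],
        },
        d_form="constant",
        d_params={"value": d_value},
        domain=(-half, half),
        temperature=temperature,
    )


def outer_membrane_like_landscape(temperature: float = 310.0) -> LandscapeSpec:
    """Full-span (−35…65 Å) asymmetric landscape with interfacial features.

    Emulates the qualitative shape of an outer-membrane solute profile:
    solution plateaus at zero, a favourable lipid core, a barrier at the
    lipid–glycan interface, and a diffusivity profile with an aqueous
    plateau of 80 Å²/ns dipping at the interfaces.
    """
    return LandscapeSpec(
        name="om-like",
        g_form="gaussian_barriers",
        g_params={
            "heights": [-3.0, 2.5, -1.5],
            "centers": [-8.0, 12.0, 20.0],
            "widths": [5.0, 4.0, 3.0],
        },
        d_form="piecewise",
        d_params={
            "values": [80.0, 30.0, 20.0, 60.0, 80.0],
            "edges": [-18.0, 5.0, 18.0, 32.0],
            "smooth": 2.5,
        },
        domain=(-35.0, 65.0),
        temperature=temperature,
    )
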