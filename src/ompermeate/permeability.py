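"""Permeability, partitioning, and O-antigen extrapolation.

Core model: the inhomogeneous solubility-diffusion (ISD) model, in which
the permeability coefficient across a membrane-normal interval is the
reciprocal resistance

    Pm = [ ∫ exp(β ΔG(ξ)) / D(ξ) dξ ]⁻¹ ,

with ΔG referenced to aqueous solution.  The total coefficient is
decomposed into three serial components — extraction through the
unglycosylated side (Pm_u), crossing the hydrophobic core (Pm_c), and
extraction through the glycosylated side (Pm_g) — by splitting the
integration range at the free-energy minima near the two interfaces.
Each component integral is referenced to the minimum free energy within
its own range, so the partition coefficient

    logP = (G_aq − G_membrane) / (RT ln 10)

restores the solution reference in the recombination

    log Pm = logP + log₁₀[(Pm_u⁻¹ + Pm_c⁻¹ + Pm_g⁻¹)⁻¹].

Unit conventions: G in kcal/mol, D in Å²/ns, ξ in Å; Pm reported in
cm/s (1 Å/ns = 10 cm/s).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import simpson
from scipy.interpolate import CubicSpline, UnivariateSpline
from scipy.special import logsumexp

from .constants import ANG_PER_NS_TO_CM_PER_S, beta, kt
from .profiles import Profile

__all__ = [
    "PermeabilityBreakdown",
    "StitchResult",
    "spline_fit",
    "isd_permeability",
    "find_region_boundaries",
    "partition_coefficient",
    "decompose_permeability",
    "recombine",
    "oantigen_thickness",
    "stitch_segments",
    "breakdown_table",
]

#: quadrature evaluation grid spacing for the spline fits, Å
QUAD_STEP = 0.05
#: boundary search intervals: free-energy minima are sought in these
#: open ranges on the unglycosylated and glycosylated sides
UNGLYCOSYLATED_SEARCH = (-22.0, -5.0)
GLYCOSYLATED_SEARCH = (5.0, 22.0)

_LN10 = np.log(10.0)


@dataclass
class PermeabilityBreakdown:
    """Partition coefficient, total and regional log-permeabilities.

    ``logPm`` is tied to the components through the serial-resistance
    recombination identity (checked to 1e-9 at construction).  All
    log-permeabilities are log₁₀(cm/s); −inf encodes an impermeable
    component (exact zero in the linear domain).
    """

    logP: float
    logPm: float
    logPm_u: float
    logPm_c: float
    logPm_g: float
    boundary_u: float
    boundary_g: float
    reference_state: str = "aqueous solution zero point"
    sd: dict = field(default_factory=dict)
    u_search: tuple = UNGLYCOSYLATED_SEARCH
    g_search: tuple = GLYCOSYLATED_SEARCH

    def __post_init__(self) -> None:
        expected = recombine(self.logP, self.logPm_u, self.logPm_c, self.logPm_g)
        if np.isfinite(expected) or np.isfinite(self.logPm):
            if not abs(expected - self.logPm) <= 1e-9:
                raise ValueError(
                    f"logPm={self.logPm} violates the serial-resistance "
                    f"identity (expected {expected})"
                )
        eps = 1e-3  # boundaries may sit at the search-interval edge
        if not self.u_search[0] - eps <= self.boundary_u <= self.u_search[1] + eps:
            raise ValueError(
                f"boundary_u={self.boundary_u} outside {self.u_search}"
            )
        if not self.g_search[0] - eps <= self.boundary_g <= self.g_search[1] + eps:
            raise ValueError(
                f"boundary_g={self.boundary_g} outside {self.g_search}"
            )

    def to_dict(self) -> dict:
        return {
            "logP": self.logP,
            "logPm": self.logPm,
            "logPm_u": self.logPm_u,
            "logPm_c": self.logPm_c,
            "logPm_g": self.logPm_g,
            "boundary_u": self.boundary_u,
            "boundary_g": self.boundary_g,
            "reference_state": self.reference_state,
            "sd": self.sd,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


@dataclass
class StitchResult:
    """Outcome of stitching overlapping profile segments."""

    segments: list
    offsets: list
    merged: Profile
    join_residuals: list


# ----------------------------------------------------------------------


def spline_fit(profile: Profile, smoothing: float = 0.0) -> Profile:
    """Attach a smooth cubic fit to a profile.

    ``smoothing=0`` gives the interpolating cubic spline (passes through
    every unmasked point and reproduces cubic polynomials exactly);
    positive values give a smoothing spline with residual budget
    ``smoothing``.  Masked points are excluded, never imputed.
    """
    m = profile.mask
    x, y = profile.grid[m], profile.values[m]
    if x.size < 4:
        raise ValueError(f"need at least 4 unmasked points, got {x.size}")
    if smoothing < 0:
        raise ValueError("smoothing must be >= 0")
    if smoothing == 0:
        fit = CubicSpline(x, y)
    else:
        fit = UnivariateSpline(x, y, k=3, s=smoothing)
    out = profile.copy(fit=fit)
    out.meta["smoothing"] = smoothing
    return out


def _ensure_fit(profile: Profile) -> Profile:
    return profile if profile.fit is not None else spline_fit(profile)


def _quad_grid(xi_l: float, xi_u: float) -> np.ndarray:
    n = int(np.ceil((xi_u - xi_l) / QUAD_STEP))
    n += n % 2  # Simpson needs an even interval count
    return np.linspace(xi_l, xi_u, max(n, 2) + 1)


def _resistance(g_prof, d_prof, xi_l, xi_u, b, g_offset=0.0):
    """∫ exp(β(G−offset))/D dξ over [xi_l, xi_u] in ns/Å (Simpson)."""
    grid = _quad_grid(xi_l, xi_u)
    g = np.asarray(g_prof(grid), dtype=float)
    d = np.asarray(d_prof(grid), dtype=float)
    integrand = np.exp(b * (g - g_offset)) / d
    if np.any(d <= 0) or not np.all(np.isfinite(integrand)):
        bad = grid[~np.isfinite(integrand) | (d <= 0)]
        raise ValueError(
            f"non-finite ISD integrand (worst at ξ={bad[0]:.3f} Å)"
        )
    return float(simpson(integrand, x=grid))


def isd_permeability(
    G: Profile,
    D: Profile,
    xi_l: float,
    xi_u: float,
    temperature: float = 310.0,
) -> float:
    """Permeability coefficient (cm/s) over [ξ_l, ξ_u] from the ISD integral.

    Both profiles' fits must cover the interval; G is used as
    referenced by the caller.  Quadrature is composite Simpson on a
    0.05 Å evaluation grid of the spline fits.
    """
    if xi_u <= xi_l:
        raise ValueError("xi_u must exceed xi_l")
    G, D = _ensure_fit(G), _ensure_fit(D)
    for prof, name in ((G, "G"), (D, "D")):
        lo, hi = prof.span
        if xi_l < lo - 1e-9 or xi_u > hi + 1e-9:
            raise ValueError(
                f"{name} fit span ({lo:.2f}, {hi:.2f}) does not cover "
                f"[{xi_l}, {xi_u}]"
            )
    r = _resistance(G, D, xi_l, xi_u, beta(temperature))
    return ANG_PER_NS_TO_CM_PER_S / r


def _argopt_on_fit(prof, lo, hi, op):
    grid = np.linspace(lo, hi, max(int(round((hi - lo) / 0.01)), 10) + 1)
    vals = np.asarray(prof(grid), dtype=float)
    opt = vals.min() if op == "min" else vals.max()
    ties = np.flatnonzero(np.abs(vals - opt) < 1e-12)
    if ties.size > 1 and (ties[-1] - ties[0]) > 1:
        warnings.warn(
            f"multiple equal {op}ima in ({lo}, {hi}); taking the leftmost",
            RuntimeWarning,
            stacklevel=3,
        )
    idx = int(ties[0])
    if idx in (0, grid.size - 1):
        warnings.warn(
            f"free energy is monotone over ({lo}, {hi}): {op}imum sits at "
            "the interval edge",
            RuntimeWarning,
            stacklevel=3,
        )
    return float(grid[idx]), float(vals[idx])


def find_region_boundaries(
    G: Profile,
    u_search: tuple[float, float] = UNGLYCOSYLATED_SEARCH,
    g_search: tuple[float, float] = GLYCOSYLATED_SEARCH,
) -> tuple[float, float]:
    """Integration boundaries at the interfacial free-energy minima.

    Returns the argmin of the fitted free energy over the
    unglycosylated-side search range and the glycosylated-side search
    range (defaults (−22, −5) and (5, 22) Å).  Ties break to the
    leftmost grid point with a warning.
    """
    G = _ensure_fit(G)
    lo, hi = G.span
    eps = 1e-6
    bu, _ = _argopt_on_fit(G, max(u_search[0] + eps, lo), min(u_search[1] - eps, hi), "min")
    bg, _ = _argopt_on_fit(G, max(g_search[0] + eps, lo), min(g_search[1] - eps, hi), "min")
    return bu, bg


def partition_coefficient(
    G: Profile,
    solution_range: tuple[float, float],
    boundary_u: float,
    boundary_g: float,
    temperature: float = 310.0,
) -> float:
    """Membrane/water partition coefficient logP from the free energy.

    G_membrane is the lower of the free-energy minima at the two
    integration boundaries; G_aq is the mean over the solution range
    (zero if the profile is already solution-referenced).  RT ln10 is
    1.4184 kcal/mol at 310 K.
    """
    G = _ensure_fit(G)
    sel = (G.grid >= solution_range[0]) & (G.grid <= solution_range[1]) & G.mask
    if not np.any(sel):
        raise ValueError("no unmasked grid points inside solution_range")
    g_aq = float(np.mean(G.values[sel]))
    g_mem = min(float(G(boundary_u)), float(G(boundary_g)))
    return (g_aq - g_mem) / (kt(temperature) * _LN10)


def recombine(logP: float, logPm_u: float, logPm_c: float, logPm_g: float) -> float:
    """Total log₁₀ Pm from the partition coefficient and three components.

    log Pm = logP + log₁₀[(Pm_u⁻¹ + Pm_c⁻¹ + Pm_g⁻¹)⁻¹]; −inf components
    are exact zeros in the linear domain (impermeable region dominates).
    """
    comps = np.array([logPm_u, logPm_c, logPm_g], dtype=float)
    if np.any(np.isnan(comps)) or np.isnan(logP):
        raise ValueError("log-permeability inputs must not be NaN")
    if np.any(np.isposinf(-comps)):  # some component is -inf
        return float("-inf")
    # log10 of the summed inverse permeabilities, computed stably
    log10_sum_inv = float(logsumexp(-comps * _LN10) / _LN10)
    return float(logP - log10_sum_inv)


def decompose_permeability(
    G: Profile,
    D: Profile,
    temperature: float = 310.0,
    solution_range: tuple[float, float] | None = None,
    u_search: tuple[float, float] = UNGLYCOSYLATED_SEARCH,
    g_search: tuple[float, float] = GLYCOSYLATED_SEARCH,
    g_draws: list[np.ndarray] | None = None,
) -> PermeabilityBreakdown:
    """Full permeability breakdown from solution-referenced profiles.

    Splits the span at the interfacial free-energy minima, integrates
    the ISD resistance over each region with the free-energy reference
    reset to the minimum within that region, and recombines with the
    partition coefficient.  ``g_draws`` (posterior free-energy vectors
    on G's grid) are pushed through the same chain to fill ``sd``.
    """
    G, D = _ensure_fit(G), _ensure_fit(D)
    lo, hi = G.span
    if solution_range is None:
        solution_range = (lo, lo + 0.05 * (hi - lo))
    bu, bg = find_region_boundaries(G, u_search, g_search)

    def chain(g_prof):
        b = beta(temperature)
        logs = []
        for a, c in ((lo, bu), (bu, bg), (bg, hi)):
            grid = _quad_grid(a, c)
            gmin = float(np.min(np.asarray(g_prof(grid), dtype=float)))
            r = _resistance(g_prof, D, a, c, b, g_offset=gmin)
            logs.append(np.log10(ANG_PER_NS_TO_CM_PER_S / r))
        logp = partition_coefficient(g_prof, solution_range, bu, bg, temperature)
        return logp, logs

    logP, (lu, lc, lg) = chain(G)
    total = recombine(logP, lu, lc, lg)
    sd: dict = {}
    if g_draws is not None and len(g_draws) >= 2:
        acc = {"logP": [], "logPm": [], "logPm_u": [], "logPm_c": [], "logPm_g": []}
        for gv in g_draws:
            gp = spline_fit(
                Profile(grid=G.grid, values=np.asarray(gv, dtype=float)),
                smoothing=float(G.meta.get("smoothing", 0.0)),
            )
            try:
                lp, (du, dc, dg) = chain(gp)
            except ValueError:
                continue
            acc["logP"].append(lp)
            acc["logPm_u"].append(du)
            acc["logPm_c"].append(dc)
            acc["logPm_g"].append(dg)
            acc["logPm"].append(recombine(lp, du, dc, dg))
        sd = {k: float(np.std(v)) for k, v in acc.items() if len(v) >= 2}
    return PermeabilityBreakdown(
        logP=logP,
        logPm=total,
        logPm_u=lu,
        logPm_c=lc,
        logPm_g=lg,
        boundary_u=bu,
        boundary_g=bg,
        sd=sd,
        u_search=tuple(u_search),
        g_search=tuple(g_search),
    )


def oantigen_thickness(
    G: Profile,
    D: Profile,
    xi_search_range: tuple[float, float],
    Pm_reference: float,
    factor: float = 10.0,
    added_resistance_multiple: float | None = None,
    temperature: float = 310.0,
) -> float:
    """Added glycan thickness (Å) that multiplies total resistance by ``factor``.

    The incremental resistance per Å of added O-antigen is taken at the
    position ξ_max where the free energy is maximal within the LPS
    search range: exp(βG(ξ_max))/D(ξ_max).  With reference resistance
    R = 1/Pm, the thickness raising the total to ``factor``·R is

        L = (factor − 1) · R · D(ξ_max) · exp(−β G(ξ_max)).

    ``added_resistance_multiple`` overrides the (factor − 1) multiple
    directly for the alternative reading in which the *added* resistance
    itself equals ``factor``·R.  ``Pm_reference`` is in cm/s.
    """
    if Pm_reference <= 0:
        raise ValueError("Pm_reference must be positive")
    G, D = _ensure_fit(G), _ensure_fit(D)
    lo, hi = xi_search_range
    g_lo, g_hi = G.span
    if lo < g_lo - 1e-9 or hi > g_hi + 1e-9:
        raise ValueError("search range outside profile span")
    grid = np.linspace(lo, hi, max(int(round((hi - lo) / 0.01)), 10) + 1)
    gvals = np.asarray(G(grid), dtype=float)
    if np.ptp(gvals) < 1e-12:
        warnings.warn(
            "free energy is flat over the search range; using its midpoint",
            RuntimeWarning,
            stacklevel=2,
        )
        xi_max = 0.5 * (lo + hi)
    else:
        xi_max, _ = _argopt_on_fit(G, lo, hi, "max")
    multiple = (factor - 1.0) if added_resistance_multiple is None else added_resistance_multiple
    r_ref = 1.0 / (Pm_reference / ANG_PER_NS_TO_CM_PER_S)  # ns/Å
    b = beta(temperature)
    return float(
        multiple * r_ref * float(D(xi_max)) * np.exp(-b * float(G(xi_max)))
    )


def stitch_segments(
    segments: list[Profile],
    overlap_policy: str = "mean",
    warn_residual: float = 0.25,
) -> StitchResult:
    """Stitch overlapping profile segments into one continuous profile.

    Segments are sorted by starting position; each is shifted by the
    constant minimizing the squared disagreement with its (already
    shifted) predecessor over their overlap, with the first segment
    unshifted.  Overlapping points in the merged profile are averaged
    (``overlap_policy='mean'``) or taken from the earlier segment
    (``'first'``).  Per-join RMS residuals after shifting are reported;
    joins worse than ``warn_residual`` trigger a warning.
    """
    if not segments:
        raise ValueError("no segments to stitch")
    if overlap_policy not in ("mean", "first"):
        raise ValueError(f"unknown overlap_policy {overlap_policy!r}")
    order = np.argsort([s.grid[0] for s in segments])
    segs = [segments[i] for i in order]
    offsets_sorted = [0.0]
    residuals = []
    prev_x = segs[0].grid[segs[0].mask]
    prev_y = segs[0].values[segs[0].mask]
    for s in segs[1:]:
        m = s.mask
        x, y = s.grid[m], s.values[m]
        ov = (x >= prev_x[0]) & (x <= prev_x[-1])
        if not np.any(ov):
            raise ValueError(
                f"segment starting at {x[0]:.2f} Å does not overlap its "
                "predecessor"
            )
        pred = np.interp(x[ov], prev_x, prev_y)
        off = float(np.mean(pred - y[ov]))
        resid = float(np.sqrt(np.mean((pred - (y[ov] + off)) ** 2)))
        residuals.append(resid)
        if resid > warn_residual:
            warnings.warn(
                f"inconsistent overlap near {x[ov][0]:.2f} Å: RMS residual "
                f"{resid:.3g} after shifting (threshold {warn_residual})",
                RuntimeWarning,
                stacklevel=2,
            )
        offsets_sorted.append(off)
        # extend the running reference with the newly shifted segment
        allx = np.concatenate([prev_x, x])
        ally = np.concatenate([prev_y, y + off])
        srt = np.argsort(allx, kind="stable")
        prev_x, prev_y = allx[srt], ally[srt]

    # merge duplicates
    ux, inv = np.unique(np.round(prev_x / 1e-9) * 1e-9, return_inverse=True)
    merged_y = np.empty(ux.size)
    if overlap_policy == "mean":
        sums = np.bincount(inv, weights=prev_y)
        cnts = np.bincount(inv)
        merged_y = sums / cnts
    else:
        for i in range(ux.size):
            merged_y[i] = prev_y[inv == i][0]
    merged = Profile(grid=ux, values=merged_y, kind=segs[0].kind)
    offsets = [0.0] * len(segments)
    for pos, orig_idx in enumerate(order):
        offsets[orig_idx] = offsets_sorted[pos]
    return StitchResult(
        segments=list(segments),
        offsets=offsets,
        merged=merged,
        join_residuals=residuals,
    )


def breakdown_table(breakdowns: dict) -> pd.DataFrame:
    """Tabulate compound breakdowns in standard column order (TSV-ready)."""
    rows = [
        {
            "Compound": name,
            "logP": bd.logP,
            "logPm": bd.logPm,
            "logPm_u": bd.logPm_u,
            "logPm_c": bd.logPm_c,
            "logPm_g": bd.logPm_g,
        }
        for name, bd in breakdowns.items()
    ]
    return pd.DataFrame(rows, columns=["Compound", "logP", "logPm", "logPm_u", "logPm_c", "logPm_g"])
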