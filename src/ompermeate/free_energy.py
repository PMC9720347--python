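"""Free-energy profile reconstruction from biased umbrella windows.

The point estimate is standard binned WHAM: self-consistent iteration of
the unbiased bin probabilities p_b and per-window free-energy constants
f_w,

    p_b ∝ M_b / Σ_w N_w exp(β f_w) exp(−β U_w(ξ_b)),
    exp(−β f_w) = Σ_b p_b exp(−β U_w(ξ_b)),

with M_b the total count in bin b, N_w the sample count of window w and
U_w its harmonic bias.  Conventions supported: a periodic reaction
coordinate (edge bins identified, bias distances by minimal image), a
solution-range zero point, and symmetrization about a chosen center for
poorly sampled charged species.

The uncertainty layer is Bayesian: per-window binned counts are
resampled from their Dirichlet posterior (Bayesian bootstrap over the
occupied bins) and WHAM re-solved for each draw, giving a pointwise
posterior standard deviation of the profile.
"""

from __future__ import annotations

import warnings

import numpy as np

from .constants import beta
from .profiles import Profile
from .synthetic import WindowSamples

__all__ = ["wham", "bayes_uncertainty", "set_reference", "symmetrize"]

DEFAULT_BIN_WIDTH = 0.25  # Å; finer than the 0.55 Å umbrella spacing
DEFAULT_EQUILIBRATION_FRACTION = 0.1


def _bias_matrix(centers, ks, bin_centers, periodic, span):
    delta = bin_centers[None, :] - np.asarray(centers)[:, None]
    if periodic:
        delta = delta - span * np.round(delta / span)
    return 0.5 * np.asarray(ks)[:, None] * delta**2  # kcal/mol


def _solve_wham(counts, u_bias, b, tol, max_iter, f_init=None):
    """Self-consistent WHAM on a count matrix.

    Parameters
    ----------
    counts : (n_win, n_bins) array
        Per-window bin counts (may be fractional).
    u_bias : (n_win, n_bins) array
        Bias energies U_w(ξ_b) in kcal/mol.
    b : float
        Inverse temperature, mol/kcal.

    Returns
    -------
    p : (n_bins,) unbiased bin probabilities (0 where unsampled)
    f : (n_win,) window free-energy constants, kcal/mol
    n_iter, residual
    """
    n_w = counts.sum(axis=1)  # samples per window
    m_b = counts.sum(axis=0)  # total per bin
    sampled = m_b > 0
    c_wb = np.exp(-b * (u_bias - u_bias.min()))  # harmless constant shift
    f = np.zeros(counts.shape[0]) if f_init is None else f_init.copy()
    residual = np.inf
    for it in range(1, max_iter + 1):
        a_w = np.exp(b * f)
        denom = (n_w * a_w) @ c_wb  # (n_bins,)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(sampled, m_b / denom, 0.0)
        p /= p.sum()
        f_new = -(1.0 / b) * np.log(c_wb @ p)
        f_new -= f_new[0]
        residual = float(np.max(np.abs(f_new - f)))
        f = f_new
        if residual < tol:
            return p, f, it, residual
    raise RuntimeError(
        f"WHAM did not converge in {max_iter} iterations "
        f"(residual {residual:.3e} kcal/mol > tol {tol:.1e})"
    )


def _prepare(windows, xi_range, n_bins, periodic, equilibration_fraction):
    windows = [w.discard_equilibration(equilibration_fraction) for w in windows]
    if xi_range is None:
        lo = min(float(np.min(w.samples)) for w in windows)
        hi = max(float(np.max(w.samples)) for w in windows)
        pad = 1e-9 * max(1.0, abs(hi - lo))
        xi_range = (lo - pad, hi + pad)
    lo, hi = xi_range
    if n_bins is None:
        n_bins = max(10, int(round((hi - lo) / DEFAULT_BIN_WIDTH)))
    edges = np.linspace(lo, hi, n_bins + 1)
    bin_centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.empty((len(windows), n_bins))
    for i, w in enumerate(windows):
        s = w.samples
        if periodic:
            s = (s - lo) % (hi - lo) + lo
        counts[i], _ = np.histogram(s, bins=edges)
    centers = [w.bias_center for w in windows]
    ks = [w.force_constant for w in windows]
    u_bias = _bias_matrix(centers, ks, bin_centers, periodic, hi - lo)
    return windows, counts, u_bias, bin_centers, (lo, hi)


def _gap_check(counts, bin_centers):
    m_b = counts.sum(axis=0)
    sampled = np.flatnonzero(m_b > 0)
    if sampled.size == 0:
        raise ValueError("no samples fall inside the requested range")
    interior = np.arange(sampled[0], sampled[-1] + 1)
    holes = interior[m_b[interior] == 0]
    if holes.size:
        warnings.warn(
            f"{holes.size} unsampled interior bins (e.g. near "
            f"ξ={bin_centers[holes[0]]:.2f} Å): adjacent windows do not "
            "overlap there; gap left masked",
            RuntimeWarning,
            stacklevel=3,
        )


def _profile_from_p(p, bin_centers, b, periodic, xi_range, meta):
    with np.errstate(divide="ignore"):
        g = np.where(p > 0, -(1.0 / b) * np.log(np.where(p > 0, p, 1.0)), np.nan)
    g -= np.nanmin(g)
    grid = bin_centers
    if periodic:
        # edge bins are identified: replicate the first bin at +period
        grid = np.append(grid, grid[0] + (xi_range[1] - xi_range[0]))
        g = np.append(g, g[0])
    return Profile(grid=grid, values=g, kind="free_energy", meta=meta)


def wham(
    windows: list[WindowSamples],
    n_bins: int | None = None,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    periodic: bool = False,
    temperature: float = 310.0,
    xi_range: tuple[float, float] | None = None,
    equilibration_fraction: float = DEFAULT_EQUILIBRATION_FRACTION,
) -> Profile:
    """Reconstruct G(ξ) from biased windows by self-consistent WHAM.

    Bins with no samples from any window are masked (NaN) rather than
    imputed; a warning is raised when interior gaps indicate
    non-overlapping adjacent windows.  With ``periodic=True`` the two
    reaction-coordinate edges are identified: bias distances use the
    minimal image and the returned profile repeats the first bin's value
    at the far edge, so G is exactly equal at the two ends.

    Returns a free-energy :class:`Profile` shifted so its minimum is 0
    (use :func:`set_reference` for the solution zero point).
    """
    if not windows:
        raise ValueError("need at least one window")
    windows, counts, u_bias, bin_centers, xi_range = _prepare(
        windows, xi_range, n_bins, periodic, equilibration_fraction
    )
    _gap_check(counts, bin_centers)
    b = beta(temperature)
    p, f, n_iter, residual = _solve_wham(counts, u_bias, b, tol, max_iter)
    meta = {
        "temperature": temperature,
        "periodic": periodic,
        "n_iterations": n_iter,
        "residual_kcal_mol": residual,
        "window_free_energies": f.tolist(),
    }
    return _profile_from_p(p, bin_centers, b, periodic, xi_range, meta)


def bayes_uncertainty(
    windows: list[WindowSamples],
    n_posterior: int = 50,
    seed: int = 0,
    n_bins: int | None = None,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    periodic: bool = False,
    temperature: float = 310.0,
    xi_range: tuple[float, float] | None = None,
    equilibration_fraction: float = DEFAULT_EQUILIBRATION_FRACTION,
) -> Profile:
    """WHAM point estimate with a Dirichlet-posterior uncertainty band.

    For each posterior draw, every window's bin counts are replaced by
    N_w · p with p ~ Dirichlet over that window's occupied bins (the
    Bayesian bootstrap), WHAM is re-solved warm-started from the point
    estimate, and the resulting profiles' pointwise standard deviation
    fills ``sd``.  Deterministic for a fixed ``seed``.
    """
    if n_posterior < 10:
        raise ValueError(f"n_posterior must be >= 10, got {n_posterior}")
    windows, counts, u_bias, bin_centers, xi_range = _prepare(
        windows, xi_range, n_bins, periodic, equilibration_fraction
    )
    _gap_check(counts, bin_centers)
    b = beta(temperature)
    p0, f0, n_iter, residual = _solve_wham(counts, u_bias, b, tol, max_iter)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 424243]))
    n_w = counts.sum(axis=1)
    draws = np.empty((n_posterior, bin_centers.size))
    for d in range(n_posterior):
        c = np.zeros_like(counts)
        for i in range(counts.shape[0]):
            occ = counts[i] > 0
            c[i, occ] = n_w[i] * rng.dirichlet(counts[i, occ])
        p, _, _, _ = _solve_wham(
            c, u_bias, b, max(tol, 1e-8), max_iter, f_init=f0
        )
        with np.errstate(divide="ignore"):
            g = np.where(p > 0, -(1.0 / b) * np.log(np.where(p > 0, p, 1.0)), np.nan)
        draws[d] = g - np.nanmin(g)
    sd = np.nanstd(draws, axis=0)
    sd[~np.isfinite(sd)] = np.nan
    meta = {
        "temperature": temperature,
        "periodic": periodic,
        "n_iterations": n_iter,
        "residual_kcal_mol": residual,
        "n_posterior": n_posterior,
    }
    prof = _profile_from_p(p0, bin_centers, b, periodic, xi_range, meta)
    if periodic:
        sd = np.append(sd, sd[0])
    prof.sd = sd
    return prof


def set_reference(profile: Profile, solution_range: tuple[float, float]) -> Profile:
    """Shift a profile so its mean over the solution range is zero.

    The aqueous-solution plateau defines the free-energy zero point;
    barrier heights and well depths are preserved relative to it.
    Idempotent.
    """
    lo, hi = solution_range
    g_lo, g_hi = profile.span
    if hi < g_lo or lo > g_hi or hi <= lo:
        raise ValueError(
            f"solution_range {solution_range} does not overlap profile span "
            f"({g_lo:.2f}, {g_hi:.2f})"
        )
    sel = (profile.grid >= lo) & (profile.grid <= hi) & profile.mask
    if not np.any(sel):
        raise ValueError("no unmasked grid points inside solution_range")
    shift = float(np.mean(profile.values[sel]))
    out = profile.copy(values=profile.values - shift, fit=None)
    out.meta["reference_range"] = (float(lo), float(hi))
    return out


def symmetrize(profile: Profile, center: float) -> Profile:
    """Average a profile with its mirror image about ``center``.

    value(ξ) ← ½[value(ξ) + value(2·center − ξ)] wherever the reflected
    point lies inside the profile span; points whose reflection falls
    outside are passed through unchanged and flagged in
    ``meta['symmetrize_passthrough']``.  Removes the odd (antisymmetric)
    component about the center, the standard remedy for sampling error
    on charged species.
    """
    g_lo, g_hi = profile.span
    if not g_lo <= center <= g_hi:
        raise ValueError(f"center {center} outside profile span ({g_lo}, {g_hi})")
    reflected_x = 2.0 * center - profile.grid
    inside = (reflected_x >= g_lo) & (reflected_x <= g_hi)
    m = profile.mask
    reflected_v = np.interp(reflected_x, profile.grid[m], profile.values[m])
    values = profile.values.copy()
    both = inside & m
    values[both] = 0.5 * (profile.values[both] + reflected_v[both])
    out = profile.copy(values=values, fit=None)
    out.meta["symmetrize_center"] = float(center)
    out.meta["symmetrize_passthrough"] = int(np.count_nonzero(~inside))
    return out
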