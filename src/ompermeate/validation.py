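"""Ground-truth self-validation experiments.

These drive the full inference chain against synthetic data whose free
energy and diffusivity are known exactly, quantifying how well the
package recovers them under a scaled-down umbrella-sampling protocol
(40 windows over a 22 Å two-barrier landscape at the standard force
constant and exchange interval; window length reduced from the
production-scale 40 ns to keep the experiment desk-sized).
"""

from __future__ import annotations

import numpy as np

from .constants import beta
from .diffusivity import diffusivity_profile, window_diffusivity
from .free_energy import set_reference, wham
from .landscapes import two_barrier_landscape
from .permeability import isd_permeability, spline_fit
from .synthetic import WindowSamples, run_reus

__all__ = ["reus_recovery", "ou_window_recovery"]


def reus_recovery(
    seed: int = 1,
    n_windows: int = 40,
    n_steps: int = 1_000_000,
    dt: float = 0.01,
    exchange_interval: float = 1.0,
    force_constant: float = 4.0,
) -> dict:
    """Free-energy / diffusivity / permeability recovery on synthetic REUS.

    Runs replica-exchange umbrella sampling on the asymmetric
    two-barrier landscape (22 Å span, constant D = 50 Å²/ns, 310 K),
    reconstructs G by WHAM and D from window fluctuations, and compares
    the inferred permeability against the exact solubility-diffusion
    integral of the true landscape.  The solution zero point is the
    flat plateau at the lower edge of the span.

    Returns a dict with ``g_rmse_kcal_mol``, ``d_interior_max_rel_err``,
    ``logpm_recovered``, ``logpm_analytic`` and ``logpm_abs_err``.
    """
    ls = two_barrier_landscape()
    lo, hi = ls.domain
    centers = np.linspace(lo, hi, n_windows)
    res = run_reus(
        ls,
        centers,
        k=force_constant,
        n_steps=n_steps,
        dt=dt,
        exchange_interval=exchange_interval,
        seed=seed,
    )
    g = wham(res.windows, xi_range=ls.domain, temperature=ls.temperature)
    ref = (lo, lo + 1.5)  # solution-like plateau at the lower edge
    g = spline_fit(set_reference(g, ref))
    d_prof = diffusivity_profile(res.windows)
    d = spline_fit(d_prof)

    m = g.mask
    truth = ls.free_energy(g.grid[m]) - float(
        np.mean(ls.free_energy(np.linspace(ref[0], ref[1], 101)))
    )
    g_rmse = float(np.sqrt(np.mean((g.values[m] - truth) ** 2)))

    d_true = ls.diffusivity(d_prof.grid)
    rel = np.abs(d_prof.values - d_true) / d_true
    d_err = float(np.max(rel[1:-1]))  # interior windows

    span = (lo + 0.5, hi - 0.5)  # inside both fitted profiles
    pm_rec = isd_permeability(g, d, span[0], span[1], ls.temperature)
    dense = np.linspace(span[0], span[1], 50_001)
    g_dense = ls.free_energy(dense) - float(
        np.mean(ls.free_energy(np.linspace(ref[0], ref[1], 101)))
    )
    resistance = np.trapezoid(
        np.exp(beta(ls.temperature) * g_dense) / ls.diffusivity(dense), dense
    )
    pm_true = 10.0 / resistance
    return {
        "g_rmse_kcal_mol": g_rmse,
        "d_interior_max_rel_err": d_err,
        "logpm_recovered": float(np.log10(pm_rec)),
        "logpm_analytic": float(np.log10(pm_true)),
        "logpm_abs_err": float(abs(np.log10(pm_rec) - np.log10(pm_true))),
        "exchange_acceptance": res.acceptance_ratio,
        "n_windows": n_windows,
        "window_length_ns": n_steps * dt / 1e3,
    }


def ou_window_recovery(
    seed: int = 1,
    d_true: float = 50.0,
    k: float = 4.0,
    temperature: float = 310.0,
    n: int = 200_000,
    dt: float = 0.1,
) -> dict:
    """Diffusivity recovery from an exact Ornstein–Uhlenbeck window.

    A harmonic restraint of stiffness k at temperature T makes the
    restrained coordinate an OU process with var = k_B T / k and
    τ = var / D.  The series is generated with the exact discrete OU
    transition (independent of the Langevin integrator) and fed to the
    variance/autocorrelation estimator.
    """
    kbt = 0.0019872041 * temperature
    var = kbt / k
    tau = var / (d_true * 1e-3)  # ps
    rho = np.exp(-dt / tau)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 555]))
    x = np.empty(n)
    x[0] = rng.normal(0.0, np.sqrt(var))
    noise = rng.normal(0.0, np.sqrt(var * (1 - rho * rho)), n - 1)
    for i in range(1, n):
        x[i] = x[i - 1] * rho + noise[i - 1]
    w = WindowSamples(
        window_id=0,
        bias_center=0.0,
        force_constant=k,
        sample_interval=dt,
        samples=x,
        exchange_interval=1.0,
    )
    _, d_hat = window_diffusivity(w)
    return {
        "d_true": d_true,
        "d_recovered": float(d_hat),
        "rel_err": float(abs(d_hat - d_true) / d_true),
        "var_expected": var,
        "tau_expected_ps": tau,
    }
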