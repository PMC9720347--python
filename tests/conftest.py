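"""Shared fixtures: synthetic landscapes, REUS datasets, direct samplers."""

from __future__ import annotations

import numpy as np
import pytest

import ompermeate as om

KBT_310 = 0.0019872041 * 310.0  # kcal/mol


@pytest.fixture(scope="session")
def flat_landscape():
    return om.LandscapeSpec(
        name="flat",
        d_form="constant",
        d_params={"value": 50.0},
        domain=(-11.0, 11.0),
        temperature=310.0,
    )


@pytest.fixture(scope="session")
def two_barrier():
    return om.two_barrier_landscape()


@pytest.fixture(scope="session")
def reus_small(two_barrier):
    """Modest REUS dataset reused across reconstruction tests (2 ns/window)."""
    centers = np.linspace(two_barrier.domain[0], two_barrier.domain[1], 40)
    return om.run_reus(
        two_barrier,
        centers,
        k=4.0,
        n_steps=200_000,
        dt=0.01,
        exchange_interval=1.0,
        seed=3,
    )


def sample_biased_boltzmann(landscape, center, k, n, seed):
    """Direct (dynamics-free) draws from a window's biased Boltzmann law.

    Inverse-CDF sampling on a dense grid of exp(-beta*(G + bias)); this
    is the independent route used to validate WHAM without trusting the
    Langevin engine.
    """
    lo, hi = landscape.domain
    grid = np.linspace(lo, hi, 20001)
    b = 1.0 / (0.0019872041 * landscape.temperature)
    u = landscape.free_energy(grid) + 0.5 * k * (grid - center) ** 2
    dens = np.exp(-b * (u - u.min()))
    cdf = np.cumsum(dens)
    cdf /= cdf[-1]
    rng = np.random.default_rng(seed)
    return np.interp(rng.random(n), cdf, grid)


def direct_windows(landscape, centers, k, n_per_window, seed):
    """Direct-sampled umbrella windows with exact biased statistics."""
    return [
        om.WindowSamples(
            window_id=i,
            bias_center=float(c),
            force_constant=k,
            sample_interval=0.1,
            samples=sample_biased_boltzmann(landscape, c, k, n_per_window, seed + i),
        )
        for i, c in enumerate(centers)
    ]


@pytest.fixture(scope="session")
def direct_window_set(two_barrier):
    centers = np.linspace(two_barrier.domain[0], two_barrier.domain[1], 40)
    return direct_windows(two_barrier, centers, 4.0, 4000, seed=11)
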