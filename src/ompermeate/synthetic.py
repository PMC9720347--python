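"""Synthetic biased/unbiased reaction-coordinate data with known ground truth.

This module stands in for the molecular-dynamics engine: it produces the
same *kind* of output a replica-exchange umbrella-sampling (REUS) or
equilibrium membrane simulation would hand to the analysis chain —
per-window biased time series, membrane-normal traces, C–H bond-vector
sets — but drawn from landscapes whose free energy G(ξ) and diffusivity
D(ξ) are known exactly, so every downstream estimator can be tested for
recovery of the truth.

Dynamics are overdamped Langevin in the Itô convention with
position-dependent diffusivity,

    ξ_{t+dt} = ξ_t + [−β D(ξ) G_tot′(ξ) + D′(ξ)] dt + sqrt(2 D(ξ) dt) η,

where G_tot includes the harmonic umbrella bias and η ~ N(0,1).  The
spurious-drift term D′(ξ) is required for the stationary law to be the
Boltzmann distribution when D varies with position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import ANG2_PER_NS_TO_ANG2_PER_PS, beta
from .landscapes import LandscapeSpec

__all__ = [
    "WindowSamples",
    "ToyTrace",
    "BondVectorSet",
    "ReusResult",
    "simulate_langevin",
    "run_reus",
    "default_umbrella_centers",
    "make_toy_traces",
    "make_bond_vectors",
]

#: Default umbrella geometry: 0.55 Å spacing over −35…65 Å, 4 kcal/mol/Å²
DEFAULT_SPACING = 0.55
DEFAULT_FORCE_CONSTANT = 4.0
DEFAULT_RANGE = (-35.0, 65.0)

_CHUNK = 8192  # Langevin steps advanced per pre-drawn noise block


@dataclass
class WindowSamples:
    """One umbrella window's biased time series plus bias metadata.

    ``force_constant == 0`` encodes an unbiased (equilibrium) window.
    ``exchange_times`` lists the times (ps) at which this window's
    configuration was swapped with a neighbour; the intervals between
    them are the contiguous segments used by the autocorrelation fit.
    """

    window_id: int
    bias_center: float  # Å
    force_constant: float  # kcal mol^-1 Å^-2
    sample_interval: float  # ps
    samples: np.ndarray  # ξ values, Å
    exchange_interval: float | None = None  # ps
    exchange_times: np.ndarray | None = None  # ps

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValueError("samples must be nonempty")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        if self.force_constant < 0:
            raise ValueError("force_constant must be >= 0")
        if self.exchange_times is not None:
            self.exchange_times = np.asarray(self.exchange_times, dtype=float)
            if np.any(np.diff(self.exchange_times) <= 0):
                raise ValueError("exchange_times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) * self.sample_interval

    def discard_equilibration(self, fraction: float = 0.1) -> "WindowSamples":
        """Return a copy with the first ``fraction`` of samples dropped.

        The cut is aligned to the exchange-attempt grid (when known) so
        that segment boundaries keep coinciding with exchange times.
        """
        n0 = int(len(self.samples) * fraction)
        if self.exchange_interval:
            stride = max(1, int(round(self.exchange_interval / self.sample_interval)))
            n0 = (n0 // stride) * stride
        out = WindowSamples(
            window_id=self.window_id,
            bias_center=self.bias_center,
            force_constant=self.force_constant,
            sample_interval=self.sample_interval,
            samples=self.samples[n0:],
            exchange_interval=self.exchange_interval,
            exchange_times=None,
        )
        if self.exchange_times is not None:
            t0 = n0 * self.sample_interval
            kept = self.exchange_times[self.exchange_times > t0] - t0
            out.exchange_times = kept if kept.size else None
        return out


@dataclass
class ToyTrace:
    """Membrane-normal trace of one molecule, possibly wrapped.

    ``region_boundaries`` are the three z values separating the four
    compartments (inner solution | core | glycan | outer solution) in
    increasing z.  Ground-truth event counts from the construction
    script are attached in ``truth``.
    """

    molecule_id: int
    times: np.ndarray  # ps
    z: np.ndarray  # Å
    box_z: float  # Å
    region_boundaries: tuple[float, float, float]
    x: np.ndarray | None = None
    y: np.ndarray | None = None
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.box_z <= 0:
            raise ValueError("box_z must be positive")


@dataclass
class BondVectorSet:
    """C–H bond direction vectors with the membrane normal they are scored against."""

    vectors: np.ndarray  # (n, 3) unit vectors
    normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    leaflet_label: str = "phospholipid"
    carbon_index: int = 2

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        norms = np.linalg.norm(self.vectors, axis=1)
        if self.vectors.size and np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("bond vectors must be unit-norm within 1e-6")


@dataclass
class ReusResult:
    """Windows plus exchange bookkeeping from a replica-exchange run."""

    windows: list  # list[WindowSamples]
    acceptance_ratio: float
    n_attempts: int


# ----------------------------------------------------------------------
# Langevin core


def _check_dt(landscape: LandscapeSpec, dt: float) -> None:
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    lo, hi = landscape.domain
    probe = np.linspace(lo, hi, 201)
    d_max = float(np.max(landscape.diffusivity(probe))) * ANG2_PER_NS_TO_ANG2_PER_PS
    feature = _feature_scale(landscape)
    if dt * d_max / feature**2 > 0.05:
        warnings.warn(
            f"dt={dt} ps may be too coarse: dt*D_max/feature^2 = "
            f"{dt * d_max / feature ** 2:.3g} (feature scale {feature:.3g} Å)",
            RuntimeWarning,
            stacklevel=3,
        )


def _feature_scale(landscape: LandscapeSpec) -> float:
    scales = [landscape.domain[1] - landscape.domain[0]]
    if landscape.g_form == "gaussian_barriers":
        scales += [float(w) for w in landscape.g_params["widths"]]
    if landscape.d_form == "piecewise":
        scales.append(float(landscape.d_params.get("smooth", 1.0)))
    return min(scales)


def _apply_boundaries(xi: np.ndarray, lo: float, hi: float, periodic: bool) -> np.ndarray:
    if periodic:
        return (xi - lo) % (hi - lo) + lo
    # reflecting: fold into [lo, hi] (twice covers any single-step overshoot)
    span = hi - lo
    xi = np.abs((xi - lo) % (2 * span))
    xi = np.where(xi > span, 2 * span - xi, xi)
    return xi + lo


def _drift_and_noise_step(
    landscape: LandscapeSpec,
    xi: np.ndarray,
    noise: np.ndarray,
    dt: float,
    bias_centers: np.ndarray | None,
    k: float,
    b: float,
) -> np.ndarray:
    d = landscape.diffusivity(xi) * ANG2_PER_NS_TO_ANG2_PER_PS
    dprime = landscape.diffusivity_grad(xi) * ANG2_PER_NS_TO_ANG2_PER_PS
    grad = landscape.free_energy_grad(xi)
    if bias_centers is not None and k > 0:
        grad = grad + k * (xi - bias_centers)
    if not np.all(np.isfinite(grad)):
        bad = xi[~np.isfinite(grad)]
        raise FloatingPointError(
            f"non-finite landscape evaluation at xi={bad[:3]}"
        )
    step = (-b * d * grad + dprime) * dt + np.sqrt(2.0 * d * dt) * noise
    return xi + step


def simulate_langevin(
    landscape: LandscapeSpec,
    bias: tuple[float, float] | None = None,
    n_steps: int = 100_000,
    dt: float = 0.01,
    seed: int = 0,
    sample_interval: float = 0.1,
    x0: float | None = None,
    window_id: int = 0,
) -> WindowSamples:
    """Overdamped Langevin trajectory on a landscape, optionally biased.

    Parameters
    ----------
    landscape : LandscapeSpec
        Ground truth G(ξ), D(ξ).
    bias : (ξ₀, k) or None
        Harmonic umbrella center (Å) and force constant (kcal/mol/Å²);
        ``None`` runs unbiased.
    n_steps : int
        Number of integrator steps of length ``dt``.
    dt : float
        Integrator time step, ps.
    seed : int
        Seed for the trajectory's random stream (deterministic output).
    sample_interval : float
        Recording stride, ps (must be a multiple of ``dt``).

    Returns
    -------
    WindowSamples
        Recorded time series; ``force_constant`` 0 when unbiased.
    """
    _check_dt(landscape, dt)
    lo, hi = landscape.domain
    b = beta(landscape.temperature)
    xi0, k = (bias if bias is not None else (0.0, 0.0))
    if x0 is None:
        x0 = min(max(xi0, lo), hi) if bias is not None else 0.5 * (lo + hi)
    stride = max(1, int(round(sample_interval / dt)))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), window_id]))
    centers = np.array([xi0]) if bias is not None else None

    xi = np.array([float(x0)])
    out = np.empty(n_steps // stride, dtype=float)
    n_rec = 0
    step = 0
    while step < n_steps:
        m = min(_CHUNK, n_steps - step)
        noise = rng.standard_normal((m, 1))
        for i in range(m):
            xi = _drift_and_noise_step(landscape, xi, noise[i], dt, centers, k, b)
            xi = _apply_boundaries(xi, lo, hi, landscape.periodic)
            step += 1
            if step % stride == 0 and n_rec < out.size:
                out[n_rec] = xi[0]
                n_rec += 1
    return WindowSamples(
        window_id=window_id,
        bias_center=xi0 if bias is not None else 0.0,
        force_constant=k,
        sample_interval=stride * dt,
        samples=out[:n_rec],
    )


def default_umbrella_centers(
    xi_range: tuple[float, float] = DEFAULT_RANGE,
    spacing: float | None = None,
    n_umbrellas: int | None = None,
) -> np.ndarray:
    """Umbrella centers on a uniform grid covering ``xi_range`` inclusively.

    The standard geometry is a series of 180 umbrella intervals over
    −35…65 Å, i.e. 181 centers at a spacing of 100/180 ≈ 0.55 Å.  Pass
    ``spacing`` to derive the interval count from a target spacing
    instead (snapped so the grid ends exactly at the range bounds).
    """
    lo, hi = xi_range
    if n_umbrellas is None:
        n_umbrellas = 180 if spacing is None else max(1, int(round((hi - lo) / spacing)))
    return np.linspace(lo, hi, n_umbrellas + 1)


def run_reus(
    landscape: LandscapeSpec,
    centers: np.ndarray,
    k: float = DEFAULT_FORCE_CONSTANT,
    n_steps: int = 100_000,
    dt: float = 0.01,
    exchange_interval: float = 1.0,
    seed: int = 0,
    sample_interval: float = 0.1,
) -> ReusResult:
    """Replica-exchange umbrella sampling on a synthetic landscape.

    One walker runs per window.  Every ``exchange_interval`` ps, swaps of
    *configurations* between alternating neighbour pairs (even pairs,
    then odd pairs on successive attempts) are accepted with the
    Metropolis probability

        min(1, exp(−β[U_i(ξ_j) + U_j(ξ_i) − U_i(ξ_i) − U_j(ξ_j)]))

    where U_w is window w's harmonic bias.  Per-window time series and
    exchange times are recorded; the mean acceptance ratio is reported
    and a warning is issued below 0.05 (poor window overlap).
    """
    centers = np.asarray(centers, dtype=float)
    if centers.size < 2:
        raise ValueError("need at least 2 umbrella centers")
    if np.any(np.diff(centers) <= 0):
        raise ValueError("centers must be strictly increasing")
    _check_dt(landscape, dt)
    lo, hi = landscape.domain
    b = beta(landscape.temperature)
    n_win = centers.size
    stride = max(1, int(round(sample_interval / dt)))
    steps_per_exchange = max(1, int(round(exchange_interval / dt)))

    ss = np.random.SeedSequence([int(seed)])
    # independent per-window dynamics streams keyed by window id, so that
    # adding windows does not perturb existing windows' noise
    win_rngs = [
        np.random.default_rng(np.random.SeedSequence([int(seed), w]))
        for w in range(n_win)
    ]
    ex_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1_000_003]))

    xi = np.clip(centers.copy(), lo, hi)
    n_samples = n_steps // stride
    series = np.empty((n_win, n_samples), dtype=float)
    exch_times: list[list[float]] = [[] for _ in range(n_win)]
    n_acc = 0
    n_att = 0
    parity = 0
    n_rec = 0
    step = 0
    noise_block = None
    block_pos = _CHUNK  # force initial draw
    while step < n_steps:
        if block_pos >= _CHUNK:
            noise_block = np.column_stack(
                [r.standard_normal(_CHUNK) for r in win_rngs]
            )
            block_pos = 0
        xi = _drift_and_noise_step(
            landscape, xi, noise_block[block_pos], dt, centers, k, b
        )
        xi = _apply_boundaries(xi, lo, hi, landscape.periodic)
        block_pos += 1
        step += 1
        if step % stride == 0 and n_rec < n_samples:
            series[:, n_rec] = xi
            n_rec += 1
        if step % steps_per_exchange == 0 and step < n_steps:
            t_now = step * dt
            first = parity % 2
            pairs = np.arange(first, n_win - 1, 2)
            if pairs.size:
                i, j = pairs, pairs + 1
                du = (
                    0.5 * k * (xi[j] - centers[i]) ** 2
                    + 0.5 * k * (xi[i] - centers[j]) ** 2
                    - 0.5 * k * (xi[i] - centers[i]) ** 2
                    - 0.5 * k * (xi[j] - centers[j]) ** 2
                )
                accept = ex_rng.random(pairs.size) < np.exp(-b * du)
                n_att += pairs.size
                n_acc += int(np.count_nonzero(accept))
                swap_i = i[accept]
                swap_j = j[accept]
                xi[swap_i], xi[swap_j] = xi[swap_j].copy(), xi[swap_i].copy()
                for w in np.concatenate([swap_i, swap_j]):
                    exch_times[w].append(t_now)
            parity += 1

    ratio = n_acc / n_att if n_att else 1.0
    if n_att and ratio < 0.05:
        warnings.warn(
            f"mean exchange acceptance ratio {ratio:.3f} < 0.05: "
            "poor overlap between adjacent windows",
            RuntimeWarning,
            stacklevel=2,
        )
    windows = [
        WindowSamples(
            window_id=w,
            bias_center=float(centers[w]),
            force_constant=k,
            sample_interval=stride * dt,
            samples=series[w, :n_rec].copy(),
            exchange_interval=exchange_interval,
            exchange_times=np.array(exch_times[w]) if exch_times[w] else None,
        )
        for w in range(n_win)
    ]
    return ReusResult(windows=windows, acceptance_ratio=ratio, n_attempts=n_att)


# ----------------------------------------------------------------------
# Toy traces and bond vectors

COMPARTMENTS = ("inner solution", "core", "glycan", "outer solution")

#: default compartment geometry (z in Å): inner solution < −20 < core
#: < 10 < glycan < 35 < outer solution; core midplane at −5
DEFAULT_BOUNDARIES = (-20.0, 10.0, 35.0)
_ANCHORS = {
    "inner solution": -30.0,
    "core": -12.0,
    "glycan": 22.0,
    "outer solution": 45.0,
}


def _script_truth(anchors_z: list[float], boundaries) -> dict:
    """Event counts implied by a monotone-between-anchors path."""
    b_lo, b_mid, b_hi = boundaries
    midplane = 0.5 * (b_lo + b_mid)
    leaflet_exchanges = 0
    for z0, z1 in zip(anchors_z[:-1], anchors_z[1:]):
        if (z0 - midplane) * (z1 - midplane) < 0:
            leaflet_exchanges += 1
    # full crossing: solution-to-opposite-solution traversal
    crossings = 0
    last_solution = None
    for z in anchors_z:
        side = "inner" if z < b_lo else ("outer" if z > b_hi else None)
        if side is not None:
            if last_solution is not None and side != last_solution:
                crossings += 1
            last_solution = side
    return {"full_crossing": crossings, "leaflet_exchange": leaflet_exchanges}


def make_toy_traces(
    n_molecules: int = 1,
    script: list[str] | None = None,
    box_z: float = 90.0,
    seed: int = 0,
    boundaries: tuple[float, float, float] = DEFAULT_BOUNDARIES,
    dwell: float = 100.0,
    ramp: float = 50.0,
    dt: float = 1.0,
    noise: float = 0.0,
    wrap: bool = False,
) -> list[ToyTrace]:
    """Piecewise-smooth z(t) traces visiting scripted compartments.

    Each molecule follows the same compartment script (dwell at each
    compartment's anchor depth, cosine ramp between them); ground-truth
    full-crossing and leaflet-exchange counts implied by the script are
    attached to every trace.  With ``wrap=True`` the trace is wrapped
    into [−box_z/2, box_z/2).
    """
    if script is None:
        script = ["outer solution", "glycan", "core", "inner solution"]
    for name in script:
        if name not in COMPARTMENTS:
            raise ValueError(
                f"unknown compartment {name!r}; expected one of {COMPARTMENTS}"
            )
    anchors = [_ANCHORS[name] for name in script]
    truth = _script_truth(anchors, boundaries)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 77]))

    segs = []
    for i, z_a in enumerate(anchors):
        n_dwell = max(1, int(round(dwell / dt)))
        segs.append(np.full(n_dwell, z_a))
        if i < len(anchors) - 1:
            n_ramp = max(2, int(round(ramp / dt)))
            s = 0.5 * (1.0 - np.cos(np.linspace(0.0, np.pi, n_ramp)))
            segs.append(z_a + (anchors[i + 1] - z_a) * s)
    z_path = np.concatenate(segs)
    times = np.arange(z_path.size) * dt

    traces = []
    for m in range(n_molecules):
        z = z_path + (rng.standard_normal(z_path.size) * noise if noise > 0 else 0.0)
        if wrap:
            z = (z + box_z / 2.0) % box_z - box_z / 2.0
        traces.append(
            ToyTrace(
                molecule_id=m,
                times=times.copy(),
                z=z,
                box_z=box_z,
                region_boundaries=tuple(boundaries),
                truth=dict(truth),
            )
        )
    return traces


def make_bond_vectors(
    target_S: float, n: int = 1000, seed: int = 0, **kwargs
) -> BondVectorSet:
    """Sample C–H bond vectors whose −S_CD converges to ``target_S``.

    −S_CD = −⟨3cos²θ − 1⟩/2 requires ⟨cos²θ⟩ = (1 − 2·target_S)/3,
    which is attainable only for target_S ∈ [−1, 0.5].  Vectors are an
    isotropic/deterministic mixture: with probability p the polar angle
    is pinned (parallel for ⟨cos²θ⟩ > 1/3, perpendicular below), and
    isotropic otherwise, so the empirical value fluctuates around the
    target and converges as n → ∞.
    """
    if not -1.0 <= target_S <= 0.5:
        raise ValueError(
            f"target_S={target_S} unreachable: -S_CD lies in [-1, 0.5]"
        )
    c = (1.0 - 2.0 * target_S) / 3.0  # required <cos^2 theta>
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101]))
    if c >= 1.0 / 3.0:
        p = (3.0 * c - 1.0) / 2.0  # pinned parallel: cos^2 = 1
        cos_pin = 1.0
    else:
        p = 1.0 - 3.0 * c  # pinned perpendicular: cos^2 = 0
        cos_pin = 0.0
    pinned = rng.random(n) < p
    u = rng.uniform(-1.0, 1.0, n)  # isotropic cos(theta)
    cos_t = np.where(pinned, cos_pin * np.sign(rng.random(n) - 0.5), u)
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, 1.0))
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    vectors = np.column_stack(
        [sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t]
    )
    vectors /= np.linalg.norm(vectors, axis=1, keepdims=True)
    return BondVectorSet(vectors=vectors, **kwargs)
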