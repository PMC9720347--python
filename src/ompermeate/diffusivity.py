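"""Position-dependent diffusivity estimators.

Two routes:

* **Biased-window route** — within each umbrella window the restrained
  motion is approximately Ornstein–Uhlenbeck, so the local diffusivity
  follows from the positional variance and autocorrelation time,
  D = var(ξ)/τ.  The autocorrelation function is computed within the
  contiguous segments between replica-exchange events (so configuration
  swaps never contaminate it) and fit to A·exp(−t/τ) over lags up to
  one exchange interval.

* **Equilibrium route** — the Einstein relation on displacement
  statistics at a fixed lag (default 20 ps), binned by the
  displacement's starting position, for membrane-normal (dims=1) or
  lateral (dims=2) diffusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .profiles import Profile
from .synthetic import ToyTrace, WindowSamples

__all__ = [
    "AcfFit",
    "autocorrelation_time",
    "window_diffusivity",
    "diffusivity_profile",
    "einstein_diffusion",
]

ACF_FLOOR = 0.05  # fit log-ACF only where normalized ACF exceeds this
DEFAULT_LAG_PS = 20.0


@dataclass
class AcfFit:
    """Exponential fit A·exp(−t/τ) to a window's positional ACF."""

    tau: float  # ps
    amplitude: float  # Å²
    fit_window: float  # ps, maximum lag used
    goodness: float  # RMS residual of the log-ACF fit
    n_lags: int = 0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")


def _segments(samples: np.ndarray, sample_interval: float, exchange_times,
              exchange_interval: float | None = None):
    """Split a window's series at exchange boundaries.

    When the exchange interval is known the series is cut at *every*
    attempt boundary, not only at accepted swaps: a segment that merely
    survived several attempts is conditioned on those rejections (the
    acceptance probability depends on position), which distorts its
    autocorrelation; intervals between attempts are condition-free.
    """
    cuts = np.array([], dtype=float)
    if exchange_times is not None and len(exchange_times):
        cuts = np.asarray(exchange_times, dtype=float)
    if exchange_interval is not None and exchange_interval > 0:
        t_end = len(samples) * sample_interval
        grid = np.arange(exchange_interval, t_end, exchange_interval)
        cuts = np.union1d(cuts, grid)
    if cuts.size == 0:
        return [samples]
    idx = np.unique(
        np.clip(np.round(cuts / sample_interval).astype(int), 0, len(samples))
    )
    bounds = np.concatenate([[0], idx, [len(samples)]])
    return [samples[a:b] for a, b in zip(bounds[:-1], bounds[1:]) if b - a >= 2]


def _segment_acf(segments, mean, max_lag):
    """Pooled autocovariance over segments at lags 0..max_lag."""
    num = np.zeros(max_lag + 1)
    cnt = np.zeros(max_lag + 1, dtype=int)
    for seg in segments:
        d = seg - mean
        n = len(d)
        for lag in range(0, min(max_lag, n - 1) + 1):
            num[lag] += float(np.dot(d[: n - lag], d[lag:]))
            cnt[lag] += n - lag
    valid = cnt > 0
    acf = np.full(max_lag + 1, np.nan)
    acf[valid] = num[valid] / cnt[valid]
    return acf, cnt


def autocorrelation_time(
    window: WindowSamples,
    fit_window: float | None = None,
    equilibration_fraction: float = 0.0,
) -> AcfFit:
    """Fit the within-segment positional ACF to A·exp(−t/τ).

    The ACF of ξ is computed within each contiguous segment between
    exchange events (deviations taken from the whole window's mean),
    pooled across segments, normalized, and fit by least squares on the
    log over lags in (0, ``fit_window``] where the normalized ACF
    exceeds ``ACF_FLOOR``.  A non-decaying ACF triggers a warning and an
    integrated-ACF fallback for τ; an ACF that decays below the floor
    already at the first lag returns τ = sample interval (resolution
    bound) with a warning.
    """
    w = (
        window.discard_equilibration(equilibration_fraction)
        if equilibration_fraction > 0
        else window
    )
    dt_s = w.sample_interval
    if fit_window is None:
        fit_window = (
            w.exchange_interval
            if w.exchange_interval is not None
            else max(5 * dt_s, 0.05 * len(w.samples) * dt_s)
        )
    segs = _segments(w.samples, dt_s, w.exchange_times, w.exchange_interval)
    if min((len(s) for s in segs), default=0) < 5 and max(
        (len(s) for s in segs), default=0
    ) < 5:
        raise ValueError("need at least 5 samples per exchange segment")
    mean = float(np.mean(w.samples))
    max_lag = int(np.floor(fit_window / dt_s))
    if max_lag < 3:
        raise ValueError(
            f"fewer than 3 usable lags inside fit window {fit_window} ps "
            f"at sample interval {dt_s} ps"
        )
    acf, cnt = _segment_acf(segs, mean, max_lag)
    c0 = acf[0]
    if not np.isfinite(c0) or c0 <= 0:
        raise ValueError("zero-variance (constant) series: no autocorrelation")
    rho = acf / c0
    lags = np.arange(1, max_lag + 1)
    # lags estimated from a handful of leftover pairs carry no weight
    supported = cnt[1:] >= 0.25 * cnt[1:].max()
    usable = lags[np.isfinite(rho[1:]) & (rho[1:] > ACF_FLOOR) & supported]
    # stop at the first excluded lag: beyond it the log-ACF is noise
    if usable.size:
        usable = usable[: int(np.argmax(np.diff(usable, prepend=0) > 1)) or None]
    if usable.size < 2:
        warnings.warn(
            "ACF decays below the fit floor within one sample interval; "
            "tau reported at the sampling resolution bound",
            RuntimeWarning,
            stacklevel=2,
        )
        return AcfFit(
            tau=dt_s, amplitude=c0, fit_window=fit_window, goodness=np.nan, n_lags=0
        )
    t = usable * dt_s
    y = np.log(rho[usable])
    slope, intercept = np.polyfit(t, y, 1, w=np.sqrt(cnt[usable]))
    if slope >= 0:
        warnings.warn(
            "non-decaying ACF; falling back to integrated autocorrelation time",
            RuntimeWarning,
            stacklevel=2,
        )
        tau = dt_s * (0.5 + float(np.nansum(rho[1:])))
        return AcfFit(
            tau=max(tau, dt_s),
            amplitude=c0,
            fit_window=fit_window,
            goodness=np.nan,
            n_lags=int(usable.size),
        )
    tau = -1.0 / slope
    resid = y - (slope * t + intercept)
    return AcfFit(
        tau=float(tau),
        amplitude=float(np.exp(intercept) * c0),
        fit_window=float(fit_window),
        goodness=float(np.sqrt(np.mean(resid**2))),
        n_lags=int(usable.size),
    )


def window_diffusivity(
    window: WindowSamples,
    equilibration_fraction: float = 0.1,
    fit_window: float | None = None,
) -> tuple[float, float]:
    """Local diffusivity from one biased window: D = var(ξ)/τ.

    Variance is taken over all post-equilibration samples of the window
    (segments between exchanges are too short for a stable variance);
    τ comes from the segment-averaged ACF fit.  Returns the mean sampled
    position ξ̄ (Å, the profile abscissa) and D in Å²/ns.
    """
    w = window.discard_equilibration(equilibration_fraction)
    var = float(np.var(w.samples))
    if var == 0.0:
        raise ValueError("zero-variance window: cannot estimate diffusivity")
    fit = autocorrelation_time(w, fit_window=fit_window)
    d_ang2_per_ps = var / fit.tau
    return float(np.mean(w.samples)), d_ang2_per_ps * 1.0e3  # Å²/ns


def diffusivity_profile(
    windows: list[WindowSamples],
    equilibration_fraction: float = 0.1,
    fit_window: float | None = None,
    smoothing: float = 0.0,
) -> Profile:
    """Assemble per-window (ξ̄, D) estimates into a diffusivity profile.

    Windows are processed independently and sorted by mean position;
    duplicate abscissae (within 1e-6 Å) are averaged with a warning.
    The returned profile carries a spline fit.
    """
    if len(windows) < 2:
        raise ValueError("need at least 2 windows for a diffusivity profile")
    pts = [
        window_diffusivity(w, equilibration_fraction, fit_window) for w in windows
    ]
    pts.sort(key=lambda p: p[0])
    xs, ds = [], []
    for x, d in pts:
        if xs and abs(x - xs[-1]) < 1e-6:
            warnings.warn(
                f"duplicate window position ξ̄={x:.6f} Å: averaging",
                RuntimeWarning,
                stacklevel=2,
            )
            ds[-1] = 0.5 * (ds[-1] + d)
        else:
            xs.append(x)
            ds.append(d)
    prof = Profile(
        grid=np.array(xs), values=np.array(ds), kind="diffusivity"
    )
    from .permeability import spline_fit  # local import avoids cycle

    return spline_fit(prof, smoothing=smoothing)


def einstein_diffusion(
    traces: list[ToyTrace],
    lag: float = DEFAULT_LAG_PS,
    bins: int | np.ndarray = 20,
    dims: int = 1,
    drift_removal: bool = False,
) -> Profile:
    """Position-binned Einstein-relation diffusivity, D = ⟨Δx²⟩/(2·dims·lag).

    Displacements over ``lag`` ps are binned by their *starting*
    membrane-normal position.  ``dims=1`` uses the membrane-normal (z)
    displacement; ``dims=2`` uses the two lateral components (traces
    must carry x and y).  ``drift_removal`` subtracts the per-bin mean
    displacement (rigid drift contaminates ⟨Δx²⟩ by drift²·lag² otherwise).
    Empty bins are masked.
    """
    if dims not in (1, 2):
        raise ValueError("dims must be 1 or 2")
    starts, sq = [], []
    for tr in traces:
        dt = float(np.median(np.diff(tr.times)))
        shift = int(round(lag / dt))
        if shift < 1 or shift >= len(tr.z):
            raise ValueError(
                f"trace duration too short for a {lag} ps displacement lag"
            )
        z0 = tr.z[:-shift]
        if dims == 1:
            disp = tr.z[shift:] - z0
            comps = disp[:, None]
        else:
            if tr.x is None or tr.y is None:
                raise ValueError("dims=2 requires lateral coordinates on traces")
            comps = np.column_stack(
                [tr.x[shift:] - tr.x[:-shift], tr.y[shift:] - tr.y[:-shift]]
            )
        starts.append(z0)
        sq.append(comps)
    z0 = np.concatenate(starts)
    comps = np.vstack(sq)
    if np.isscalar(bins):
        edges = np.linspace(z0.min(), z0.max() + 1e-9, int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    which = np.digitize(z0, edges) - 1
    values = np.full(centers.size, np.nan)
    for bi in range(centers.size):
        sel = which == bi
        if not np.any(sel):
            continue
        c = comps[sel]
        if drift_removal:
            c = c - c.mean(axis=0, keepdims=True)
        msd = float(np.mean(np.sum(c**2, axis=1)))
        values[bi] = msd / (2.0 * dims * lag) * 1.0e3  # Å²/ps → Å²/ns
    return Profile(grid=centers, values=values, kind="diffusivity")
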