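"""Plain-text formats and run configuration.

Window data travel as whitespace-delimited collective-variable
trajectory files: '#'-prefixed header lines carry the bias metadata,
followed by two columns (time_ps, xi_angstrom).  One file per window.
Profiles are CSV (xi_angstrom, value[, sd]); configuration is JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .synthetic import (
    DEFAULT_FORCE_CONSTANT,
    DEFAULT_RANGE,
    DEFAULT_SPACING,
    WindowSamples,
)

__all__ = ["read_window_file", "write_window_file", "RunConfig"]

_REQUIRED_KEYS = ("window_id", "bias_center", "force_constant", "sample_interval")


def write_window_file(ws: WindowSamples, path) -> None:
    """Write a window's time series with its bias metadata header."""
    def num(x) -> str:
        return f"{float(x):.17g}"

    lines = [
        f"# window_id: {ws.window_id}",
        f"# bias_center: {num(ws.bias_center)}",
        f"# force_constant: {num(ws.force_constant)}",
        f"# sample_interval: {num(ws.sample_interval)}",
    ]
    if ws.exchange_interval is not None:
        lines.append(f"# exchange_interval: {num(ws.exchange_interval)}")
    if ws.exchange_times is not None:
        lines.append(
            "# exchange_times: " + " ".join(num(t) for t in ws.exchange_times)
        )
    lines.append("# time_ps xi_angstrom")
    for ti, xi in zip(ws.times, ws.samples):
        lines.append(f"{num(ti)} {num(xi)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_window_file(path) -> WindowSamples:
    """Parse a collective-variable window file (lossless round-trip).

    Tolerates blank lines, arbitrary metadata key order, and trailing
    comments; missing required metadata raises an error naming the key,
    and malformed numeric rows raise an error with the line number.
    """
    meta: dict = {}
    samples = []
    path = Path(path)
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(
                f"{path.name}:{lineno}: expected 'time xi' columns, got {raw!r}"
            )
        try:
            samples.append(float(parts[1]))
        except ValueError as exc:
            raise ValueError(
                f"{path.name}:{lineno}: malformed numeric row {raw!r}"
            ) from exc
    for key in _REQUIRED_KEYS:
        if key not in meta:
            raise ValueError(f"{path.name}: missing metadata key {key!r}")
    exchange_interval = (
        float(meta["exchange_interval"]) if "exchange_interval" in meta else None
    )
    exchange_times = (
        np.array([float(x) for x in meta["exchange_times"].split()])
        if "exchange_times" in meta
        else None
    )
    return WindowSamples(
        window_id=int(meta["window_id"]),
        bias_center=float(meta["bias_center"]),
        force_constant=float(meta["force_constant"]),
        sample_interval=float(meta["sample_interval"]),
        samples=np.array(samples),
        exchange_interval=exchange_interval,
        exchange_times=exchange_times,
    )


@dataclass
class RunConfig:
    """Protocol constants and paths for a pipeline run.

    Defaults follow the standard outer-membrane umbrella protocol:
    310 K, reaction coordinate −35…65 Å, 0.55 Å umbrella spacing with
    4 kcal/mol/Å² force constants, boundary searches in (−22, −5) and
    (5, 22) Å, exchanges attempted every 1 ps.
    """

    temperature: float = 310.0
    reaction_coordinate: tuple[float, float] = DEFAULT_RANGE
    umbrella_spacing: float = DEFAULT_SPACING
    force_constant: float = DEFAULT_FORCE_CONSTANT
    exchange_interval: float = 1.0
    sample_interval: float = 0.1
    boundary_search_u: tuple[float, float] = (-22.0, -5.0)
    boundary_search_g: tuple[float, float] = (5.0, 22.0)
    solution_range: tuple[float, float] = (45.0, 65.0)
    n_bins: int | None = None
    spline_smoothing: float = 0.0
    equilibration_fraction: float = 0.1
    wham_tol: float = 1e-7
    wham_max_iter: int = 100_000
    periodic: bool = False
    seed: int = 0
    compounds: list = field(default_factory=list)
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("reaction_coordinate", "boundary_search_u",
                     "boundary_search_g", "solution_range"):
            lo, hi = getattr(self, name)
            if not hi > lo:
                raise ValueError(f"{name} must be an ordered range, got ({lo}, {hi})")
            setattr(self, name, (float(lo), float(hi)))
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        for name in ("reaction_coordinate", "boundary_search_u",
                     "boundary_search_g", "solution_range"):
            d[name] = list(d[name])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        for name in ("reaction_coordinate", "boundary_search_u",
                     "boundary_search_g", "solution_range"):
            if name in kwargs:
                kwargs[name] = tuple(kwargs[name])
        return cls(**kwargs)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
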