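"""Skin-patch geometry, moving-edge / dot stimuli, patch noise and clocks.

Coordinate convention: millimetres, origin at the lower-left corner of the
skin patch, x is the direction of stimulus motion.  Edge orientation is the
signed angle (degrees, positive counterclockwise) between the edge line and
the y axis, so orientation 0 means the edge is perpendicular to its motion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from ._rng import stream

__all__ = [
    "SkinPatch",
    "MechanoreceptorGrid",
    "EdgeStimulus",
    "DotStimulus",
    "NoiseField",
    "SimulationClock",
    "build_grid",
    "edge_distance",
    "edge_signed_offsets",
    "local_amplitude",
    "make_noise_field",
    "sweep_interval",
    "prepare_edge",
]

#: Sentinel for an edge sweep that traverses the whole patch.
UNLIMITED = None

DEFAULT_SPEED = 30.0  # mm/s
DEFAULT_AMPLITUDE = 0.5  # mm
DEFAULT_MARGIN = 2.0  # mm beyond the patch for unlimited sweeps
NOISE_PATCH_SIZE = 0.4  # mm


@dataclass(frozen=True)
class SkinPatch:
    """Rectangular patch of skin, extents in mm."""

    extent_x: float = 12.0
    extent_y: float = 12.0

    @property
    def center(self) -> tuple[float, float]:
        return (self.extent_x / 2.0, self.extent_y / 2.0)

    @property
    def area_cm2(self) -> float:
        return self.extent_x * self.extent_y / 100.0

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        return (
            (p[:, 0] >= 0)
            & (p[:, 0] <= self.extent_x)
            & (p[:, 1] >= 0)
            & (p[:, 1] <= self.extent_y)
        )


@dataclass(frozen=True)
class MechanoreceptorGrid:
    """Regular lattice of mechanoreceptor sites covering a patch."""

    extent_x: float
    extent_y: float
    spacing: float
    positions: np.ndarray  # (n, 2), row-major from the origin corner

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def patch(self) -> SkinPatch:
        return SkinPatch(self.extent_x, self.extent_y)


def build_grid(extent_x: float, extent_y: float, spacing: float = 0.1) -> MechanoreceptorGrid:
    """Build the mechanoreceptor lattice (``spacing`` intervals, row-major)."""
    if extent_x <= 0 or extent_y <= 0 or spacing <= 0:
        raise ValueError("extents and spacing must be positive")
    nx = int(round(extent_x / spacing)) + 1
    ny = int(round(extent_y / spacing)) + 1
    xs = np.arange(nx) * spacing
    ys = np.arange(ny) * spacing
    gx, gy = np.meshgrid(xs, ys)
    positions = np.column_stack([gx.ravel(), gy.ravel()])
    return MechanoreceptorGrid(extent_x, extent_y, spacing, positions)


@dataclass(frozen=True)
class EdgeStimulus:
    """An infinite line indentation moving along +x at constant speed.

    ``ref_start`` is the point the line passes through at t = 0; it is set by
    :func:`prepare_edge` from the sweep plan and patch geometry.
    """

    orientation_deg: float
    speed: float = DEFAULT_SPEED  # mm/s
    amplitude: float = DEFAULT_AMPLITUDE  # mm indentation
    window_ms: Optional[float] = UNLIMITED
    ref_start: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (-90.0 < self.orientation_deg < 90.0):
            raise ValueError("orientation must lie in (-90, 90) degrees")
        if self.speed <= 0 or self.amplitude <= 0:
            raise ValueError("speed and amplitude must be positive")
        if self.window_ms is not None and self.window_ms <= 0:
            raise ValueError("window must be positive or UNLIMITED")

    @property
    def normal(self) -> np.ndarray:
        """Unit normal of the edge line (points along motion at 0 deg)."""
        th = math.radians(self.orientation_deg)
        return np.array([math.cos(th), math.sin(th)])

    @property
    def direction(self) -> np.ndarray:
        """Unit vector along the edge line."""
        th = math.radians(self.orientation_deg)
        return np.array([-math.sin(th), math.cos(th)])


@dataclass(frozen=True)
class DotStimulus:
    """A point indentation at a fixed position."""

    center: tuple[float, float]
    amplitude: float = DEFAULT_AMPLITUDE

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


@dataclass(frozen=True)
class SimulationClock:
    """Uniform time grid in milliseconds."""

    dt: float = 1.0
    t_start: float = 0.0
    t_end: float = 1.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")

    @property
    def n_ticks(self) -> int:
        return int(round((self.t_end - self.t_start) / self.dt))

    @property
    def times(self) -> np.ndarray:
        return self.t_start + self.dt * np.arange(self.n_ticks)


def prepare_edge(
    stimulus: EdgeStimulus, patch: SkinPatch, margin: float = DEFAULT_MARGIN
) -> EdgeStimulus:
    """Anchor the edge's t = 0 reference point for its sweep over ``patch``.

    Unlimited window: the line starts ``margin`` before the patch along x and
    finishes ``margin`` beyond it.  Windowed: the travel of length
    speed x window is centred on the patch centre.
    """
    cy = patch.extent_y / 2.0
    if stimulus.window_ms is UNLIMITED:
        x0 = -margin
    else:
        travel = stimulus.speed * stimulus.window_ms / 1000.0
        x0 = patch.extent_x / 2.0 - travel / 2.0
    return replace(stimulus, ref_start=(x0, cy))


def sweep_interval(
    stimulus: EdgeStimulus, patch: SkinPatch, margin: float = DEFAULT_MARGIN
) -> SimulationClock:
    """Clock spanning the stimulus sweep (dt = 1 ms)."""
    if stimulus.window_ms is UNLIMITED:
        travel = patch.extent_x + 2.0 * margin
        duration = 1000.0 * travel / stimulus.speed
    else:
        duration = float(stimulus.window_ms)
    return SimulationClock(dt=1.0, t_start=0.0, t_end=duration)


def edge_signed_offsets(
    points: np.ndarray, stimulus: EdgeStimulus, clock: SimulationClock
) -> np.ndarray:
    """Signed point-to-line distances for all points x all clock ticks.

    Returns an array of shape ``(n_points, n_ticks)``; take ``abs`` for the
    perpendicular distance.  The line translates along +x at the stimulus
    speed, so the offset of a point shrinks linearly at speed*cos(theta).
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    n = stimulus.normal
    c0 = (p - np.asarray(stimulus.ref_start)) @ n  # offset at t = 0
    v_ms = stimulus.speed / 1000.0
    return c0[:, None] - v_ms * n[0] * clock.times[None, :]


def edge_distance(point: np.ndarray, stimulus: EdgeStimulus, t: float) -> float:
    """Perpendicular distance (mm) from ``point`` to the edge line at time ``t`` (ms)."""
    clock = SimulationClock(dt=1.0, t_start=float(t), t_end=float(t) + 1.0)
    return float(np.abs(edge_signed_offsets(np.atleast_2d(point), stimulus, clock))[0, 0])


@dataclass(frozen=True)
class NoiseField:
    """Static additive-amplitude noise, one offset per 0.4 mm patch tile."""

    level_pct: float
    patch_size: float
    offsets: np.ndarray  # (ny_tiles, nx_tiles), mm
    seed: Optional[int] = None

    def offset_at(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        ny, nx = self.offsets.shape
        ix = np.clip((p[:, 0] / self.patch_size).astype(int), 0, nx - 1)
        iy = np.clip((p[:, 1] / self.patch_size).astype(int), 0, ny - 1)
        return self.offsets[iy, ix]


def make_noise_field(
    level_pct: float,
    patch: SkinPatch,
    stim_amplitude: float = DEFAULT_AMPLITUDE,
    patch_size: float = NOISE_PATCH_SIZE,
    seed: int = 0,
) -> NoiseField:
    """Draw per-tile offsets uniformly in +-(level_pct/100 * stim_amplitude)."""
    if level_pct < 0:
        raise ValueError("noise level must be non-negative")
    nx = int(math.ceil(patch.extent_x / patch_size))
    ny = int(math.ceil(patch.extent_y / patch_size))
    if level_pct == 0:
        offsets = np.zeros((ny, nx))
    else:
        bound = level_pct / 100.0 * stim_amplitude
        offsets = stream(seed, "noise-field").uniform(-bound, bound, size=(ny, nx))
    return NoiseField(level_pct, patch_size, offsets, seed=seed)


def local_amplitude(
    points: np.ndarray,
    stim_amplitude: float,
    noise: Optional[NoiseField],
    patch: Optional[SkinPatch] = None,
) -> np.ndarray:
    """Stimulus amplitude experienced at each point: base + tile offset, floored at 0."""
    p = np.atleast_2d(np.asarray(points, dtype=float))
    if patch is not None and not patch.contains(p).all():
        raise ValueError("point outside skin patch")
    if noise is None:
        amp = np.full(len(p), float(stim_amplitude))
    else:
        amp = stim_amplitude + noise.offset_at(p)
    return np.maximum(amp, 0.0)
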