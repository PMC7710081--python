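"""Multi-branch spiking model of an FA-1 first-order tactile neuron.

Each neuron innervates a set of mechanoreceptors (MRs).  The drive of one MR
is the stimulus amplitude times a sigmoid of the edge distance; spikes are
initiated per branch by a phase accumulator with a linear input-rate relation
(gain 1), saturation at the neuron's maximal rate, an adaptation rule that
permits firing only while the drive is increasing, and a 0.01 mm indentation
threshold.  Under the default RESET scheme a spike at any branch resets spike
initiation at all branches; MIXING and SUMMATION are diagnostic variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .skin_stimulus import (
    DotStimulus,
    EdgeStimulus,
    NoiseField,
    SimulationClock,
    SkinPatch,
    edge_signed_offsets,
    local_amplitude,
)

__all__ = [
    "ResponsivityParams",
    "NeuronModel",
    "BranchState",
    "SpikeTrain",
    "RateCurve",
    "mr_input",
    "effective_indentation",
    "step_branch",
    "simulate_neuron",
    "run_branches",
    "edge_drive",
    "rate_curve",
    "rates_from_spike_matrix",
    "make_simple_rf_neuron",
    "rf_boundary_from_dot_scan",
    "sigmoid_responsivity",
]

SPIKE_INDENT_THRESHOLD = 0.01  # mm of effective indentation
R1_LIMITS = (0.05, 1.0)
R2_LIMITS = (0.2, 1.0)

RESET = "reset"
MIXING = "mixing"
SUMMATION = "summation"
SCHEMES = (RESET, MIXING, SUMMATION)


@dataclass(frozen=True)
class ResponsivityParams:
    """Distance responsivity of a mechanoreceptor.

    ``r1`` is the sigmoidal half-height distance, ``r1 + r2`` the total reach,
    and ``w_mr`` the input weight in Hz per mm of indentation (set to twice
    the target neuron's maximal firing rate, shared by all MRs).
    """

    r1: float
    r2: float
    w_mr: float

    def __post_init__(self) -> None:
        if self.r1 <= 0 or self.r2 <= 0 or self.w_mr <= 0:
            raise ValueError("r1, r2 and w_mr must be positive")

    @property
    def reach(self) -> float:
        return self.r1 + self.r2


@dataclass(frozen=True)
class NeuronModel:
    mr_locations: np.ndarray  # (n, 2) mm
    responsivity: ResponsivityParams
    max_rate: float  # Hz, saturation
    scheme: str = RESET

    def __post_init__(self) -> None:
        locs = np.atleast_2d(np.asarray(self.mr_locations, dtype=float))
        object.__setattr__(self, "mr_locations", locs)
        if locs.shape[0] < 1 or locs.shape[1] != 2:
            raise ValueError("need at least one 2-D mechanoreceptor location")
        if self.max_rate <= 0:
            raise ValueError("max_rate must be positive")
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")

    @property
    def n_mr(self) -> int:
        return len(self.mr_locations)

    def with_locations(self, locations: np.ndarray) -> "NeuronModel":
        return replace(self, mr_locations=np.asarray(locations, dtype=float))


@dataclass
class BranchState:
    """Per-branch accumulator state (plumbing for the scalar stepper)."""

    phase: float = 0.0
    prev_input: float = 0.0


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times on the 1 ms grid, strictly increasing."""

    times: np.ndarray  # ms
    duration: float  # ms
    t_start: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float).ravel()
        object.__setattr__(self, "times", t)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class RateCurve:
    times: np.ndarray  # ms
    rate: np.ndarray  # Hz

    def __post_init__(self) -> None:
        if len(self.times) != len(self.rate):
            raise ValueError("times and rate must have equal length")


def sigmoid_responsivity(d: np.ndarray, r1: np.ndarray, r2: np.ndarray) -> np.ndarray:
    """Dimensionless distance factor: sigmoid in d/r1, zero beyond r1 + r2."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    term = 1.0 - 1.0 / (1.0 + np.exp(-5.0 * (d / r1 - 1.0)))
    return np.where(d <= np.asarray(r1) + np.asarray(r2), term, 0.0)


def mr_input(d, a_local, params: ResponsivityParams):
    """Mechanoreceptor drive in Hz for distance ``d`` and local amplitude ``a_local``."""
    return np.asarray(a_local) * params.w_mr * sigmoid_responsivity(d, params.r1, params.r2)


def effective_indentation(d, a_local, params: ResponsivityParams):
    """Indentation (mm) felt at the MR; spiking requires >= 0.01 mm."""
    return np.asarray(a_local) * sigmoid_responsivity(d, params.r1, params.r2)


def step_branch(
    state: BranchState,
    drive: float,
    dt: float,
    max_rate: float,
    eff_indent: Optional[float] = None,
) -> tuple[BranchState, bool]:
    """Advance one branch by one tick; returns the new state and spike flag.

    On a spike the branch's own phase restarts at 0 (cross-branch resetting is
    the RESET scheme's job in :func:`run_branches`).  Pass ``eff_indent`` to
    enforce the 0.01 mm indentation spike threshold.
    """
    if drive < 0:
        raise ValueError("drive must be non-negative")
    rate = min(drive, max_rate)
    phase = state.phase + rate * dt / 1000.0
    increasing = drive > state.prev_input
    above = True if eff_indent is None else eff_indent >= SPIKE_INDENT_THRESHOLD
    spike = phase >= 1.0 and increasing and above
    if spike:
        phase = 0.0
    return BranchState(phase=phase, prev_input=drive), spike


def run_branches(
    drive: np.ndarray,
    eff_indent: np.ndarray,
    neuron_index: np.ndarray,
    max_rate: np.ndarray,
    dt: float,
    scheme: str = RESET,
) -> np.ndarray:
    """Tick the accumulator dynamics for a batch of branches.

    Parameters
    ----------
    drive, eff_indent : (B, T) arrays of per-branch input (Hz) and effective
        indentation (mm), precomputed over the clock.
    neuron_index : (B,) sorted array mapping each branch to its neuron.
    max_rate : (B,) per-branch saturation rate.
    dt : tick length in ms.

    Returns a boolean spike matrix of shape (n_neurons, T).
    """
    drive = np.asarray(drive, dtype=float)
    B, T = drive.shape
    neuron_index = np.asarray(neuron_index)
    if np.any(np.diff(neuron_index) < 0):
        raise ValueError("neuron_index must be sorted")
    n_neurons = int(neuron_index[-1]) + 1 if B else 0
    starts = np.searchsorted(neuron_index, np.arange(n_neurons))

    increasing = np.empty_like(drive, dtype=bool)
    increasing[:, 0] = drive[:, 0] > 0.0
    increasing[:, 1:] = drive[:, 1:] > drive[:, :-1]
    above = np.asarray(eff_indent) >= SPIKE_INDENT_THRESHOLD
    gate = increasing & above
    rate = np.minimum(drive, np.asarray(max_rate, dtype=float)[:, None])
    incr = rate * (dt / 1000.0)

    phase = np.zeros(B)
    spikes = np.zeros((n_neurons, T), dtype=bool)
    for t in range(T):
        phase += incr[:, t]
        eligible = (phase >= 1.0) & gate[:, t]
        if not eligible.any():
            continue
        fired = np.logical_or.reduceat(eligible, starts)
        spikes[:, t] = fired
        if scheme == RESET:
            phase[fired[neuron_index]] = 0.0
        else:  # MIXING / SUMMATION: only the spiking branch restarts
            phase[eligible] = 0.0
    return spikes


def edge_drive(
    positions: np.ndarray,
    stimulus: EdgeStimulus,
    clock: SimulationClock,
    r1: np.ndarray,
    r2: np.ndarray,
    w: np.ndarray,
    noise: Optional[NoiseField] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-branch (drive Hz, effective indentation mm) matrices for a moving edge.

    ``r1``, ``r2``, ``w`` broadcast against the branch axis, so heterogeneous
    batches (e.g. a GA population) are simulated in one call.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    d = np.abs(edge_signed_offsets(positions, stimulus, clock))
    r1 = np.broadcast_to(np.asarray(r1, dtype=float), (len(positions),))[:, None]
    r2 = np.broadcast_to(np.asarray(r2, dtype=float), (len(positions),))[:, None]
    sig = sigmoid_responsivity(d, r1, r2)
    if stimulus.window_ms is not None:
        # windowed presentation: the stimulus exists only during the window,
        # though the clock may extend past it (e.g. for PSP integration)
        present = (clock.times >= 0.0) & (clock.times <= stimulus.window_ms)
        sig = sig * present[None, :]
    a_local = local_amplitude(positions, stimulus.amplitude, noise)
    eff = a_local[:, None] * sig
    w = np.broadcast_to(np.asarray(w, dtype=float), (len(positions),))[:, None]
    return w * eff, eff


def simulate_neuron(
    neuron: NeuronModel,
    stimulus: EdgeStimulus,
    clock: SimulationClock,
    noise: Optional[NoiseField] = None,
) -> SpikeTrain:
    """Simulate one neuron's response to a moving edge over ``clock``."""
    p = neuron.responsivity
    drive, eff = edge_drive(
        neuron.mr_locations, stimulus, clock, p.r1, p.r2, p.w_mr, noise
    )
    if neuron.scheme == SUMMATION:
        drive = drive.sum(axis=0, keepdims=True)
        eff = eff.sum(axis=0, keepdims=True)
        index = np.zeros(1, dtype=int)
        max_rate = np.full(1, neuron.max_rate)
    else:
        index = np.zeros(neuron.n_mr, dtype=int)
        max_rate = np.full(neuron.n_mr, neuron.max_rate)
    spikes = run_branches(drive, eff, index, max_rate, clock.dt, scheme=neuron.scheme)
    return SpikeTrain(
        times=clock.times[spikes[0]],
        duration=clock.t_end - clock.t_start,
        t_start=clock.t_start,
    )


def rates_from_spike_matrix(
    spikes: np.ndarray, dt: float, smoothing_sigma: float = 5.0
) -> np.ndarray:
    """Gaussian-smoothed instantaneous rate (Hz) per row of a spike matrix."""
    counts = np.asarray(spikes, dtype=float) * (1000.0 / dt)
    # truncate far out so a mid-trace spike integrates to 1 within 1e-6
    return gaussian_filter1d(
        counts, sigma=smoothing_sigma / dt, axis=-1, mode="constant", truncate=8.0
    )


def rate_curve(
    train: SpikeTrain, clock: SimulationClock, smoothing_sigma: float = 5.0
) -> RateCurve:
    """Smoothed firing-rate time series; integrates to the spike count."""
    if smoothing_sigma <= 0:
        raise ValueError("smoothing sigma must be positive")
    idx = np.round((train.times - clock.t_start) / clock.dt).astype(int)
    counts = np.zeros(clock.n_ticks)
    np.add.at(counts, np.clip(idx, 0, clock.n_ticks - 1), 1.0)
    rate = rates_from_spike_matrix(counts[None, :], clock.dt, smoothing_sigma)[0]
    return RateCurve(times=clock.times, rate=rate)


def make_simple_rf_neuron(
    center: Sequence[float], max_rate: float, r1: float = 0.05, r2: float = 1.45
) -> NeuronModel:
    """Single-MR neuron with a symmetric responsivity profile (simple RF)."""
    return NeuronModel(
        mr_locations=np.asarray([center], dtype=float),
        responsivity=ResponsivityParams(r1=r1, r2=r2, w_mr=2.0 * max_rate),
        max_rate=max_rate,
    )


def rf_boundary_from_dot_scan(
    neuron: NeuronModel,
    patch: SkinPatch,
    dot_amplitude: float = 0.5,
    scan_spacing: float = 0.2,
    ramp_ms: float = 50.0,
):
    """Receptive-field boundary: region of dot positions evoking >= 1 spike.

    Each scan position presents a dot whose amplitude ramps from 0 to
    ``dot_amplitude`` over ``ramp_ms`` (so drive is increasing); all positions
    are simulated in one batch.  Returns a shapely polygon built as the union
    of scan tiles around responsive positions.
    """
    from shapely.geometry import box
    from shapely.ops import unary_union

    if dot_amplitude <= 0:
        raise ValueError("dot amplitude must be positive")
    nx = int(round(patch.extent_x / scan_spacing)) + 1
    ny = int(round(patch.extent_y / scan_spacing)) + 1
    xs = np.arange(nx) * scan_spacing
    ys = np.arange(ny) * scan_spacing
    gx, gy = np.meshgrid(xs, ys)
    scan = np.column_stack([gx.ravel(), gy.ravel()])  # (P, 2)

    p = neuron.responsivity
    # static distances: (P, n_mr)
    dists = np.linalg.norm(scan[:, None, :] - neuron.mr_locations[None, :, :], axis=-1)
    sig = sigmoid_responsivity(dists, p.r1, p.r2).ravel()  # (P * n_mr,)

    T = int(ramp_ms) + 10
    amp_t = np.minimum(np.arange(1, T + 1) / ramp_ms, 1.0) * dot_amplitude  # (T,)
    eff = sig[:, None] * amp_t[None, :]
    drive = p.w_mr * eff
    index = np.repeat(np.arange(len(scan)), neuron.n_mr)
    max_rate = np.full(len(sig), neuron.max_rate)
    spikes = run_branches(drive, eff, index, max_rate, dt=1.0, scheme=neuron.scheme)
    responsive = spikes.any(axis=1)
    if not responsive.any():
        raise ValueError("no dot position evoked a spike (empty receptive field)")

    half = scan_spacing * 0.51  # slight overlap merges corner-touching tiles
    tiles = [
        box(x - half, y - half, x + half, y + half) for x, y in scan[responsive]
    ]
    return unary_union(tiles)
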