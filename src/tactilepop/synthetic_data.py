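"""Synthetic stand-ins for the microneurography recordings.

Generates ground-truth model neurons, multi-trial jittered spike "recordings"
following the experimental orientation protocol (train +-22.5/+-45 deg,
cross-validate 0 deg, test 30 deg), and a small perfectly separable
classification fixture.  Datasets are schema-identical to what the fitting
pipeline consumes, so every downstream module runs unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._rng import stream
from .fitting import CROSSVAL_ORIENTATION, FitDataset, TEST_ORIENTATION, TRAIN_ORIENTATIONS
from .neuron_model import (
    NeuronModel,
    ResponsivityParams,
    SpikeTrain,
    rate_curve,
    rf_boundary_from_dot_scan,
    simulate_neuron,
)
from .readout import features_from_spikes, psp_kernel
from .skin_stimulus import EdgeStimulus, SkinPatch, prepare_edge, sweep_interval

__all__ = [
    "SyntheticNeuronSpec",
    "JitterModel",
    "SyntheticDataset",
    "make_synthetic_neuron",
    "synth_recordings",
    "make_separable_fixture",
]

#: 7 trials at the test orientation mirror the published reliability statistic.
N_TEST_TRIALS = 7


@dataclass(frozen=True)
class SyntheticNeuronSpec:
    n_mr: int = 20
    rf_center: tuple[float, float] = (6.0, 6.0)
    rf_axes: tuple[float, float] = (3.0, 2.0)  # ellipse semi-axes, mm
    rf_rotation_deg: float = 0.0
    r1: float = 0.5
    r2: float = 0.8
    max_rate: float = 250.0
    seed: int = 0


@dataclass(frozen=True)
class JitterModel:
    """Trial-to-trial variability: Gaussian spike-time jitter + thinning."""

    sigma_ms: float = 2.0
    deletion_p: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_ms < 0:
            raise ValueError("jitter sigma must be non-negative")
        if not 0.0 <= self.deletion_p <= 1.0:
            raise ValueError("deletion probability must lie in [0, 1]")


@dataclass
class SyntheticDataset(FitDataset):
    """FitDataset plus the generating ground truth, for recovery scoring."""

    ground_truth: Optional[NeuronModel] = None


def make_synthetic_neuron(spec: SyntheticNeuronSpec, patch: SkinPatch = SkinPatch()) -> NeuronModel:
    """Ground-truth neuron with MRs uniform inside the RF ellipse."""
    cx, cy = spec.rf_center
    a, b = spec.rf_axes
    if not (0 < a and 0 < b):
        raise ValueError("ellipse axes must be positive")
    if cx - a < 0 or cx + a > patch.extent_x or cy - b < 0 or cy + b > patch.extent_y:
        raise ValueError("RF ellipse does not fit inside the patch")
    rng = stream(spec.seed, "synthetic-neuron")
    # uniform in unit disc, scaled and rotated into the ellipse
    r = np.sqrt(rng.uniform(0, 1, size=spec.n_mr))
    phi = rng.uniform(0, 2 * np.pi, size=spec.n_mr)
    pts = np.column_stack([a * r * np.cos(phi), b * r * np.sin(phi)])
    th = np.radians(spec.rf_rotation_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    locations = pts @ rot.T + np.array([cx, cy])
    return NeuronModel(
        mr_locations=locations,
        responsivity=ResponsivityParams(spec.r1, spec.r2, 2.0 * spec.max_rate),
        max_rate=spec.max_rate,
    )


def _jitter_train(
    train: SpikeTrain, jitter: JitterModel, rng: np.random.Generator, dt: float = 1.0
) -> SpikeTrain:
    times = train.times
    if jitter.deletion_p > 0:
        times = times[rng.random(len(times)) >= jitter.deletion_p]
    if jitter.sigma_ms > 0 and len(times):
        times = times + rng.normal(0.0, jitter.sigma_ms, size=len(times))
    times = np.round(times / dt) * dt
    times = np.unique(times[(times >= train.t_start) & (times < train.t_start + train.duration)])
    return SpikeTrain(times=times, duration=train.duration, t_start=train.t_start)


def synth_recordings(
    neuron: NeuronModel,
    patch: SkinPatch = SkinPatch(),
    n_trials: int = 7,
    jitter: JitterModel = JitterModel(),
    orientations: Sequence[float] = TRAIN_ORIENTATIONS + (CROSSVAL_ORIENTATION, TEST_ORIENTATION),
    smoothing_sigma: float = 10.0,
    boundary_scan_spacing: float = 0.25,
) -> SyntheticDataset:
    """Simulate the ground-truth neuron and emit jittered multi-trial recordings."""
    if n_trials < 1:
        raise ValueError("need at least one trial")
    probe = prepare_edge(EdgeStimulus(orientation_deg=0.0), patch)
    clock = sweep_interval(probe, patch)
    trains: dict[float, list[SpikeTrain]] = {}
    for orientation in orientations:
        stim = prepare_edge(EdgeStimulus(orientation_deg=orientation), patch)
        clean = simulate_neuron(neuron, stim, clock)
        count = max(n_trials, N_TEST_TRIALS) if orientation == TEST_ORIENTATION else n_trials
        rng = stream(jitter.seed, "recording", orientation)
        trains[orientation] = [_jitter_train(clean, jitter, rng) for _ in range(count)]

    boundary = rf_boundary_from_dot_scan(neuron, patch, scan_spacing=boundary_scan_spacing)
    from .fitting import estimate_max_rate

    try:
        max_rate = estimate_max_rate(
            [t for o in TRAIN_ORIENTATIONS if o in trains for t in trains[o]]
        )
    except ValueError:
        # recordings too sparse to estimate (e.g. heavy deletion); fall back
        # on the generator's ground truth
        max_rate = neuron.max_rate
    return SyntheticDataset(
        trains=trains,
        boundary=boundary,
        patch=patch,
        clock=clock,
        max_rate=float(max_rate),
        smoothing_sigma=smoothing_sigma,
        ground_truth=neuron,
    )


def make_separable_fixture(
    n_neurons: int = 6,
    n_trials: int = 40,
    n_ticks: int = 120,
    channels: Sequence[str] = ("ampa",),
    noise_rate: float = 0.02,
    seed: int = 0,
):
    """Tiny trial set where a known sparse weight vector separates the labels.

    Neuron 0 fires a burst only on +theta trials and neuron 1 only on -theta
    trials; the rest fire label-independent random spikes.  Returns
    ``(features, labels, true_weights)`` where ``true_weights`` (shape
    ``(2, n_neurons * n_channels)``) classifies every trial correctly.
    """
    rng = stream(seed, "separable-fixture")
    labels = np.array([1, -1] * (n_trials // 2) + [1] * (n_trials % 2))
    features = []
    n_channels = len(channels)
    for y in labels:
        spikes = rng.random((n_neurons, n_ticks)) < noise_rate
        spikes[0, :] = False
        spikes[1, :] = False
        burst = slice(n_ticks // 2, n_ticks // 2 + 5)
        if y > 0:
            spikes[0, burst] = True
        else:
            spikes[1, burst] = True
        features.append(features_from_spikes(spikes.astype(float), channels))
    true_weights = np.zeros((2, n_neurons * n_channels))
    true_weights[1, 0 * n_channels] = 1.0  # +theta unit listens to neuron 0
    true_weights[0, 1 * n_channels] = 1.0  # -theta unit listens to neuron 1
    return np.asarray(features), labels, true_weights
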