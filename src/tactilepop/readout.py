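"""PSP kernels, spike-train convolution and the two-unit orientation classifier.

The classifier has one unit per orientation (-theta, +theta).  Each unit takes
a weighted sum of per-neuron, per-channel PSP traces (weights in [-1, 1];
negative weights model feed-forward inhibition) and responds with the maximum
of the summed trace over time; the unit with the larger response wins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import fftconvolve

from . import fitting
from ._rng import stream

__all__ = [
    "PSPKernel",
    "Classifier",
    "CHANNEL_TAU_DECAY",
    "psp_kernel",
    "kernel_peak_time",
    "convolve_psp",
    "features_from_spikes",
    "unit_response",
    "classify_trial",
    "train_classifier",
    "random_classifier",
    "evaluate_classifier",
]

#: Decay time constants (ms) of the named synaptic channels.
CHANNEL_TAU_DECAY = {"ampa": 3.0, "nmda": 65.0}
TAU_RISE = 0.5  # ms
KERNEL_CUTOFF_DECAYS = 8  # truncate at 8 * tau_decay; tail < e^-8

RAW = "raw"
PEAK1 = "peak1"


def kernel_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Closed-form argmax of the difference-of-exponentials kernel (ms)."""
    return math.log(tau_decay / tau_rise) / (1.0 / tau_rise - 1.0 / tau_decay)


@dataclass(frozen=True)
class PSPKernel:
    tau_rise: float = TAU_RISE
    tau_decay: float = 3.0
    normalization: str = PEAK1

    def __post_init__(self) -> None:
        if not (0 < self.tau_rise < self.tau_decay):
            raise ValueError("require tau_decay > tau_rise > 0")
        if self.normalization not in (RAW, PEAK1):
            raise ValueError("normalization must be 'raw' or 'peak1'")

    def sample(self, dt: float = 1.0, duration: Optional[float] = None) -> np.ndarray:
        return psp_kernel(self.tau_rise, self.tau_decay, dt, duration, self.normalization)


def psp_kernel(
    tau_rise: float = TAU_RISE,
    tau_decay: float = 3.0,
    dt: float = 1.0,
    duration: Optional[float] = None,
    normalization: str = PEAK1,
) -> np.ndarray:
    """Sampled kernel exp(-t/tau_decay) - exp(-t/tau_rise) for t >= 0."""
    if tau_decay <= tau_rise:
        raise ValueError("tau_decay must exceed tau_rise")
    if duration is None:
        duration = KERNEL_CUTOFF_DECAYS * tau_decay
    t = np.arange(0.0, duration, dt)
    k = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    if normalization == PEAK1:
        t_star = kernel_peak_time(tau_rise, tau_decay)
        peak = math.exp(-t_star / tau_decay) - math.exp(-t_star / tau_rise)
        k = k / peak
    elif normalization != RAW:
        raise ValueError("normalization must be 'raw' or 'peak1'")
    return k


def convolve_psp(spikes: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Superpose kernel copies at spike ticks; output length equals input length.

    ``spikes`` may be a single 0/1 vector or a (rows, T) matrix.
    """
    spikes = np.asarray(spikes, dtype=float)
    single = spikes.ndim == 1
    mat = np.atleast_2d(spikes)
    T = mat.shape[1]
    out = fftconvolve(mat, np.atleast_2d(kernel), axes=1)[:, :T]
    return out[0] if single else out


def features_from_spikes(
    spike_matrix: np.ndarray, channels: Sequence[str], dt: float = 1.0
) -> np.ndarray:
    """PSP feature block for one trial.

    Returns shape (n_neurons * n_channels, T) with neuron-major layout:
    feature index = neuron * n_channels + channel.
    """
    blocks = []
    for name in channels:
        kernel = psp_kernel(tau_decay=CHANNEL_TAU_DECAY[name], dt=dt)
        blocks.append(convolve_psp(spike_matrix, kernel))
    stacked = np.stack(blocks, axis=1)  # (neurons, channels, T)
    n, c, T = stacked.shape
    return stacked.reshape(n * c, T)


@dataclass(frozen=True)
class Classifier:
    """Two-unit linear PSP readout; unit 0 is tuned to -theta, unit 1 to +theta."""

    weights: np.ndarray  # (2, n_features) in [-1, 1]
    channels: tuple[str, ...]
    theta_deg: float
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "channels", tuple(self.channels))
        if w.ndim != 2 or w.shape[0] != 2:
            raise ValueError("weights must have shape (2, n_features)")
        if np.any(np.abs(w) > 1.0 + 1e-12):
            raise ValueError("weights must lie in [-1, 1]")

    @property
    def n_features(self) -> int:
        return self.weights.shape[1]


def unit_response(features: np.ndarray, weights: np.ndarray) -> float:
    """Max over time of the weighted sum of PSP traces."""
    features = np.asarray(features, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if features.shape[0] != weights.shape[0]:
        raise ValueError("weight/feature dimension mismatch")
    return float(np.max(weights @ features))


def classify_trial(
    features: np.ndarray, classifier: Classifier, rng: Optional[np.random.Generator] = None
) -> int:
    """Return -1 (unit tuned to -theta) or +1; exact ties resolved at random."""
    r_neg = unit_response(features, classifier.weights[0])
    r_pos = unit_response(features, classifier.weights[1])
    if r_neg == r_pos:
        rng = rng if rng is not None else np.random.default_rng()
        return int(rng.choice([-1, 1]))
    return 1 if r_pos > r_neg else -1


def _batch_success(
    genomes: np.ndarray, features: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Training success and mean margin per genome, fully vectorised.

    ``genomes`` is (P, 2F); ``features`` is (n_trials, F, T); ``labels`` +-1.
    """
    P = genomes.shape[0]
    n_trials, F, T = features.shape
    # responses[u]: (P, n_trials) via one matmul per unit
    flat2 = np.ascontiguousarray(features.transpose(1, 0, 2).reshape(F, n_trials * T))
    resp = []
    for u in range(2):
        W = genomes[:, u * F : (u + 1) * F]
        r = (W @ flat2).reshape(P, n_trials, T).max(axis=2)
        resp.append(r)
    margin = (resp[1] - resp[0]) * labels[None, :]  # >0 means correct
    success = (margin > 0).mean(axis=1)
    return success, np.tanh(margin).mean(axis=1)


def train_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    channels: Sequence[str],
    theta_deg: float,
    config: Optional["fitting.GAConfig"] = None,
) -> Classifier:
    """GA search for the two units' weight vectors maximising training success.

    Ties in success rate are broken by the mean classification margin so the
    GA keeps a gradient once training accuracy saturates.
    """
    labels = np.asarray(labels)
    if labels.sum() != 0:
        raise ValueError("training trials must be balanced between orientations")
    if config is None:
        config = fitting.GAConfig(iterations=200)
    F = features.shape[1]

    def evaluate(pop: np.ndarray) -> np.ndarray:
        success, margin = _batch_success(pop, features, labels)
        return success + 1e-3 * margin

    bounds = (np.full(2 * F, -1.0), np.full(2 * F, 1.0))
    result = fitting.ga_optimize_box(evaluate, bounds, config)
    weights = result.best_genome.reshape(2, F)
    return Classifier(
        weights=weights, channels=tuple(channels), theta_deg=theta_deg, seed=config.seed
    )


def random_classifier(
    n_features: int, channels: Sequence[str], theta_deg: float, seed: int = 0
) -> Classifier:
    """Untrained classifier with weights drawn uniformly in [-1, 1]."""
    rng = stream(seed, "random-classifier")
    weights = rng.uniform(-1.0, 1.0, size=(2, n_features))
    return Classifier(weights=weights, channels=tuple(channels), theta_deg=theta_deg, seed=seed)


def evaluate_classifier(
    classifier: Classifier,
    features: np.ndarray,
    labels: np.ndarray,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Fraction of trials classified correctly."""
    rng = rng if rng is not None else np.random.default_rng(0)
    correct = 0
    for f, y in zip(features, labels):
        correct += classify_trial(f, classifier, rng) == y
    return correct / len(labels)
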