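"""Ensemble statistics over trained classifiers.

Key synapses are inputs whose mean weight across the 20-classifier ensemble
is significantly nonzero by a percentile bootstrap with Bonferroni-widened
confidence intervals.  Whole classifiers (rows) are resampled, preserving
cross-synapse correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter

from ._rng import stream
from .population import PopulationLayout
from .skin_stimulus import SkinPatch

__all__ = [
    "WeightEnsemble",
    "KeySynapseReport",
    "RFMap",
    "bootstrap_key_synapses",
    "unit_rf_map",
    "weight_correlation",
    "key_excitatory_union",
]


@dataclass(frozen=True)
class WeightEnsemble:
    """Weights of one classifier unit across an ensemble of trained classifiers."""

    weights: np.ndarray  # (n_classifiers, n_synapses)
    unit: int  # 0 = -theta, 1 = +theta

    def __post_init__(self) -> None:
        w = np.atleast_2d(np.asarray(self.weights, dtype=float))
        object.__setattr__(self, "weights", w)
        if w.shape[0] < 2:
            raise ValueError("need at least two classifiers in the ensemble")


@dataclass
class KeySynapseReport:
    mean: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    key: np.ndarray  # bool
    alpha: float
    n_comparisons: int

    @property
    def n_key(self) -> int:
        return int(self.key.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "synapse": np.arange(len(self.mean)),
                "mean": self.mean,
                "ci_lo": self.ci_lo,
                "ci_hi": self.ci_hi,
                "key": self.key,
            }
        )


@dataclass
class RFMap:
    image: np.ndarray  # (ny, nx) weight density
    patch: SkinPatch
    spacing: float
    n_averaged: int


def bootstrap_key_synapses(
    ensemble: WeightEnsemble,
    n_boot: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
    n_comparisons: Optional[int] = None,
) -> KeySynapseReport:
    """Bootstrap each synapse's mean weight, Bonferroni-corrected.

    Whole classifiers are resampled; the CI is the bootstrap standard-error
    interval mean +- t_{1-alpha/(2N)} * SE_boot at level 1 - alpha/N
    (N = number of synapses unless overridden), equivalent to multiplying
    p-values by N. A percentile interval cannot resolve quantiles as extreme
    as alpha/(2N) from a feasible number of resamples, so the SE form is used
    throughout. A synapse is key iff its CI excludes zero.
    """
    if n_boot < 1000:
        raise ValueError("n_boot must be at least 1000")
    w = ensemble.weights
    n_clf, n_syn = w.shape
    N = n_syn if n_comparisons is None else n_comparisons
    level = alpha / N
    rng = stream(seed, "bootstrap-keys")
    idx = rng.integers(0, n_clf, size=(n_boot, n_clf))
    boot_se = w[idx].mean(axis=1).std(axis=0, ddof=1)  # (n_syn,)
    # undo the bootstrap's 1/n (vs 1/(n-1)) variance bias for small ensembles
    boot_se = boot_se * np.sqrt(n_clf / (n_clf - 1.0))
    mean = w.mean(axis=0)
    t_crit = stats.t.ppf(1.0 - level / 2.0, df=n_clf - 1)
    lo = mean - t_crit * boot_se
    hi = mean + t_crit * boot_se
    key = (lo > 0) | (hi < 0)
    return KeySynapseReport(
        mean=mean, ci_lo=lo, ci_hi=hi, key=key, alpha=alpha, n_comparisons=N
    )


def unit_rf_map(
    unit_weights: np.ndarray,
    layout: PopulationLayout,
    smoothing_mm: float = 0.3,
    spacing: float = 0.1,
) -> RFMap:
    """Spatial weight-density map of one classifier unit.

    Each neuron's weight is split equally over its MR locations and deposited
    on a patch-covering grid, then Gaussian smoothed.  ``unit_weights`` may be
    a single vector (n_neurons,) or a (n_classifiers, n_neurons) ensemble,
    which is averaged.
    """
    w = np.atleast_2d(np.asarray(unit_weights, dtype=float))
    n_averaged = w.shape[0]
    mean_w = w.mean(axis=0)
    if len(mean_w) != len(layout):
        raise ValueError("weight vector does not match the population layout")
    patch = layout.patch
    nx = int(round(patch.extent_x / spacing)) + 1
    ny = int(round(patch.extent_y / spacing)) + 1
    image = np.zeros((ny, nx))
    for weight, inst in zip(mean_w, layout.instances):
        locs = inst.model.mr_locations
        share = weight / len(locs)
        ix = np.clip(np.round(locs[:, 0] / spacing).astype(int), 0, nx - 1)
        iy = np.clip(np.round(locs[:, 1] / spacing).astype(int), 0, ny - 1)
        np.add.at(image, (iy, ix), share)
    if smoothing_mm > 0:
        image = gaussian_filter(
            image, sigma=smoothing_mm / spacing, mode="constant", truncate=8.0
        )
    return RFMap(image=image, patch=patch, spacing=spacing, n_averaged=n_averaged)


def key_excitatory_union(
    report_a: KeySynapseReport, report_b: KeySynapseReport
) -> np.ndarray:
    """Indices of synapses that are key with positive mean in either unit."""
    key_a = report_a.key & (report_a.mean > 0)
    key_b = report_b.key & (report_b.mean > 0)
    return np.flatnonzero(key_a | key_b)


def weight_correlation(
    weights_a: np.ndarray,
    weights_b: np.ndarray,
    restriction: Optional[np.ndarray] = None,
) -> tuple[float, float]:
    """Pearson r (and two-sided p) between the two units' mean weights."""
    a = np.asarray(weights_a, dtype=float)
    b = np.asarray(weights_b, dtype=float)
    if restriction is not None:
        a, b = a[restriction], b[restriction]
    if len(a) < 3:
        raise ValueError("need at least three synapses for a correlation")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant weight vector: correlation undefined")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
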