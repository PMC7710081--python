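"""Discrimination experiments: trial generation, splits, repeats and sweeps."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._rng import stream
from .fitting import GAConfig
from .neuron_model import edge_drive, run_branches
from .population import PopulationLayout
from .readout import (
    Classifier,
    evaluate_classifier,
    features_from_spikes,
    train_classifier,
)
from .skin_stimulus import (
    EdgeStimulus,
    SimulationClock,
    SkinPatch,
    make_noise_field,
    prepare_edge,
    sweep_interval,
)

__all__ = [
    "ExperimentConfig",
    "TrialSet",
    "DiscriminationResult",
    "simulate_population_response",
    "generate_trials",
    "run_discrimination_experiment",
    "performance_summary",
]


@dataclass(frozen=True)
class ExperimentConfig:
    theta_deg: float = 20.0
    noise_pct: float = 0.0
    window_ms: Optional[float] = None  # None = unlimited
    channels: tuple[str, ...] = ("ampa",)
    n_trials_per_orientation: int = 100
    n_train_per_orientation: int = 50
    n_repeats: int = 20
    seed: int = 0
    ga: GAConfig = field(default_factory=lambda: GAConfig(iterations=200))

    def __post_init__(self) -> None:
        if self.n_train_per_orientation >= self.n_trials_per_orientation:
            raise ValueError("n_train must be smaller than n_trials")
        if self.n_repeats < 1:
            raise ValueError("need at least one repeat")


@dataclass
class TrialSet:
    """Balanced PSP features for the two orientations of one condition."""

    features: np.ndarray  # (2 * n_trials, n_features, T) float32
    labels: np.ndarray  # (2 * n_trials,) of -1 / +1
    theta_deg: float
    channels: tuple[str, ...]
    noise_pct: float
    trial_seeds: np.ndarray

    @property
    def n_trials(self) -> int:
        return len(self.labels)


@dataclass
class DiscriminationResult:
    config: ExperimentConfig
    train_success: np.ndarray  # per repeat
    test_success: np.ndarray  # per repeat
    mean_test: float
    ci95: tuple[float, float]
    classifiers: list[Classifier]


def simulate_population_response(
    layout: PopulationLayout,
    stimulus: EdgeStimulus,
    clock,
    noise=None,
) -> np.ndarray:
    """Boolean spike raster (n_neurons, T) for the whole population in one batch."""
    models = layout.models
    counts = [m.n_mr for m in models]
    positions = np.vstack([m.mr_locations for m in models])
    index = np.repeat(np.arange(len(models)), counts)
    r1 = np.concatenate([np.full(c, m.responsivity.r1) for m, c in zip(models, counts)])
    r2 = np.concatenate([np.full(c, m.responsivity.r2) for m, c in zip(models, counts)])
    w = np.concatenate([np.full(c, m.responsivity.w_mr) for m, c in zip(models, counts)])
    max_rate = np.concatenate([np.full(c, m.max_rate) for m, c in zip(models, counts)])
    drive, eff = edge_drive(positions, stimulus, clock, r1, r2, w, noise)
    return run_branches(drive, eff, index, max_rate, clock.dt)


def generate_trials(
    layout: PopulationLayout, config: ExperimentConfig, patch: Optional[SkinPatch] = None
) -> TrialSet:
    """Simulate noisy population responses to edges at -theta and +theta.

    Every trial gets an independently seeded noise field; spike rasters are
    convolved with the configured PSP channels once and cached as float32
    features, which are reused across classifier repeats.
    """
    patch = patch if patch is not None else layout.patch
    base = EdgeStimulus(orientation_deg=0.0, window_ms=config.window_ms)
    clock = sweep_interval(base, patch)
    if config.window_ms is not None:
        # keep integrating PSPs after a short presentation ends
        from .readout import CHANNEL_TAU_DECAY

        settle = 5.0 * max(CHANNEL_TAU_DECAY[c] for c in config.channels)
        clock = SimulationClock(dt=clock.dt, t_start=0.0, t_end=clock.t_end + settle)
    master = stream(config.seed, "trials", config.theta_deg, config.noise_pct)
    n = config.n_trials_per_orientation
    trial_seeds = master.integers(0, 2**31 - 1, size=2 * n)

    features, labels = [], []
    for k, sign in enumerate((-1, 1)):
        stim = prepare_edge(
            EdgeStimulus(
                orientation_deg=sign * config.theta_deg, window_ms=config.window_ms
            ),
            patch,
        )
        for j in range(n):
            seed = int(trial_seeds[k * n + j])
            noise = (
                make_noise_field(config.noise_pct, patch, stim.amplitude, seed=seed)
                if config.noise_pct > 0
                else None
            )
            raster = simulate_population_response(layout, stim, clock, noise)
            features.append(
                features_from_spikes(raster, config.channels, clock.dt).astype(np.float32)
            )
            labels.append(sign)
    return TrialSet(
        features=np.asarray(features),
        labels=np.asarray(labels),
        theta_deg=config.theta_deg,
        channels=config.channels,
        noise_pct=config.noise_pct,
        trial_seeds=trial_seeds,
    )


def _split(
    labels: np.ndarray, n_train: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train_idx, test_idx = [], []
    for value in (-1, 1):
        idx = np.flatnonzero(labels == value)
        idx = rng.permutation(idx)
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def run_discrimination_experiment(
    layout: PopulationLayout,
    config: ExperimentConfig,
    trials: Optional[TrialSet] = None,
) -> DiscriminationResult:
    """Train/test ``n_repeats`` classifiers on random balanced splits.

    The repeats share one simulated trial set and differ in the train/test
    split and the GA seed.  The summary is the mean held-out success with a
    bootstrap 95% CI over repeats.
    """
    if trials is None:
        trials = generate_trials(layout, config)
    feats = trials.features.astype(np.float64)
    train_s, test_s, classifiers = [], [], []
    for rep in range(config.n_repeats):
        rng = stream(config.seed, "split", rep)
        tr, te = _split(trials.labels, config.n_train_per_orientation, rng)
        ga = replace(config.ga, seed=int(stream(config.seed, "ga-seed", rep).integers(2**31)))
        clf = train_classifier(
            feats[tr], trials.labels[tr], config.channels, config.theta_deg, ga
        )
        eval_rng = stream(config.seed, "eval", rep)
        train_s.append(evaluate_classifier(clf, feats[tr], trials.labels[tr], eval_rng))
        test_s.append(evaluate_classifier(clf, feats[te], trials.labels[te], eval_rng))
        classifiers.append(clf)
    test_arr = np.asarray(test_s)
    boot_rng = stream(config.seed, "bootstrap-ci")
    boots = boot_rng.choice(test_arr, size=(1000, len(test_arr)), replace=True).mean(axis=1)
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    return DiscriminationResult(
        config=config,
        train_success=np.asarray(train_s),
        test_success=test_arr,
        mean_test=float(test_arr.mean()),
        ci95=ci,
        classifiers=classifiers,
    )


def retile_simple_rf(
    layout: PopulationLayout, max_rate: Optional[float] = None
) -> PopulationLayout:
    """Re-tile the patch with single-MR (simple-RF) neurons, same size/density."""
    from .neuron_model import make_simple_rf_neuron
    from .population import tile_population

    if max_rate is None:
        max_rate = float(np.mean([m.max_rate for m in layout.models]))
    base = [make_simple_rf_neuron((0.0, 0.0), max_rate)]
    return tile_population(
        base,
        layout.patch,
        density=layout.density,
        seed=layout.seed,
        target_count=len(layout),
    )


def performance_summary(results: Sequence[DiscriminationResult]) -> pd.DataFrame:
    """Tidy per-condition table with AMPA-NMDA differences where both exist."""
    rows = []
    for res in results:
        cfg = res.config
        rows.append(
            {
                "theta_deg": cfg.theta_deg,
                "noise_pct": cfg.noise_pct,
                "window_ms": cfg.window_ms if cfg.window_ms is not None else np.inf,
                "channels": "+".join(cfg.channels),
                "mean_test_success": res.mean_test,
                "ci_lo": res.ci95[0],
                "ci_hi": res.ci95[1],
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    pivot = df.pivot_table(
        index=["theta_deg", "noise_pct", "window_ms"],
        columns="channels",
        values="mean_test_success",
    )
    if {"ampa", "nmda"} <= set(pivot.columns):
        diff = (pivot["ampa"] - pivot["nmda"]).rename("ampa_minus_nmda").reset_index()
        df = df.merge(diff, on=["theta_deg", "noise_pct", "window_ms"], how="left")
    return df
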