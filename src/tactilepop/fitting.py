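"""Model fitting: rate-curve fitness, the genetic algorithm, model selection.

The fitted free parameters are the mechanoreceptor locations (constrained to
the dot-scan receptive-field boundary) and the two responsivity distances
(r1 in [0.05, 1] mm, r2 in [0.2, 1] mm).  Fitness is the coefficient of
determination between model and observed smoothed rate curves, averaged over
the four training orientations (+-22.5, +-45 deg); 0 deg cross-validates and
30 deg is held out for testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from ._rng import stream
from .neuron_model import (
    R1_LIMITS,
    R2_LIMITS,
    NeuronModel,
    RateCurve,
    ResponsivityParams,
    SpikeTrain,
    edge_drive,
    rate_curve,
    rates_from_spike_matrix,
    run_branches,
)
from .skin_stimulus import (
    EdgeStimulus,
    SimulationClock,
    SkinPatch,
    prepare_edge,
    sweep_interval,
)

__all__ = [
    "TRAIN_ORIENTATIONS",
    "CROSSVAL_ORIENTATION",
    "TEST_ORIENTATION",
    "FitDataset",
    "GAConfig",
    "GAResult",
    "CandidateModel",
    "r2_score",
    "fitness_over_orientations",
    "ga_optimize",
    "ga_optimize_box",
    "fit_neuron",
    "select_model",
    "make_null_model",
    "nearest_edge_prediction",
    "sample_in_region",
]

TRAIN_ORIENTATIONS = (-45.0, -22.5, 22.5, 45.0)
CROSSVAL_ORIENTATION = 0.0
TEST_ORIENTATION = 30.0


@dataclass
class FitDataset:
    """Multi-trial spike recordings keyed by edge orientation, plus geometry.

    ``trains`` maps orientation (deg) to a list of per-trial SpikeTrains that
    share ``clock``.  ``boundary`` is a shapely region of admissible MR
    locations (from the dot scan); ``max_rate`` the maximal observed smoothed
    firing rate, which also fixes w_MR = 2 * max_rate.
    """

    trains: dict[float, list[SpikeTrain]]
    boundary: object  # shapely geometry
    patch: SkinPatch
    clock: SimulationClock
    max_rate: float
    speed: float = 30.0
    amplitude: float = 0.5
    smoothing_sigma: float = 5.0

    def stimulus(self, orientation: float) -> EdgeStimulus:
        stim = EdgeStimulus(
            orientation_deg=orientation, speed=self.speed, amplitude=self.amplitude
        )
        return prepare_edge(stim, self.patch)

    def mean_rate(self, orientation: float) -> np.ndarray:
        """Trial-mean smoothed rate curve for one orientation."""
        trials = self.trains[orientation]
        curves = [
            rate_curve(t, self.clock, self.smoothing_sigma).rate for t in trials
        ]
        return np.mean(curves, axis=0)


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 100
    mutation_p: float = 0.1
    crossover_p: float = 0.1
    iterations: int = 500
    tournament_size: int = 3
    elitism: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")
        for p in (self.mutation_p, self.crossover_p):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.iterations < 1:
            raise ValueError("iterations must be positive")


@dataclass
class GAResult:
    best_genome: np.ndarray
    best_fitness: float
    trace: np.ndarray  # best-ever fitness per generation


def estimate_max_rate(trains: Sequence[SpikeTrain], isi_quantile: float = 0.05) -> float:
    """Maximal firing rate (Hz) from the pooled inter-spike intervals.

    The peak instantaneous rate is 1000 / ISI; a low quantile rather than the
    strict minimum keeps the estimate robust to jittered near-coincident
    spikes.  Falls back to the single shortest ISI when spikes are scarce.
    """
    isis = np.concatenate(
        [np.diff(t.times) for t in trains if len(t.times) > 1] or [np.array([])]
    )
    if len(isis) == 0:
        raise ValueError("cannot estimate a maximal rate without inter-spike intervals")
    return float(1000.0 / np.quantile(isis, isi_quantile))


def r2_score(model_rate, observed_rate) -> float:
    """1 - <(SRm - SRo)^2> / <(SRo - mean(SRo))^2>; may be negative."""
    m = model_rate.rate if isinstance(model_rate, RateCurve) else np.asarray(model_rate)
    o = observed_rate.rate if isinstance(observed_rate, RateCurve) else np.asarray(observed_rate)
    if m.shape != o.shape:
        raise ValueError("rate curves must share the time grid")
    denom = np.mean((o - o.mean()) ** 2)
    if denom == 0:
        raise ValueError("observed rate curve is constant (undefined variance)")
    return float(1.0 - np.mean((m - o) ** 2) / denom)


def _batch_r2(model_rates: np.ndarray, observed: np.ndarray) -> np.ndarray:
    denom = np.mean((observed - observed.mean()) ** 2)
    if denom == 0:
        raise ValueError("observed rate curve is constant (undefined variance)")
    return 1.0 - np.mean((model_rates - observed[None, :]) ** 2, axis=1) / denom


def _simulate_candidates(
    locations: np.ndarray,  # (P, n_mr, 2)
    r1: np.ndarray,  # (P,)
    r2: np.ndarray,  # (P,)
    w: float,
    max_rate: float,
    stimulus: EdgeStimulus,
    clock: SimulationClock,
    smoothing_sigma: float,
) -> np.ndarray:
    """Smoothed rate curves (P, T) for a batch of candidate neurons."""
    P, n_mr, _ = locations.shape
    flat = locations.reshape(P * n_mr, 2)
    drive, eff = edge_drive(
        flat,
        stimulus,
        clock,
        np.repeat(r1, n_mr),
        np.repeat(r2, n_mr),
        w,
    )
    index = np.repeat(np.arange(P), n_mr)
    spikes = run_branches(drive, eff, index, np.full(P * n_mr, max_rate), clock.dt)
    return rates_from_spike_matrix(spikes, clock.dt, smoothing_sigma)


def fitness_over_orientations(
    model: NeuronModel, dataset: FitDataset, orientations: Sequence[float] = TRAIN_ORIENTATIONS
) -> float:
    """Mean R^2 of the model rate curve vs the trial-mean observed rate."""
    scores = []
    for orientation in orientations:
        stim = dataset.stimulus(orientation)
        rates = _simulate_candidates(
            model.mr_locations[None, :, :],
            np.array([model.responsivity.r1]),
            np.array([model.responsivity.r2]),
            model.responsivity.w_mr,
            model.max_rate,
            stim,
            dataset.clock,
            dataset.smoothing_sigma,
        )
        scores.append(_batch_r2(rates, dataset.mean_rate(orientation))[0])
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# Generic GA engine


def ga_optimize(
    evaluate: Callable[[np.ndarray], np.ndarray],
    initialize: Callable[[np.random.Generator, int], np.ndarray],
    mutate: Callable[[np.random.Generator, np.ndarray], np.ndarray],
    crossover: Callable[[np.random.Generator, np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]],
    config: GAConfig,
) -> GAResult:
    """Elitist generational GA with tournament selection.

    ``evaluate`` maps a (P, G) population matrix to a (P,) fitness vector;
    ``mutate`` and ``crossover`` are applied with the configured
    probabilities per individual / per pair.  Fully reproducible from
    ``config.seed``; the returned trace is the running best fitness.
    """
    rng = stream(config.seed, "ga")
    pop = np.asarray(initialize(rng, config.population_size), dtype=float)
    P = config.population_size
    best_genome, best_fit = None, -np.inf
    trace = np.empty(config.iterations)

    for it in range(config.iterations):
        fitness = np.asarray(evaluate(pop), dtype=float)
        gen_best = int(np.argmax(fitness))
        if fitness[gen_best] > best_fit:
            best_fit = float(fitness[gen_best])
            best_genome = pop[gen_best].copy()
        trace[it] = best_fit

        # tournament selection
        contenders = rng.integers(0, P, size=(P, config.tournament_size))
        winners = contenders[np.arange(P), np.argmax(fitness[contenders], axis=1)]
        nxt = pop[winners].copy()

        # crossover on consecutive pairs
        for i in range(0, P - 1, 2):
            if rng.random() < config.crossover_p:
                nxt[i], nxt[i + 1] = crossover(rng, nxt[i], nxt[i + 1])
        # mutation per individual
        for i in range(P):
            if rng.random() < config.mutation_p:
                nxt[i] = mutate(rng, nxt[i])
        # elitism: re-insert the best-ever genome
        for e in range(min(config.elitism, P)):
            nxt[e] = best_genome
        pop = nxt

    return GAResult(best_genome=best_genome, best_fitness=best_fit, trace=trace)


def ga_optimize_box(
    evaluate: Callable[[np.ndarray], np.ndarray],
    bounds: tuple[np.ndarray, np.ndarray],
    config: GAConfig,
    mutation_sigma_frac: float = 0.1,
) -> GAResult:
    """GA over a box-bounded real vector with Gaussian mutation and uniform crossover."""
    lo = np.asarray(bounds[0], dtype=float)
    hi = np.asarray(bounds[1], dtype=float)
    if lo.shape != hi.shape or np.any(hi <= lo):
        raise ValueError("invalid bounds")
    span = hi - lo

    def initialize(rng, n):
        return rng.uniform(lo, hi, size=(n, len(lo)))

    def mutate(rng, genome):
        out = genome + rng.normal(0.0, mutation_sigma_frac * span)
        return np.clip(out, lo, hi)

    def crossover(rng, a, b):
        mask = rng.random(len(a)) < 0.5
        a2, b2 = a.copy(), b.copy()
        a2[mask], b2[mask] = b[mask], a[mask]
        return a2, b2

    return ga_optimize(evaluate, initialize, mutate, crossover, config)


# ---------------------------------------------------------------------------
# Neuron fitting


def sample_in_region(region, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform points inside a shapely region via rejection sampling."""
    from shapely import contains_xy

    minx, miny, maxx, maxy = region.bounds
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        xs = rng.uniform(minx, maxx, size=4 * n)
        ys = rng.uniform(miny, maxy, size=4 * n)
        keep = contains_xy(region, xs, ys)
        pts = np.column_stack([xs[keep], ys[keep]])
        take = min(len(pts), n - filled)
        out[filled : filled + take] = pts[:take]
        filled += take
    return out


def _project_into_region(region, points: np.ndarray) -> np.ndarray:
    """Snap points outside the region onto its nearest interior point."""
    from shapely import contains_xy
    from shapely.geometry import Point
    from shapely.ops import nearest_points

    inside = contains_xy(region, points[:, 0], points[:, 1])
    if inside.all():
        return points
    out = points.copy()
    for i in np.flatnonzero(~inside):
        nearest = nearest_points(region, Point(out[i]))[0]
        out[i] = (nearest.x, nearest.y)
    return out


@dataclass
class CandidateModel:
    model: NeuronModel
    n_mr: int
    train_fitness: dict[float, float]
    crossval_fitness: float
    test_fitness: float
    trace: Optional[np.ndarray] = None

    @property
    def mean_train_fitness(self) -> float:
        return float(np.mean(list(self.train_fitness.values())))


def fit_neuron(
    dataset: FitDataset,
    n_mr: int,
    config: GAConfig,
    location_sigma: float = 0.3,
    r_sigma: float = 0.05,
) -> CandidateModel:
    """GA fit of MR locations and (r1, r2) to the training orientations.

    Genome layout: [r1, r2, x1, y1, ..., xn, yn].  Locations are initialised
    uniformly inside the dot-scan boundary and kept inside it throughout
    (mutations landing outside are projected back to the region).
    """
    if n_mr not in (10, 20, 30, 40):
        warnings.warn(
            f"n_mr={n_mr} is outside the standard ladder (10, 20, 30, 40)",
            stacklevel=2,
        )
    region = dataset.boundary
    if region.is_empty:
        raise ValueError("infeasible: empty receptive-field boundary")
    w_mr = 2.0 * dataset.max_rate
    observed = {o: dataset.mean_rate(o) for o in TRAIN_ORIENTATIONS}
    stimuli = {o: dataset.stimulus(o) for o in TRAIN_ORIENTATIONS}

    def initialize(rng, n):
        pop = np.empty((n, 2 + 2 * n_mr))
        pop[:, 0] = rng.uniform(*R1_LIMITS, size=n)
        pop[:, 1] = rng.uniform(*R2_LIMITS, size=n)
        for i in range(n):
            pop[i, 2:] = sample_in_region(region, n_mr, rng).ravel()
        return pop

    def mutate(rng, genome):
        # per-slot moves at a random scale (coarse early exploration and fine
        # late refinement both stay reachable throughout the run)
        out = genome.copy()
        scale = rng.choice([0.1, 1.0])
        if rng.random() < 0.5:
            out[0] = np.clip(out[0] + rng.normal(0, scale * r_sigma), *R1_LIMITS)
        if rng.random() < 0.5:
            out[1] = np.clip(out[1] + rng.normal(0, scale * r_sigma), *R2_LIMITS)
        locs = out[2:].reshape(n_mr, 2).copy()
        moved = rng.random(n_mr) < 0.5
        locs[moved] += rng.normal(0, scale * location_sigma, size=(moved.sum(), 2))
        out[2:] = _project_into_region(region, locs).ravel()
        return out

    def crossover(rng, a, b):
        a2, b2 = a.copy(), b.copy()
        for g in range(2):  # r1, r2 swap independently
            if rng.random() < 0.5:
                a2[g], b2[g] = b[g], a[g]
        mask = rng.random(n_mr) < 0.5  # swap whole (x, y) slots
        for i in np.flatnonzero(mask):
            s = slice(2 + 2 * i, 4 + 2 * i)
            a2[s], b2[s] = b[s], a[s]
        return a2, b2

    def evaluate(pop):
        P = len(pop)
        locations = pop[:, 2:].reshape(P, n_mr, 2)
        scores = np.zeros(P)
        for orientation in TRAIN_ORIENTATIONS:
            rates = _simulate_candidates(
                locations,
                pop[:, 0],
                pop[:, 1],
                w_mr,
                dataset.max_rate,
                stimuli[orientation],
                dataset.clock,
                dataset.smoothing_sigma,
            )
            scores += _batch_r2(rates, observed[orientation])
        return scores / len(TRAIN_ORIENTATIONS)

    result = ga_optimize(evaluate, initialize, mutate, crossover, config)
    g = result.best_genome
    model = NeuronModel(
        mr_locations=g[2:].reshape(n_mr, 2),
        responsivity=ResponsivityParams(r1=float(g[0]), r2=float(g[1]), w_mr=w_mr),
        max_rate=dataset.max_rate,
    )
    train_fitness = {
        o: r2_score(
            _simulate_candidates(
                model.mr_locations[None],
                np.array([g[0]]),
                np.array([g[1]]),
                w_mr,
                dataset.max_rate,
                stimuli[o],
                dataset.clock,
                dataset.smoothing_sigma,
            )[0],
            observed[o],
        )
        for o in TRAIN_ORIENTATIONS
    }
    crossval = _held_out_fitness(model, dataset, CROSSVAL_ORIENTATION)
    test = _held_out_fitness(model, dataset, TEST_ORIENTATION)
    return CandidateModel(
        model=model,
        n_mr=n_mr,
        train_fitness=train_fitness,
        crossval_fitness=crossval,
        test_fitness=test,
        trace=result.trace,
    )


def _held_out_fitness(model: NeuronModel, dataset: FitDataset, orientation: float) -> float:
    return fitness_over_orientations(model, dataset, orientations=[orientation])


def select_model(candidates: Sequence[CandidateModel]) -> CandidateModel:
    """Apply the selection ladder and return the winning candidate.

    1. keep models whose training R^2 is within 5% of the per-orientation
       maximum, for every training orientation;
    2. of those, keep models with cross-validation R^2 within 5% of the
       maximum and MR count within 5 of the minimum;
    3. return the survivor with the best cross-validation R^2.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    survivors = list(candidates)
    for orientation in TRAIN_ORIENTATIONS:
        if not all(orientation in c.train_fitness for c in survivors):
            continue
        best = max(c.train_fitness[orientation] for c in survivors)
        survivors = [
            c for c in survivors if c.train_fitness[orientation] >= 0.95 * best
        ] or survivors
    best_cv = max(c.crossval_fitness for c in survivors)
    min_mr = min(c.n_mr for c in survivors)
    filtered = [
        c
        for c in survivors
        if c.crossval_fitness >= 0.95 * best_cv and c.n_mr <= min_mr + 5
    ]
    if filtered:
        survivors = filtered
    return max(survivors, key=lambda c: c.crossval_fitness)


def make_null_model(model: NeuronModel, boundary, seed: int = 0) -> NeuronModel:
    """Shuffle MR locations uniformly within the RF boundary; keep all else."""
    if boundary.is_empty:
        raise ValueError("empty boundary")
    rng = stream(seed, "null-model")
    locations = sample_in_region(boundary, model.n_mr, rng)
    return model.with_locations(locations)


def nearest_edge_prediction(dataset: FitDataset) -> float:
    """R^2 of the 22.5 deg trial-mean rate as a predictor of the 30 deg rate."""
    if 22.5 not in dataset.trains or TEST_ORIENTATION not in dataset.trains:
        raise ValueError("dataset must contain 22.5 and 30 deg responses")
    return r2_score(dataset.mean_rate(22.5), dataset.mean_rate(TEST_ORIENTATION))
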