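"""Fingertip population: randomly rotated base neurons tiled at fixed density."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._rng import stream
from .neuron_model import NeuronModel
from .skin_stimulus import SkinPatch

__all__ = ["NeuronInstance", "PopulationLayout", "rotate_neuron", "tile_population"]

DEFAULT_DENSITY = 140.0  # neurons / cm^2


@dataclass(frozen=True)
class NeuronInstance:
    base_id: int
    rotation_deg: float
    translation: tuple[float, float]  # centre of the placed MR cloud
    model: NeuronModel  # realized (rotated + translated) model

    def __post_init__(self) -> None:
        if not (0.0 <= self.rotation_deg < 360.0):
            raise ValueError("rotation must lie in [0, 360)")


@dataclass(frozen=True)
class PopulationLayout:
    instances: tuple[NeuronInstance, ...]
    patch: SkinPatch
    density: float
    seed: int

    def __len__(self) -> int:
        return len(self.instances)

    @property
    def models(self) -> list[NeuronModel]:
        return [inst.model for inst in self.instances]


def rotate_neuron(
    model: NeuronModel, angle_deg: float, pivot: Optional[Sequence[float]] = None
) -> NeuronModel:
    """Rigidly rotate the MR locations about ``pivot`` (default: MR centroid)."""
    locs = model.mr_locations
    pivot = locs.mean(axis=0) if pivot is None else np.asarray(pivot, dtype=float)
    th = math.radians(angle_deg)
    rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    return model.with_locations((locs - pivot) @ rot.T + pivot)


def _rf_radius(model: NeuronModel) -> float:
    locs = model.mr_locations
    centroid = locs.mean(axis=0)
    spread = float(np.linalg.norm(locs - centroid, axis=1).max()) if len(locs) else 0.0
    return spread + model.responsivity.reach


def tile_population(
    base_models: Sequence[NeuronModel],
    patch: SkinPatch = SkinPatch(),
    density: float = DEFAULT_DENSITY,
    seed: int = 0,
    border: Optional[float] = None,
    target_count: Optional[int] = None,
) -> PopulationLayout:
    """Place randomly rotated copies of the base models at ``density``.

    Centres are drawn uniformly over the patch dilated by ``border`` (default:
    the maximal RF radius of the base models, so neurons centred outside the
    patch but innervating it are represented); instances with no MR inside the
    patch are dropped.  ``target_count`` keeps drawing until exactly that many
    instances are retained, which reproduces the published population size
    without changing the density.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    if not base_models:
        raise ValueError("need at least one base model")
    rng = stream(seed, "population")
    if border is None:
        border = max(_rf_radius(m) for m in base_models)
    lo = np.array([-border, -border])
    hi = np.array([patch.extent_x + border, patch.extent_y + border])
    area_cm2 = (hi - lo).prod() / 100.0

    def draw(n: int) -> list[NeuronInstance]:
        out = []
        for _ in range(n):
            center = rng.uniform(lo, hi)
            base_id = int(rng.integers(0, len(base_models)))
            angle = float(rng.uniform(0.0, 360.0))
            base = base_models[base_id]
            rotated = rotate_neuron(base, angle)
            centroid = rotated.mr_locations.mean(axis=0)
            placed = rotated.with_locations(rotated.mr_locations - centroid + center)
            if patch.contains(placed.mr_locations).any():
                out.append(
                    NeuronInstance(
                        base_id=base_id,
                        rotation_deg=angle,
                        translation=(float(center[0]), float(center[1])),
                        model=placed,
                    )
                )
        return out

    if target_count is None:
        instances = draw(int(round(density * area_cm2)))
    else:
        instances = []
        while len(instances) < target_count:
            instances.extend(draw(max(target_count - len(instances), 8)))
        instances = instances[:target_count]
    return PopulationLayout(
        instances=tuple(instances), patch=patch, density=density, seed=seed
    )
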