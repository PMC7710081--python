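"""Serialization: JSON model schemas, CSV spike trains, run manifests."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .neuron_model import NeuronModel, ResponsivityParams, SpikeTrain
from .population import NeuronInstance, PopulationLayout
from .readout import Classifier
from .skin_stimulus import SkinPatch

__all__ = [
    "SCHEMA_VERSION",
    "RunManifest",
    "write_model",
    "read_model",
    "write_population",
    "read_population",
    "write_classifier",
    "read_classifier",
    "write_spike_trains",
    "read_spike_trains",
    "write_manifest",
]

SCHEMA_VERSION = 1


class FormatError(ValueError):
    """Malformed input file."""


def _check_version(payload: dict, path) -> None:
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        raise FormatError(f"{path}: unsupported schema version {version!r}")


def model_to_dict(model: NeuronModel) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "kind": "neuron_model",
        "mr_locations": model.mr_locations.tolist(),
        "r1": model.responsivity.r1,
        "r2": model.responsivity.r2,
        "w_mr": model.responsivity.w_mr,
        "max_rate": model.max_rate,
        "scheme": model.scheme,
    }


def model_from_dict(payload: dict) -> NeuronModel:
    return NeuronModel(
        mr_locations=np.asarray(payload["mr_locations"], dtype=float),
        responsivity=ResponsivityParams(
            r1=payload["r1"], r2=payload["r2"], w_mr=payload["w_mr"]
        ),
        max_rate=payload["max_rate"],
        scheme=payload.get("scheme", "reset"),
    )


def write_model(model: NeuronModel, path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1))


def read_model(path) -> NeuronModel:
    payload = json.loads(Path(path).read_text())
    _check_version(payload, path)
    return model_from_dict(payload)


def write_population(layout: PopulationLayout, path) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "kind": "population",
        "patch": [layout.patch.extent_x, layout.patch.extent_y],
        "density": layout.density,
        "seed": layout.seed,
        "instances": [
            {
                "base_id": inst.base_id,
                "rotation_deg": inst.rotation_deg,
                "translation": list(inst.translation),
                "model": model_to_dict(inst.model),
            }
            for inst in layout.instances
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_population(path) -> PopulationLayout:
    payload = json.loads(Path(path).read_text())
    _check_version(payload, path)
    instances = tuple(
        NeuronInstance(
            base_id=item["base_id"],
            rotation_deg=item["rotation_deg"],
            translation=tuple(item["translation"]),
            model=model_from_dict(item["model"]),
        )
        for item in payload["instances"]
    )
    return PopulationLayout(
        instances=instances,
        patch=SkinPatch(*payload["patch"]),
        density=payload["density"],
        seed=payload["seed"],
    )


def write_classifier(classifier: Classifier, path) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "kind": "classifier",
        "weights": classifier.weights.tolist(),
        "channels": list(classifier.channels),
        "theta_deg": classifier.theta_deg,
        "seed": classifier.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_classifier(path) -> Classifier:
    payload = json.loads(Path(path).read_text())
    _check_version(payload, path)
    return Classifier(
        weights=np.asarray(payload["weights"], dtype=float),
        channels=tuple(payload["channels"]),
        theta_deg=payload["theta_deg"],
        seed=payload.get("seed"),
    )


def write_spike_trains(
    trains: dict, path, duration: Optional[float] = None
) -> None:
    """CSV with columns trial_id, orientation_deg, spike_time_ms.

    ``trains`` maps orientation -> list of SpikeTrain.
    """
    rows = []
    for orientation, trials in trains.items():
        for trial_id, train in enumerate(trials):
            for t in train.times:
                rows.append((trial_id, orientation, float(t)))
    # empty trials contribute no rows; duration travels separately
    df = pd.DataFrame(rows, columns=["trial_id", "orientation_deg", "spike_time_ms"])
    df.to_csv(path, index=False)


def read_spike_trains(path, duration: float, dt: float = 1.0) -> dict:
    """Read the CSV layout written by :func:`write_spike_trains`, validated."""
    df = pd.read_csv(path)
    expected = ["trial_id", "orientation_deg", "spike_time_ms"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    if len(df) and (df["spike_time_ms"] < 0).any():
        row = int(df.index[df["spike_time_ms"] < 0][0]) + 2  # 1-based + header
        raise FormatError(f"{path}: negative spike time at row {row}")
    trains: dict[float, list[SpikeTrain]] = {}
    for orientation, group in df.groupby("orientation_deg"):
        trials = []
        for trial_id in sorted(group["trial_id"].unique()):
            sel = group.loc[group["trial_id"] == trial_id, "spike_time_ms"]
            times = sel.to_numpy()
            bad = np.flatnonzero(np.diff(times) <= 0)
            if len(bad):
                row = int(sel.index[bad[0] + 1]) + 2  # 1-based + header
                raise FormatError(
                    f"{path}: unsorted or duplicate spike time in trial {trial_id}"
                    f" at row {row}"
                )
            trials.append(SpikeTrain(times=times, duration=duration))
        trains[float(orientation)] = trials
    return trains


@dataclass
class RunManifest:
    command: str
    seed: int
    config: dict
    inputs: list = field(default_factory=list)
    outputs: list = field(default_factory=list)
    package_version: str = __version__
    timestamp: float = field(default_factory=time.time)

    @property
    def config_digest(self) -> str:
        blob = json.dumps(self.config, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(manifest: RunManifest, out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "manifest.json"
    payload = asdict(manifest)
    payload["config_digest"] = manifest.config_digest
    payload["schema_version"] = SCHEMA_VERSION
    path.write_text(json.dumps(payload, indent=1, default=str))
    return path
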