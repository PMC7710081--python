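import numpy as np
import pytest

from tactilepop.fitting import GAConfig
from tactilepop.population import tile_population
from tactilepop.skin_stimulus import SkinPatch
from tactilepop.synthetic_data import (
    JitterModel,
    SyntheticNeuronSpec,
    make_synthetic_neuron,
    synth_recordings,
)


@pytest.fixture(scope="session")
def patch():
    return SkinPatch(12.0, 12.0)


@pytest.fixture(scope="session")
def truth_neuron(patch):
    return make_synthetic_neuron(SyntheticNeuronSpec(n_mr=10, seed=1), patch)


@pytest.fixture(scope="session")
def clean_dataset(truth_neuron, patch):
    """Jitter-free synthetic recordings of the session ground-truth neuron."""
    return synth_recordings(
        truth_neuron, patch, jitter=JitterModel(sigma_ms=0.0, deletion_p=0.0, seed=1)
    )


@pytest.fixture(scope="session")
def base_models(patch):
    return [
        make_synthetic_neuron(SyntheticNeuronSpec(n_mr=15, seed=s), patch)
        for s in range(5)
    ]


@pytest.fixture(scope="session")
def small_layout(base_models, patch):
    return tile_population(base_models, patch, density=140.0, seed=0, target_count=60)


@pytest.fixture
def tiny_ga():
    return GAConfig(population_size=20, iterations=40, seed=5)
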