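import numpy as np
import pytest

from paraniche import SynthConfig, aggregate_dataset, generate_dataset
from paraniche.data import Dataset, LayerObservation, PlotHeader, TraitRecord


def make_trait(taxon_id, functional_type="autotroph", **eive):
    return TraitRecord(taxon_id=taxon_id, functional_type=functional_type, **eive)


def make_plot(plot_id, x=0.0, y=0.0, **kwargs):
    env = {"bio2": 9.0, "bio4": 650.0, "bio10": 16.0, "bio12": 700.0,
           "bio15": 30.0, "bio18": 220.0, "pet_penman": 80.0, "tri": 150.0}
    env.update(kwargs.pop("env", {}))
    return PlotHeader(plot_id=plot_id, x=x, y=y, env=env, **kwargs)


@pytest.fixture
def toy_dataset():
    """Two plots, three species (one euphytoid hemiparasite), two layers."""
    headers = [make_plot("p1", 0.0, 0.0, plot_size_m2=25.0),
               make_plot("p2", 10.0, 0.0, plot_size_m2=100.0)]
    traits = [
        make_trait("auto1", eive_n=2.0, eive_m=5.0),
        make_trait("auto2", eive_n=4.0, eive_m=5.0),
        make_trait("hemi1", "euphytoid", eive_n=5.0),
    ]
    observations = [
        LayerObservation("p1", "auto1", 1, 50.0),
        LayerObservation("p1", "auto1", 2, 50.0),
        LayerObservation("p1", "auto2", 1, 25.0),
        LayerObservation("p1", "hemi1", 1, 25.0),
        LayerObservation("p2", "auto1", 1, 30.0),
        LayerObservation("p2", "auto2", 1, 60.0),
    ]
    return Dataset(headers=headers, observations=observations, traits=traits)


@pytest.fixture(scope="session")
def synth_2000():
    """One effectful synthetic dataset at the generator's default scale."""
    dataset, truth = generate_dataset(SynthConfig(n_plots=2000, seed=11))
    return dataset, truth


@pytest.fixture(scope="session")
def synth_2000_agg(synth_2000):
    dataset, truth = synth_2000
    return dataset, truth, aggregate_dataset(dataset)
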