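import numpy as np
import pytest

from mica import SimulationConfig, StudyData, simulate_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture()
def two_identical_studies():
    """Two studies with an identical strong two-class pattern."""
    x = StudyData(values=[0.0, 0.0, 2.0, 2.0], labels=[1, 1, 2, 2], study="X")
    y = StudyData(values=[0.0, 0.0, 2.0, 2.0], labels=[1, 1, 2, 2], study="Y")
    return x, y


def random_study(rng, n_classes=3, n_per_class=5, n_genes=None, study="S", scale=1.0):
    """Random class-labelled study; 1-D when n_genes is None."""
    labels = np.repeat(np.arange(1, n_classes + 1), n_per_class)
    shape = (labels.size,) if n_genes is None else (n_genes, labels.size)
    return StudyData(values=scale * rng.standard_normal(shape), labels=labels, study=study)


@pytest.fixture()
def small_dataset():
    """Small mixed-type simulated dataset (40 genes, 4 studies, 3 classes)."""
    cfg = SimulationConfig(
        seed=7, genes_per_type={"I": 10, "II": 10, "III": 10, "IV": 10}
    )
    return simulate_dataset(cfg)
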