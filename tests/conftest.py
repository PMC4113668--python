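import numpy as np
import pytest

from pathprofiler import ExpressionDataset, Pathway, PathwayCollection, SimulationConfig
from pathprofiler.simulate import simulate_study


@pytest.fixture
def toy_collection():
    return PathwayCollection(
        [
            Pathway(id="P1", name="one", genes=frozenset({"A", "B", "C", "D"})),
            Pathway(id="P2", name="two", genes=frozenset({"C", "D", "E", "F"})),
            Pathway(id="P3", name="three", genes=frozenset({"G", "H", "I"})),
        ]
    )


@pytest.fixture
def toy_dataset():
    """9 genes x 12 samples; genes A-D shifted up in tumors."""
    rng = np.random.default_rng(42)
    genes = list("ABCDEFGHI")
    samples = [f"T{i}" for i in range(6)] + [f"N{i}" for i in range(6)]
    values = rng.normal(8.0, 1.0, size=(9, 12))
    values[:4, :6] += 3.0
    group = {s: ("tumor" if s.startswith("T") else "normal") for s in samples}
    return ExpressionDataset(genes=genes, samples=samples, values=values, group=group)


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down study for fast integration tests."""
    return SimulationConfig(
        n_genes=800,
        n_pathways=40,
        pathway_size_range=(10, 16),
        n_tumor_per_subtype=12,
        n_normal=12,
        n_shared_perturbed=6,
        n_specific_perturbed=2,
        effect_size=3.0,
        responsive_fraction=0.6,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)
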