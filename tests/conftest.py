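import numpy as np
import pandas as pd
import pytest

from immunomod.datatypes import ExpressionMatrix, Module, ModuleSet, SurvivalTable
from immunomod.simulate import (
    SimulationConfig,
    generate_reference_cohort,
    generate_tumor_cohort,
)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale planted cohort: 5 modules (3 linked), 800 genes."""
    return SimulationConfig(
        seed=11,
        n_ref_samples=100,
        n_tumor_samples=200,
        n_genes=800,
        n_modules=5,
        module_size=50,
        linked_pool_extra=15,
        deletion_locus=("9", "9p21.3", 20),
    )


@pytest.fixture(scope="session")
def reference_cohort(small_config):
    return generate_reference_cohort(small_config)


@pytest.fixture(scope="session")
def tumor_cohort(small_config):
    return generate_tumor_cohort(small_config)


@pytest.fixture(scope="session")
def disjoint_config():
    """No shared module family: planted members are exactly the modules."""
    return SimulationConfig(
        seed=23,
        n_ref_samples=134,
        n_tumor_samples=300,
        n_genes=2500,
        n_modules=20,
        module_size=100,
        n_linked_modules=1,
    )


@pytest.fixture(scope="session")
def disjoint_reference(disjoint_config):
    return generate_reference_cohort(disjoint_config)


@pytest.fixture
def toy_expression():
    """4-sample toy matrix with hand-computable marker correlations."""
    frame = pd.DataFrame(
        {
            "s1": [1.0, 2.0, 4.0, 1.0],
            "s2": [2.0, 4.0, 3.0, 1.0],
            "s3": [3.0, 6.0, 2.0, 2.0],
            "s4": [4.0, 8.0, 1.0, 1.0],
        },
        index=["M", "G2", "G3", "G4"],
    )
    return ExpressionMatrix(frame)


def make_survival(times, events, prefix="s"):
    idx = [f"{prefix}{i}" for i in range(len(times))]
    return SurvivalTable(pd.DataFrame({"time": times, "event": events}, index=idx))


def make_module(name, genes, start_r=1.0):
    rs = np.linspace(start_r, start_r - 0.01 * (len(genes) - 1), len(genes))
    return Module(name=name, members=tuple(zip(genes, rs)))
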