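import numpy as np
import pytest

from endoclock.calibration import Calibration, CalibrationSet
from endoclock.treedata import CladeSpec, parse_newick


@pytest.fixture
def three_leaf_tree():
    return parse_newick("((A:1,B:1):1,C:2);", dating=True)


@pytest.fixture
def root_only_calset():
    return CalibrationSet(
        [Calibration(clade=None, t_min=1000, t_max=3000, name="root")]
    )


@pytest.fixture
def small_calset():
    return CalibrationSet([
        Calibration(clade=None, t_min=1000, t_max=3000, name="root"),
        Calibration(clade=CladeSpec.of("A", "B"), t_min=450, t_max=509,
                    name="ab"),
    ])


@pytest.fixture(scope="session")
def benchmark_dataset():
    """The packaged 20-leaf synthetic benchmark (session-scoped: expensive)."""
    from endoclock.synthetic_data import benchmark_20leaf

    return benchmark_20leaf(seed=42)


@pytest.fixture(scope="session")
def benchmark_trace(benchmark_dataset):
    """One desk-scale posterior chain on the benchmark, shared across tests."""
    from endoclock.sampler import MCMCSettings, run_mcmc

    ds = benchmark_dataset
    return run_mcmc(ds.tree, ds.calibrations, ds.spec.clock, ds.partitions,
                    MCMCSettings.desk(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
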