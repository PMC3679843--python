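import numpy as np
import pytest

from qsarad import DescriptorTable, SimulationSpec, simulate_cluster_with_outliers


@pytest.fixture
def toy_1d():
    """1-D training set {0, 1, 3} as a DescriptorTable."""
    return DescriptorTable(["a", "b", "c"], np.array([[0.0], [1.0], [3.0]]), ["x"])


@pytest.fixture
def outlier_1d():
    """1-D training set {0, 1, 2, 100}: three clustered points and one extreme."""
    return DescriptorTable(
        ["a", "b", "c", "d"], np.array([[0.0], [1.0], [2.0], [100.0]]), ["x"]
    )


@pytest.fixture(scope="session")
def cluster_fixture():
    """Seeded 48-sample cluster plus 2 detached outliers in 2-D."""
    return simulate_cluster_with_outliers(SimulationSpec(seed=7))


def random_table(rng, n, p, y=False):
    X = rng.standard_normal((n, p)) * (1 + rng.random(p))
    ids = [f"m{i}" for i in range(n)]
    names = [f"x{j}" for j in range(p)]
    kwargs = {}
    if y:
        kwargs["y"] = rng.standard_normal(n)
        kwargs["y_hat"] = rng.standard_normal(n)
    return DescriptorTable(ids, X, names, **kwargs)
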