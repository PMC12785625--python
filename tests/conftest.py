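import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from hetmix.presets import taxane_resistant_crpc, unstratified_crpc

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# compact study-condition configs used across module tests; full-size runs
# live in the acceptance suite
SMALL = dict(n_genes=700, markers_per_type=60)


@pytest.fixture(scope="session")
def small_config():
    return unstratified_crpc(seed=11, n_patients=40, **SMALL)


@pytest.fixture(scope="session")
def small_taxane():
    return taxane_resistant_crpc(seed=12, n_patients=40, **SMALL)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_expression(values: np.ndarray, roles=None, batches=None, prefix="S"):
    """Helper building an ExpressionMatrix from a plain array."""
    from hetmix.datatypes import ExpressionMatrix

    n_genes, n_samples = values.shape
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"{prefix}{j}" for j in range(n_samples)]
    roles = roles if roles is not None else ["patient"] * n_samples
    batches = batches if batches is not None else ["b0"] * n_samples
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples),
        pd.Series(roles, index=samples),
        pd.Series(batches, index=samples),
    )
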