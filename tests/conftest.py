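import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from methsig.simulate import SimulationConfig, simulate_dataset

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

# Small study for unit tests: same design as the default, scaled down.
SMALL_CONFIG = SimulationConfig(
    n_probes=2_000, n_common_hypo=100, n_common_hyper=100,
    n_tissue_specific=50, n_genes=600, seed=11)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(SMALL_CONFIG)


@pytest.fixture()
def tiny_beta():
    """3 probes x 6 samples with a strong effect on cg1, none on cg2/cg3."""
    from methsig.io import BetaMatrix
    cols = ["i1", "i2", "i3", "n1", "n2", "n3"]
    data = pd.DataFrame(
        [[0.85, 0.90, 0.88, 0.20, 0.22, 0.18],
         [0.50, 0.52, 0.48, 0.49, 0.51, 0.50],
         [0.30, 0.30, 0.30, 0.30, 0.30, 0.30]],
        index=["cg1", "cg2", "cg3"], columns=cols)
    return BetaMatrix(data)


@pytest.fixture()
def tiny_sheet():
    from methsig.io import SampleSheet
    rows = []
    for i, s in enumerate(["i1", "i2", "i3"], 1):
        rows.append({"sample_id": s, "tissue": "breast", "phenotype": "invasive", "replicate": i})
    for i, s in enumerate(["n1", "n2", "n3"], 1):
        rows.append({"sample_id": s, "tissue": "breast", "phenotype": "non_invasive", "replicate": i})
    return SampleSheet(pd.DataFrame(rows))
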