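import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from scumc import Methylome, SimConfig, run_scumc_pipeline, simulate_methylomes

settings.register_profile(
    "suite",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: seed fixing the study conditions of the bundled simulation
SIM_SEED = 1


def make_methylome(
    ratios,
    sample_id="S",
    chrom="chr1",
    start=1000,
    spacing=50,
    coverage=10,
):
    """Build a methylome from a flat list of ratios on an even CpG grid."""
    n = len(ratios)
    cov = np.full(n, coverage) if np.isscalar(coverage) else np.asarray(coverage)
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": start + spacing * np.arange(n),
            "meth_ratio": ratios,
            "coverage": cov,
        }
    )
    return Methylome(sample_id, df)


@pytest.fixture(scope="session")
def default_sim():
    """The bundled study conditions: 31 samples, 200-kb chromosome."""
    return simulate_methylomes(SimConfig(seed=SIM_SEED))


@pytest.fixture(scope="session")
def default_result(default_sim):
    methylomes, truth = default_sim
    return run_scumc_pipeline(methylomes, snp_positions=truth.snps)
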