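import numpy as np
import pytest

from teneigh.simulate import GeneratorConfig, generate, worked_fixture


@pytest.fixture(scope="session")
def fixture_bundle():
    """Hand-sized bundle with independently hand-computed expected values."""
    return worked_fixture()


@pytest.fixture(scope="session")
def bundle2000():
    """Synthetic bundle with 2000 two-gene families (4100 genes), shared by
    the parameter-recovery and calibration tests."""
    cfg = GeneratorConfig(
        n_chromosomes=8,
        chromosome_length=45_000_000,
        n_genes=4_100,
        gene_length_log_mean=float(np.log(8_000)),
        n_families=2_000,
    )
    return generate(cfg, seed=1)
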