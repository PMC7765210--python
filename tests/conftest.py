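import numpy as np
import pytest

import loxminer as lm


@pytest.fixture(scope="session")
def default_bundle():
    """One synthetic genome bundle under the default study conditions."""
    return lm.generate_genome_bundle(lm.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def bundle_proteins(default_bundle):
    return {r.id: r for r in default_bundle.proteins}


@pytest.fixture(scope="session")
def gene_table():
    return lm.datasets.load_splox_gene_table()


@pytest.fixture(scope="session")
def domain_table():
    return lm.datasets.load_splox_domain_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(20201215)
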