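import numpy as np
import pytest

from elasuite.synth_genomes import ClusterSpec, generate_assembly


@pytest.fixture(scope="session")
def clean_assembly():
    """One undiverged planted cluster with its truth table."""
    return generate_assembly(ClusterSpec(seed=42))


@pytest.fixture(scope="session")
def diverged_assembly():
    """Planted cluster at 20% divergence on every gene."""
    from elasuite.reference import GENE_ORDER
    spec = ClusterSpec(seed=43, divergence={g: 0.2 for g in GENE_ORDER})
    return generate_assembly(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
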