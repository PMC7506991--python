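import numpy as np
import pytest

from g4prom.simulate import PromoterSimConfig, gen_promoters


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_promoters():
    """80 short promoters with planted motifs, shared across tests."""
    cfg = PromoterSimConfig(
        n_genes=80, flank=300, planted_rate_enriched=1.5, planted_rate_background=0.3, seed=42
    )
    return gen_promoters(cfg, enriched_gene_fraction=0.5)


def random_seq(rng, length, alphabet="ACGT", p=None):
    return "".join(rng.choice(list(alphabet), size=length, p=p))
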