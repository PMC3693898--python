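import numpy as np
import pytest

import seqphenosim as sps


@pytest.fixture(scope="session")
def small_pool():
    """200 haplotypes over 3 linked blocks; enough polymorphism for
    gene-dropping and map tests without being slow."""
    return sps.generate_block_pool(200, 3, 8.0, seed=42)


@pytest.fixture(scope="session")
def rare_pool():
    """2000 haplotypes, one block, coalescent spectrum rich in rare variants
    (the regime of the PAR disease model)."""
    return sps.generate_block_pool(2000, 1, 45.0, seed=11)


@pytest.fixture(scope="session")
def small_rmap(small_pool):
    return sps.fixed_map(0.2, small_pool.n_blocks, small_pool.block_centers_bp())


@pytest.fixture()
def hand_pool():
    """Tiny handcrafted pool: 10 haplotypes, 2 sites in one block, derived
    frequencies 0.3 and 0.5."""
    matrix = np.zeros((10, 2), dtype=np.uint8)
    matrix[:3, 0] = 1
    matrix[:5, 1] = 1
    return sps.HaplotypePool(
        matrix,
        np.array(["1", "1"], dtype=object),
        np.array([100, 200]),
        np.array([0, 0]),
    )


@pytest.fixture(scope="session")
def par_model(rare_pool):
    """30 rare causal loci, additive PAR model with f0 = 0.1, total PAR 0.1
    split equally."""
    causal = sps.select_causal_sites(rare_pool, 30, (0.0, 0.01), seed=3)
    spec = sps.DiseaseSpec(causal_sites=causal, mode="additive", model="par",
                           f0=0.1, par_total=0.1)
    return sps.build_disease_model(rare_pool, spec, seed=5)
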