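import numpy as np
import pytest
from hypothesis import settings

import combqtl as cq
from combqtl.simulate import QTLSpec, SimConfig

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cfg():
    """3 x 100 cM chromosomes, 10 cM spacing, 120 F8 birds."""
    return SimConfig(n_chromosomes=3, chr_length=100.0, marker_spacing=10.0,
                     n_individuals=120, n_breeding_pairs=15, seed=11)


@pytest.fixture(scope="session")
def small_map(small_cfg):
    return cq.simulate_map(small_cfg)


@pytest.fixture(scope="session")
def small_geno(small_cfg, small_map):
    return cq.simulate_ail_genotypes(small_map, small_cfg)


@pytest.fixture(scope="session")
def qtl_cross(small_cfg, small_map, small_geno):
    """Cross with one planted additive+dominance QTL at chr2:50."""
    qtl = QTLSpec(chromosome="2", position=50.0, additive_effect=1.0,
                  dominance_effect=0.5, trait_name="area")
    table = cq.simulate_quantitative_trait(
        small_geno, small_map, [qtl],
        {"sex": 0.5, "weight": 0.002}, noise_sd=1.0, seed=21)
    return cq.to_cross(small_geno, table)


@pytest.fixture(scope="session")
def qtl_probs(qtl_cross):
    return cq.genotype_probabilities(qtl_cross)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
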