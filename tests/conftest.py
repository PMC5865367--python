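"""Shared fixtures: small simulated worlds reused across test modules.

Everything is generated at run time from fixed seeds; the "small" profile
keeps the four-chromosome layout but shrinks locus counts and population
sizes so the whole suite stays fast.
"""
import numpy as np
import pytest

from heterosim.config import (ChainConfig, GenomeConfig, SelectionConfig,
                              trait_config_for_model)
from heterosim.runner import build_base_world


@pytest.fixture(scope="session")
def small_genome_cfg():
    return GenomeConfig(n_chromosomes=4, chromosome_length=1.0,
                        n_snps_target=400, n_qtl_target=40,
                        n_candidate_loci=880, historical_size=200,
                        historical_generations=200)


@pytest.fixture(scope="session")
def small_selection_cfg():
    return SelectionConfig(n_founders=50, n_expansion_generations=40,
                           n_candidates=200, n_males_selected=20,
                           n_females_selected=40, n_purebred_offspring=200,
                           n_crossbred_offspring=200)


@pytest.fixture(scope="session")
def small_world(small_genome_cfg, small_selection_cfg):
    """One fully built small world (Model 1), shared read-only."""
    return build_base_world(small_genome_cfg, trait_config_for_model(1), 1,
                            small_selection_cfg, seed=12345, with_f1=True,
                            keep_historical=True)


@pytest.fixture(scope="session")
def short_chain():
    return ChainConfig(n_iter=1200, burn_in=300)


@pytest.fixture()
def rng():
    return np.random.default_rng(987654321)
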