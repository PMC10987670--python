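"""Shared fixtures: a small deterministic synthetic study used across tests."""

import logging

import numpy as np
import pandas as pd
import pytest

from diallel_eqtl import (
    EigenKinship,
    SimulationConfig,
    estimate_kinship,
    ld_filter_matrix,
    sample_parents,
    simulate_design,
    simulate_expression,
    simulate_source_population,
)

logging.getLogger("diallel_eqtl").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(
        seed=11,
        n_pop=400,
        n_snps=1200,
        n_genes=40,
        hotspot_count=1,
        hotspot_gene_range=(5, 10),
        causal_gene_fraction=0.5,
        n_causal_per_gene=1,
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    variants, pop_haps, pop_maf = simulate_source_population(small_cfg)
    parents = sample_parents(variants, pop_haps, small_cfg)
    design = simulate_design(small_cfg)
    traits, truth, matrix = simulate_expression(parents, design, variants, small_cfg)
    return {
        "variants": variants,
        "parents": parents,
        "design": design,
        "traits": traits,
        "truth": truth,
        "matrix": matrix,
    }


@pytest.fixture(scope="session")
def small_eig(small_sim):
    kin = estimate_kinship(ld_filter_matrix(small_sim["matrix"], 0.8))
    return EigenKinship(kin)


@pytest.fixture()
def toy_parents():
    """Three parents x four variants with hand-checkable dosages."""
    hap = pd.DataFrame(
        [[0, 1, 1, 0], [1, 0, 1, 0], [0, 0, 1, 1]],
        index=["A", "B", "C"],
        columns=["v1", "v2", "v3", "v4"],
        dtype=np.int8,
    )
    return hap
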