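"""Shared fixtures: small synthetic panels generated at test time."""

import numpy as np
import pytest

import tsopt


@pytest.fixture(scope="session")
def small_complete_panel() -> tsopt.GenotypeMatrix:
    """30 individuals x 300 loci, 3 groups, no missingness."""
    cfg = tsopt.SimulationConfig(
        n_individuals=30, n_loci=300, group_sizes=(10, 10, 10), n_qtl=50,
        fst=0.2, seed=42, missing_locus_rate=0.0, missing_indiv_rate=0.0,
    )
    return tsopt.simulate_genotypes(cfg, complete=True)


@pytest.fixture(scope="session")
def small_dataset() -> tsopt.SimulatedDataset:
    """60 individuals x 500 loci with phenotypes for 3 traits, 2 years."""
    cfg = tsopt.SimulationConfig(
        n_individuals=60, n_loci=500, group_sizes=(20, 20, 20), n_qtl=100,
        fst=0.1, seed=7,
    )
    return tsopt.simulate_dataset(cfg)


def make_toy_context(seed: int, n: int = 12, n_loci: int = 60, n_pc: int = 5):
    """12-individual criterion context used by the oracle-equivalence tests."""
    cfg = tsopt.SimulationConfig(
        n_individuals=n, n_loci=n_loci, n_groups=3,
        group_sizes=(n // 3, n // 3, n - 2 * (n // 3)), n_qtl=min(20, n_loci),
        fst=0.3, seed=seed, missing_locus_rate=0.0, missing_indiv_rate=0.0,
    )
    g = tsopt.simulate_genotypes(cfg, complete=True)
    return tsopt.CriterionContext(
        G=tsopt.vanraden_g(g),
        S=tsopt.pc_scores(g, n_pc),
        D=tsopt.modified_rogers(g),
        n_markers=n_loci,
    )


@pytest.fixture(scope="session")
def toy_ctx() -> tsopt.CriterionContext:
    return make_toy_context(seed=42)
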