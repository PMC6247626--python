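"""Shared fixtures: small synthetic datasets reused across test modules."""

import numpy as np
import pytest

from rlfvpredict import simulate
from rlfvpredict.kinship import pedigree_a_matrix, vanraden_grm


@pytest.fixture(scope="session")
def small_genome():
    """4 chromosomes x 10 genes x 8 RLFV, 40 common SNPs/chr, some intergenic RLFV."""
    return simulate.simulate_genome_map(
        n_chr=4, genes_per_chr=10, rlfv_per_gene=8, n_common_per_chr=40,
        seed=11, intergenic_rlfv_per_chr=6)


@pytest.fixture(scope="session")
def small_population(small_genome):
    """12 half-sib families of 8 daughters: n = 108 genotyped individuals."""
    return simulate.simulate_population(small_genome, n_sires=12,
                                        daughters_per_sire=8, seed=12)


@pytest.fixture(scope="session")
def small_phenotypes(small_genome, small_population):
    _, geno = small_population
    return simulate.simulate_drp(
        geno.dosages[:, small_genome.common_indices], sigma2_g=145.0,
        total_variance=328.8, mean_r2_drp=0.85, seed=13, n_validation=24,
        ids=geno.ids)


@pytest.fixture(scope="session")
def small_grm(small_genome, small_population):
    _, geno = small_population
    return vanraden_grm(geno, small_genome.common_indices)


@pytest.fixture(scope="session")
def small_a_matrix(small_population):
    ped, _ = small_population
    return pedigree_a_matrix(ped)


@pytest.fixture(scope="session")
def null_scan():
    """A pure-null gene scan: 1000 genes, half-sib population, polygenic trait.

    Returns the per-gene p-value table from scanning phenotypes with no gene
    effects, used for type-I-error calibration and p-value uniformity checks.
    """
    from rlfvpredict.genetest import scan_genes

    genome = simulate.simulate_genome_map(
        n_chr=25, genes_per_chr=40, rlfv_per_gene=8, n_common_per_chr=40,
        seed=101)
    ped, geno = simulate.simulate_population(genome, n_sires=40,
                                             daughters_per_sire=10, seed=102)
    pheno = simulate.simulate_drp(
        geno.dosages[:, genome.common_indices], sigma2_g=145.0,
        total_variance=328.8, mean_r2_drp=0.85, seed=103, n_validation=40,
        ids=geno.ids)
    a_mat = pedigree_a_matrix(ped)
    _, table = scan_genes(genome, geno, pheno, a_mat, alpha=0.01)
    return table
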