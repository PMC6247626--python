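"""Synthetic-data generator: layout, determinism, gene-dropping, scaling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rlfvpredict import simulate
from rlfvpredict.kinship import allele_frequencies, pedigree_a_matrix, vanraden_grm
from rlfvpredict.simulate import (PANEL_COMMON, PANEL_RLFV, QtnSet, SimulationError,
                                  compose_phenotype, simulate_drp,
                                  simulate_genome_map, simulate_population,
                                  simulate_qtn_scenario)


class TestGenomeMap:
    def test_gene_and_variant_counts(self):
        gm = simulate_genome_map(29, 10, 2, 3, seed=0)
        assert len(gm.genes) == 290
        assert gm.n_variants == 29 * (10 * 2 + 3)

    def test_deterministic_for_fixed_seed(self):
        a = simulate_genome_map(3, 5, 4, 10, seed=42, intergenic_rlfv_per_chr=2)
        b = simulate_genome_map(3, 5, 4, 10, seed=42, intergenic_rlfv_per_chr=2)
        pd.testing.assert_frame_equal(a.variants, b.variants)

    def test_panel_maf_ranges(self, small_genome):
        v = small_genome.variants
        common = v[v["panel"] == PANEL_COMMON]["target_maf"]
        rlfv = v[v["panel"] == PANEL_RLFV]["target_maf"]
        assert (common >= 0.05).all()
        assert ((rlfv >= 0.001) & (rlfv < 0.05)).all()

    def test_gene_variant_lists_position_sorted_and_disjoint(self, small_genome):
        pos = small_genome.variants["pos"].to_numpy()
        seen = set()
        for gene, idx in small_genome.genes.items():
            assert len(idx) > 0
            assert np.all(np.diff(pos[idx]) > 0)
            assert not (set(idx) & seen)
            seen.update(idx)

    def test_annotation_fractions_within_binomial_ci(self):
        # 10,000 genic RLFV; realized class counts inside the exact 99% CI
        probs = {"high": 0.01, "medium": 0.02, "low": 0.97}
        gm = simulate_genome_map(10, 25, 40, 1, annotation_class_probs=probs, seed=7)
        genic = gm.variants[gm.variants["gene"].notna()]
        assert len(genic) == 10_000
        for cls, p in probs.items():
            count = int((genic["annotation"] == cls).sum())
            lo, hi = stats.binom.ppf([0.005, 0.995], 10_000, p)
            assert lo <= count <= hi, f"{cls}: {count} outside [{lo}, {hi}]"

    @pytest.mark.parametrize("kwargs", [
        dict(n_chr=0, genes_per_chr=1, rlfv_per_gene=1, n_common_per_chr=1),
        dict(n_chr=1, genes_per_chr=1, rlfv_per_gene=0, n_common_per_chr=1),
        dict(n_chr=1, genes_per_chr=1, rlfv_per_gene=1, n_common_per_chr=1,
             annotation_class_probs={"high": 0.5, "medium": 0.2, "low": 0.2}),
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(SimulationError):
            simulate_genome_map(**kwargs, seed=0)


class TestPopulation:
    def test_deterministic_for_fixed_seed(self, small_genome):
        _, a = simulate_population(small_genome, 5, 3, seed=9)
        _, b = simulate_population(small_genome, 5, 3, seed=9)
        np.testing.assert_array_equal(a.dosages, b.dosages)

    def test_founder_frequencies_track_targets(self):
        # with 2000 founders nearly all loci fall within 3 binomial SEs
        gm = simulate_genome_map(2, 10, 10, 50, seed=5)
        _, geno = simulate_population(gm, 2000, 0, seed=6)
        target = gm.variants["target_maf"].to_numpy()
        realized = allele_frequencies(geno)
        se = np.sqrt(target * (1 - target) / (2 * 2000))
        frac_within = np.mean(np.abs(realized - target) <= 3 * se)
        assert frac_within >= 0.985

    def test_unrelated_founders_have_near_zero_grm_offdiagonal(self):
        # independent draws at m ~ 5000 loci: mean off-diagonal of G ~ 0
        # (with observed-frequency centring it is exactly -mean(diag)/(n-1))
        gm = simulate_genome_map(1, 50, 80, 1000, seed=21)
        _, geno = simulate_population(gm, 200, 0, seed=22)
        G = vanraden_grm(geno).values
        off = G[~np.eye(200, dtype=bool)]
        assert abs(off.mean()) < 0.02

    def test_half_sib_pedigree_relationship(self, small_population, small_a_matrix):
        ped, _ = small_population
        t = ped.table
        daughters = t[t["generation"] == 1]
        d1, d2 = daughters.iloc[0]["id"], daughters.iloc[1]["id"]
        assert daughters.iloc[0]["sire"] == daughters.iloc[1]["sire"]
        sub = small_a_matrix.align(np.array([d1, d2]))
        assert sub[0, 1] == pytest.approx(0.25)

    def test_gene_dropping_transmission_unbiased(self):
        # offspring frequency matches the parental mean over 10,000 loci
        gm = simulate_genome_map(4, 25, 80, 500, seed=31)
        assert gm.n_variants == 10_000
        ped, geno = simulate_population(gm, 20, 10, seed=32)
        n_s, n_d = 20, 200
        sire_freq_per_daughter = np.repeat(
            geno.dosages[:n_s].astype(float) / 2.0, 10, axis=0)
        # dam genotypes are not in the matrix; expectation over the dam draw
        # is the target MAF
        expected = 0.5 * sire_freq_per_daughter.mean(axis=0) \
            + 0.5 * gm.variants["target_maf"].to_numpy()
        realized = geno.dosages[n_s:].mean(axis=0) / 2.0
        assert abs((realized - expected).mean()) < 0.01

    def test_empty_map_rejected(self, small_genome):
        with pytest.raises(SimulationError):
            simulate_population(small_genome, 0, 5, seed=1)


class TestDrp:
    def test_perfect_reliability_means_drp_equals_tbv(self, small_genome,
                                                      small_population):
        _, geno = small_population
        ph = simulate_drp(geno.dosages[:, small_genome.common_indices],
                          145.0, 328.8, mean_r2_drp=1.0, seed=1,
                          n_validation=10, ids=geno.ids)
        np.testing.assert_allclose(ph.table["drp"].to_numpy(), ph.tbv)
        assert (ph.table["r2_drp"] == 1.0).all()

    def test_polygenic_variance_scaled_exactly(self, small_phenotypes):
        assert small_phenotypes.tbv.var(ddof=1) == pytest.approx(145.0, rel=1e-12)

    def test_h2_target_arithmetic(self, small_phenotypes):
        assert small_phenotypes.h2_target == pytest.approx(0.441, abs=5e-4)

    def test_validation_is_youngest_block(self, small_phenotypes):
        t = small_phenotypes.table
        val_ranks = t.loc[t["cohort"] == "validation", "birth_order"]
        train_ranks = t.loc[t["cohort"] == "training", "birth_order"]
        assert val_ranks.min() > train_ranks.max()
        assert (t["cohort"] == "validation").sum() == 24

    def test_y_equals_drp_without_overlay(self, small_phenotypes):
        np.testing.assert_array_equal(small_phenotypes.table["y"],
                                      small_phenotypes.table["drp"])

    @pytest.mark.parametrize("s2g,tot,r2", [
        (0.0, 1.0, 0.5), (2.0, 1.0, 0.5), (1.0, 2.0, 0.0), (1.0, 2.0, 1.5),
    ])
    def test_invalid_variances_rejected(self, small_genome, small_population,
                                        s2g, tot, r2):
        _, geno = small_population
        with pytest.raises(SimulationError):
            simulate_drp(geno.dosages[:, small_genome.common_indices],
                         s2g, tot, r2, seed=1, n_validation=10)


class TestQtnScenarios:
    def test_lqtn_selects_nine_genes(self, small_genome, small_population):
        _, geno = small_population
        q = simulate_qtn_scenario(small_genome, geno, "LQTN", 0.10, 145.0, seed=3)
        assert len(q.gene_ids) == 9

    def test_mqtn_selects_one_gene_per_chromosome(self, small_genome,
                                                  small_population):
        _, geno = small_population
        q = simulate_qtn_scenario(small_genome, geno, "MQTN", 0.10, 145.0, seed=3)
        chroms = {g.split("_")[0] for g in q.gene_ids}
        assert len(q.gene_ids) == len(small_genome.chromosomes)
        assert len(chroms) == len(small_genome.chromosomes)

    def test_sqtn_draws_seven_to_ten_genes_per_chromosome(self, small_genome):
        # needs >= 10 genes per chromosome; counts recorded in metadata
        ped, geno = simulate_population(small_genome, 10, 4, seed=8)
        q = simulate_qtn_scenario(small_genome, geno, "SQTN", 0.10, 145.0, seed=4)
        assert set(q.genes_per_chr_drawn) == set(small_genome.chromosomes)
        assert all(7 <= k <= 10 for k in q.genes_per_chr_drawn.values())

    def test_variance_scaling_exact(self, small_genome, small_population):
        _, geno = small_population
        q = simulate_qtn_scenario(small_genome, geno, "MQTN", 0.10, 145.0, seed=5)
        assert abs(q.tbv_q.var(ddof=1) - 14.5) <= 1e-10 * 14.5
        # union of the selected genes' RLFV
        expected = np.sort(np.concatenate(
            [small_genome.genes[g] for g in q.gene_ids]))
        np.testing.assert_array_equal(q.variant_indices, expected)

    def test_qtn_set_equals_union_of_selected_gene_rlfv(self, small_genome,
                                                        small_population):
        _, geno = small_population
        q = simulate_qtn_scenario(small_genome, geno, "LQTN", 0.10, 145.0, seed=6)
        panel = small_genome.variants["panel"].to_numpy()
        assert (panel[q.variant_indices] == PANEL_RLFV).all()

    def test_degenerate_fraction_rejected(self, small_genome, small_population):
        _, geno = small_population
        with pytest.raises(SimulationError):
            simulate_qtn_scenario(small_genome, geno, "LQTN", 0.0, 145.0, seed=1)

    def test_unknown_scenario_rejected(self, small_genome, small_population):
        _, geno = small_population
        with pytest.raises(SimulationError):
            simulate_qtn_scenario(small_genome, geno, "XQTN", 0.1, 145.0, seed=1)

    def test_deterministic_for_fixed_seed(self, small_genome, small_population):
        _, geno = small_population
        a = simulate_qtn_scenario(small_genome, geno, "SQTN", 0.10, 145.0, seed=9)
        b = simulate_qtn_scenario(small_genome, geno, "SQTN", 0.10, 145.0, seed=9)
        np.testing.assert_array_equal(a.variant_indices, b.variant_indices)
        np.testing.assert_array_equal(a.tbv_q, b.tbv_q)


class TestComposePhenotype:
    def test_zero_overlay_is_identity(self, small_phenotypes):
        n = len(small_phenotypes.table)
        q = QtnSet(scenario="LQTN", gene_ids=(), variant_indices=np.array([], int),
                   alpha=np.array([]), tbv_q=np.zeros(n), fraction=0.0,
                   sigma2_50k=145.0, realized_variance=0.0)
        out = compose_phenotype(small_phenotypes, q)
        np.testing.assert_array_equal(out.table["y"], out.table["drp"])

    def test_y_is_drp_plus_tbvq_elementwise(self, small_genome, small_population,
                                            small_phenotypes):
        _, geno = small_population
        q = simulate_qtn_scenario(small_genome, geno, "MQTN", 0.10, 145.0, seed=7)
        out = compose_phenotype(small_phenotypes, q)
        np.testing.assert_allclose(
            out.table["y"], small_phenotypes.table["drp"].to_numpy() + q.tbv_q)
        # other columns untouched
        pd.testing.assert_frame_equal(out.table.drop(columns="y"),
                                      small_phenotypes.table.drop(columns="y"))

    def test_variance_decomposition_approximately_additive(self, small_genome):
        # QTN genes are disjoint from the common panel; on unrelated founders
        # DRP and TBV_Q are independent, so variances add within sampling error
        _, geno = simulate_population(small_genome, 500, 0, seed=41)
        ph = simulate_drp(geno.dosages[:, small_genome.common_indices],
                          145.0, 328.8, 0.85, seed=42, n_validation=50,
                          ids=geno.ids)
        q = simulate_qtn_scenario(small_genome, geno, "MQTN", 0.10, 145.0, seed=43)
        out = compose_phenotype(ph, q)
        vy = out.table["y"].var(ddof=1)
        vd = ph.table["drp"].var(ddof=1)
        assert vy == pytest.approx(vd + q.tbv_q.var(ddof=1), rel=0.10)

    def test_mismatched_individuals_rejected(self, small_phenotypes):
        q = QtnSet(scenario="LQTN", gene_ids=(), variant_indices=np.array([], int),
                   alpha=np.array([]), tbv_q=np.zeros(3), fraction=0.0,
                   sigma2_50k=145.0, realized_variance=0.0)
        with pytest.raises(SimulationError):
            compose_phenotype(small_phenotypes, q)
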