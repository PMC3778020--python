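"""Tests of the synthetic segregant-cross generator."""

import numpy as np
import pandas as pd
import pytest

import envqtl as eq
from envqtl.data import InvalidDesignError


def _design(**kw):
    base = dict(
        n_segregants=100,
        chromosomes=(("chr1", 200_000), ("chr2", 200_000)),
        markers_per_chromosome=25,
        recomb_prob=0.02,
        seed=0,
    )
    base.update(kw)
    return eq.CrossDesign(**base)


class TestGenotypes:
    def test_no_recombination_gives_constant_chromosomes(self):
        geno = eq.simulate_genotypes(_design(recomb_prob=0.0))
        for chrom, grp in geno.marker_map.groupby("chrom"):
            block = geno.alleles[grp.index].to_numpy()
            assert (block == block[:, [0]]).all()

    def test_free_recombination_decorrelates_adjacent_markers(self):
        geno = eq.simulate_genotypes(_design(n_segregants=10_000, recomb_prob=0.5))
        a = geno.alleles.to_numpy(dtype=float)
        for chrom, grp in geno.marker_map.groupby("chrom"):
            cols = [geno.markers.get_loc(m) for m in grp.index]
            for j, k in zip(cols, cols[1:]):
                r = np.corrcoef(a[:, j], a[:, k])[0, 1]
                assert abs(r) < 0.05

    def test_allele_frequency_is_mendelian(self):
        geno = eq.simulate_genotypes(_design(n_segregants=2_000))
        freq = geno.alleles.mean()
        se = np.sqrt(0.25 / geno.n_segregants)
        assert ((freq - 0.5).abs() < 5 * se).all()

    def test_reproducible_from_seed(self):
        a = eq.simulate_genotypes(_design(seed=9))
        b = eq.simulate_genotypes(_design(seed=9))
        assert a.alleles.equals(b.alleles)
        assert a.marker_map.equals(b.marker_map)

    def test_positions_strictly_increasing(self):
        geno = eq.simulate_genotypes(_design())
        for _, grp in geno.marker_map.groupby("chrom"):
            assert grp["pos"].is_monotonic_increasing
            assert not grp["pos"].duplicated().any()

    @pytest.mark.parametrize("kw", [
        dict(n_segregants=1),
        dict(recomb_prob=0.6),
        dict(recomb_prob=-0.1),
        dict(markers_per_chromosome=0),
    ])
    def test_invalid_designs_raise(self, kw):
        with pytest.raises(InvalidDesignError):
            _design(**kw)


def _one_mediator_setup(expr_noise=0.0, growth_noise=0.0, beta_t=1.0, beta_g=0.5,
                        n=100, seed=0):
    design = _design(n_segregants=n, seed=seed)
    geno = eq.simulate_genotypes(design)
    marker = geno.markers[5]
    envs = ["envA", "envB"]
    trait = eq.TraitArchitecture(qtl_terms=[], residual_sd=growth_noise,
                                 env_means={"envA": 2.0, "envB": 3.0})
    expr = eq.ExpressionArchitecture(
        n_genes=10,
        mediators=[eq.MediatorGene("g0000", marker, beta_t, {"envA": beta_g})],
        expr_noise_sd=expr_noise,
    )
    phen, roles = eq.simulate_phenotypes(geno, trait, expr, envs, seed=seed + 1)
    return geno, marker, phen, roles


class TestPhenotypes:
    def test_noiseless_chain_growth_is_affine_in_mediator_expression(self):
        geno, marker, phen, _ = _one_mediator_setup()
        t = phen.expression["envA"]["g0000"]
        g = phen.growth["envA"]
        # growth = 2.0 + 0.5 * expression exactly
        assert np.allclose(g, 2.0 + 0.5 * t)
        # no growth linkage in envB
        assert np.allclose(phen.growth["envB"], 3.0)

    def test_mediator_effect_recovered_by_regression(self):
        geno, marker, phen, _ = _one_mediator_setup(expr_noise=0.1, n=200, seed=4)
        s = geno.column(marker)
        t = phen.expression["envA"]["g0000"].to_numpy()
        x = np.column_stack([np.ones_like(s), s])
        coef, res, _, _ = np.linalg.lstsq(x, t, rcond=None)
        resid = t - x @ coef
        se = np.sqrt(resid @ resid / (len(t) - 2) / np.sum((s - s.mean()) ** 2))
        assert abs(coef[1] - 1.0) < 3 * se

    def test_global_null_gives_uniform_association_pvalues(self):
        from scipy import stats

        design = _design(n_segregants=150, markers_per_chromosome=50, recomb_prob=0.5)
        geno = eq.simulate_genotypes(design)
        trait = eq.TraitArchitecture(qtl_terms=[], residual_sd=1.0,
                                     env_means={"envA": 0.0})
        expr = eq.ExpressionArchitecture(n_genes=2, expr_noise_sd=1.0)
        phen, _ = eq.simulate_phenotypes(geno, trait, expr, ["envA"], seed=2)
        scan = eq.MixedModelScan().fit(geno, phen.growth["envA"])
        assert stats.kstest(scan.results_["p"], "uniform").pvalue > 0.01

    def test_growth_unchanged_by_consequence_coupling(self):
        # consequence-gene expression is downstream of growth: altering the
        # coupling never propagates back into the growth table
        design = _design(seed=5)
        geno = eq.simulate_genotypes(design)
        marker = geno.markers[3]
        trait = eq.TraitArchitecture(qtl_terms=[eq.QtlEffect(marker, {"envA": 1.0})],
                                     residual_sd=0.3, env_means={"envA": 2.0})
        base = dict(n_genes=5, expr_noise_sd=0.2)
        arch1 = eq.ExpressionArchitecture(
            consequence=[eq.ConsequenceGene("g0001", {"envA": 0.5})], **base)
        arch2 = eq.ExpressionArchitecture(
            consequence=[eq.ConsequenceGene("g0001", {"envA": 5.0})], **base)
        p1, _ = eq.simulate_phenotypes(geno, trait, arch1, ["envA"], seed=8)
        p2, _ = eq.simulate_phenotypes(geno, trait, arch2, ["envA"], seed=8)
        assert p1.growth.equals(p2.growth)
        assert not p1.expression["envA"]["g0001"].equals(p2.expression["envA"]["g0001"])

    def test_unknown_marker_raises(self):
        geno = eq.simulate_genotypes(_design())
        trait = eq.TraitArchitecture(qtl_terms=[eq.QtlEffect("nope", {"e": 1.0})],
                                     residual_sd=0.1, env_means={"e": 0.0})
        arch = eq.ExpressionArchitecture(n_genes=2)
        with pytest.raises(InvalidDesignError):
            eq.simulate_phenotypes(geno, trait, arch, ["e"], seed=0)

    def test_overlapping_gene_roles_raise(self):
        with pytest.raises(InvalidDesignError):
            eq.ExpressionArchitecture(
                n_genes=5,
                mediators=[eq.MediatorGene("g0000", "m", 1.0, {"e": 1.0})],
                side_effects=[eq.SideEffectGene("g0000", "m", 1.0)],
            )


class TestCheckeredDesign:
    def _phen(self, n=159):
        design = _design(n_segregants=n, seed=6)
        geno = eq.simulate_genotypes(design)
        envs = [f"env{i}" for i in range(5)]
        trait = eq.TraitArchitecture(qtl_terms=[], residual_sd=0.5,
                                     env_means={e: 1.0 for e in envs})
        arch = eq.ExpressionArchitecture(n_genes=4, expr_noise_sd=0.5)
        phen, _ = eq.simulate_phenotypes(geno, trait, arch, envs, seed=6)
        return phen

    def test_exact_subset_size_and_untouched_growth(self):
        phen = self._phen()
        masked = eq.apply_checkered_design(phen, n_per_env=35, seed=1)
        for env in masked.expr_environments:
            assert len(masked.profiled_ids(env)) == 35
        assert masked.growth.equals(phen.growth)
        assert not masked.growth.isna().any().any()

    def test_full_coverage_leaves_nothing_missing(self):
        phen = self._phen(n=40)
        masked = eq.apply_checkered_design(phen, n_per_env=40, seed=1)
        for env in masked.expr_environments:
            assert not masked.expression[env].isna().any().any()

    def test_oversized_subset_raises(self):
        phen = self._phen(n=30)
        with pytest.raises(InvalidDesignError):
            eq.apply_checkered_design(phen, n_per_env=31, seed=1)

    def test_pairwise_mask_overlap_matches_hypergeometric_expectation(self):
        phen = self._phen(n=159)
        overlaps = []
        for seed in range(30):
            masked = eq.apply_checkered_design(phen, n_per_env=35, seed=seed)
            ids = [set(masked.mask.profiled[e]) for e in masked.expr_environments]
            overlaps.extend(len(a & b) for i, a in enumerate(ids) for b in ids[i + 1:])
        expected = 35 * 35 / 159          # ~7.7
        assert abs(np.mean(overlaps) - expected) < 0.5


class TestDeletionAssay:
    def _truth(self, s, noise=0.0):
        genes = [f"g{i}" for i in range(len(s))]
        return eq.DeletionTruth(s=pd.DataFrame({"envA": s}, index=genes),
                                noise_sd=noise)

    def test_zero_selection_no_noise_is_flat(self):
        tab = eq.simulate_deletion_assay(self._truth([0.0, 0.0]), seed=0)
        wide = tab.pivot_table(index="gene", columns="generation",
                               values="log2_abundance")
        assert np.allclose(wide[0], wide[5])

    def test_slope_definition(self):
        tab = eq.simulate_deletion_assay(self._truth([0.1]), seed=0)
        wide = tab.pivot_table(index="gene", columns="generation",
                               values="log2_abundance")
        assert np.allclose(wide[5] - wide[0], 0.5)

    def test_negative_noise_raises(self):
        with pytest.raises(InvalidDesignError):
            self._truth([0.0], noise=-1.0)

    def test_sign_recovery_through_estimator(self):
        rng = np.random.default_rng(0)
        s_true = rng.choice([-0.2, 0.0, 0.2], size=300)
        tab = eq.simulate_deletion_assay(self._truth(s_true, noise=0.05), seed=1)
        est = eq.estimate_selection_coefficients(tab).set_index("gene")
        est = est.loc[[f"g{i}" for i in range(300)]]
        nz = s_true != 0
        agree = (np.sign(est["s"].to_numpy()[nz]) == np.sign(s_true[nz])).mean()
        assert agree >= 0.99
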