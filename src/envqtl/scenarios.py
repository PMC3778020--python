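"""Ready-made simulation scenarios used by the test-bench and the CLI.

``benchmark_scenario`` builds the default synthetic cross on which the
ranking strategies are compared: 200 segregants, 500 markers on 5
chromosomes, 500 genes, 5 environments with 35 strains profiled per
environment, and 6 growth QTLs whose effects on growth flow entirely
through 5 mediator genes each.  One QTL has a sign-flip architecture
(beneficial in one environment, detrimental in another), mirroring
loci whose alleles help growth in one condition and hurt it in another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GenotypeMatrix, MultiEnvPhenotypes
from .simulate import (
    ConsequenceGene,
    CrossDesign,
    DeletionTruth,
    DependentGene,
    ExpressionArchitecture,
    MediatorGene,
    QtlEffect,
    SideEffectGene,
    TraitArchitecture,
    apply_checkered_design,
    simulate_deletion_assay,
    simulate_genotypes,
    simulate_phenotypes,
)

ENVIRONMENTS = ["glucose", "ethanol", "rapamycin", "low_iron", "maltose"]

# Default effect scales (log2-like expression units; growth in generations/day).
MEDIATOR_BETA_T = 0.8          # persistent genotype -> expression effect
MEDIATOR_BETA_G = 0.3          # per-mediator expression -> growth effect
EXPR_NOISE_SD = 0.6
GROWTH_NOISE_SD = 0.5
CONSEQUENCE_COEFF = 0.5        # growth -> expression coupling
SIDE_EFFECT_BETA = 0.8
DEPENDENT_BETA = 1.2
DELETION_S = 0.15              # |true selection coefficient| of real fitness genes
BACKGROUND_HIT_PROB = 0.25     # gene-env pairs with a deletion fitness effect


@dataclass
class Scenario:
    design: CrossDesign
    trait_arch: TraitArchitecture
    expr_arch: ExpressionArchitecture
    environments: list[str]
    qtl_markers: list[str]
    # environments in which each QTL affects growth, signed
    qtl_active: dict[str, dict[str, float]] = field(default_factory=dict)

    def simulate(self, seed: int, n_per_env: int = 35):
        """Generate (genotypes, masked phenotypes, role labels) for one seed."""
        design = CrossDesign(
            n_segregants=self.design.n_segregants,
            chromosomes=self.design.chromosomes,
            markers_per_chromosome=self.design.markers_per_chromosome,
            recomb_prob=self.design.recomb_prob,
            seed=seed,
        )
        genotypes = simulate_genotypes(design)
        phen, roles = simulate_phenotypes(
            genotypes, self.trait_arch, self.expr_arch, self.environments, seed=seed + 1
        )
        masked = apply_checkered_design(phen, n_per_env=n_per_env, seed=seed + 2)
        return genotypes, masked, roles

    def deletion_truth(self, seed: int) -> DeletionTruth:
        """True deletion fitness effects implied by the causal wiring.

        Deleting a mediator abolishes its expression, so the sign of its
        fitness effect in an environment is minus the sign of its
        expression->growth effect there.  A random background fraction of
        all other gene-environment pairs also carries a fitness effect,
        as non-essential deletions commonly do.
        """
        rng = np.random.default_rng(seed + 3)
        genes = self.expr_arch.gene_ids()
        s = pd.DataFrame(0.0, index=pd.Index(genes, name="gene"), columns=self.environments)
        background = (rng.random(s.shape) < BACKGROUND_HIT_PROB) * np.where(
            rng.random(s.shape) < 0.5, DELETION_S, -DELETION_S
        )
        s.loc[:, :] = background
        for med in self.expr_arch.mediators:
            for env, bg in med.beta_g.items():
                if bg != 0.0:
                    s.at[med.gene, env] = -np.sign(bg * med.beta_t) * DELETION_S
        return DeletionTruth(s=s)

    def simulate_deletion_assay(self, seed: int) -> pd.DataFrame:
        return simulate_deletion_assay(self.deletion_truth(seed), seed=seed + 4)


def benchmark_scenario(
    n_segregants: int = 200,
    markers_per_chromosome: int = 100,
    n_chromosomes: int = 5,
    n_genes: int = 500,
    n_qtl: int = 6,
    mediators_per_qtl: int = 5,
    consequence_per_qtl: int = 20,
    side_per_qtl: int = 20,
    dependent_per_qtl: int = 20,
    null: bool = False,
) -> Scenario:
    """Build the default multi-QTL mediation benchmark.

    With ``null=True`` every genetic, mediation and deletion effect is
    zeroed (global-null configuration) while dimensions are preserved.
    """
    chromosomes = tuple((f"chr{i + 1:02d}", 1_000_000) for i in range(n_chromosomes))
    design = CrossDesign(
        n_segregants=n_segregants,
        chromosomes=chromosomes,
        markers_per_chromosome=markers_per_chromosome,
        recomb_prob=0.02,
        seed=0,
    )
    # marker ids mirror simulate_genotypes' naming
    step = 1_000_000 // (markers_per_chromosome + 1)

    def marker_id(chrom_idx: int, marker_idx: int) -> str:
        return f"chr{chrom_idx + 1:02d}:{(marker_idx + 1) * step}"

    # QTLs spread over chromosomes at alternating positions
    lo, hi = markers_per_chromosome // 4, (3 * markers_per_chromosome) // 4
    qtl_markers = [
        marker_id(i % n_chromosomes, lo if i < n_chromosomes else hi) for i in range(n_qtl)
    ]
    envs = ENVIRONMENTS
    scale = 0.0 if null else 1.0

    # active environments: QTL 0 flips sign between envs 0 and 2; others rotate
    qtl_active: dict[str, dict[str, float]] = {}
    for i, mk in enumerate(qtl_markers):
        if i == 0:
            qtl_active[mk] = {envs[0]: +1.0, envs[2]: -1.0}
        else:
            qtl_active[mk] = {envs[i % len(envs)]: +1.0}

    gene_iter = iter(range(n_genes))
    mediators, consequence, side_effects, dependent = [], [], [], []
    for i, mk in enumerate(qtl_markers):
        for _ in range(mediators_per_qtl):
            g = f"g{next(gene_iter):04d}"
            if not null:
                beta_g = {e: sgn * MEDIATOR_BETA_G for e, sgn in qtl_active[mk].items()}
                mediators.append(MediatorGene(g, mk, MEDIATOR_BETA_T, beta_g))
        for _ in range(side_per_qtl):
            g = f"g{next(gene_iter):04d}"
            side_effects.append(SideEffectGene(g, mk, SIDE_EFFECT_BETA * scale))
        for j in range(dependent_per_qtl):
            g = f"g{next(gene_iter):04d}"
            dependent.append(DependentGene(g, mk, envs[j % len(envs)], DEPENDENT_BETA * scale))
        for _ in range(consequence_per_qtl):
            g = f"g{next(gene_iter):04d}"
            consequence.append(ConsequenceGene(g, {e: CONSEQUENCE_COEFF * scale for e in envs}))

    expr_arch = ExpressionArchitecture(
        n_genes=n_genes,
        mediators=mediators,
        dependent=dependent,
        consequence=consequence,
        side_effects=side_effects,
        expr_noise_sd=EXPR_NOISE_SD,
    )
    trait_arch = TraitArchitecture(
        qtl_terms=[],                                  # growth effects are fully mediated
        residual_sd=GROWTH_NOISE_SD,
        env_means={e: 2.0 + 0.5 * i for i, e in enumerate(envs)},
    )
    if null:
        qtl_active = {mk: {} for mk in qtl_markers}
    return Scenario(design, trait_arch, expr_arch, list(envs), qtl_markers, qtl_active)


def null_scenario(**kwargs) -> Scenario:
    scen = benchmark_scenario(null=True, **kwargs)
    return scen
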