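"""Seeded simulation of a segregant cross and its multi-environment phenotypes.

The generator reproduces the causal wiring used throughout the package:

    genotype --> mediator expression --> environment-dependent growth
                                              |
                                              v
                                   consequence-gene expression

together with side-effect genes (genotype-associated but causally inert),
environment-dependent eQTL genes (genotype effect in one environment only,
no growth linkage), a checkered expression-profiling design, and a pooled
deletion-collection competition assay read out as log2 barcode abundances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CheckeredMask, GenotypeMatrix, InvalidDesignError, MultiEnvPhenotypes


# ---------------------------------------------------------------------------
# designs and architectures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrossDesign:
    """Design of a biallelic haploid cross with Markovian linkage.

    ``recomb_prob`` is the probability that adjacent markers on a chromosome
    derive from different parental chromatids (a constant per-interval
    crossover probability, not a genetic-map model).
    """

    n_segregants: int
    chromosomes: tuple[tuple[str, int], ...]
    markers_per_chromosome: int
    recomb_prob: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_segregants < 2:
            raise InvalidDesignError("need at least 2 segregants")
        if self.markers_per_chromosome < 1 or not self.chromosomes:
            raise InvalidDesignError("non-positive design dimensions")
        if not 0.0 <= self.recomb_prob <= 0.5:
            raise InvalidDesignError("recomb_prob must lie in [0, 0.5]")
        for _, length in self.chromosomes:
            if length < self.markers_per_chromosome:
                raise InvalidDesignError("chromosome shorter than its marker count")


@dataclass(frozen=True)
class QtlEffect:
    """A direct (unmediated) growth QTL: marker plus per-environment effects."""

    marker: str
    effects: dict[str, float]    # environment -> growth units per Y allele

    def __post_init__(self) -> None:
        if not self.effects:
            raise InvalidDesignError("QTL term needs at least one environment")
        if not all(math.isfinite(v) for v in self.effects.values()):
            raise InvalidDesignError("QTL effects must be finite")


@dataclass
class TraitArchitecture:
    qtl_terms: list[QtlEffect]
    residual_sd: float
    env_means: dict[str, float]

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise InvalidDesignError("residual_sd must be non-negative")


@dataclass(frozen=True)
class MediatorGene:
    """Causal intermediate: persistent genotype->expression effect ``beta_t``
    and per-environment expression->growth effects ``beta_g``."""

    gene: str
    marker: str
    beta_t: float
    beta_g: dict[str, float]


@dataclass(frozen=True)
class DependentGene:
    """Environment-dependent eQTL gene: genotype effect in one environment only."""

    gene: str
    marker: str
    env: str
    effect: float


@dataclass(frozen=True)
class ConsequenceGene:
    """Expression responds to realized growth (per-environment coefficient)."""

    gene: str
    coeff: dict[str, float]


@dataclass(frozen=True)
class SideEffectGene:
    """Persistent genotype effect on expression with zero growth linkage."""

    gene: str
    marker: str
    effect: float


@dataclass
class ExpressionArchitecture:
    n_genes: int
    mediators: list[MediatorGene] = field(default_factory=list)
    dependent: list[DependentGene] = field(default_factory=list)
    consequence: list[ConsequenceGene] = field(default_factory=list)
    side_effects: list[SideEffectGene] = field(default_factory=list)
    expr_noise_sd: float = 0.5

    def __post_init__(self) -> None:
        roles = {
            "mediator": {m.gene for m in self.mediators},
            "dependent": {d.gene for d in self.dependent},
            "consequence": {c.gene for c in self.consequence},
            "side_effect": {s.gene for s in self.side_effects},
        }
        all_ids: set[str] = set()
        for ids in roles.values():
            if all_ids & ids:
                raise InvalidDesignError("gene roles must be disjoint")
            all_ids |= ids
        for m in self.mediators:
            if m.beta_t == 0 or not any(v != 0 for v in m.beta_g.values()):
                raise InvalidDesignError(
                    "mediators need beta_t != 0 and a nonzero growth effect"
                )
        if self.expr_noise_sd < 0:
            raise InvalidDesignError("expr_noise_sd must be non-negative")

    def gene_ids(self) -> list[str]:
        return [f"g{i:04d}" for i in range(self.n_genes)]

    def roles(self) -> pd.DataFrame:
        """Ground-truth role labels for benchmarking (never read by the pipeline)."""
        rows = []
        for m in self.mediators:
            envs = ",".join(e for e, v in m.beta_g.items() if v != 0)
            rows.append((m.gene, "mediator", m.marker, envs))
        for d in self.dependent:
            rows.append((d.gene, "dependent", d.marker, d.env))
        for c in self.consequence:
            rows.append((c.gene, "consequence", "", ""))
        for s in self.side_effects:
            rows.append((s.gene, "side_effect", s.marker, ""))
        labeled = {r[0] for r in rows}
        for g in self.gene_ids():
            if g not in labeled:
                rows.append((g, "none", "", ""))
        df = pd.DataFrame(rows, columns=["gene", "role", "marker", "env"])
        return df.set_index("gene").loc[self.gene_ids()]


@dataclass
class DeletionTruth:
    """Per-gene true selection coefficients (log2 abundance change/generation)."""

    s: pd.DataFrame                      # genes x environments
    replicates: int = 3
    generations: tuple[int, ...] = (0, 5)
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if not np.isfinite(self.s.to_numpy()).all():
            raise InvalidDesignError("selection coefficients must be finite")
        if any(g < 0 for g in self.generations):
            raise InvalidDesignError("generations must be non-negative")
        if self.noise_sd < 0:
            raise InvalidDesignError("negative noise sd")
        if self.replicates < 1:
            raise InvalidDesignError("need at least one replicate")


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def simulate_genotypes(design: CrossDesign) -> GenotypeMatrix:
    """Simulate segregant genotypes as an independent Markov chain per chromosome.

    The first marker of each chromosome is Bernoulli(0.5); each subsequent
    marker flips parental origin with probability ``design.recomb_prob``.
    """
    rng = np.random.default_rng(design.seed)
    n, m = design.n_segregants, design.markers_per_chromosome
    blocks, ids, chroms, positions = [], [], [], []
    for chrom, length in design.chromosomes:
        first = rng.random(n) < 0.5
        flips = rng.random((n, m - 1)) < design.recomb_prob if m > 1 else np.zeros((n, 0), bool)
        states = np.concatenate([first[:, None], flips], axis=1)
        alleles = np.logical_xor.accumulate(states, axis=1).astype(np.int8)
        blocks.append(alleles)
        step = length // (m + 1)
        pos = (np.arange(m) + 1) * max(step, 1)
        positions.extend(int(p) for p in pos)
        chroms.extend([chrom] * m)
        ids.extend(f"{chrom}:{int(p)}" for p in pos)
    seg_ids = [f"seg{i:04d}" for i in range(n)]
    alleles = pd.DataFrame(np.concatenate(blocks, axis=1), index=seg_ids, columns=ids)
    marker_map = pd.DataFrame({"chrom": chroms, "pos": positions}, index=pd.Index(ids, name="marker"))
    return GenotypeMatrix(alleles, marker_map)


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    trait_arch: TraitArchitecture,
    expr_arch: ExpressionArchitecture,
    environments: list[str],
    seed: int = 0,
) -> tuple[MultiEnvPhenotypes, pd.DataFrame]:
    """Generate growth and expression respecting the causal order.

    1. genotype-driven expression (mediators, side effects, dependent genes);
    2. growth = environment baseline + direct QTL effects
       + sum of mediator ``beta_g[env] * expression`` + noise;
    3. consequence-gene expression from realized growth.

    Returns the phenotypes and a ground-truth role table.
    """
    for term in trait_arch.qtl_terms:
        if term.marker not in genotypes.markers:
            raise InvalidDesignError(f"unknown marker {term.marker!r}")
    for lst, attr in ((expr_arch.mediators, "marker"), (expr_arch.dependent, "marker"),
                      (expr_arch.side_effects, "marker")):
        for item in lst:
            if getattr(item, attr) not in genotypes.markers:
                raise InvalidDesignError(f"unknown marker {getattr(item, attr)!r}")

    rng = np.random.default_rng(seed)
    segs = genotypes.segregants
    n = len(segs)
    genes = expr_arch.gene_ids()
    sd = expr_arch.expr_noise_sd

    expression: dict[str, pd.DataFrame] = {}
    growth = pd.DataFrame(index=segs, columns=environments, dtype=float)

    for env in environments:
        # (1) upstream expression: independent biological cultures per environment
        mat = rng.normal(0.0, sd, size=(n, len(genes)))
        expr = pd.DataFrame(mat, index=segs, columns=genes)
        for med in expr_arch.mediators:
            expr[med.gene] += med.beta_t * genotypes.column(med.marker)
        for se in expr_arch.side_effects:
            expr[se.gene] += se.effect * genotypes.column(se.marker)
        for dep in expr_arch.dependent:
            if dep.env == env:
                expr[dep.gene] += dep.effect * genotypes.column(dep.marker)

        # (2) growth
        g = np.full(n, trait_arch.env_means.get(env, 0.0))
        for term in trait_arch.qtl_terms:
            g = g + term.effects.get(env, 0.0) * genotypes.column(term.marker)
        for med in expr_arch.mediators:
            bg = med.beta_g.get(env, 0.0)
            if bg != 0.0:
                g = g + bg * expr[med.gene].to_numpy()
        g = g + rng.normal(0.0, trait_arch.residual_sd, size=n)
        growth[env] = g

        # (3) consequences of realized growth
        for cons in expr_arch.consequence:
            expr[cons.gene] += cons.coeff.get(env, 0.0) * g
        expression[env] = expr

    phen = MultiEnvPhenotypes(growth=growth, expression=expression)
    return phen, expr_arch.roles()


def apply_checkered_design(
    phenotypes: MultiEnvPhenotypes, n_per_env: int, seed: int = 0
) -> MultiEnvPhenotypes:
    """Mask expression outside a random per-environment subset of strains.

    The growth table is untouched; each environment keeps exactly
    ``n_per_env`` profiled strains drawn without replacement.
    """
    segs = list(phenotypes.growth.index)
    if n_per_env > len(segs):
        raise InvalidDesignError("n_per_env exceeds number of segregants")
    rng = np.random.default_rng(seed)
    profiled: dict[str, list[str]] = {}
    expression: dict[str, pd.DataFrame] = {}
    for env in phenotypes.expr_environments:
        keep = sorted(rng.choice(len(segs), size=n_per_env, replace=False))
        ids = [segs[i] for i in keep]
        profiled[env] = ids
        mat = phenotypes.expression[env].copy()
        mat.loc[~mat.index.isin(ids)] = np.nan
        expression[env] = mat
    return MultiEnvPhenotypes(
        growth=phenotypes.growth.copy(),
        expression=expression,
        mask=CheckeredMask(profiled),
    )


def simulate_deletion_assay(truth: DeletionTruth, seed: int = 0) -> pd.DataFrame:
    """Simulate replicate log2 barcode abundances at the assayed generations.

    log2 abundance(g) = baseline + s_true * g + Gaussian noise per replicate.
    Returns a long table with columns gene, environment, generation,
    replicate, log2_abundance.
    """
    rng = np.random.default_rng(seed)
    genes = truth.s.index
    baselines = rng.normal(10.0, 1.0, size=len(genes))
    frames = []
    for env in truth.s.columns:
        s = truth.s[env].to_numpy()
        for gen in truth.generations:
            for rep in range(truth.replicates):
                vals = baselines + s * gen + rng.normal(0.0, truth.noise_sd, size=len(genes))
                frames.append(pd.DataFrame({
                    "gene": genes,
                    "environment": env,
                    "generation": gen,
                    "replicate": rep,
                    "log2_abundance": vals,
                }))
    return pd.concat(frames, ignore_index=True)
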