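"""End-to-end orchestration: simulate -> map -> decompose -> model -> mediate
-> deletion benchmark, with a JSON report contrasting the four ranking
strategies (multi-environment network, persistent-eQTL, single-environment
network, environment-dependent eQTL)."""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .benchmark import (
    curve_value_at,
    jackknife_enrichment,
    pooled_enrichment_curve,
    validation_rate,
)
from .data import GenotypeMatrix, MultiEnvPhenotypes
from .deletions import DeletionFitnessModel
from .fdr import storey_qvalues
from .growth import GrowthGeneticModel, StepwiseGrowthModel, Term, variance_explained
from .gxe import classify_eqtls, fit_gxe_table, GxeFit
from .lmm import MixedModelScan, compute_kinship
from .mediation import MediationScorer
from .regions import call_qtl_regions, merge_region_peaks
from .scenarios import Scenario, benchmark_scenario

STRATEGIES = ("bn_multi", "eqtl_persistent", "bn_single", "eqtl_dependent")


@dataclass
class PipelineConfig:
    seed: int = 0
    n_per_env: int = 35
    fdr: float = 0.05
    window: int = 50_000
    s_cut: float = 0.05
    top_n: int = 100
    kinship: str = "ibs"            # "ibs" | "identity"
    contrast: str = "sum"           # "sum" | "reference"
    partial_mediation: bool = False
    downsample: bool = False
    gxe_kinship: bool = True
    null_simulation: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.fdr < 1):
            raise ValueError("fdr must lie in (0, 1)")
        if self.window <= 0 or self.top_n <= 0 or self.n_per_env <= 0:
            raise ValueError("window, top_n and n_per_env must be positive")
        if self.s_cut < 0:
            raise ValueError("s_cut must be non-negative")
        if self.kinship not in ("ibs", "identity"):
            raise ValueError(f"unknown kinship {self.kinship!r}")
        if self.contrast not in ("sum", "reference"):
            raise ValueError(f"unknown contrast {self.contrast!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def map_growth_qtl(growth: pd.DataFrame, genotypes: GenotypeMatrix,
                   config: PipelineConfig) -> tuple[dict, dict, list[str]]:
    """Per-environment genome scans for growth plus merged candidate loci."""
    scans, regions = {}, {}
    for env in growth.columns:
        scan = MixedModelScan(kinship=config.kinship).fit(genotypes, growth[env])
        scans[env] = scan.results_
        regions[env] = call_qtl_regions(scan.results_, fdr=config.fdr,
                                        window=config.window, environment=env)
    merged = merge_region_peaks(regions, window=config.window)
    return scans, regions, [r.peak_marker for r in merged]


def _direction_table(phenotypes: MultiEnvPhenotypes) -> dict[str, pd.Series]:
    """Sign of the expression-growth correlation per gene and environment."""
    out = {}
    for env in phenotypes.expr_environments:
        ids = phenotypes.profiled_ids(env)
        e = phenotypes.expression[env].loc[ids]
        g = phenotypes.growth.loc[ids, env]
        ec = e - e.mean()
        gc = g - g.mean()
        dots = ec.mul(gc, axis=0).sum()
        out[env] = np.sign(dots).astype(int)
    return out


def strategy_rankings(
    phenotypes: MultiEnvPhenotypes,
    genotypes: GenotypeMatrix,
    growth_model: GrowthGeneticModel,
    terms: list[Term],
    gxe_tables: dict[str, pd.DataFrame],
    config: PipelineConfig,
) -> dict[str, dict[Term, pd.DataFrame]]:
    """Per-term candidate rankings for the four strategies.

    Every table has columns gene, posterior (the ranking score, larger =
    more confident) and direction, ordered best-first.
    """
    multi = MediationScorer(single_env=False, partial=config.partial_mediation).fit(
        phenotypes, genotypes, growth_model, terms=terms
    )
    single = MediationScorer(single_env=True, partial=config.partial_mediation).fit(
        phenotypes, genotypes, growth_model, terms=terms
    )
    directions = _direction_table(phenotypes)

    rankings: dict[str, dict[Term, pd.DataFrame]] = {s: {} for s in STRATEGIES}
    for term in terms:
        marker, env = term
        rankings["bn_multi"][term] = multi.scores_[term][["gene", "posterior", "direction"]]
        rankings["bn_single"][term] = single.scores_[term][["gene", "posterior", "direction"]]
        tab = gxe_tables[marker]
        dirs = directions[env].reindex(tab.index).fillna(0).astype(int)
        for label, pcol in (("eqtl_persistent", "p_shared"), ("eqtl_dependent", f"p_dep_{env}")):
            p = tab[pcol].clip(lower=1e-300)
            score = -np.log10(p)
            df = pd.DataFrame({"gene": tab.index, "posterior": score.to_numpy(),
                               "direction": dirs.to_numpy()})
            df = df.sort_values(["posterior", "gene"], ascending=[False, True],
                                kind="mergesort").reset_index(drop=True)
            rankings[label][term] = df
    return rankings


def benchmark_report(
    rankings: dict[str, dict[Term, pd.DataFrame]],
    calls: pd.DataFrame,
    config: PipelineConfig,
) -> dict:
    """Validation rates, jackknife errors and pooled enrichment curves."""
    report: dict = {"strategies": {}}
    for strat, per_term in rankings.items():
        folds, rates, term_entries = [], [], []
        for term, ranked in per_term.items():
            res = validation_rate(ranked, calls, term[1], top_n=config.top_n, term=term)
            folds.append(res.fold_enrichment)
            rates.append(res.rate)
            term_entries.append({
                "marker": term[0], "environment": term[1],
                "n_validated": res.n_validated, "rate": res.rate,
                "background": res.background, "fold_enrichment": res.fold_enrichment,
            })
        curve = pooled_enrichment_curve(per_term, calls)
        entry = {
            "per_term": term_entries,
            "fold_enrichments": folds,
            "mean_fold_enrichment": float(np.mean(folds)) if folds else float("nan"),
            "curve_value_at_top_n": curve_value_at(curve, config.top_n),
            "curve_random_at_top_n": (
                float(curve["expected_random"].iloc[min(config.top_n, len(curve)) - 1])
                if len(curve) else float("nan")
            ),
        }
        if len(folds) >= 2:
            mean, sd = jackknife_enrichment(folds)
            entry["jackknife_mean"] = mean
            entry["jackknife_sd"] = sd
        report["strategies"][strat] = entry
    return report


@dataclass
class PipelineResult:
    genotypes: GenotypeMatrix
    phenotypes: MultiEnvPhenotypes
    scans: dict
    candidate_loci: list[str]
    growth_model: GrowthGeneticModel
    r2_per_env: pd.Series
    gxe_tables: dict[str, pd.DataFrame]
    classification: pd.DataFrame
    rankings: dict[str, dict[Term, pd.DataFrame]]
    deletion_calls: pd.DataFrame
    report: dict


def analyze(
    genotypes: GenotypeMatrix,
    phenotypes: MultiEnvPhenotypes,
    deletion_table: pd.DataFrame,
    config: PipelineConfig,
) -> PipelineResult:
    """Run every analysis stage on in-memory data."""
    scans, _, loci = map_growth_qtl(phenotypes.growth, genotypes, config)

    growth_est = StepwiseGrowthModel().fit(phenotypes.growth, genotypes, loci)
    model = growth_est.model_
    terms = [t for t in model.terms if t[1] != "all"]

    kin = compute_kinship(genotypes) if config.gxe_kinship else None
    markers = sorted({t[0] for t in terms} | set(loci))
    gxe_tables = fit_gxe_table(phenotypes, genotypes, markers, kinship=kin,
                               contrast=config.contrast)
    # classification needs the one-environment-deviation coding: a strong
    # single-environment effect must not register as persistent
    class_tables = fit_gxe_table(phenotypes, genotypes, markers, kinship=kin,
                                 contrast="single")

    fits_for_class = []
    envs = sorted(phenotypes.expr_environments)
    for marker in markers:
        tab = class_tables[marker]
        for gene, row in tab.iterrows():
            fits_for_class.append(GxeFit(
                gene=gene, marker=marker,
                beta_shared=row["beta_shared"], se_shared=float("nan"),
                p_shared=row["p_shared"], environments=envs,
                beta_env={e: row[f"beta_dep_{e}"] for e in envs},
                se_env={e: float("nan") for e in envs},
                p_env={e: row[f"p_dep_{e}"] for e in envs},
                intercepts={}, n=int(row["n"]),
            ))
    classification = classify_eqtls(fits_for_class, fdr_persistent=config.fdr,
                                    fdr_dependent=config.fdr)

    rankings = strategy_rankings(phenotypes, genotypes, model, terms,
                                 gxe_tables, config)

    deletion_est = DeletionFitnessModel(s_cut=config.s_cut, fdr=config.fdr).fit(
        deletion_table
    )
    report = benchmark_report(rankings, deletion_est.calls_, config)
    report["growth_model"] = {
        "terms": [list(t) for t in model.terms],
        "coefficients": {f"{t[0]}|{t[1]}": c for t, c in model.coefficients.items()},
        "r2_per_env": {e: (None if pd.isna(v) else float(v))
                       for e, v in growth_est.r2_per_env_.items()},
    }
    report["n_candidate_loci"] = len(loci)
    report["seed"] = config.seed

    return PipelineResult(
        genotypes=genotypes,
        phenotypes=phenotypes,
        scans=scans,
        candidate_loci=loci,
        growth_model=model,
        r2_per_env=growth_est.r2_per_env_,
        gxe_tables=gxe_tables,
        classification=classification,
        rankings=rankings,
        deletion_calls=deletion_est.calls_,
        report=report,
    )


def run_pipeline(config: PipelineConfig, outdir, scenario: Scenario | None = None) -> dict:
    """Simulate a dataset (unless a scenario is supplied), run all stages and
    persist every stage output under ``outdir``.  Returns the report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if scenario is None:
        scenario = benchmark_scenario(null=config.null_simulation)
    genotypes, phenotypes, roles = scenario.simulate(config.seed,
                                                     n_per_env=config.n_per_env)
    deletion_table = scenario.simulate_deletion_assay(config.seed)

    eio.write_genotypes(genotypes, outdir / "genotypes.tsv", outdir / "markers.bed")
    eio.write_phenotypes(phenotypes, outdir)
    deletion_table.to_csv(outdir / "deletion_assay.tsv", sep="\t", index=False)
    eio.write_json({"roles": roles.reset_index().to_dict(orient="records")},
                   outdir / "truth.json")

    result = analyze(genotypes, phenotypes, deletion_table, config)

    for env, scan in result.scans.items():
        scan.to_csv(outdir / f"assoc_growth_{env}.tsv", sep="\t")
    result.classification.to_csv(outdir / "eqtl_classification.tsv", sep="\t", index=False)
    for strat, per_term in result.rankings.items():
        for term, ranked in per_term.items():
            ranked.to_csv(outdir / f"ranking_{strat}_{term[0].replace(':', '_')}_{term[1]}.tsv",
                          sep="\t", index=False)
    result.deletion_calls.to_csv(outdir / "deletion_calls.tsv", sep="\t", index=False)
    eio.write_json(result.report, outdir / "report.json")
    return result.report
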