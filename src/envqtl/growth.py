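"""Multi-environment growth genetic model via stepwise term selection.

Growth rates are stacked across environments and regressed on
environment intercepts (always included) plus a selected set of terms,
each either a marker main effect (shared across environments) or a
marker x environment interaction.  Forward-backward selection minimizes
BIC; an interaction may enter without its main effect, which is what a
sign-flip locus (beneficial in one environment, detrimental in another)
requires.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data import GenotypeMatrix

Term = tuple[str, str]          # (marker id, environment id or "all")


def _gaussian_ic(rss: float, n: int, n_coef: int, criterion: str) -> float:
    # profile log-likelihood: -(n/2) (log(2 pi rss / n) + 1); k counts the
    # noise variance too
    k = n_coef + 1
    ll = -0.5 * n * (math.log(2.0 * math.pi * rss / n) + 1.0)
    if criterion == "bic":
        return -2.0 * ll + k * math.log(n)
    if criterion == "aic":
        return -2.0 * ll + 2.0 * k
    raise ValueError(f"unknown criterion {criterion!r}")


def term_column(term: Term, genotypes: GenotypeMatrix, stack: pd.DataFrame) -> np.ndarray:
    """Design column for one (marker, environment-or-"all") term on stacked samples."""
    marker, env = term
    s = genotypes.alleles[marker].astype(float)
    col = s.loc[stack["segregant"]].to_numpy()
    if env != "all":
        col = col * (stack["environment"].to_numpy() == env)
    return col


@dataclass
class GrowthGeneticModel:
    terms: list[Term]
    coefficients: dict[Term, float]
    intercepts: dict[str, float]
    environments: list[str]
    criterion_trace: list[float]
    residual_variance: float
    n: int

    def design(self, genotypes: GenotypeMatrix, stack: pd.DataFrame,
               exclude: Term | None = None) -> np.ndarray:
        """Model-term columns for arbitrary stacked samples (no intercepts).

        ``exclude`` drops one term — used when the growth model serves as the
        covariate set for mediation scoring of that term.
        """
        cols = [term_column(t, genotypes, stack)
                for t in self.terms if t != exclude]
        if not cols:
            return np.empty((len(stack), 0))
        return np.column_stack(cols)

    def predict(self, genotypes: GenotypeMatrix, stack: pd.DataFrame) -> np.ndarray:
        yhat = np.array([self.intercepts[e] for e in stack["environment"]])
        for t in self.terms:
            yhat = yhat + self.coefficients[t] * term_column(t, genotypes, stack)
        return yhat


def _growth_stack(growth: pd.DataFrame) -> pd.DataFrame:
    long = growth.stack().rename("growth").reset_index()
    long.columns = ["segregant", "environment", "growth"]
    return long


def stepwise_growth_model(
    growth: pd.DataFrame,
    genotypes: GenotypeMatrix,
    candidate_loci: list[str],
    criterion: str = "bic",
    max_steps: int = 200,
) -> GrowthGeneticModel:
    """Forward-backward selection over candidate (marker, environment) terms.

    ``candidate_loci`` are peak markers (typically from QTL-region calling).
    Candidates are ordered by genomic position with main effects ahead of
    interactions, which fixes tie-breaking.
    """
    stack = _growth_stack(growth)
    stack = stack[stack["growth"].notna()].reset_index(drop=True)
    envs = list(growth.columns)
    y = stack["growth"].to_numpy(dtype=float)
    n = len(y)
    onehot = pd.get_dummies(stack["environment"], dtype=float)[envs].to_numpy()

    mmap = genotypes.marker_map
    loci = sorted(set(candidate_loci),
                  key=lambda mk: (mmap.at[mk, "chrom"], mmap.at[mk, "pos"]))
    candidates: list[Term] = [(mk, "all") for mk in loci] + [
        (mk, e) for mk in loci for e in envs
    ]
    columns = {t: term_column(t, genotypes, stack) for t in candidates}

    def fit(terms: list[Term]):
        d = np.column_stack([onehot] + [columns[t] for t in terms]) if terms else onehot
        coef, _, _, _ = np.linalg.lstsq(d, y, rcond=None)
        rss = float(np.sum((y - d @ coef) ** 2))
        return coef, rss, _gaussian_ic(max(rss, 1e-300), n, d.shape[1], criterion)

    selected: list[Term] = []
    coef, rss, current = fit(selected)
    trace = [current]
    for _ in range(max_steps):
        best_move, best_ic = None, current
        for t in candidates:
            if t in selected:
                continue
            _, _, ic = fit(selected + [t])
            if ic < best_ic - 1e-9:
                best_move, best_ic = ("add", t), ic
        if best_move is None:
            for t in list(selected):
                _, _, ic = fit([u for u in selected if u != t])
                if ic < best_ic - 1e-9:
                    best_move, best_ic = ("drop", t), ic
        if best_move is None:
            break
        action, t = best_move
        if action == "add":
            selected.append(t)
        else:
            selected.remove(t)
        current = best_ic
        trace.append(current)

    selected = sorted(selected, key=lambda t: (mmap.at[t[0], "chrom"],
                                               mmap.at[t[0], "pos"],
                                               t[1]))
    coef, rss, current = fit(selected)
    return GrowthGeneticModel(
        terms=selected,
        coefficients={t: float(coef[len(envs) + i]) for i, t in enumerate(selected)},
        intercepts={e: float(coef[i]) for i, e in enumerate(envs)},
        environments=envs,
        criterion_trace=trace,
        residual_variance=rss / max(n - len(envs) - len(selected), 1),
        n=n,
    )


def variance_explained(model: GrowthGeneticModel, growth: pd.DataFrame,
                       genotypes: GenotypeMatrix) -> pd.Series:
    """Per-environment R-squared of the fitted growth genetic model."""
    stack = _growth_stack(growth)
    stack = stack[stack["growth"].notna()].reset_index(drop=True)
    yhat = model.predict(genotypes, stack)
    out = {}
    for env, grp in stack.groupby("environment", sort=False):
        yy = grp["growth"].to_numpy()
        ss_tot = float(np.sum((yy - yy.mean()) ** 2))
        if ss_tot == 0.0:
            out[env] = np.nan
            continue
        ss_res = float(np.sum((yy - yhat[grp.index.to_numpy()]) ** 2))
        out[env] = 1.0 - ss_res / ss_tot
    return pd.Series(out).reindex(model.environments)


class StepwiseGrowthModel(BaseEstimator):
    """sklearn-style wrapper around :func:`stepwise_growth_model`.

    Attributes after fit: ``model_`` (the GrowthGeneticModel), ``terms_``,
    ``coefficients_``, ``bic_trace_``, ``r2_per_env_``.
    """

    def __init__(self, criterion: str = "bic"):
        self.criterion = criterion

    def fit(self, growth: pd.DataFrame, genotypes: GenotypeMatrix,
            candidate_loci: list[str]):
        self.model_ = stepwise_growth_model(growth, genotypes, candidate_loci,
                                            criterion=self.criterion)
        self.terms_ = self.model_.terms
        self.coefficients_ = self.model_.coefficients
        self.bic_trace_ = self.model_.criterion_trace
        self.r2_per_env_ = variance_explained(self.model_, growth, genotypes)
        return self

    def predict(self, genotypes: GenotypeMatrix, stack: pd.DataFrame) -> np.ndarray:
        return self.model_.predict(genotypes, stack)
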