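"""Bayesian-network scoring of candidate causal intermediate genes.

For one growth-model interaction term (marker n_i, environment e_i) and one
gene, two linear-Gaussian networks are compared by BIC:

Model 1 (causal intermediate)
    t ~ env intercepts + beta_s * s            (persistent genotype effect)
    g ~ env intercepts + covariates + gamma * (t x 1{env = e_i})
    i.e. growth and genotype are independent given the gene's expression,
    and the gene affects growth only in the tested environment.

Model 0 (no mediation)
    t ~ env intercepts
    g ~ env intercepts + covariates + delta * (s x 1{env = e_i})
    i.e. expression is unrelated to the locus and growth follows the
    multi-environment growth genetic model itself.

All other growth-model terms are included as covariates in both growth
sub-models.  The posterior probability of mediation uses equal prior odds:
P(M1) = exp(-BIC_1/2) / (exp(-BIC_0/2) + exp(-BIC_1/2)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator

from .data import GenotypeMatrix, MultiEnvPhenotypes
from .growth import GrowthGeneticModel, Term


@dataclass
class MediationInput:
    """Row-aligned stacked data for one gene and one interaction term."""

    g: np.ndarray                    # growth rates over profiled samples
    t: np.ndarray                    # the gene's expression, same rows
    s: np.ndarray                    # genotype at the term's marker
    env_labels: np.ndarray           # environment of each row
    term: Term                       # (marker, environment) under test
    covariates: np.ndarray           # other growth-model term columns
    gene: str = ""

    def __post_init__(self) -> None:
        n = len(self.g)
        if not (len(self.t) == len(self.s) == len(self.env_labels) == n
                and self.covariates.shape[0] == n):
            raise ValueError("mediation input vectors are not row-aligned")

    @property
    def environments(self) -> list[str]:
        return sorted(set(self.env_labels.tolist()))

    def onehot(self) -> np.ndarray:
        envs = self.environments
        idx = np.array([envs.index(e) for e in self.env_labels])
        return np.eye(len(envs))[idx]

    def env_mask(self) -> np.ndarray:
        return (self.env_labels == self.term[1]).astype(float)


def _gaussian_fit(y: np.ndarray, design: np.ndarray) -> tuple[float, int]:
    """Profile Gaussian log-likelihood and coefficient count of an OLS fit."""
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    rss = float(np.sum((y - design @ coef) ** 2))
    n = len(y)
    rss = max(rss, 1e-300)
    ll = -0.5 * n * (math.log(2.0 * math.pi * rss / n) + 1.0)
    return ll, design.shape[1]


def fit_model1(inp: MediationInput, partial: bool = False) -> tuple[float, int]:
    """Joint log-likelihood and parameter count of the mediation model.

    ``partial=True`` keeps the tested term's direct genotype effect in the
    growth sub-model alongside the expression term (partial mediation).
    """
    if np.var(inp.t) < 1e-12:
        raise ValueError("degenerate input: constant expression")
    onehot = inp.onehot()
    ll_t, k_t = _gaussian_fit(inp.t, np.column_stack([onehot, inp.s]))
    g_cols = [onehot, inp.covariates, (inp.t * inp.env_mask())[:, None]]
    if partial:
        g_cols.append((inp.s * inp.env_mask())[:, None])
    ll_g, k_g = _gaussian_fit(inp.g, np.column_stack(g_cols))
    return ll_t + ll_g, k_t + k_g + 2        # + two noise variances


def model1_coefficients(inp: MediationInput, partial: bool = False) -> tuple[float, float]:
    """(beta_s, gamma) of the mediation model's two sub-fits."""
    onehot = inp.onehot()
    d_t = np.column_stack([onehot, inp.s])
    coef_t, _, _, _ = np.linalg.lstsq(d_t, inp.t, rcond=None)
    g_cols = [onehot, inp.covariates, (inp.t * inp.env_mask())[:, None]]
    if partial:
        g_cols.append((inp.s * inp.env_mask())[:, None])
    d_g = np.column_stack(g_cols)
    coef_g, _, _, _ = np.linalg.lstsq(d_g, inp.g, rcond=None)
    n_env = onehot.shape[1]
    gamma_idx = n_env + inp.covariates.shape[1]
    return float(coef_t[n_env]), float(coef_g[gamma_idx])


def fit_model0(inp: MediationInput) -> tuple[float, int]:
    """Joint log-likelihood and parameter count of the no-mediation model."""
    onehot = inp.onehot()
    ll_t, k_t = _gaussian_fit(inp.t, onehot)
    ll_g, k_g = _gaussian_fit(
        inp.g,
        np.column_stack([onehot, inp.covariates, (inp.s * inp.env_mask())[:, None]]),
    )
    return ll_t + ll_g, k_t + k_g + 2


@dataclass
class MediationScore:
    gene: str
    term: Term
    bic0: float
    bic1: float
    posterior: float
    direction: int
    flagged: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.posterior <= 1.0):
            raise ValueError("posterior must lie in [0, 1]")


def _bic(ll: float, k: int, n: int) -> float:
    return -2.0 * ll + k * math.log(n)


def _direction(t: np.ndarray, g: np.ndarray, mask: np.ndarray) -> int:
    tt, gg = t[mask > 0], g[mask > 0]
    if len(tt) < 3 or np.std(tt) == 0 or np.std(gg) == 0:
        return 0
    r = float(np.corrcoef(tt, gg)[0, 1])
    return 1 if r >= 0 else -1


def score_mediation(inp: MediationInput, partial: bool = False) -> MediationScore:
    """BIC comparison of the two networks for one gene and term."""
    n = len(inp.g)
    try:
        ll1, k1 = fit_model1(inp, partial=partial)
    except ValueError:
        ll0, k0 = fit_model0(inp)
        bic0 = _bic(ll0, k0, n)
        return MediationScore(inp.gene, inp.term, bic0, math.inf, 0.0, 0, flagged=True)
    ll0, k0 = fit_model0(inp)
    bic0, bic1 = _bic(ll0, k0, n), _bic(ll1, k1, n)
    # expit of half the BIC difference is overflow-safe for any magnitude
    posterior = float(expit((bic0 - bic1) / 2.0))
    return MediationScore(inp.gene, inp.term, bic0, bic1, posterior,
                          _direction(inp.t, inp.g, inp.env_mask()))


def single_env_variant(inp: MediationInput, partial: bool = False) -> MediationScore:
    """Same comparison restricted to the tested environment's samples.

    The persistent expression sub-model collapses to a single-environment
    genotype effect, mirroring causal-inference approaches that analyse one
    condition at a time.
    """
    keep = inp.env_labels == inp.term[1]
    sub = MediationInput(
        g=inp.g[keep], t=inp.t[keep], s=inp.s[keep],
        env_labels=inp.env_labels[keep], term=inp.term,
        covariates=inp.covariates[keep], gene=inp.gene,
    )
    return score_mediation(sub, partial=partial)


def rank_candidates(scores: list[MediationScore]) -> pd.DataFrame:
    """Descending posterior with deterministic gene-id tie-break."""
    rows = sorted(scores, key=lambda s: (-s.posterior, s.gene))
    return pd.DataFrame(
        {
            "gene": [s.gene for s in rows],
            "posterior": [s.posterior for s in rows],
            "bic0": [s.bic0 for s in rows],
            "bic1": [s.bic1 for s in rows],
            "direction": [s.direction for s in rows],
            "rank": np.arange(1, len(rows) + 1),
        }
    )


def build_mediation_input(
    phenotypes: MultiEnvPhenotypes,
    genotypes: GenotypeMatrix,
    growth_model: GrowthGeneticModel,
    gene: str,
    term: Term,
    stack: pd.DataFrame | None = None,
    expr: pd.DataFrame | None = None,
    standardize: bool = True,
) -> MediationInput:
    """Assemble the row-aligned stacked vectors for one gene and term.

    Expression is standardized to zero mean and unit variance within each
    environment by default, making the expression->growth coefficient
    comparable across genes.
    """
    if stack is None or expr is None:
        stack, expr = phenotypes.stacked_all()
    t = expr[gene].to_numpy(dtype=float).copy()
    env_labels = stack["environment"].to_numpy()
    if standardize:
        for env in np.unique(env_labels):
            m = env_labels == env
            sd = t[m].std()
            t[m] = (t[m] - t[m].mean()) / (sd if sd > 0 else 1.0)
    s = genotypes.alleles[term[0]].astype(float).loc[stack["segregant"]].to_numpy()
    cov = growth_model.design(genotypes, stack, exclude=term)
    return MediationInput(
        g=stack["growth"].to_numpy(dtype=float),
        t=t,
        s=s,
        env_labels=env_labels,
        term=term,
        covariates=cov,
        gene=gene,
    )


class MediationScorer(BaseEstimator):
    """Score every gene for mediating one or all growth-model interaction terms.

    Parameters
    ----------
    single_env : bool
        Restrict each comparison to the tested environment's samples.
    partial : bool
        Keep the tested term's direct genotype effect in Model 1's growth
        sub-model (partial mediation).
    standardize : bool
        Standardize expression per environment before fitting.

    Attributes after :meth:`fit`
    ----------------------------
    scores_ : dict[Term, pandas.DataFrame]
        Ranked candidate table per term (gene, posterior, BICs, direction).
    """

    def __init__(self, single_env: bool = False, partial: bool = False,
                 standardize: bool = True):
        self.single_env = single_env
        self.partial = partial
        self.standardize = standardize

    def fit(self, phenotypes: MultiEnvPhenotypes, genotypes: GenotypeMatrix,
            growth_model: GrowthGeneticModel, terms: list[Term] | None = None,
            genes: list[str] | None = None):
        if terms is None:
            terms = [t for t in growth_model.terms if t[1] != "all"]
        if genes is None:
            genes = list(phenotypes.genes)
        stack, expr = phenotypes.stacked_all()
        env_labels = stack["environment"].to_numpy()
        tmat = expr[genes].to_numpy(dtype=float).copy()
        if self.standardize:
            for env in np.unique(env_labels):
                m = env_labels == env
                mu = tmat[m].mean(axis=0)
                sd = tmat[m].std(axis=0)
                sd[sd == 0] = 1.0
                tmat[m] = (tmat[m] - mu) / sd
        g = stack["growth"].to_numpy(dtype=float)
        self.scores_ = {}
        for term in terms:
            s = genotypes.alleles[term[0]].astype(float).loc[stack["segregant"]].to_numpy()
            cov = growth_model.design(genotypes, stack, exclude=term)
            scores = []
            for j, gene in enumerate(genes):
                inp = MediationInput(g=g, t=tmat[:, j], s=s, env_labels=env_labels,
                                     term=term, covariates=cov, gene=gene)
                if self.single_env:
                    scores.append(single_env_variant(inp, partial=self.partial))
                else:
                    scores.append(score_mediation(inp, partial=self.partial))
            self.scores_[term] = rank_candidates(scores)
        self.terms_ = terms
        return self
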