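"""Persistent vs environment-dependent decomposition of genetic effects.

A gene's expression across all profiled environments is modelled jointly as

    t = env intercepts + beta_shared * s + sum_e gamma_e * (s x 1{env})

with sum-to-zero contrasts on the interactions, so ``beta_shared`` is the
across-environment mean genotype effect ("persistent" component) and each
``gamma_e`` the deviation of environment e from it.  Testing all gamma_e = 0
makes "persistent in direction and amplitude" the literal null hypothesis.

Three interaction codings are available.  ``sum`` (the joint decomposition
above) gives a calibrated test of the mean effect; ``reference`` uses the
first environment as baseline; ``single`` fits one deviating environment at
a time and takes the least favourable shared test, which is the coding used
for classification — under ``sum`` a strong effect confined to one
environment leaks 1/E of itself into the shared component and would be
mislabelled as persistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .data import GenotypeMatrix, MultiEnvPhenotypes
from .fdr import storey_qvalues
from .lmm import KinshipMatrix, fit_null_lmm


@dataclass
class GxeFit:
    gene: str
    marker: str
    beta_shared: float
    se_shared: float
    p_shared: float
    environments: list[str]
    beta_env: dict[str, float]
    se_env: dict[str, float]
    p_env: dict[str, float]
    intercepts: dict[str, float]
    n: int
    shared_by_env: dict[str, float] | None = None   # per-deviating-env shared
                                                    # estimates ("single" mode)


def _sum_contrast(n_env: int) -> np.ndarray:
    """(n_env x n_env-1) sum-to-zero contrast columns."""
    c = np.zeros((n_env, n_env - 1))
    c[: n_env - 1, :] = np.eye(n_env - 1)
    c[n_env - 1, :] = -1.0
    return c


def _design(s: np.ndarray, env_idx: np.ndarray, n_env: int, contrast: str):
    onehot = np.eye(n_env)[env_idx]
    if contrast == "sum":
        inter = s[:, None] * (_sum_contrast(n_env)[env_idx])
    elif contrast == "reference":
        inter = s[:, None] * onehot[:, 1:]
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    return np.column_stack([onehot, s, inter])


def _gls_fit(design: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted LS fit returning (beta, covariance, df)."""
    sw = np.sqrt(w)
    a = design * sw[:, None]
    b = y * sw
    ata = a.T @ a
    beta = np.linalg.solve(ata, a.T @ b)
    resid = b - a @ beta
    df = design.shape[0] - design.shape[1]
    sigma2 = float(resid @ resid) / df
    return beta, sigma2 * np.linalg.inv(ata), df


def _tp(est: float, var: float, df: int) -> tuple[float, float]:
    se = math.sqrt(max(var, 0.0))
    if se == 0.0:
        return se, 1.0 if est == 0.0 else 0.0
    return se, float(2.0 * stats.t.sf(abs(est / se), df))


def fit_joint_env_model(
    expression: np.ndarray,
    genotype_at_marker: np.ndarray,
    env_labels,
    kinship: KinshipMatrix | np.ndarray | None = None,
    contrast: str = "sum",
    gene: str = "",
    marker: str = "",
    null_eigen: tuple[np.ndarray, np.ndarray, float] | None = None,
) -> GxeFit:
    """Joint GLS fit of the persistent + interaction expression model.

    ``kinship`` (optional) is the stacked-sample covariance structure (for
    the checkered design, a block-diagonal expansion of the per-environment
    kinship).  ``null_eigen`` may carry a precomputed
    (eigenvalues, eigenvectors, delta) triple so that scans over many genes
    with the same missingness pattern pay for one REML fit only.
    """
    t = np.asarray(expression, dtype=float)
    s = np.asarray(genotype_at_marker, dtype=float)
    env_labels = np.asarray(env_labels)
    envs = sorted(set(env_labels.tolist()))
    n_env = len(envs)
    if n_env < 2:
        raise ValueError("decomposition requires at least 2 environments")
    for e in envs:
        if (env_labels == e).sum() < 3:
            raise ValueError(f"environment {e!r} has fewer than 3 profiled samples")
    env_idx = np.array([envs.index(e) for e in env_labels])
    onehot = np.eye(n_env)[env_idx]
    n = len(t)

    if kinship is None and null_eigen is None:
        w = np.ones(n)
        rot = None
    else:
        if null_eigen is None:
            kin = kinship if isinstance(kinship, KinshipMatrix) else KinshipMatrix(
                pd.DataFrame(kinship)
            )
            null = fit_null_lmm(t, kin, covariates=onehot[:, 1:])
            lam, u, delta = null.eigenvalues, null.eigenvectors, null.delta
        else:
            lam, u, delta = null_eigen
        w = 1.0 / (lam + delta)
        rot = u.T

    def fit(design):
        dd = design if rot is None else rot @ design
        tt = t if rot is None else rot @ t
        return _gls_fit(dd, tt, w)

    beta_env, se_env, p_env = {}, {}, {}
    if contrast == "single":
        # One deviating environment at a time: t ~ env intercepts
        # + beta_shared*s + gamma_e*(s x 1{env=e}).  The persistent evidence
        # is the least favourable shared test over the E fits, so a gene
        # whose effect is confined to one environment is not called
        # persistent merely because the grand-mean effect is nonzero.
        shared_candidates = []
        shared_by_env: dict[str, float] = {}
        for j, e in enumerate(envs):
            d = np.column_stack([onehot, s, s * onehot[:, j]])
            beta, cov, df = fit(d)
            i_sh, i_g = n_env, n_env + 1
            se_sh, p_sh = _tp(float(beta[i_sh]), float(cov[i_sh, i_sh]), df)
            shared_candidates.append((p_sh, float(beta[i_sh]), se_sh))
            shared_by_env[e] = float(beta[i_sh])
            se_g, p_g = _tp(float(beta[i_g]), float(cov[i_g, i_g]), df)
            beta_env[e], se_env[e], p_env[e] = float(beta[i_g]), se_g, p_g
        p_shared, b_shared, se_shared = max(shared_candidates, key=lambda c: c[0])
        d0 = np.column_stack([onehot, s])
        beta0, _, _ = fit(d0)
        intercepts = {e: float(beta0[j]) for j, e in enumerate(envs)}
        kwargs_extra = shared_by_env
    else:
        d = _design(s, env_idx, n_env, contrast)
        beta, cov, df = fit(d)
        k = d.shape[1]
        i_shared = n_env
        b_shared = float(beta[i_shared])
        se_shared, p_shared = _tp(b_shared, float(cov[i_shared, i_shared]), df)
        if contrast == "sum":
            for j, e in enumerate(envs):
                vec = np.zeros(k)
                if j < n_env - 1:
                    vec[n_env + 1 + j] = 1.0
                else:
                    vec[n_env + 1:] = -1.0
                est = float(vec @ beta)
                se, p = _tp(est, float(vec @ cov @ vec), df)
                beta_env[e], se_env[e], p_env[e] = est, se, p
        else:
            beta_env[envs[0]] = 0.0
            se_env[envs[0]], p_env[envs[0]] = float("nan"), float("nan")
            for j, e in enumerate(envs[1:]):
                idx = n_env + 1 + j
                est = float(beta[idx])
                se, p = _tp(est, float(cov[idx, idx]), df)
                beta_env[e], se_env[e], p_env[e] = est, se, p
        intercepts = {e: float(beta[j]) for j, e in enumerate(envs)}
        kwargs_extra = None

    return GxeFit(
        gene=gene,
        marker=marker,
        beta_shared=b_shared,
        se_shared=se_shared,
        p_shared=p_shared,
        environments=envs,
        beta_env=beta_env,
        se_env=se_env,
        p_env=p_env,
        intercepts=intercepts,
        n=n,
        shared_by_env=kwargs_extra,
    )


def classify_eqtl(q_shared: float, q_env: dict[str, float],
                  fdr_persistent: float = 0.05, fdr_dependent: float = 0.05) -> str:
    """Four-way eQTL label from family-pooled q-values."""
    if q_shared is None or any(v is None for v in q_env.values()):
        raise ValueError("q-values must be computed before classification")
    persistent = q_shared < fdr_persistent
    dependent = any(q < fdr_dependent for q in q_env.values())
    if persistent and dependent:
        return "both"
    if persistent:
        return "persistent-only"
    if dependent:
        return "dependent-only"
    return "none"


def classify_eqtls(fits: list[GxeFit], fdr_persistent: float = 0.05,
                   fdr_dependent: float = 0.05, pi0: float | None = 1.0) -> pd.DataFrame:
    """Label each fit from family-pooled q-values.

    The persistent family pools the shared-effect p-values across genes.
    The dependent family pools one p-value per gene — the Bonferroni-
    corrected minimum over its environment interactions — so a gene with
    several strong interactions contributes one discovery, not E of them
    (pooling every gene x environment p into one family lets genes with
    many true interactions drag pi0 down and mislabel persistent genes).
    Both families default to the conservative pi0 = 1 (Benjamini-Hochberg)
    variant; at this family size the pi0 smoother is too unstable for
    stable labels.
    """
    shared_p = np.array([f.p_shared for f in fits])
    q_shared, _ = storey_qvalues(shared_p, pi0=pi0)
    envs = fits[0].environments
    inter_p = np.array([[f.p_env[e] for e in envs] for f in fits])
    dep_p = np.minimum(1.0, len(envs) * np.nanmin(inter_p, axis=1))
    q_dep, _ = storey_qvalues(dep_p, pi0=pi0)
    rows = []
    for i, f in enumerate(fits):
        persistent = q_shared[i] < fdr_persistent
        dependent = q_dep[i] < fdr_dependent
        label = ("both" if persistent and dependent
                 else "persistent-only" if persistent
                 else "dependent-only" if dependent
                 else "none")
        rows.append((f.gene, f.marker, f.beta_shared, f.p_shared, q_shared[i],
                     dep_p[i], q_dep[i], label))
    out = pd.DataFrame(rows, columns=["gene", "marker", "beta_shared", "p_shared",
                                      "q_shared", "p_dependent", "q_dependent",
                                      "label"])
    for j, e in enumerate(envs):
        out[f"p_dep_{e}"] = inter_p[:, j]
    return out


def downsample_for_power(stack: pd.DataFrame, seed: int = 0,
                         target: int | None = None) -> pd.DataFrame:
    """Subsample the stacked dataset to the average per-environment size.

    Used when comparing persistent vs dependent detection at matched power:
    draws (uniformly, without replacement) ceil(mean per-environment count)
    rows from the full stack.
    """
    counts = stack["environment"].value_counts()
    if target is None:
        target = math.ceil(counts.mean())
    if target > len(stack):
        raise ValueError("downsampling target exceeds available rows")
    if target == len(stack):
        return stack.copy()
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(len(stack), size=target, replace=False))
    return stack.iloc[keep].copy()


class JointEnvironmentModel(BaseEstimator):
    """Estimator wrapper for the persistent/interaction decomposition.

    Fit on stacked arrays; exposes ``beta_shared_``, ``p_shared_``,
    ``beta_env_``, ``p_env_`` and the full :class:`GxeFit` as ``fit_``.
    """

    def __init__(self, contrast: str = "sum", use_kinship: bool = False):
        self.contrast = contrast
        self.use_kinship = use_kinship

    def fit(self, expression, genotype_at_marker, env_labels,
            kinship: KinshipMatrix | None = None, null_eigen=None):
        kin = kinship if self.use_kinship else None
        self.fit_ = fit_joint_env_model(
            expression, genotype_at_marker, env_labels, kinship=kin,
            contrast=self.contrast, null_eigen=null_eigen if self.use_kinship else None,
        )
        self.beta_shared_ = self.fit_.beta_shared
        self.p_shared_ = self.fit_.p_shared
        self.beta_env_ = self.fit_.beta_env
        self.p_env_ = self.fit_.p_env
        self.n_samples_ = self.fit_.n
        return self


def fit_gxe_table(
    phenotypes: MultiEnvPhenotypes,
    genotypes: GenotypeMatrix,
    markers: list[str],
    kinship: KinshipMatrix | None = None,
    contrast: str = "sum",
) -> dict[str, pd.DataFrame]:
    """Joint persistent/interaction fits of every gene at each marker.

    When ``kinship`` (segregant-level) is given, it is expanded block-
    diagonally over the stacked checkered samples and its eigendecomposition
    is shared across genes and markers; only the variance ratio is
    re-estimated per gene.  Returns one DataFrame per marker with columns
    gene, beta_shared, p_shared and p_dep_<env>/beta_dep_<env>.
    """
    stack, expr = phenotypes.stacked_all()
    env_labels = stack["environment"].to_numpy()
    envs = sorted(set(env_labels.tolist()))
    onehot = np.eye(len(envs))[[envs.index(e) for e in env_labels]]

    null_eigens: dict[str, tuple] = {}
    if kinship is not None:
        skin = stacked_kinship(kinship, stack)
        lam_all, u_all = np.linalg.eigh(
            skin.values.to_numpy() + 1e-8 * np.eye(len(stack))
        )
        lam_all = np.clip(lam_all, 0.0, None)
        for gene in expr.columns:
            null = fit_null_lmm(expr[gene].to_numpy(), skin, covariates=onehot[:, 1:])
            null_eigens[gene] = (lam_all, u_all, null.delta)

    out: dict[str, pd.DataFrame] = {}
    for marker in markers:
        s = genotypes.alleles[marker].astype(float).loc[stack["segregant"]].to_numpy()
        rows = []
        for gene in expr.columns:
            fit = fit_joint_env_model(
                expr[gene].to_numpy(), s, env_labels,
                kinship=None, contrast=contrast, gene=gene, marker=marker,
                null_eigen=null_eigens.get(gene),
            )
            row = {"gene": gene, "beta_shared": fit.beta_shared,
                   "p_shared": fit.p_shared, "n": fit.n}
            for e in fit.environments:
                row[f"beta_dep_{e}"] = fit.beta_env[e]
                row[f"p_dep_{e}"] = fit.p_env[e]
            rows.append(row)
        out[marker] = pd.DataFrame(rows).set_index("gene")
    return out


def stacked_kinship(kinship: KinshipMatrix, stack: pd.DataFrame) -> KinshipMatrix:
    """Block-diagonal expansion of the segregant kinship over the stack.

    Samples from different environments are treated as independent draws
    (separate cultures); within an environment the usual segregant-level
    relatedness applies.
    """
    n = len(stack)
    out = np.zeros((n, n))
    for env, grp in stack.groupby("environment", sort=False):
        idx = grp.index.to_numpy()
        ids = grp["segregant"].tolist()
        out[np.ix_(idx, idx)] = kinship.values.loc[ids, ids].to_numpy()
    np.fill_diagonal(out, 1.0)
    return KinshipMatrix(pd.DataFrame(out, index=stack.index, columns=stack.index),
                         "stacked-" + kinship.construction)
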