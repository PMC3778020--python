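"""Kinship-corrected single-marker association scans.

The variance model is the classic two-component animal model
``y = Xb + u + e`` with ``u ~ N(0, sigma2_g K)`` and ``e ~ N(0, sigma2_e I)``.
Variance components are estimated once per trait under the null design by
REML over the variance ratio ``delta = sigma2_e / sigma2_g`` (spectral
decomposition of K plus Brent's method on log delta), and each marker is
then tested by generalized least squares with the null covariance held
fixed — the standard two-stage approximation to a full per-marker mixed
model.  ``exact_emma=True`` re-optimizes delta for every marker instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .data import GenotypeMatrix
from .fdr import storey_qvalues

_RIDGE = 1e-8
_LOG_DELTA_BOUNDS = (-10.0, 10.0)


@dataclass
class KinshipMatrix:
    values: pd.DataFrame
    construction: str = "ibs"

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")

    def subset(self, ids) -> "KinshipMatrix":
        return KinshipMatrix(self.values.loc[ids, ids], self.construction)


def compute_kinship(genotypes: GenotypeMatrix) -> KinshipMatrix:
    """Identity-by-state allele-sharing kinship.

    Entry (i, j) is the fraction of markers at which segregants i and j
    carry the same allele; the diagonal is 1.
    """
    g = genotypes.alleles.to_numpy(dtype=float)
    if g.shape[1] == 0:
        raise ValueError("cannot compute kinship with zero markers")
    shared = g @ g.T + (1.0 - g) @ (1.0 - g).T
    k = shared / g.shape[1]
    return KinshipMatrix(
        pd.DataFrame(k, index=genotypes.segregants, columns=genotypes.segregants), "ibs"
    )


def identity_kinship(ids) -> KinshipMatrix:
    n = len(ids)
    return KinshipMatrix(pd.DataFrame(np.eye(n), index=ids, columns=ids), "identity")


@dataclass
class NullModel:
    """REML fit of the null (covariates-only) mixed model for one trait."""

    sigma2_g: float
    sigma2_e: float
    delta: float
    loglik: float
    boundary: bool
    eigenvalues: np.ndarray      # of K + ridge
    eigenvectors: np.ndarray
    degenerate: bool = False     # constant trait


def _reml_neg_loglik(log_delta: float, lam: np.ndarray, yt: np.ndarray,
                     xt: np.ndarray, logdet_xx: float) -> float:
    delta = np.exp(log_delta)
    w = 1.0 / (lam + delta)
    a = xt.T @ (xt * w[:, None])
    b = xt.T @ (yt * w)
    beta = np.linalg.solve(a, b)
    resid = yt - xt @ beta
    rss_w = float(resid @ (resid * w))
    n, q = xt.shape
    sigma2 = rss_w / (n - q)
    if sigma2 <= 0:
        return np.inf
    sign, logdet_a = np.linalg.slogdet(a)
    ll = -0.5 * (
        (n - q) * np.log(2.0 * np.pi * sigma2)
        + np.sum(np.log(lam + delta))
        + logdet_a
        - logdet_xx
        + (n - q)
    )
    return -ll


def fit_null_lmm(trait: np.ndarray, kinship: KinshipMatrix,
                 covariates: np.ndarray | None = None) -> NullModel:
    """Estimate (sigma2_g, sigma2_e) by REML via spectral decomposition of K.

    With an identity kinship the split between the two components is
    unidentifiable; the optimum found is reported and flagged as a boundary
    solution when delta hits the search bounds.
    """
    y = np.asarray(trait, dtype=float)
    n = y.shape[0]
    k = kinship.values.to_numpy()
    if k.shape[0] != n:
        raise ValueError("trait length does not match kinship dimension")
    x = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), np.asarray(covariates, dtype=float)]
    )
    lam, u = np.linalg.eigh(k + _RIDGE * np.eye(n))
    if lam.min() < -1e-6:
        raise np.linalg.LinAlgError(
            f"kinship not PSD after ridge (min eigenvalue {lam.min():.3g})"
        )
    lam = np.clip(lam, 0.0, None)

    if np.var(y) < 1e-14:
        return NullModel(0.0, 0.0, 1.0, 0.0, True, lam, u, degenerate=True)

    yt, xt = u.T @ y, u.T @ x
    _, logdet_xx = np.linalg.slogdet(x.T @ x)
    res = optimize.minimize_scalar(
        _reml_neg_loglik,
        bounds=_LOG_DELTA_BOUNDS,
        method="bounded",
        args=(lam, yt, xt, logdet_xx),
        options={"xatol": 1e-6},
    )
    log_delta = float(res.x)
    delta = float(np.exp(log_delta))
    boundary = (log_delta <= _LOG_DELTA_BOUNDS[0] + 0.1) or (
        log_delta >= _LOG_DELTA_BOUNDS[1] - 0.1
    )
    w = 1.0 / (lam + delta)
    a = xt.T @ (xt * w[:, None])
    beta = np.linalg.solve(a, xt.T @ (yt * w))
    resid = yt - xt @ beta
    sigma2_g = float(resid @ (resid * w)) / (n - x.shape[1])
    return NullModel(sigma2_g, delta * sigma2_g, delta, -float(res.fun), boundary, lam, u)


def _gls_scan(yt, xt, gt, w, df):
    """Vectorized GLS marker tests with per-marker residual rescaling.

    Partialling out the covariates under weights w reduces each marker test
    to a simple weighted regression of residualized trait on residualized
    genotype; the noise scale is re-estimated per marker so that the test
    statistic is exactly t-distributed under normality.
    """
    sw = np.sqrt(w)
    a = xt * sw[:, None]
    b = yt * sw
    g = gt * sw[:, None]
    q_mat, _ = np.linalg.qr(a)
    b_res = b - q_mat @ (q_mat.T @ b)
    g_res = g - q_mat @ (q_mat.T @ g)
    gg = np.einsum("ij,ij->j", g_res, g_res)
    gy = g_res.T @ b_res
    yy = float(b_res @ b_res)
    mono = gg < 1e-12
    gg_safe = np.where(mono, 1.0, gg)
    beta = gy / gg_safe
    rss = np.maximum(yy - beta * gy, 0.0)
    sigma2 = rss / df
    tiny = sigma2 < 1e-300
    se = np.sqrt(np.where(tiny, np.nan, sigma2) / gg_safe)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    beta = np.where(mono, 0.0, beta)
    se = np.where(mono, np.nan, se)
    tstat = np.where(mono | tiny, 0.0, tstat)
    pvals = np.where(mono | tiny, 1.0, pvals)
    return beta, se, tstat, pvals, mono


def single_marker_scan(
    trait: np.ndarray,
    genotypes: GenotypeMatrix,
    kinship: KinshipMatrix,
    covariates: np.ndarray | None = None,
    null_model: NullModel | None = None,
    exact_emma: bool = False,
) -> pd.DataFrame:
    """Test every marker for association with one trait.

    Returns a DataFrame indexed by marker with columns chrom, pos, beta,
    se, stat, p, q, monomorphic, plus null-model variance components as
    DataFrame attrs.
    """
    y = np.asarray(trait, dtype=float)
    n = y.shape[0]
    if null_model is None:
        null_model = fit_null_lmm(y, kinship, covariates)
    x = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), np.asarray(covariates, dtype=float)]
    )
    gmat = genotypes.alleles.loc[kinship.values.index].to_numpy(dtype=float)
    df = n - x.shape[1] - 1

    if null_model.degenerate:
        m = gmat.shape[1]
        beta = np.zeros(m)
        se = np.full(m, np.nan)
        tstat = np.zeros(m)
        pvals = np.ones(m)
        mono = np.zeros(m, dtype=bool)
    elif exact_emma:
        beta = np.empty(gmat.shape[1])
        se = np.empty_like(beta)
        tstat = np.empty_like(beta)
        pvals = np.empty_like(beta)
        mono = np.zeros(gmat.shape[1], dtype=bool)
        for j in range(gmat.shape[1]):
            gj = gmat[:, j]
            if np.var(gj) < 1e-12:
                beta[j], se[j], tstat[j], pvals[j], mono[j] = 0.0, np.nan, 0.0, 1.0, True
                continue
            nm = fit_null_lmm(y, kinship, covariates=np.column_stack([x[:, 1:], gj]))
            w = 1.0 / (nm.eigenvalues + nm.delta)
            yt, xt = nm.eigenvectors.T @ y, nm.eigenvectors.T @ x
            gt = (nm.eigenvectors.T @ gj)[:, None]
            b_, s_, t_, p_, m_ = _gls_scan(yt, xt, gt, w, df)
            beta[j], se[j], tstat[j], pvals[j], mono[j] = b_[0], s_[0], t_[0], p_[0], m_[0]
    else:
        w = 1.0 / (null_model.eigenvalues + null_model.delta)
        u = null_model.eigenvectors
        yt, xt, gt = u.T @ y, u.T @ x, u.T @ gmat
        beta, se, tstat, pvals, mono = _gls_scan(yt, xt, gt, w, df)

    qvals, _ = storey_qvalues(pvals)
    out = pd.DataFrame(
        {
            "chrom": genotypes.marker_map["chrom"].to_numpy(),
            "pos": genotypes.marker_map["pos"].to_numpy(),
            "beta": beta,
            "se": se,
            "stat": tstat,
            "p": pvals,
            "q": qvals,
            "monomorphic": mono,
        },
        index=genotypes.markers,
    )
    out.attrs["sigma2_g"] = null_model.sigma2_g
    out.attrs["sigma2_e"] = null_model.sigma2_e
    out.attrs["delta"] = null_model.delta
    return out


class MixedModelScan(BaseEstimator):
    """Single-trait genome scan with a kinship random effect.

    Parameters
    ----------
    kinship : {"ibs", "identity"}
        Genetic-similarity construction for the random effect.
    exact_emma : bool
        Re-optimize the variance ratio for every marker instead of reusing
        the null-model fit.

    Attributes (after :meth:`fit`)
    ------------------------------
    results_ : pandas.DataFrame
        Per-marker beta, se, stat, p, q.
    sigma2_g_, sigma2_e_, delta_ : float
        Null-model variance components.
    """

    def __init__(self, kinship: str = "ibs", exact_emma: bool = False):
        self.kinship = kinship
        self.exact_emma = exact_emma

    def fit(self, genotypes: GenotypeMatrix, trait: pd.Series,
            covariates: np.ndarray | None = None):
        trait = pd.Series(trait).reindex(genotypes.segregants)
        keep = trait.notna()
        ids = trait.index[keep]
        if self.kinship == "ibs":
            kin = compute_kinship(genotypes).subset(ids)
        elif self.kinship == "identity":
            kin = identity_kinship(ids)
        else:
            raise ValueError(f"unknown kinship construction {self.kinship!r}")
        sub_geno = GenotypeMatrix(genotypes.alleles.loc[ids], genotypes.marker_map)
        cov = None
        if covariates is not None:
            cov = np.asarray(covariates, dtype=float)[np.asarray(keep)]
        self.null_model_ = fit_null_lmm(trait[keep].to_numpy(), kin, cov)
        self.results_ = single_marker_scan(
            trait[keep].to_numpy(), sub_geno, kin, cov,
            null_model=self.null_model_, exact_emma=self.exact_emma,
        )
        self.sigma2_g_ = self.null_model_.sigma2_g
        self.sigma2_e_ = self.null_model_.sigma2_e
        self.delta_ = self.null_model_.delta
        self.n_samples_ = int(keep.sum())
        return self
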