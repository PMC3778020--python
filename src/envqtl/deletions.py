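"""Fitness effects of gene deletions from pooled barcode competition assays.

Each deletion strain's selection coefficient s (log2 relative abundance
change per generation) is the least-squares slope of log2 abundance on
generation count over replicates.  Significance uses an empirical-Bayes
moderated t-test: per-gene residual variances are shrunk toward a prior
(d0, s0^2) fitted by matching moments of the scaled-F distribution of
sample variances, and the moderated t is referred to a t distribution
with d0 + d_g degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator

from .fdr import storey_qvalues


def estimate_selection_coefficients(log_abundance: pd.DataFrame) -> pd.DataFrame:
    """Per-gene, per-environment slope of log2 abundance on generation.

    Parameters
    ----------
    log_abundance : long DataFrame with columns gene, environment,
        generation, replicate, log2_abundance.

    Returns
    -------
    DataFrame with columns gene, environment, s, t_ordinary, resid_var,
    df, c2 (squared standard-error multiplier), n_obs.  Genes with all
    values missing in an environment are excluded.
    """
    df_in = log_abundance.dropna(subset=["log2_abundance"])
    if df_in.empty:
        raise ValueError("no usable observations")
    rows = []
    for (gene, env), grp in df_in.groupby(["gene", "environment"], sort=False):
        x = grp["generation"].to_numpy(dtype=float)
        y = grp["log2_abundance"].to_numpy(dtype=float)
        n = len(x)
        if n < 2 or np.ptp(x) == 0:
            continue
        xc = x - x.mean()
        sxx = float(xc @ xc)
        slope = float(xc @ y) / sxx
        intercept = y.mean() - slope * x.mean()
        resid = y - intercept - slope * x
        dof = n - 2
        s2 = float(resid @ resid) / dof if dof > 0 else np.nan
        c2 = 1.0 / sxx
        with np.errstate(divide="ignore", invalid="ignore"):
            t_ord = slope / math.sqrt(s2 * c2) if dof > 0 and s2 > 0 else np.nan
        rows.append((gene, env, slope, t_ord, s2, dof, c2, n))
    out = pd.DataFrame(rows, columns=["gene", "environment", "s", "t_ordinary",
                                      "resid_var", "df", "c2", "n_obs"])
    return out


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration."""
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-matching fit of the (d0, s0^2) variance prior.

    Sample variances around a common true variance follow a scaled F
    distribution; matching the mean and spread of log variances yields the
    prior degrees of freedom d0 (np.inf when the observed spread is fully
    explained by chi-square sampling noise) and the prior variance s0^2.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = (s2 > 0) & (df > 0)
    if ok.sum() < 10:
        raise ValueError("need at least 10 positive variances to fit the prior")
    z = np.log(s2[ok])
    e = z - special.digamma(df[ok] / 2.0) + np.log(df[ok] / 2.0)
    emean = float(e.mean())
    n = len(e)
    evar = float(((e - emean) ** 2).sum() / (n - 1))
    evar -= float(np.mean(special.polygamma(1, df[ok] / 2.0)))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = math.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0_sq = math.exp(emean)
    return d0, s0_sq


def moderated_t(fitness: pd.DataFrame, d0: float | None = None,
                s0_sq: float | None = None) -> pd.DataFrame:
    """Attach moderated statistics, p- and q-values to a fitness table.

    Parameters
    ----------
    fitness : output of :func:`estimate_selection_coefficients`.
    d0, s0_sq : optional prior overrides (d0=0 gives the ordinary t;
        d0=inf fully pools the variance).

    Returns a copy with columns s2_moderated, t_moderated, p, q.
    """
    out = fitness.copy()
    s2 = out["resid_var"].to_numpy(dtype=float)
    df = out["df"].to_numpy(dtype=float)
    if (s2 <= 0).any():
        raise ValueError("non-positive residual variances")
    if d0 is None or s0_sq is None:
        d0_fit, s0_fit = fit_variance_prior(s2, df)
        d0 = d0_fit if d0 is None else d0
        s0_sq = s0_fit if s0_sq is None else s0_sq
    if math.isinf(d0):
        s2_mod = np.full_like(s2, s0_sq)
        df_total = np.full_like(df, np.inf)
    else:
        s2_mod = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = out["s"].to_numpy() / np.sqrt(s2_mod * out["c2"].to_numpy())
    finite_df = np.where(np.isinf(df_total), 1e12, df_total)
    p = 2.0 * stats.t.sf(np.abs(t_mod), finite_df)
    out["s2_moderated"] = s2_mod
    out["t_moderated"] = t_mod
    out["p"] = p
    out["q"] = np.nan
    for env, grp in out.groupby("environment", sort=False):
        q, _ = storey_qvalues(grp["p"].to_numpy())
        out.loc[grp.index, "q"] = q
    out.attrs["d0"] = d0
    out.attrs["s0_sq"] = s0_sq
    return out


def call_deletion_effects(fitness: pd.DataFrame, s_cut: float = 0.05,
                          fdr: float = 0.05) -> pd.DataFrame:
    """Three-way call per gene x environment.

    beneficial: s > s_cut and q < fdr; detrimental: s < -s_cut and q < fdr;
    otherwise none.
    """
    out = fitness.copy()
    sig = out["q"] < fdr
    out["call"] = "none"
    out.loc[sig & (out["s"] > s_cut), "call"] = "beneficial"
    out.loc[sig & (out["s"] < -s_cut), "call"] = "detrimental"
    return out


class DeletionFitnessModel(BaseEstimator):
    """Estimator over a long log2-abundance table.

    ``fit`` computes selection coefficients, the moderated test and the
    three-way calls; results land in ``fitness_`` and ``calls_``.
    """

    def __init__(self, s_cut: float = 0.05, fdr: float = 0.05,
                 d0: float | None = None, s0_sq: float | None = None):
        self.s_cut = s_cut
        self.fdr = fdr
        self.d0 = d0
        self.s0_sq = s0_sq

    def fit(self, log_abundance: pd.DataFrame):
        fitness = estimate_selection_coefficients(log_abundance)
        fitness = moderated_t(fitness, d0=self.d0, s0_sq=self.s0_sq)
        self.fitness_ = fitness
        self.calls_ = call_deletion_effects(fitness, s_cut=self.s_cut, fdr=self.fdr)
        self.d0_ = fitness.attrs["d0"]
        self.s0_sq_ = fitness.attrs["s0_sq"]
        return self
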