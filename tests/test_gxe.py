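"""Persistent vs environment-dependent decomposition."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import envqtl as eq
from envqtl.gxe import (
    classify_eqtl,
    classify_eqtls,
    downsample_for_power,
    fit_joint_env_model,
    stacked_kinship,
)

ENVS5 = [f"e{i}" for i in range(5)]


def _stacked(n_per=35, n_env=5, seed=0):
    rng = np.random.default_rng(seed)
    env_labels = np.repeat(ENVS5[:n_env], n_per)
    s = rng.integers(0, 2, size=n_env * n_per).astype(float)
    return rng, env_labels, s


@pytest.mark.parametrize("contrast", ["sum", "single", "reference"])
def test_uniform_effect_no_noise_is_purely_persistent(contrast):
    rng, env_labels, s = _stacked(seed=1)
    t = 0.7 * s + np.repeat(np.arange(5) * 0.3, 35)
    fit = fit_joint_env_model(t, s, env_labels, contrast=contrast)
    assert fit.beta_shared == pytest.approx(0.7, abs=1e-10)
    devs = [v for v in fit.beta_env.values() if not np.isnan(v)]
    assert np.allclose(devs, 0.0, atol=1e-10)


@pytest.mark.parametrize("contrast", ["sum", "single"])
def test_decomposition_consistent_with_marginal_effects(contrast):
    # balanced noiseless data with arbitrary per-environment effects:
    # shared + deviation reproduces each environment's marginal OLS effect
    n_per, n_env = 20, 4
    env_labels = np.repeat(ENVS5[:n_env], n_per)
    s = np.tile(np.repeat([0.0, 1.0], n_per // 2), n_env)   # balanced
    effects = {"e0": 1.0, "e1": -0.5, "e2": 0.0, "e3": 2.0}
    t = np.array([effects[e] for e in env_labels]) * s
    fit = fit_joint_env_model(t, s, env_labels, contrast=contrast)
    for e in fit.environments:
        shared = (fit.beta_shared if contrast == "sum"
                  else fit.shared_by_env[e])       # shared term of env-e's fit
        assert shared + fit.beta_env[e] == pytest.approx(effects[e], abs=1e-8)


def test_single_environment_input_rejected():
    rng, env_labels, s = _stacked(n_env=1)
    with pytest.raises(ValueError):
        fit_joint_env_model(rng.normal(size=len(s)), s, env_labels)


def test_tiny_environment_rejected():
    env_labels = np.array(["a"] * 10 + ["b"] * 2)
    s = np.zeros(12)
    with pytest.raises(ValueError):
        fit_joint_env_model(np.zeros(12), s, env_labels)


def test_single_env_interaction_power():
    hits = 0
    for rep in range(100):
        rng, env_labels, s = _stacked(seed=rep + 10)
        t = rng.normal(0, 0.1, size=len(s)) + 1.0 * s * (env_labels == "e0")
        fit = fit_joint_env_model(t, s, env_labels, contrast="sum")
        hits += fit.p_env["e0"] < 0.001
    assert hits >= 95


def test_shared_pvalues_uniform_under_global_null():
    ps = []
    for rep in range(400):
        rng, env_labels, s = _stacked(seed=rep + 1000)
        t = rng.normal(size=len(s))
        ps.append(fit_joint_env_model(t, s, env_labels, contrast="sum").p_shared)
    assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestClassification:
    def test_threshold_logic(self):
        assert classify_eqtl(0.001, {"e0": 0.9, "e1": 0.7}) == "persistent-only"
        assert classify_eqtl(0.8, {"e0": 0.001, "e1": 0.7}) == "dependent-only"
        assert classify_eqtl(0.001, {"e0": 0.001, "e1": 0.7}) == "both"
        assert classify_eqtl(0.8, {"e0": 0.9, "e1": 0.7}) == "none"
        with pytest.raises(ValueError):
            classify_eqtl(None, {"e0": 0.1})

    def test_mixture_recovery(self):
        # 50/50 persistent and env-0-dependent genes at strong effect
        fits, truth = [], []
        for g in range(60):
            rng, env_labels, s = _stacked(seed=g)
            t = rng.normal(0, 0.3, size=len(s)) + 1.0 * s
            fits.append(fit_joint_env_model(t, s, env_labels, contrast="single",
                                            gene=f"p{g}"))
            truth.append("persistent-only")
        for g in range(60):
            rng, env_labels, s = _stacked(seed=g + 500)
            t = rng.normal(0, 0.3, size=len(s)) + 1.0 * s * (env_labels == "e0")
            fits.append(fit_joint_env_model(t, s, env_labels, contrast="single",
                                            gene=f"d{g}"))
            truth.append("dependent-only")
        cls = classify_eqtls(fits)
        assert (cls["label"].to_numpy() == np.array(truth)).mean() >= 0.9

    def test_mostly_none_under_global_null(self):
        fits = []
        for g in range(200):
            rng, env_labels, s = _stacked(seed=g + 3000)
            fits.append(fit_joint_env_model(rng.normal(size=len(s)), s, env_labels,
                                            contrast="single", gene=f"n{g}"))
        cls = classify_eqtls(fits, fdr_persistent=0.05, fdr_dependent=0.05)
        assert (cls["label"] == "none").mean() >= 0.9


class TestDownsample:
    def _stack_df(self, n_per=35, n_env=5):
        return pd.DataFrame({
            "environment": np.repeat(ENVS5[:n_env], n_per),
            "segregant": [f"s{i}" for i in range(n_per * n_env)],
            "growth": 0.0,
        })

    def test_target_is_mean_environment_size(self):
        out = downsample_for_power(self._stack_df(), seed=0)
        assert len(out) == 35

    def test_full_size_subsample_is_identity(self):
        stack = self._stack_df()
        out = downsample_for_power(stack, seed=0, target=len(stack))
        assert out.equals(stack)

    def test_oversized_target_raises(self):
        with pytest.raises(ValueError):
            downsample_for_power(self._stack_df(), seed=0, target=1000)

    def test_detection_rate_stable_across_seeds(self):
        # persistent effect detectable in the 35-row subsample; the mean
        # detection rate over seeds is stable
        rng, env_labels, s = _stacked(seed=77)
        genes = [1.2 * s + np.random.default_rng(g).normal(0, 0.5, len(s))
                 for g in range(20)]
        stack = pd.DataFrame({"environment": env_labels,
                              "segregant": [f"s{i}" for i in range(len(s))],
                              "growth": 0.0})
        rates = []
        for seed in range(10):
            sub = downsample_for_power(stack, seed=seed)
            idx = sub.index.to_numpy()
            det = 0
            for t in genes:
                sl, inter, r, p, se = stats.linregress(s[idx], t[idx])
                det += p < 0.05
            rates.append(det / len(genes))
        assert np.std(rates) < 0.2 and np.mean(rates) > 0.5


def test_stacked_kinship_is_block_diagonal(small_genotypes):
    kin = eq.compute_kinship(small_genotypes)
    ids = list(small_genotypes.segregants[:6])
    stack = pd.DataFrame({
        "segregant": ids + ids[:3],
        "environment": ["a"] * 6 + ["b"] * 3,
        "growth": 0.0,
    })
    sk = stacked_kinship(kin, stack).values.to_numpy()
    assert np.allclose(sk[:6, :6], kin.values.loc[ids, ids].to_numpy())
    assert np.allclose(sk[:6, 6:], 0.0)
    assert np.allclose(np.diag(sk), 1.0)
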