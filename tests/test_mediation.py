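"""Bayesian-network mediation scoring."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import envqtl as eq
from envqtl.mediation import (
    MediationInput,
    fit_model0,
    fit_model1,
    model1_coefficients,
    rank_candidates,
    score_mediation,
    single_env_variant,
)

ENVS = [f"e{i}" for i in range(5)]


def _chain_input(n_per=35, beta_s=1.0, gamma=1.0, t_noise=0.2, g_noise=0.2,
                 seed=0, term_env="e0", n_env=5, gene="gX"):
    """Genotype -> expression -> growth chain in the term's environment."""
    rng = np.random.default_rng(seed)
    envs = ENVS[:n_env]
    env_labels = np.repeat(envs, n_per)
    n = n_per * n_env
    s = rng.integers(0, 2, size=n).astype(float)
    t = beta_s * s + rng.normal(0, t_noise, n)
    g = gamma * t * (env_labels == term_env) + rng.normal(0, g_noise, n)
    return MediationInput(g=g, t=t, s=s, env_labels=env_labels,
                          term=("mk", term_env), covariates=np.empty((n, 0)),
                          gene=gene)


def profile_gaussian_loglik(y, design):
    """Independent closed-form oracle: -(n/2)(log(2 pi RSS / n) + 1)."""
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    rss = float(np.sum((y - design @ coef) ** 2))
    n = len(y)
    return -0.5 * n * (math.log(2.0 * math.pi * rss / n) + 1.0)


class TestModelFits:
    def test_deterministic_chain_recovers_unit_coefficients(self):
        inp = _chain_input(t_noise=1e-6, g_noise=1e-6, seed=1)
        beta_s, gamma = model1_coefficients(inp)
        assert beta_s == pytest.approx(1.0, abs=1e-3)
        assert gamma == pytest.approx(1.0, abs=1e-3)

    def test_loglik_matches_closed_form_oracle(self):
        inp = _chain_input(seed=2)
        onehot = inp.onehot()
        mask = inp.env_mask()
        ll1, k1 = fit_model1(inp)
        oracle1 = (profile_gaussian_loglik(inp.t, np.column_stack([onehot, inp.s]))
                   + profile_gaussian_loglik(
                       inp.g, np.column_stack([onehot, (inp.t * mask)[:, None]])))
        assert ll1 == pytest.approx(oracle1, abs=1e-8)
        ll0, k0 = fit_model0(inp)
        oracle0 = (profile_gaussian_loglik(inp.t, onehot)
                   + profile_gaussian_loglik(
                       inp.g, np.column_stack([onehot, (inp.s * mask)[:, None]])))
        assert ll0 == pytest.approx(oracle0, abs=1e-8)

    def test_parameter_counts_differ_by_exactly_one(self):
        inp = _chain_input(seed=3)
        _, k1 = fit_model1(inp)
        _, k0 = fit_model0(inp)
        assert k1 - k0 == 1

    def test_covariates_absorb_independent_qtl(self):
        # a second, independent growth QTL in the covariate set must not
        # shift the expression->growth estimate by more than 3 s.e.
        rng = np.random.default_rng(4)
        base = _chain_input(seed=4)
        s2 = rng.integers(0, 2, size=len(base.g)).astype(float)
        g2 = base.g + 2.0 * s2 * base.env_mask()
        with_cov = MediationInput(g=g2, t=base.t, s=base.s,
                                  env_labels=base.env_labels, term=base.term,
                                  covariates=(s2 * base.env_mask())[:, None],
                                  gene="gX")
        _, gamma_base = model1_coefficients(base)
        _, gamma_cov = model1_coefficients(with_cov)
        # rough gamma s.e. at this n and noise
        assert abs(gamma_cov - gamma_base) < 3 * 0.1

    def test_constant_expression_rejected_with_flag(self):
        inp = _chain_input(seed=5)
        inp.t[:] = 1.0
        score = score_mediation(inp)
        assert score.flagged and score.posterior == 0.0


class TestScoring:
    def test_posterior_is_symmetric_function_of_bics(self):
        inp = _chain_input(seed=6)
        score = score_mediation(inp)
        assert score.posterior == pytest.approx(
            expit((score.bic0 - score.bic1) / 2.0))
        # complement posterior from swapped BICs sums to one exactly
        comp = float(expit((score.bic1 - score.bic0) / 2.0))
        assert score.posterior + comp == pytest.approx(1.0, abs=1e-15)

    def test_equal_bics_give_half(self):
        assert float(expit(0.0)) == 0.5

    def test_posterior_invariant_to_growth_shift_and_expression_scale(self):
        inp = _chain_input(seed=7)
        p_ref = score_mediation(inp).posterior
        shifted = MediationInput(g=inp.g + 100.0, t=inp.t * 7.0, s=inp.s,
                                 env_labels=inp.env_labels, term=inp.term,
                                 covariates=inp.covariates, gene=inp.gene)
        assert score_mediation(shifted).posterior == pytest.approx(p_ref, abs=1e-9)

    def test_strong_mediator_chain_scores_high(self):
        hits = 0
        for rep in range(100):
            inp = _chain_input(seed=rep + 100)
            hits += score_mediation(inp).posterior > 0.9
        assert hits >= 90

    def test_mediators_outrank_consequence_genes(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(11)
        scores, labels = [], []
        for rep in range(30):
            inp = _chain_input(seed=rep + 300)
            scores.append(score_mediation(inp).posterior)
            labels.append(1)
        for rep in range(30):
            base = _chain_input(seed=rep + 600)
            # pure consequence: expression responds to growth, no genotype link
            t_cons = 0.8 * base.g + rng.normal(0, 0.2, len(base.g))
            cons = MediationInput(g=base.g, t=t_cons, s=base.s,
                                  env_labels=base.env_labels, term=base.term,
                                  covariates=base.covariates, gene="gC")
            scores.append(score_mediation(cons).posterior)
            labels.append(0)
        assert roc_auc_score(labels, scores) >= 0.9

    def test_direction_sign_follows_expression_growth_correlation(self):
        pos = _chain_input(seed=12, gamma=1.0)
        neg = _chain_input(seed=12, gamma=-1.0)
        assert score_mediation(pos).direction == 1
        assert score_mediation(neg).direction == -1


class TestSingleEnvVariant:
    def test_equals_multi_env_when_only_one_environment(self):
        inp = _chain_input(seed=13, n_env=1, term_env="e0")
        a = score_mediation(inp)
        b = single_env_variant(inp)
        assert a.posterior == pytest.approx(b.posterior, abs=1e-12)
        assert a.bic0 == pytest.approx(b.bic0, abs=1e-9)

    def test_uses_only_tested_environment_samples(self):
        inp = _chain_input(seed=14)
        score = single_env_variant(inp)
        # corrupting other environments' data must not change the result
        inp2 = _chain_input(seed=14)
        other = inp2.env_labels != "e0"
        inp2.g[other] = 999.0
        score2 = single_env_variant(inp2)
        assert score.posterior == pytest.approx(score2.posterior, abs=1e-12)

    def test_noisier_than_multi_env_across_replicates(self):
        multi, single = [], []
        for rep in range(50):
            inp = _chain_input(seed=rep + 900, t_noise=0.8, g_noise=0.6)
            multi.append(score_mediation(inp).posterior)
            single.append(single_env_variant(inp).posterior)
        assert np.var(single) > np.var(multi)


class TestRanking:
    def test_strict_ordering_and_tie_break(self):
        scores = [
            eq.MediationScore("gB", ("m", "e0"), 10.0, 8.0, 0.7, 1),
            eq.MediationScore("gA", ("m", "e0"), 10.0, 8.0, 0.7, 1),
            eq.MediationScore("gC", ("m", "e0"), 10.0, 4.0, 0.9, -1),
        ]
        ranked = rank_candidates(scores)
        assert list(ranked["gene"]) == ["gC", "gA", "gB"]
        assert list(ranked["rank"]) == [1, 2, 3]

    def test_input_order_irrelevant(self):
        scores = [eq.MediationScore(f"g{i}", ("m", "e0"), 0.0, 0.0, p, 1)
                  for i, p in enumerate([0.2, 0.9, 0.5, 0.7])]
        a = rank_candidates(scores)
        b = rank_candidates(scores[::-1])
        assert list(a["gene"]) == list(b["gene"])
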