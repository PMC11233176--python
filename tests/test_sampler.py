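"""Guided collapsed-Gibbs core: initialization, conditional, joint, chains.

The deep checks here are oracle-based: the collapsed joint is re-derived
independently through the sequential Polya-urn factorization (product of
predictive probabilities token by token), and the per-token conditional is
compared against renormalized exponentiated joints over single-token
completions.
"""

import math

import numpy as np
import pytest

from gldadec import (
    GibbsState,
    GuideSpec,
    Priors,
    SamplerConfig,
    SyntheticDesign,
    conditional_topic_probs,
    estimate_distributions,
    gibbs_sweep,
    initialize_state,
    log_joint,
    make_pseudo_bulk,
    make_signatures,
    run_chain,
)
from conftest import make_corpus


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def polya_log_joint(token_gene, token_sample, z, K, V, M, alpha, eta):
    """Sequential predictive (Polya urn) evaluation of log p(G, Z | a, e).

    Builds the probability token by token with running counts — an
    evaluation route independent of the gamma-function form.
    """
    alpha = np.broadcast_to(np.asarray(alpha, float), (K,))
    eta = np.broadcast_to(np.asarray(eta, float), (V,))
    n_kv = np.zeros((K, V))
    n_mk = np.zeros((M, K))
    n_k = np.zeros(K)
    n_m = np.zeros(M)
    total = 0.0
    for v, m, k in zip(token_gene, token_sample, z):
        total += math.log((alpha[k] + n_mk[m, k]) / (alpha.sum() + n_m[m]))
        total += math.log((eta[v] + n_kv[k, v]) / (eta.sum() + n_k[k]))
        n_kv[k, v] += 1
        n_mk[m, k] += 1
        n_k[k] += 1
        n_m[m] += 1
    return total


def state_from_tokens(token_gene, token_sample, z, K, V, M):
    token_gene = np.asarray(token_gene, np.int32)
    token_sample = np.asarray(token_sample, np.int32)
    z = np.asarray(z, np.int32)
    n_kv = np.zeros((K, V), np.int64)
    n_mk = np.zeros((M, K), np.int64)
    np.add.at(n_kv, (z, token_gene), 1)
    np.add.at(n_mk, (token_sample, z), 1)
    return GibbsState(
        token_gene=token_gene,
        token_sample=token_sample,
        z=z,
        n_kv=n_kv,
        n_mk=n_mk,
        n_k=n_kv.sum(axis=1),
        n_m=n_mk.sum(axis=1),
        marker_gene=np.zeros(V, bool),
    )


def random_token_state(rng, K, V, M, T):
    tg = rng.integers(0, V, T)
    ts = np.sort(rng.integers(0, M, T))
    z = rng.integers(0, K, T)
    return state_from_tokens(tg, ts, z, K, V, M)


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------


class TestInitialization:
    def test_disjoint_markers_give_block_diagonal_counts(self):
        corpus = make_corpus([[4, 2], [3, 5]], genes=["ma", "mb"])
        guide = GuideSpec(
            K_g=2,
            topic_of_gene={"ma": frozenset({0}), "mb": frozenset({1})},
        )
        state = initialize_state(corpus, guide, Priors(), seed=0)
        np.testing.assert_array_equal(state.n_kv, [[6, 0], [0, 8]])
        state.validate()

    def test_single_topic_takes_everything(self):
        corpus = make_corpus([[3, 1], [2, 2]])
        state = initialize_state(corpus, GuideSpec(K_g=1), Priors(), seed=0)
        np.testing.assert_array_equal(state.n_mk[:, 0], corpus.total_tokens)

    def test_shared_marker_splits_binomially(self):
        corpus = make_corpus([[10_000]], genes=["shared"])
        guide = GuideSpec(K_g=2, topic_of_gene={"shared": frozenset({0, 1})})
        state = initialize_state(corpus, guide, Priors(), seed=7)
        # Binomial(10000, 1/2): 3 sigma = 150
        assert abs(state.n_k[0] - 5000) < 150
        assert state.n_k.sum() == 10_000

    def test_nonmarker_tokens_spread_over_all_topics(self):
        corpus = make_corpus([[9000]])
        state = initialize_state(corpus, GuideSpec(K_g=3), Priors(), seed=1)
        assert (state.n_k > 2700).all()  # ~3000 each, 3 sigma ~ 135


# ---------------------------------------------------------------------------
# Conditional vs exact joint
# ---------------------------------------------------------------------------


class TestConditional:
    def test_single_topic(self):
        state = state_from_tokens([0, 1], [0, 0], [0, 0], K=1, V=2, M=1)
        state.n_kv[0, 0] -= 1
        state.n_k[0] -= 1
        state.n_mk[0, 0] -= 1
        state.n_m[0] -= 1
        np.testing.assert_allclose(
            conditional_topic_probs(state, 0, 0, Priors()), [1.0]
        )

    def test_symmetric_counts_give_uniform(self):
        state = state_from_tokens(
            [0, 0, 1, 1], [0, 0, 0, 0], [0, 1, 0, 1], K=2, V=2, M=1
        )
        probs = conditional_topic_probs(state, 0, 0, Priors(alpha=0.3, eta=0.3))
        np.testing.assert_allclose(probs, [0.5, 0.5])

    def test_hand_worked_two_topic_case(self):
        # decremented tables seen by the held-out token: n_kv[:,v]=[2,0],
        # n_k=[4,1], n_mk[0,:]=[3,1], n_m[0]=4 (a second sample holds the
        # remaining token so the tables are jointly consistent)
        state = state_from_tokens(
            [0, 0, 1, 2, 1], [0, 0, 0, 0, 1], [0, 0, 0, 1, 0], K=2, V=3, M=2
        )
        probs = conditional_topic_probs(state, 0, 0, Priors(alpha=0.1, eta=0.1))
        k0 = (2.1 / 4.3) * (3.1 / 4.2)
        k1 = (0.1 / 1.3) * (1.1 / 4.2)
        np.testing.assert_allclose(probs, [k0 / (k0 + k1), k1 / (k0 + k1)])
        np.testing.assert_allclose(probs, [0.947, 0.053], atol=5e-4)

    def test_negative_decrement_trips_bug_trap(self):
        state = state_from_tokens([0], [0], [0], K=2, V=1, M=1)
        state.n_kv[0, 0] -= 2
        with pytest.raises(RuntimeError, match="negative"):
            conditional_topic_probs(state, 0, 0, Priors())

    @pytest.mark.parametrize("K,V", [(1, 2), (2, 2), (2, 4), (3, 3)])
    def test_matches_renormalized_joint_over_completions(self, K, V):
        rng = np.random.default_rng(K * 10 + V)
        for _ in range(10):
            M = int(rng.integers(1, 3))
            T = int(rng.integers(1, 9))
            state = random_token_state(rng, K, V, M, T)
            alpha = rng.uniform(0.05, 2.0, K)
            eta = rng.uniform(0.05, 2.0, V)
            priors = Priors(alpha=alpha, eta=eta)
            for t in range(T):
                v, m, k_cur = (
                    int(state.token_gene[t]),
                    int(state.token_sample[t]),
                    int(state.z[t]),
                )
                state.n_kv[k_cur, v] -= 1
                state.n_mk[m, k_cur] -= 1
                state.n_k[k_cur] -= 1
                state.n_m[m] -= 1
                probs = conditional_topic_probs(state, m, v, priors)
                logps = []
                for k in range(K):
                    z_try = state.z.copy()
                    z_try[t] = k
                    logps.append(
                        polya_log_joint(
                            state.token_gene,
                            state.token_sample,
                            z_try,
                            K,
                            V,
                            M,
                            alpha,
                            eta,
                        )
                    )
                expect = np.exp(np.array(logps) - max(logps))
                expect /= expect.sum()
                np.testing.assert_allclose(probs, expect, atol=1e-10)
                state.n_kv[k_cur, v] += 1
                state.n_mk[m, k_cur] += 1
                state.n_k[k_cur] += 1
                state.n_m[m] += 1


# ---------------------------------------------------------------------------
# Joint log-likelihood
# ---------------------------------------------------------------------------


class TestLogJoint:
    def test_forced_single_outcome_is_zero(self):
        state = state_from_tokens([0], [0], [0], K=1, V=1, M=1)
        assert log_joint(state, Priors(alpha=1.0, eta=1.0)) == 0.0

    def test_topic_label_permutation_invariance(self):
        rng = np.random.default_rng(5)
        state = random_token_state(rng, K=3, V=4, M=2, T=20)
        priors = Priors(alpha=0.2, eta=0.4)
        base = log_joint(state, priors)
        perm = np.array([2, 0, 1])
        permuted = state_from_tokens(
            state.token_gene, state.token_sample, perm[state.z], K=3, V=4, M=2
        )
        assert log_joint(permuted, priors) == pytest.approx(base, abs=1e-10)

    def test_matches_polya_urn_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            K, V, M = rng.integers(1, 4), rng.integers(1, 5), rng.integers(1, 3)
            T = int(rng.integers(1, 12))
            state = random_token_state(rng, K, V, M, T)
            alpha = rng.uniform(0.05, 3.0, K)
            eta = rng.uniform(0.05, 3.0, V)
            expect = polya_log_joint(
                state.token_gene, state.token_sample, state.z, K, V, M, alpha, eta
            )
            got = log_joint(state, Priors(alpha=alpha, eta=eta))
            assert got == pytest.approx(expect, abs=1e-9)

    def test_rejects_nonpositive_priors(self):
        state = state_from_tokens([0], [0], [0], K=1, V=1, M=1)
        with pytest.raises(ValueError):
            log_joint(state, Priors(alpha=0.0, eta=1.0))


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------


class TestSweeps:
    def test_pinned_markers_freeze_the_state(self):
        corpus = make_corpus([[5, 3], [2, 6]], genes=["ma", "mb"])
        guide = GuideSpec(
            K_g=2,
            topic_of_gene={"ma": frozenset({0}), "mb": frozenset({1})},
            refresh_prob=0.0,
        )
        state = initialize_state(corpus, guide, Priors(), seed=0)
        z0 = state.z.copy()
        rng = np.random.default_rng(1)
        for _ in range(20):
            gibbs_sweep(state, guide, Priors(), rng)
        np.testing.assert_array_equal(state.z, z0)

    def test_count_conservation_and_consistency(self):
        rng = np.random.default_rng(0)
        corpus = make_corpus(rng.integers(0, 30, size=(12, 4)) + 1)
        guide = GuideSpec(K_g=3, K_u=1)
        state = initialize_state(corpus, guide, Priors(), seed=3)
        n_m = state.n_m.copy()
        sweep_rng = np.random.default_rng(9)
        for _ in range(10):
            gibbs_sweep(state, guide, Priors(), sweep_rng)
            np.testing.assert_array_equal(state.n_mk.sum(axis=1), n_m)
            state.validate()

    def test_numba_and_python_paths_identical(self):
        rng = np.random.default_rng(0)
        corpus = make_corpus(rng.integers(0, 20, size=(8, 3)) + 1)
        guide = GuideSpec(K_g=2, K_u=1, refresh_prob=0.5)
        priors = Priors()
        s1 = initialize_state(corpus, guide, priors, seed=4)
        s2 = s1.copy()
        r1, r2 = np.random.default_rng(7), np.random.default_rng(7)
        for _ in range(5):
            gibbs_sweep(s1, guide, priors, r1, use_numba=True)
            gibbs_sweep(s2, guide, priors, r2, use_numba=False)
        np.testing.assert_array_equal(s1.z, s2.z)
        np.testing.assert_array_equal(s1.n_kv, s2.n_kv)

    def test_free_token_samples_from_its_conditional(self):
        # two pinned marker genes anchor the counts; one free token is then
        # re-drawn i.i.d. from a fixed conditional every sweep
        corpus = make_corpus([[3], [2], [1]], genes=["ma", "mb", "free"])
        guide = GuideSpec(
            K_g=2,
            topic_of_gene={"ma": frozenset({0}), "mb": frozenset({1})},
            refresh_prob=0.0,
        )
        priors = Priors(alpha=0.5, eta=0.5)
        state = initialize_state(corpus, guide, priors, seed=0)
        t_free = int(np.where(state.token_gene == 2)[0][0])
        k_cur = int(state.z[t_free])
        state.n_kv[k_cur, 2] -= 1
        state.n_mk[0, k_cur] -= 1
        state.n_k[k_cur] -= 1
        state.n_m[0] -= 1
        expected = conditional_topic_probs(state, 0, 2, priors)
        state.n_kv[k_cur, 2] += 1
        state.n_mk[0, k_cur] += 1
        state.n_k[k_cur] += 1
        state.n_m[0] += 1

        n_draws = 20_000
        rng = np.random.default_rng(11)
        hits = np.zeros(2)
        for _ in range(n_draws):
            gibbs_sweep(state, guide, priors, rng)
            hits[state.z[t_free]] += 1
        freq = hits / n_draws
        se = np.sqrt(expected * (1 - expected) / n_draws)
        assert np.all(np.abs(freq - expected) < 3 * se + 1e-12)

    def test_chain_reaches_exact_stationary_distribution(self):
        # 2 free tokens, K=2: all 4 ordered assignments enumerable; long-run
        # visit frequencies must match exp(log joint) renormalized
        corpus = make_corpus([[1], [1]])
        guide = GuideSpec(K_g=2)
        priors = Priors(alpha=0.7, eta=0.4)
        state = initialize_state(corpus, guide, priors, seed=0)
        weights = {}
        for z0 in (0, 1):
            for z1 in (0, 1):
                s = state_from_tokens([0, 1], [0, 0], [z0, z1], K=2, V=2, M=1)
                weights[(z0, z1)] = math.exp(log_joint(s, priors))
        total = sum(weights.values())
        expected = {kk: w / total for kk, w in weights.items()}

        rng = np.random.default_rng(3)
        counts = {kk: 0 for kk in expected}
        n_sweeps = 40_000
        for _ in range(n_sweeps):
            gibbs_sweep(state, guide, priors, rng)
            counts[(int(state.z[0]), int(state.z[1]))] += 1
        for kk in expected:
            assert counts[kk] / n_sweeps == pytest.approx(expected[kk], abs=0.02)


# ---------------------------------------------------------------------------
# Posterior means and full chains
# ---------------------------------------------------------------------------


class TestEstimates:
    def test_single_topic_theta_is_one(self):
        state = state_from_tokens([0, 1], [0, 0], [0, 0], K=1, V=2, M=1)
        theta, _ = estimate_distributions(state, Priors())
        np.testing.assert_allclose(theta, [[1.0]])

    def test_empty_topic_phi_is_prior_uniform(self):
        state = state_from_tokens([0, 1], [0, 0], [0, 0], K=2, V=2, M=1)
        _, phi = estimate_distributions(state, Priors(eta=0.3))
        np.testing.assert_allclose(phi[1], [0.5, 0.5])

    def test_smoothed_count_arithmetic(self):
        state = state_from_tokens([0, 0, 0, 1], [0, 0, 0, 0], [0, 0, 0, 1], K=2, V=2, M=1)
        theta, _ = estimate_distributions(state, Priors(alpha=0.1))
        np.testing.assert_allclose(theta[0], [3.1 / 4.2, 1.1 / 4.2])

    def test_rows_stochastic(self):
        rng = np.random.default_rng(2)
        state = random_token_state(rng, K=3, V=5, M=4, T=60)
        theta, phi = estimate_distributions(state, Priors())
        np.testing.assert_allclose(theta.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(phi.sum(axis=1), 1.0, atol=1e-9)


class TestRunChain:
    def test_single_topic_theta_all_ones(self):
        corpus = make_corpus([[4, 2], [1, 3]])
        res = run_chain(corpus, GuideSpec(K_g=1), Priors(), SamplerConfig(n_iter=5, burn_in=1), seed=0)
        np.testing.assert_allclose(res.theta, 1.0)

    def test_bitwise_determinism(self):
        rng = np.random.default_rng(1)
        corpus = make_corpus(rng.integers(1, 20, size=(10, 3)))
        guide = GuideSpec(K_g=2, K_u=1)
        cfg = SamplerConfig(n_iter=20, burn_in=5)
        r1 = run_chain(corpus, guide, Priors(), cfg, seed=13)
        r2 = run_chain(corpus, guide, Priors(), cfg, seed=13)
        assert np.array_equal(r1.theta, r2.theta)
        assert r1.loglik_trace == r2.loglik_trace

    def test_pinned_marker_theta_closed_form(self):
        counts = np.array([[6, 1], [3, 5], [1, 8]])
        corpus = make_corpus(counts, genes=["ma", "mb", "mc"])
        guide = GuideSpec(
            K_g=3,
            topic_of_gene={
                "ma": frozenset({0}),
                "mb": frozenset({1}),
                "mc": frozenset({2}),
            },
            refresh_prob=0.0,
        )
        alpha = 0.01
        res = run_chain(corpus, guide, Priors(alpha=alpha), SamplerConfig(n_iter=10, burn_in=2), seed=0)
        expect = (counts.T + alpha) / (counts.sum(axis=0)[:, None] + 3 * alpha)
        np.testing.assert_allclose(res.theta, expect, atol=1e-12)

    def test_topic_labels_order(self):
        corpus = make_corpus([[2], [3]], genes=["ma", "mb"])
        guide = GuideSpec(
            K_g=1,
            K_u=2,
            topic_of_gene={"ma": frozenset({0})},
            topic_names=["B_cells"],
        )
        res = run_chain(corpus, guide, Priors(), SamplerConfig(n_iter=3, burn_in=1), seed=0)
        assert res.topic_labels == ["B_cells", "additional_1", "additional_2"]

    def test_loglik_improves_on_separable_mixtures(self):
        design = SyntheticDesign(L=100, markers_per_type=5, depth=1000, seed=2)
        signatures, guide = make_signatures(design)
        expr, _ = make_pseudo_bulk(signatures, 10, design)
        from gldadec import build_corpus

        corpus, _ = build_corpus(expr, guide, topn=20)
        gs = GuideSpec.from_marker_guide(guide)
        improved = 0
        n_runs = 40
        for seed in range(n_runs):
            res = run_chain(corpus, gs, Priors(), SamplerConfig(n_iter=60, burn_in=30), seed=seed)
            improved += res.loglik_trace[-1][1] > res.loglik_trace[0][1]
        assert improved >= 0.95 * n_runs
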