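"""Guided collapsed-Gibbs LDA core for bulk deconvolution.

Each bulk sample is a bag of gene tokens generated by a mixture of K topics
(cell types): per-sample topic weights theta_m ~ Dir(alpha) and per-topic
gene distributions phi_k ~ Dir(eta). With theta and phi integrated out, a
token for gene v in sample m is re-assigned to topic k with probability

    p(k) ∝ (n_kv + eta_v) / (n_k + sum(eta)) * (n_mk + alpha_k) / (n_m + sum(alpha))

where the count tables exclude the token itself. Guidance enters in two
places: at initialization every token of a marker gene is assigned to its
cell type's topic, and during sweeps marker tokens are only re-sampled with
probability ``refresh_prob`` (0 pins them forever). The sample-topic
posterior means are the estimated cell-type proportions.

Convergence is monitored through the collapsed joint log-likelihood

    log p(G, Z | alpha, eta) =
        sum_k [ lgamma(sum eta) - lgamma(n_k + sum eta)
                + sum_v (lgamma(n_kv + eta_v) - lgamma(eta_v)) ]
      + sum_m [ lgamma(sum alpha) - lgamma(n_m + sum alpha)
                + sum_k (lgamma(n_mk + alpha_k) - lgamma(alpha_k)) ].

The per-sweep inner loop is JIT-compiled with numba when available; a
NumPy/Python fallback consumes the identical pre-drawn uniform streams, so
trajectories are bit-identical across the two paths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln

from .preprocessing import CountCorpus, MarkerGuide

logger = logging.getLogger("gldadec")

__all__ = [
    "Priors",
    "GuideSpec",
    "GibbsState",
    "SamplerConfig",
    "DeconvolutionResult",
    "initialize_state",
    "conditional_topic_probs",
    "gibbs_sweep",
    "log_joint",
    "estimate_distributions",
    "run_chain",
]

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(f):
            return f

        return wrap if not args or not callable(args[0]) else args[0]


# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------


@dataclass
class Priors:
    """Dirichlet hyperparameters; scalars mean symmetric priors.

    Small values (default 0.01) encode the expectation that mixtures are
    sparse: a sample contains few cell types and a topic loads few genes.
    """

    alpha: float | np.ndarray = 0.01
    eta: float | np.ndarray = 0.01

    def expand(self, K: int, V: int) -> tuple[np.ndarray, np.ndarray]:
        alpha = np.broadcast_to(np.asarray(self.alpha, dtype=float), (K,)).copy()
        eta = np.broadcast_to(np.asarray(self.eta, dtype=float), (V,)).copy()
        if np.any(alpha <= 0) or np.any(eta <= 0):
            raise ValueError("Dirichlet hyperparameters must be positive")
        return alpha, eta


@dataclass
class GuideSpec:
    """Topic layout: K_g guided (marker-anchored) + K_u unguided topics.

    ``topic_of_gene`` maps a gene name to the guided topic indices whose
    marker set contains it. ``refresh_prob`` is the per-sweep probability
    that a marker token's assignment is re-sampled (0 = pinned forever).
    """

    K_g: int
    K_u: int = 0
    topic_of_gene: Mapping[str, frozenset[int]] = field(default_factory=dict)
    refresh_prob: float = 0.01
    topic_names: list[str] | None = None

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("need at least one topic (K_g + K_u >= 1)")
        if self.K_g < 0 or self.K_u < 0:
            raise ValueError("topic counts must be non-negative")
        if not 0.0 <= self.refresh_prob <= 1.0:
            raise ValueError("refresh_prob must be in [0, 1]")
        for g, topics in self.topic_of_gene.items():
            if any(t < 0 or t >= self.K_g for t in topics):
                raise ValueError(f"marker gene {g!r} mapped to a non-guided topic")

    @property
    def K(self) -> int:
        return self.K_g + self.K_u

    @classmethod
    def from_marker_guide(
        cls,
        guide: MarkerGuide,
        K_u: int = 0,
        refresh_prob: float = 0.01,
    ) -> "GuideSpec":
        mapping: dict[str, set[int]] = {}
        for k, markers in enumerate(guide.marker_sets):
            for g in markers:
                mapping.setdefault(g.strip().casefold(), set()).add(k)
        return cls(
            K_g=guide.n_topics,
            K_u=K_u,
            topic_of_gene={g: frozenset(t) for g, t in mapping.items()},
            refresh_prob=refresh_prob,
            topic_names=list(guide.topic_names),
        )

    def labels(self) -> list[str]:
        guided = (
            list(self.topic_names)
            if self.topic_names is not None
            else [f"topic_{k}" for k in range(self.K_g)]
        )
        return guided + [f"additional_{i + 1}" for i in range(self.K_u)]


@dataclass
class SamplerConfig:
    """Chain-length and recording choices for a single Gibbs run."""

    n_iter: int = 200
    burn_in: int = 100
    loglik_every: int = 10
    avg_window: int = 1

    def __post_init__(self) -> None:
        if not self.n_iter > self.burn_in >= 0:
            raise ValueError("need n_iter > burn_in >= 0")
        if self.loglik_every < 1 or self.avg_window < 1:
            raise ValueError("loglik_every and avg_window must be >= 1")


# ---------------------------------------------------------------------------
# State
# ---------------------------------------------------------------------------


@dataclass
class GibbsState:
    """Token topic assignments plus the sufficient-statistic count tables.

    Tokens are stored flat in the fixed visitation order (sample-major,
    gene-major within sample); ``z[t]`` is token t's topic.
    """

    token_gene: np.ndarray  # (T,) int32 gene index
    token_sample: np.ndarray  # (T,) int32 sample index
    z: np.ndarray  # (T,) int32 topic assignment
    n_kv: np.ndarray  # (K, V) int64
    n_mk: np.ndarray  # (M, K) int64
    n_k: np.ndarray  # (K,) int64
    n_m: np.ndarray  # (M,) int64
    marker_gene: np.ndarray  # (V,) bool — is this gene a marker of some topic
    rng_seed: int | None = None

    @property
    def K(self) -> int:
        return self.n_kv.shape[0]

    @property
    def V(self) -> int:
        return self.n_kv.shape[1]

    @property
    def M(self) -> int:
        return self.n_mk.shape[0]

    def validate(self) -> None:
        """Internal-consistency trap: tables must agree with Z exactly."""
        K, V, M = self.K, self.V, self.M
        n_kv = np.zeros((K, V), dtype=np.int64)
        n_mk = np.zeros((M, K), dtype=np.int64)
        np.add.at(n_kv, (self.z, self.token_gene), 1)
        np.add.at(n_mk, (self.token_sample, self.z), 1)
        if not (
            np.array_equal(n_kv, self.n_kv)
            and np.array_equal(n_mk, self.n_mk)
            and np.array_equal(n_kv.sum(axis=1), self.n_k)
            and np.array_equal(n_mk.sum(axis=1), self.n_m)
        ):
            raise RuntimeError("Gibbs state count tables inconsistent with Z")
        if np.any(self.n_kv < 0) or np.any(self.n_mk < 0):
            raise RuntimeError("negative counts in Gibbs state")

    def copy(self) -> "GibbsState":
        return GibbsState(
            token_gene=self.token_gene.copy(),
            token_sample=self.token_sample.copy(),
            z=self.z.copy(),
            n_kv=self.n_kv.copy(),
            n_mk=self.n_mk.copy(),
            n_k=self.n_k.copy(),
            n_m=self.n_m.copy(),
            marker_gene=self.marker_gene.copy(),
            rng_seed=self.rng_seed,
        )


@dataclass
class DeconvolutionResult:
    """Outputs of one chain: theta (M×K), phi (K×V), trace, labels."""

    theta: np.ndarray
    phi: np.ndarray
    loglik_trace: list[tuple[int, float]]
    topic_labels: list[str]
    sample_ids: list[str]
    gene_ids: list[str]
    config: dict

    def theta_frame(self):
        import pandas as pd

        return pd.DataFrame(self.theta, index=self.sample_ids, columns=self.topic_labels)

    def phi_frame(self):
        import pandas as pd

        return pd.DataFrame(self.phi, index=self.topic_labels, columns=self.gene_ids)


# ---------------------------------------------------------------------------
# Initialization (guided seeding)
# ---------------------------------------------------------------------------


def initialize_state(
    corpus: CountCorpus,
    guide: GuideSpec,
    priors: Priors,
    seed: int | np.random.Generator,
) -> GibbsState:
    """Seed token assignments: marker tokens go to their guided topic(s).

    A gene in several marker sets splits its tokens uniformly at random
    among its topics; non-marker tokens start uniformly over all K topics.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    K = guide.K
    V, M = corpus.n_genes, corpus.n_samples
    priors.expand(K, V)  # validates positivity

    # per-gene allowed initial topics
    norm_names = [g.strip().casefold() for g in corpus.gene_ids]
    allowed: list[np.ndarray] = []
    marker_gene = np.zeros(V, dtype=bool)
    for v, g in enumerate(norm_names):
        topics = guide.topic_of_gene.get(g)
        if topics:
            allowed.append(np.array(sorted(topics), dtype=np.int32))
            marker_gene[v] = True
        else:
            allowed.append(np.arange(K, dtype=np.int32))

    counts = corpus.counts  # (V, M)
    T = int(counts.sum())
    token_gene = np.empty(T, dtype=np.int32)
    token_sample = np.empty(T, dtype=np.int32)
    pos = 0
    for m in range(M):
        col = counts[:, m]
        reps = np.repeat(np.arange(V, dtype=np.int32), col)
        n = reps.shape[0]
        token_gene[pos : pos + n] = reps
        token_sample[pos : pos + n] = m
        pos += n

    u = rng.random(T)
    n_allowed = np.array([a.shape[0] for a in allowed], dtype=np.int64)
    choice_idx = np.minimum(
        (u * n_allowed[token_gene]).astype(np.int64), n_allowed[token_gene] - 1
    )
    # gather: z[t] = allowed[gene[t]][choice_idx[t]]
    allowed_flat = np.concatenate(allowed)
    offsets = np.concatenate([[0], np.cumsum(n_allowed)[:-1]])
    z = allowed_flat[offsets[token_gene] + choice_idx].astype(np.int32)

    n_kv = np.zeros((K, V), dtype=np.int64)
    n_mk = np.zeros((M, K), dtype=np.int64)
    np.add.at(n_kv, (z, token_gene), 1)
    np.add.at(n_mk, (token_sample, z), 1)
    state = GibbsState(
        token_gene=token_gene,
        token_sample=token_sample,
        z=z,
        n_kv=n_kv,
        n_mk=n_mk,
        n_k=n_kv.sum(axis=1),
        n_m=n_mk.sum(axis=1),
        marker_gene=marker_gene,
        rng_seed=None if isinstance(seed, np.random.Generator) else int(seed),
    )
    if not np.array_equal(state.n_m, corpus.total_tokens):
        raise RuntimeError("token expansion lost counts")
    return state


# ---------------------------------------------------------------------------
# Per-token conditional and sweeps
# ---------------------------------------------------------------------------


def conditional_topic_probs(
    state: GibbsState,
    m: int,
    v: int,
    priors: Priors,
) -> np.ndarray:
    """Collapsed conditional p(Z = k | everything else) for one held-out token.

    The count tables in ``state`` must already exclude the token (the
    ``\\m,n`` convention); a negative decremented count is a bug trap.
    """
    alpha, eta = priors.expand(state.K, state.V)
    if np.any(state.n_kv[:, v] < 0) or np.any(state.n_mk[m, :] < 0):
        raise RuntimeError("negative decremented count: token not removed correctly")
    word_part = (state.n_kv[:, v] + eta[v]) / (state.n_k + eta.sum())
    doc_part = (state.n_mk[m, :] + alpha) / (state.n_m[m] + alpha.sum())
    p = word_part * doc_part
    return p / p.sum()


@njit(cache=False)
def _sweep_kernel(
    token_gene,
    token_sample,
    z,
    marker_gene,
    refresh_prob,
    refresh_u,
    u,
    n_kv,
    n_mk,
    n_k,
    alpha,
    eta,
    eta_sum,
):  # pragma: no cover - numba-compiled; logic mirrored by _sweep_python
    K = n_kv.shape[0]
    p = np.empty(K)
    for t in range(token_gene.shape[0]):
        v = token_gene[t]
        m = token_sample[t]
        k = z[t]
        if marker_gene[v] and refresh_u[t] >= refresh_prob:
            continue
        n_kv[k, v] -= 1
        n_mk[m, k] -= 1
        n_k[k] -= 1
        tot = 0.0
        for kk in range(K):
            val = (
                (n_kv[kk, v] + eta[v])
                / (n_k[kk] + eta_sum)
                * (n_mk[m, kk] + alpha[kk])
            )
            p[kk] = val
            tot += val
        r = u[t] * tot
        acc = 0.0
        knew = K - 1
        for kk in range(K):
            acc += p[kk]
            if r < acc:
                knew = kk
                break
        z[t] = knew
        n_kv[knew, v] += 1
        n_mk[m, knew] += 1
        n_k[knew] += 1


def _sweep_python(
    token_gene,
    token_sample,
    z,
    marker_gene,
    refresh_prob,
    refresh_u,
    u,
    n_kv,
    n_mk,
    n_k,
    alpha,
    eta,
    eta_sum,
):
    """Reference implementation of one sweep; same semantics as the kernel."""
    K = n_kv.shape[0]
    for t in range(token_gene.shape[0]):
        v = token_gene[t]
        m = token_sample[t]
        k = z[t]
        if marker_gene[v] and refresh_u[t] >= refresh_prob:
            continue
        n_kv[k, v] -= 1
        n_mk[m, k] -= 1
        n_k[k] -= 1
        p = (n_kv[:, v] + eta[v]) / (n_k + eta_sum) * (n_mk[m, :] + alpha)
        r = u[t] * p.sum()
        knew = int(np.searchsorted(np.cumsum(p), r, side="right"))
        if knew >= K:
            knew = K - 1
        z[t] = knew
        n_kv[knew, v] += 1
        n_mk[m, knew] += 1
        n_k[knew] += 1


def gibbs_sweep(
    state: GibbsState,
    guide: GuideSpec,
    priors: Priors,
    rng: np.random.Generator,
    use_numba: bool = True,
) -> GibbsState:
    """One full pass over all tokens, in place; returns the same state.

    Non-marker tokens are always re-sampled from the collapsed conditional;
    marker tokens only when their refresh draw falls below ``refresh_prob``.
    Visitation order is fixed (sample-major, gene-major), so a trajectory is
    fully determined by the seed.
    """
    alpha, eta = priors.expand(state.K, state.V)
    T = state.z.shape[0]
    refresh_u = rng.random(T)
    u = rng.random(T)
    fn = _sweep_kernel if (_HAVE_NUMBA and use_numba) else _sweep_python
    fn(
        state.token_gene,
        state.token_sample,
        state.z,
        state.marker_gene,
        float(guide.refresh_prob),
        refresh_u,
        u,
        state.n_kv,
        state.n_mk,
        state.n_k,
        alpha,
        eta,
        float(eta.sum()),
    )
    return state


# ---------------------------------------------------------------------------
# Collapsed joint log-likelihood and posterior means
# ---------------------------------------------------------------------------


def log_joint(state: GibbsState, priors: Priors) -> float:
    """log p(G, Z | alpha, eta) with theta and phi integrated out."""
    alpha, eta = priors.expand(state.K, state.V)
    eta_sum = eta.sum()
    alpha_sum = alpha.sum()
    topic_term = (
        state.K * gammaln(eta_sum)
        - gammaln(state.n_k + eta_sum).sum()
        + gammaln(state.n_kv + eta[None, :]).sum()
        - state.K * gammaln(eta).sum()
    )
    doc_term = (
        state.M * gammaln(alpha_sum)
        - gammaln(state.n_m + alpha_sum).sum()
        + gammaln(state.n_mk + alpha[None, :]).sum()
        - state.M * gammaln(alpha).sum()
    )
    value = float(topic_term + doc_term)
    if not np.isfinite(value):
        raise RuntimeError("non-finite log joint")
    return value


def estimate_distributions(
    state: GibbsState, priors: Priors
) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed-count posterior means: theta (M×K) and phi (K×V)."""
    alpha, eta = priors.expand(state.K, state.V)
    theta = (state.n_mk + alpha[None, :]) / (state.n_m + alpha.sum())[:, None]
    phi = (state.n_kv + eta[None, :]) / (state.n_k + eta.sum())[:, None]
    return theta, phi


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------


def run_chain(
    corpus: CountCorpus,
    guide: GuideSpec,
    priors: Priors,
    config: SamplerConfig | None = None,
    seed: int = 0,
    use_numba: bool = True,
) -> DeconvolutionResult:
    """Run one guided Gibbs chain and return posterior-mean estimates.

    The joint log-likelihood is recorded after the first sweep and then at
    every ``loglik_every``-th sweep. theta/phi are the smoothed-count
    posterior means of the final state, or the average over the last
    ``avg_window`` recorded post-burn-in states when ``avg_window`` > 1.
    """
    config = config or SamplerConfig()
    rng = np.random.default_rng(seed)
    state = initialize_state(corpus, guide, priors, rng)
    state.rng_seed = int(seed)

    trace: list[tuple[int, float]] = []
    snapshots: list[tuple[np.ndarray, np.ndarray]] = []
    for s in range(1, config.n_iter + 1):
        gibbs_sweep(state, guide, priors, rng, use_numba=use_numba)
        if s == 1 or s % config.loglik_every == 0:
            ll = log_joint(state, priors)
            trace.append((s, ll))
            logger.debug("seed=%s sweep=%d log_joint=%.4f", seed, s, ll)
            if config.avg_window > 1 and s > config.burn_in:
                snapshots.append(estimate_distributions(state, priors))
                snapshots = snapshots[-config.avg_window :]

    if config.avg_window > 1:
        final = estimate_distributions(state, priors)
        if not snapshots or trace[-1][0] != config.n_iter:
            snapshots.append(final)
            snapshots = snapshots[-config.avg_window :]
        theta = np.mean([t for t, _ in snapshots], axis=0)
        phi = np.mean([p for _, p in snapshots], axis=0)
    else:
        theta, phi = estimate_distributions(state, priors)

    return DeconvolutionResult(
        theta=theta,
        phi=phi,
        loglik_trace=trace,
        topic_labels=guide.labels(),
        sample_ids=list(corpus.sample_ids),
        gene_ids=list(corpus.gene_ids),
        config={
            "seed": int(seed),
            "K_g": guide.K_g,
            "K_u": guide.K_u,
            "refresh_prob": guide.refresh_prob,
            "alpha": np.asarray(priors.alpha).tolist(),
            "eta": np.asarray(priors.eta).tolist(),
            "n_iter": config.n_iter,
            "burn_in": config.burn_in,
            "loglik_every": config.loglik_every,
            "avg_window": config.avg_window,
        },
    )
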