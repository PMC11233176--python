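"""Choosing the number of additional (unguided) topics K_u.

Tissue samples contain cell types and confounders beyond the guided cell
types; unguided topics absorb them. Too many unguided topics, however, start
duplicating signal that other topics already carry. The selection rule is a
recursive redundancy test on the NON-marker gene contributions phi': fit the
model with K_u added topics, pool the top floor(L'/K) contributing non-marker
genes of each added topic, and correlate each added topic's contribution
profile over the pooled genes against every topic's profile (a K_u × K
Pearson matrix P). A significantly positive off-self correlation means the
added topics are redundant; K_u is grown from 1 until redundancy appears and
the last non-redundant value is kept.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .ensemble import run_ensemble
from .preprocessing import CountCorpus
from .sampler import GuideSpec, Priors, SamplerConfig

logger = logging.getLogger("gldadec")

__all__ = [
    "RedundancyReport",
    "pool_top_contrib_genes",
    "redundancy_matrix",
    "select_num_additional",
]


@dataclass
class RedundancyReport:
    K_u_tested: int
    pooled_genes: list[str]
    P: np.ndarray  # (K_u, K) Pearson correlations
    redundant: bool
    offending_pairs: list[tuple[int, int, float, float]] = field(default_factory=list)
    # entries: (added topic index 0-based, other topic index in 0..K-1, r, p)

    def to_dict(self) -> dict:
        return {
            "K_u_tested": self.K_u_tested,
            "n_pooled_genes": len(self.pooled_genes),
            "pooled_genes": self.pooled_genes,
            "P": np.where(np.isnan(self.P), None, self.P).tolist(),
            "redundant": self.redundant,
            "offending_pairs": [
                {"added_topic": i, "other_topic": j, "r": r, "p": p}
                for i, j, r, p in self.offending_pairs
            ],
        }


def pool_top_contrib_genes(
    phi_added: np.ndarray,
    genes: Sequence[str],
    K: int,
) -> list[str]:
    """Union of each added topic's top floor(L'/K) non-marker genes.

    ``phi_added`` holds the added-topic contribution rows over the L'
    non-marker genes; ``K`` is the TOTAL topic count (guided + added), which
    sets the per-topic quota. Ties break by gene name; output order is
    deterministic (sorted).
    """
    phi_added = np.atleast_2d(np.asarray(phi_added, dtype=float))
    L = phi_added.shape[1]
    if L != len(genes):
        raise ValueError("phi_added columns must match gene list")
    if K < 1:
        raise ValueError("K must be >= 1")
    quota = L // K
    if quota < 1:
        raise ValueError(f"too few non-marker genes (L'={L} < K={K})")
    pool: set[str] = set()
    names = np.asarray(genes, dtype=object)
    for row in phi_added:
        order = np.lexsort((names, -row))  # contribution desc, name asc on ties
        pool.update(names[order[:quota]].tolist())
    return sorted(pool)


def redundancy_matrix(
    phi_full: np.ndarray,
    genes: Sequence[str],
    pooled: Sequence[str],
    K_u: int,
    alpha: float = 0.05,
) -> RedundancyReport:
    """Pearson matrix of added-topic vs all-topic profiles over pooled genes.

    The added topics are the last ``K_u`` rows of ``phi_full`` (K × L' over
    non-marker genes). Redundancy: any pair other than an added topic with
    itself whose one-sided (positive) correlation p-value is below ``alpha``.
    A constant profile makes r undefined; such pairs are logged and treated
    as non-redundant.
    """
    phi_full = np.asarray(phi_full, dtype=float)
    K = phi_full.shape[0]
    if not 1 <= K_u <= K:
        raise ValueError("need 1 <= K_u <= K")
    idx = {g: i for i, g in enumerate(genes)}
    missing = [g for g in pooled if g not in idx]
    if missing:
        raise ValueError(f"pooled genes absent from phi columns: {missing[:5]}")
    cols = [idx[g] for g in pooled]
    if len(cols) < 3:
        raise ValueError("need at least 3 pooled genes for a correlation test")
    sub = phi_full[:, cols]
    K_g = K - K_u
    P = np.full((K_u, K), np.nan)
    redundant = False
    offending: list[tuple[int, int, float, float]] = []
    for i in range(K_u):
        x = sub[K_g + i]
        for j in range(K):
            if j == K_g + i:
                P[i, j] = 1.0  # self-pair, excluded from the decision
                continue
            y = sub[j]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                logger.warning(
                    "constant contribution profile (added %d vs topic %d); "
                    "correlation undefined, treated as non-redundant",
                    i,
                    j,
                )
                continue
            res = stats.pearsonr(x, y, alternative="greater")
            P[i, j] = res.statistic
            if res.pvalue < alpha:
                redundant = True
                offending.append((i, j, float(res.statistic), float(res.pvalue)))
    return RedundancyReport(
        K_u_tested=K_u,
        pooled_genes=list(pooled),
        P=P,
        redundant=redundant,
        offending_pairs=offending,
    )


def select_num_additional(
    corpus: CountCorpus,
    guide: GuideSpec,
    priors: Priors,
    max_Ku: int,
    config: SamplerConfig | None = None,
    seeds: Sequence[int] = (0, 1, 2),
    redundancy_alpha: float = 0.05,
) -> tuple[int, list[RedundancyReport]]:
    """Grow K_u from 1 until the redundancy test fires; refit at each step.

    Returns the largest K_u before the first redundant fit (0 when K_u = 1
    is already redundant), and the per-step reports. Each candidate refits
    from scratch on the fixed seed list; contributions are the entrywise
    median phi over those seeds. If ``max_Ku`` is reached without redundancy
    it is returned with a warning.
    """
    if max_Ku < 0:
        raise ValueError("max_Ku must be >= 0")
    if max_Ku == 0:
        return 0, []
    marker = {g for g, t in guide.topic_of_gene.items() if t}
    nonmarker_idx = [
        v for v, g in enumerate(corpus.gene_ids) if g.strip().casefold() not in marker
    ]
    nonmarker_genes = [corpus.gene_ids[v] for v in nonmarker_idx]
    if not nonmarker_genes:
        raise ValueError("no non-marker genes in the corpus; cannot test redundancy")

    reports: list[RedundancyReport] = []
    for K_u in range(1, max_Ku + 1):
        g = GuideSpec(
            K_g=guide.K_g,
            K_u=K_u,
            topic_of_gene=guide.topic_of_gene,
            refresh_prob=guide.refresh_prob,
            topic_names=guide.topic_names,
        )
        ens = run_ensemble(corpus, g, priors, config=config, seeds=seeds)
        phi_prime = ens.median_phi[:, nonmarker_idx]  # (K, L')
        pooled = pool_top_contrib_genes(phi_prime[guide.K_g :], nonmarker_genes, g.K)
        report = redundancy_matrix(
            phi_prime, nonmarker_genes, pooled, K_u, alpha=redundancy_alpha
        )
        reports.append(report)
        logger.info(
            "K_u=%d: %d pooled genes, redundant=%s", K_u, len(pooled), report.redundant
        )
        if report.redundant:
            return K_u - 1, reports
    logger.warning("no redundancy detected up to max_Ku=%d; returning max_Ku", max_Ku)
    return max_Ku, reports


def write_reports(reports: Sequence[RedundancyReport], path: str | Path) -> None:
    Path(path).write_text(json.dumps([r.to_dict() for r in reports], indent=2))
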