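"""Interpretation of topics via their gene contributions.

Unguided topics have no a-priori identity, so they are interpreted after the
fact: the per-seed contribution rows of the additional topics (K_u × En rows
over the analysis genes) are clustered with k-means into K_u putative
topics, and each cluster's top-contributing floor(L/K_u) genes are tested
for over-representation in user-supplied gene-set collections (GMT) with a
one-sided Fisher's exact test and Benjamini–Hochberg adjustment. A
single-sample enrichment score (weighted Kolmogorov–Smirnov running sum over
the contribution-ranked gene list) summarizes how concentrated a gene set is
near the top of a topic's contribution profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("gldadec")

__all__ = [
    "AnnotationCollection",
    "cluster_additional_topics",
    "top_cluster_genes",
    "fisher_enrichment",
    "ss_enrichment_score",
    "write_enrichment_table",
]


@dataclass
class AnnotationCollection:
    """Named gene sets plus the background universe they are tested against.

    Sets are intersected with the universe on construction; sets left empty
    are dropped with a warning. The universe should be the analysis gene
    list (the genes the model actually saw), not the whole genome.
    """

    set_names: list[str]
    sets: list[set[str]]
    universe: list[str]

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("empty annotation universe")
        if len(set(self.universe)) != len(self.universe):
            raise ValueError("duplicate genes in universe")
        uni = set(self.universe)
        kept_names, kept_sets = [], []
        for name, s in zip(self.set_names, self.sets):
            inter = set(s) & uni
            if inter:
                kept_names.append(name)
                kept_sets.append(inter)
            else:
                logger.warning("annotation set %r has no genes in universe; dropped", name)
        if not kept_names:
            raise ValueError("no annotation set overlaps the universe")
        self.set_names = kept_names
        self.sets = kept_sets

    @classmethod
    def from_gmt(cls, path: str | Path, universe: Sequence[str]) -> "AnnotationCollection":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"annotation file not found: {path}")
        names: list[str] = []
        sets: list[set[str]] = []
        for lineno, line in enumerate(path.read_text().splitlines(), 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description, genes")
            names.append(fields[0])
            sets.append({g for g in fields[2:] if g.strip()})
        if not names:
            raise ValueError(f"empty annotation file: {path}")
        return cls(set_names=names, sets=sets, universe=list(universe))


def cluster_additional_topics(
    phi_stack: np.ndarray,
    K_u: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """K-means partition of the (K_u · En) × L additional-topic rows.

    Rows are L2-normalized first so clusters reflect contribution shape, not
    chain-to-chain scale. Cluster identities are arbitrary; only the
    partition and centroids are meaningful. Deterministic given ``seed``.
    """
    phi_stack = np.atleast_2d(np.asarray(phi_stack, dtype=float))
    if phi_stack.shape[0] == 0:
        raise ValueError("empty contribution stack")
    if K_u < 1:
        raise ValueError("K_u must be >= 1")
    if phi_stack.shape[0] < K_u:
        raise ValueError(
            f"fewer rows ({phi_stack.shape[0]}) than clusters ({K_u})"
        )
    norms = np.linalg.norm(phi_stack, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    X = phi_stack / norms
    km = KMeans(n_clusters=K_u, random_state=seed, n_init=10)
    labels = km.fit_predict(X)
    return labels, km.cluster_centers_


def top_cluster_genes(
    centroid: np.ndarray,
    genes: Sequence[str],
    K_u: int,
) -> list[str]:
    """The floor(L/K_u) genes with highest centroid contribution.

    Ties break lexicographically by gene name (so a uniform centroid yields
    the alphabetically first genes), making the list deterministic.
    """
    centroid = np.asarray(centroid, dtype=float)
    L = centroid.shape[0]
    if L != len(genes):
        raise ValueError("centroid length must match gene list")
    if not 1 <= K_u <= L:
        raise ValueError("need 1 <= K_u <= L")
    n = L // K_u
    names = np.asarray(genes, dtype=object)
    order = np.lexsort((names, -centroid))
    return names[order[:n]].tolist()


def fisher_enrichment(
    query: set[str] | Sequence[str],
    annotations: AnnotationCollection,
) -> pd.DataFrame:
    """One-sided (over-representation) Fisher's exact test per gene set.

    For each set the 2×2 table over the universe is (in query ∧ in set,
    in query only, in set only, neither); the p-value is the hypergeometric
    upper tail P(X >= overlap). BH step-up adjusts across all tested sets.
    Returns a table with columns term, overlap, odds_ratio, p, p_adj sorted
    by adjusted p.
    """
    query = set(query)
    if not query:
        raise ValueError("empty query gene set")
    uni = set(annotations.universe)
    outside = query - uni
    if outside:
        logger.warning("%d query genes outside universe dropped", len(outside))
        query &= uni
        if not query:
            raise ValueError("no query genes in universe")
    N = len(uni)
    n_query = len(query)
    rows = []
    for name, s in zip(annotations.set_names, annotations.sets):
        overlap = query & s
        a = len(overlap)
        b = n_query - a
        c = len(s) - a
        d = N - a - b - c
        # upper-tail hypergeometric: draws = |query|, successes = |set|
        p = float(stats.hypergeom.sf(a - 1, N, len(s), n_query))
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
        rows.append((name, sorted(overlap), odds, min(p, 1.0)))
    table = pd.DataFrame(rows, columns=["term", "overlap", "odds_ratio", "p"])
    table["p_adj"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    table = table.sort_values(["p_adj", "p", "term"], kind="stable").reset_index(drop=True)
    return table


def write_enrichment_table(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    out["overlap"] = out["overlap"].map(lambda genes: ",".join(genes))
    out.to_csv(path, sep="\t", index=False)


def ss_enrichment_score(
    contributions: Mapping[str, float] | pd.Series,
    gene_set: set[str] | Sequence[str],
    weight: str = "contribution",
) -> float:
    """Single-sample enrichment score of a gene set in a contribution profile.

    Genes are ranked by contribution descending; walking down the list, the
    running sum rises by the member gene's normalized weight and falls by
    1/(L - |set|) for non-members. The score is the running sum's maximum
    deviation from zero, sign retained: positive means the set concentrates
    near the top of the ranking.

    ``weight="contribution"`` uses |contribution| (exponent 1) as the member
    weight; ``weight="rank"`` uses the descending-rank score L - position,
    which makes the score invariant to strictly monotone transforms of the
    contributions.
    """
    if isinstance(contributions, pd.Series):
        contributions = contributions.to_dict()
    genes = sorted(contributions)  # name order breaks contribution ties
    L = len(genes)
    members = set(gene_set) & set(genes)
    if not members:
        raise ValueError("gene set disjoint from the contribution universe")
    if len(members) == L:
        logger.warning("gene set covers the whole universe; score is 0 by convention")
        return 0.0
    values = np.array([float(contributions[g]) for g in genes])
    order = np.lexsort((np.asarray(genes, dtype=object), -values))
    ranked = [genes[i] for i in order]
    if weight == "contribution":
        w = np.abs(values[order])
    elif weight == "rank":
        w = (L - np.arange(L)).astype(float)
    else:
        raise ValueError(f"unknown weight mode {weight!r}")
    is_member = np.array([g in members for g in ranked])
    w_members = w[is_member]
    if w_members.sum() == 0:
        w_members = np.ones_like(w_members)  # all-zero weights: fall back to uniform
    inc = np.zeros(L)
    inc[is_member] = w_members / w_members.sum()
    inc[~is_member] = -1.0 / (L - len(members))
    running = np.cumsum(inc)
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak])
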