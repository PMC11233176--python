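"""Multi-seed ensembles with median selection.

A single Gibbs chain depends on its random seed; running several independent
chains and taking the entrywise median of the sample-topic matrices, then
renormalizing each sample's row to sum to 1, gives a proportion estimate that
is robust to individual stray chains. Guided topics keep their identity
across seeds (the marker anchoring pins the labels), so no cross-run topic
alignment is needed for theta; additional (unguided) topics are NOT
identifiable across runs, which is why the per-seed phi stack is preserved
for downstream interpretation instead of being medianned into one matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .preprocessing import CountCorpus
from .sampler import (
    DeconvolutionResult,
    GuideSpec,
    Priors,
    SamplerConfig,
    run_chain,
)

logger = logging.getLogger("gldadec")

__all__ = ["EnsembleResult", "run_ensemble", "median_select"]


@dataclass
class EnsembleResult:
    per_seed_theta: list[np.ndarray]
    median_theta: np.ndarray
    per_seed_phi: list[np.ndarray]
    median_phi: np.ndarray
    seeds: list[int]
    results: list[DeconvolutionResult]

    @property
    def En(self) -> int:
        return len(self.seeds)

    @property
    def topic_labels(self) -> list[str]:
        return self.results[0].topic_labels

    def theta_frame(self):
        import pandas as pd

        r = self.results[0]
        return pd.DataFrame(self.median_theta, index=r.sample_ids, columns=r.topic_labels)


def median_select(thetas: Sequence[np.ndarray]) -> np.ndarray:
    """Entrywise median over runs, then renormalize each row to sum to 1."""
    if len(thetas) == 0:
        raise ValueError("median_select needs at least one matrix")
    shapes = {t.shape for t in map(np.asarray, thetas)}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent theta shapes: {shapes}")
    med = np.median(np.stack([np.asarray(t, dtype=float) for t in thetas]), axis=0)
    rowsum = med.sum(axis=1, keepdims=True)
    if np.any(rowsum <= 0):
        raise ValueError("median row sums to zero; cannot renormalize")
    return med / rowsum


def run_ensemble(
    corpus: CountCorpus,
    guide: GuideSpec,
    priors: Priors,
    config: SamplerConfig | None = None,
    seeds: Sequence[int] = tuple(range(10)),
) -> EnsembleResult:
    """One independent chain per seed, aggregated by median selection.

    Results are collected in seed order regardless of execution order, so the
    output is a pure function of (corpus, guide, priors, config, seeds).
    """
    seeds = [int(s) for s in seeds]
    if not seeds:
        raise ValueError("need at least one seed")
    if len(set(seeds)) != len(seeds):
        raise ValueError(f"duplicate seeds: {seeds}")
    results: list[DeconvolutionResult] = []
    for s in seeds:
        try:
            results.append(run_chain(corpus, guide, priors, config=config, seed=s))
        except Exception as exc:
            raise RuntimeError(f"chain with seed {s} failed: {exc}") from exc
        logger.info("ensemble chain seed=%d done (%d/%d)", s, len(results), len(seeds))
    thetas = [r.theta for r in results]
    phis = [r.phi for r in results]
    return EnsembleResult(
        per_seed_theta=thetas,
        median_theta=median_select(thetas),
        per_seed_phi=phis,
        median_phi=np.median(np.stack(phis), axis=0),
        seeds=seeds,
        results=results,
    )
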