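"""Synthetic cell-type signatures and pseudo-bulk mixtures with known truth.

The generator emulates the pseudo-bulk protocol used to stress-test
deconvolution methods: K_true cell types, each with a block of private
marker genes expressed ``marker_fold`` times higher in its own type than
elsewhere, shared background genes with log-normal gene-level variation, and
bulk samples built as Dirichlet-weighted mixtures of the type signatures
scaled to a sequencing depth and count-sampled (Poisson or negative
binomial). The true mixing proportions are returned alongside, so recovery
can be scored exactly. Optional ``contaminant_types`` are generated with
their own signatures but left out of the marker guide, to exercise the
absorption of unexpected cell types by additional topics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .preprocessing import ExpressionMatrix, MarkerGuide

logger = logging.getLogger("gldadec")

__all__ = [
    "SyntheticDesign",
    "GroundTruth",
    "make_signatures",
    "make_pseudo_bulk",
    "score_recovery",
]


@dataclass
class SyntheticDesign:
    """Parameters of the synthetic mixture experiment.

    Defaults describe a clearly separable 5-type mixture at bulk-like depth:
    10 private markers per type at a 20-fold expression ratio over a
    baseline of 10 (linear-scale units), 20 000 tokens per sample, Poisson
    counting noise, and flat Dirichlet(1) mixing proportions.
    """

    K_true: int = 5
    L: int = 300
    markers_per_type: int = 10
    marker_fold: float = 20.0
    baseline: float = 10.0
    depth: float = 20_000.0
    noise_model: str = "poisson"  # or "negative_binomial"
    nb_dispersion: float = 10.0  # NB size parameter (larger = closer to Poisson)
    dirichlet_conc: float = 1.0
    contaminant_types: int = 0
    gene_sigma: float = 0.5  # log-normal sd of gene-level baseline variation
    seed: int = 0

    def __post_init__(self) -> None:
        total_types = self.K_true + self.contaminant_types
        if total_types * self.markers_per_type > self.L:
            raise ValueError("more marker genes than genes in the design")
        if self.K_true < 1 or self.L < 1 or self.markers_per_type < 1:
            raise ValueError("counts must be positive")
        for name in ("marker_fold", "baseline", "depth", "dirichlet_conc", "nb_dispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_model not in ("poisson", "negative_binomial"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


@dataclass
class GroundTruth:
    true_theta: np.ndarray  # (M, K_all) rows sum to 1
    signatures: np.ndarray  # (K_all, L)
    guide: MarkerGuide  # over the non-contaminant types only
    type_names: list[str]
    gene_ids: list[str]

    def theta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.true_theta,
            index=[f"sample_{m}" for m in range(self.true_theta.shape[0])],
            columns=self.type_names,
        )


def make_signatures(design: SyntheticDesign) -> tuple[np.ndarray, MarkerGuide]:
    """Expected per-type expression profiles and the matching marker guide.

    Markers occupy disjoint leading gene blocks; the guide covers only the
    first ``K_true`` types (contaminant types keep their markers out of the
    guide). With ``marker_fold`` = 1 the signatures carry no marker signal —
    a negative control.
    """
    rng = np.random.default_rng(design.seed)
    K_all = design.K_true + design.contaminant_types
    L = design.L
    type_names = [f"type_{k}" for k in range(design.K_true)] + [
        f"contaminant_{c}" for c in range(design.contaminant_types)
    ]
    gene_ids = [f"gene_{i:04d}" for i in range(L)]

    gene_level = np.exp(rng.normal(0.0, design.gene_sigma, size=L))
    signatures = np.tile(design.baseline * gene_level, (K_all, 1))
    marker_sets: list[set[str]] = []
    for k in range(K_all):
        lo = k * design.markers_per_type
        hi = lo + design.markers_per_type
        signatures[k, lo:hi] *= design.marker_fold
        marker_sets.append({gene_ids[i] for i in range(lo, hi)})

    guide = MarkerGuide(
        topic_names=type_names[: design.K_true],
        marker_sets=marker_sets[: design.K_true],
    )
    return signatures, guide


def make_pseudo_bulk(
    signatures: np.ndarray,
    M: int,
    design: SyntheticDesign,
    seed: int | None = None,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Dirichlet-mixed, depth-scaled, count-sampled bulk profiles.

    ``seed`` defaults to ``design.seed`` + 1 so signatures and mixtures use
    distinct streams but the whole fixture is reproducible from the design.
    """
    if M < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(design.seed + 1 if seed is None else seed)
    K_all = signatures.shape[0]
    L = signatures.shape[1]
    type_names = [f"type_{k}" for k in range(design.K_true)] + [
        f"contaminant_{c}" for c in range(K_all - design.K_true)
    ]
    gene_ids = [f"gene_{i:04d}" for i in range(L)]

    true_theta = rng.dirichlet(np.full(K_all, design.dirichlet_conc), size=M)
    expected = true_theta @ signatures  # (M, L)
    expected = expected / expected.sum(axis=1, keepdims=True) * design.depth
    if design.noise_model == "poisson":
        values = rng.poisson(expected).astype(float)
    else:
        size = design.nb_dispersion
        p = size / (size + expected)
        values = rng.negative_binomial(size, p).astype(float)

    expr = ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=[f"sample_{m}" for m in range(M)],
        values=values.T,
    )
    _, guide = make_signatures(design)
    truth = GroundTruth(
        true_theta=true_theta,
        signatures=signatures,
        guide=guide,
        type_names=type_names,
        gene_ids=gene_ids,
    )
    return expr, truth


def make_hidden_factor_bulk(
    M: int = 20,
    block_genes: int = 60,
    depth: float = 20_000.0,
    seed: int = 11,
) -> tuple[ExpressionMatrix, MarkerGuide, np.ndarray]:
    """Pseudo-bulk with one hidden expression factor outside the guide.

    Five guided cell types (10 markers each, as in the default design) are
    mixed as usual, and on top of them a single hidden source — a rank-1
    block of ``block_genes`` genes with linearly varying loadings, driven by
    a per-sample activity sampled independently of the guided mixture —
    contributes a share of each sample. The block genes are not markers of
    anything, and their coefficient of variation dominates the background
    genes', so with ``topn`` = ``block_genes`` the corpus's non-marker genes
    are exactly the block. One additional topic suffices to absorb the
    hidden factor; a second one has nothing of its own and ends up
    duplicating existing topic loadings, which is what the redundancy scan
    is meant to detect.

    Returns the expression matrix, the (five-type) marker guide, and the
    hidden per-sample activity.
    """
    rng = np.random.default_rng(seed)
    base = SyntheticDesign(
        K_true=5, L=200, markers_per_type=10, gene_sigma=0.2, seed=seed
    )
    signatures, guide = make_signatures(base)
    theta_g = rng.dirichlet(np.ones(base.K_true), size=M)
    hidden = rng.beta(2, 4, size=M)  # hidden source's share per sample
    expected = ((1 - hidden)[:, None] * theta_g) @ signatures
    loadings = np.linspace(0.5, 2.0, block_genes) * 300.0
    block = np.outer(hidden, loadings)
    guided_mass = expected.sum(axis=1, keepdims=True)
    block = (
        block
        / block.sum(axis=1, keepdims=True)
        * guided_mass
        * (hidden / (1 - hidden))[:, None]
    )
    full = np.hstack([expected, block])
    full = full / full.sum(axis=1, keepdims=True) * depth
    counts = rng.poisson(full).astype(float)
    gene_ids = [f"gene_{i:04d}" for i in range(base.L)] + [
        f"hidden_{i:03d}" for i in range(block_genes)
    ]
    expr = ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=[f"sample_{m}" for m in range(M)],
        values=counts.T,
    )
    return expr, guide, hidden


def score_recovery(
    estimated_theta: pd.DataFrame | np.ndarray,
    true_theta: pd.DataFrame | np.ndarray,
    label_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-type Pearson r and MSE between estimated and true proportions.

    With labelled frames, estimated topics are matched to true types by name
    (optionally through ``label_map``: estimated label -> true type). A
    constant estimated column has undefined r, reported as NaN.
    """
    if isinstance(estimated_theta, pd.DataFrame) and isinstance(true_theta, pd.DataFrame):
        est, tru = estimated_theta, true_theta
        pairs = []
        for col in est.columns:
            target = (label_map or {}).get(col, col)
            if target in tru.columns:
                pairs.append((col, target))
        if not pairs:
            raise ValueError("no estimated topic matches a true type")
        est_m = est[[c for c, _ in pairs]].to_numpy()
        tru_m = tru[[t for _, t in pairs]].to_numpy()
        names = [c for c, _ in pairs]
    else:
        est_m = np.asarray(estimated_theta, dtype=float)
        tru_m = np.asarray(true_theta, dtype=float)
        if est_m.shape != tru_m.shape:
            raise ValueError("shape mismatch between estimate and truth")
        names = [f"type_{k}" for k in range(est_m.shape[1])]

    rows = []
    for j, name in enumerate(names):
        e, t = est_m[:, j], tru_m[:, j]
        mse = float(np.mean((e - t) ** 2))
        if np.ptp(e) == 0 or np.ptp(t) == 0:
            logger.warning("constant column for %s: Pearson r undefined", name)
            r = np.nan
        else:
            r = float(stats.pearsonr(e, t).statistic)
        rows.append((name, r, mse))
    out = pd.DataFrame(rows, columns=["type", "pearson_r", "mse"]).set_index("type")
    rs = out["pearson_r"].to_numpy()
    out.attrs["mean_r"] = float(np.nanmean(rs)) if np.isfinite(rs).any() else float("nan")
    out.attrs["mean_mse"] = float(out["mse"].mean())
    return out
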