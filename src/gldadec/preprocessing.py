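"""Expression / marker input handling and analysis-gene selection.

The deconvolution model treats a bulk expression profile as a bag of gene
tokens, so the raw genes × samples matrix (linear, non-log scale) has to be
reduced to an informative gene set and integerized before sampling:

1. genes with consistently extreme expression (mitochondrial/ribosomal-like,
   > ``sigma`` standard deviations above the mean of the log mean-expression
   distribution) are dropped — they swamp the token counts without carrying
   cell-composition signal;
2. the marker genes named in the guide are kept unconditionally (they anchor
   the guided topics);
3. the ``topn`` non-marker genes with the largest coefficient of variation
   across samples are added, since composition changes express themselves as
   between-sample variation;
4. expression values are rounded half-up to integer token counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("gldadec")

__all__ = [
    "ExpressionMatrix",
    "MarkerGuide",
    "CountCorpus",
    "GeneFilterReport",
    "filter_outlier_genes",
    "select_high_cv_genes",
    "build_corpus",
    "read_expression",
    "write_expression",
    "read_marker_sets",
]


def _norm(name: str) -> str:
    """Normalization key for gene-name matching: strip + casefold."""
    return name.strip().casefold()


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes × samples non-negative expression on linear (non-log) scale."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # (L, M) float

    def __post_init__(self) -> None:
        self.gene_ids = [g.strip() for g in self.gene_ids]
        self.sample_ids = [s.strip() for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        L, M = self.values.shape
        if L != len(self.gene_ids) or M != len(self.sample_ids):
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.gene_ids)} genes × {len(self.sample_ids)} samples"
            )
        if L < 1 or M < 1:
            raise ValueError("expression matrix must have at least 1 gene and 1 sample")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative (linear scale)")
        keys = [_norm(g) for g in self.gene_ids]
        if len(set(keys)) != len(keys):
            dup = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate gene ids after case normalization: {dup[:5]}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            gene_ids=[str(g) for g in df.index],
            sample_ids=[str(s) for s in df.columns],
            values=df.to_numpy(dtype=float),
        )

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        index = {_norm(g): i for i, g in enumerate(self.gene_ids)}
        rows = [index[_norm(g)] for g in genes]
        return ExpressionMatrix(
            gene_ids=[self.gene_ids[i] for i in rows],
            sample_ids=list(self.sample_ids),
            values=self.values[rows, :],
        )


@dataclass
class MarkerGuide:
    """Ordered cell-type names, each with a set of marker gene names."""

    topic_names: list[str]
    marker_sets: list[set[str]]

    def __post_init__(self) -> None:
        if len(self.topic_names) < 1:
            raise ValueError("at least one guided cell type is required")
        if len(self.topic_names) != len(self.marker_sets):
            raise ValueError("topic_names and marker_sets length mismatch")
        if len(set(self.topic_names)) != len(self.topic_names):
            raise ValueError("duplicate cell-type names in guide")
        self.marker_sets = [{m.strip() for m in s} for s in self.marker_sets]
        for name, s in zip(self.topic_names, self.marker_sets):
            if not s:
                raise ValueError(f"marker set for {name!r} is empty")

    @property
    def n_topics(self) -> int:
        return len(self.topic_names)

    def all_markers(self) -> set[str]:
        out: set[str] = set()
        for s in self.marker_sets:
            out |= s
        return out


@dataclass
class CountCorpus:
    """Integer gene-token counts over the analysis gene set."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # (L_a, M) int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded):
                raise ValueError("corpus counts must be integers")
            self.counts = rounded.astype(np.int64)
        self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("corpus counts must be non-negative")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("corpus shape mismatch")
        if np.any(self.total_tokens < 1):
            empty = [s for s, n in zip(self.sample_ids, self.total_tokens) if n < 1]
            raise ValueError(f"samples with zero tokens after integerization: {empty}")

    @property
    def total_tokens(self) -> np.ndarray:
        """Per-sample token counts n_m (column sums)."""
        return self.counts.sum(axis=0)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


@dataclass
class GeneFilterReport:
    """Record of what the gene filters did, for run manifests."""

    removed_outliers: list[str] = field(default_factory=list)
    cv_selected: list[str] = field(default_factory=list)
    markers_found: dict[str, int] = field(default_factory=dict)
    markers_missing: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.removed_outliers) & set(self.cv_selected)
        if overlap:
            raise ValueError(f"genes both removed and CV-selected: {sorted(overlap)}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "removed_outliers": self.removed_outliers,
                    "cv_selected": self.cv_selected,
                    "markers_found": self.markers_found,
                    "markers_missing": self.markers_missing,
                },
                indent=2,
            )
        )


# ---------------------------------------------------------------------------
# Gene filters
# ---------------------------------------------------------------------------


def filter_outlier_genes(
    expr: ExpressionMatrix,
    sigma: float = 2.0,
    guide: MarkerGuide | None = None,
) -> tuple[ExpressionMatrix, GeneFilterReport]:
    """Drop genes whose log mean expression is an upper-tail outlier.

    The per-gene statistic is ``log(mean expression across samples + 1)``;
    genes more than ``sigma`` standard deviations ABOVE the mean of that
    statistic are removed. Only the upper tail is trimmed: the filter targets
    consistently over-expressed housekeeping-like genes, and two-sided
    trimming would discard informative low-expression markers. Marker genes
    named in ``guide`` are exempt.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    stat = np.log(expr.values.mean(axis=1) + 1.0)
    sd = stat.std()  # population sd; degenerate dispersion -> nothing removed
    if sd == 0:
        keep = np.ones(expr.n_genes, dtype=bool)
    else:
        keep = stat <= stat.mean() + sigma * sd
    exempt = {_norm(m) for m in guide.all_markers()} if guide is not None else set()
    removed: list[str] = []
    for i, g in enumerate(expr.gene_ids):
        if not keep[i]:
            if _norm(g) in exempt:
                keep[i] = True
            else:
                removed.append(g)
    if not keep.any():
        raise ValueError("empty matrix after filtering")
    filtered = ExpressionMatrix(
        gene_ids=[g for g, k in zip(expr.gene_ids, keep) if k],
        sample_ids=list(expr.sample_ids),
        values=expr.values[keep, :],
    )
    if removed:
        logger.info("outlier filter removed %d genes (sigma=%g)", len(removed), sigma)
    return filtered, GeneFilterReport(removed_outliers=removed)


def select_high_cv_genes(
    expr: ExpressionMatrix,
    topn: int,
    exclude: set[str] | None = None,
) -> list[str]:
    """Top-``topn`` genes by coefficient of variation (sd/mean) across samples.

    Genes in ``exclude`` (the markers) are not eligible; genes with mean 0
    get CV 0; ties break lexicographically by gene name so the selection is
    deterministic.
    """
    if topn < 0:
        raise ValueError("topn must be >= 0")
    if topn == 0:
        return []
    excl = {_norm(g) for g in exclude} if exclude else set()
    mean = expr.values.mean(axis=1)
    sd = expr.values.std(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), 0.0)
    candidates = [
        (g, cv[i]) for i, g in enumerate(expr.gene_ids) if _norm(g) not in excl
    ]
    if topn > len(candidates):
        logger.warning(
            "requested topn=%d high-CV genes but only %d available; returning all",
            topn,
            len(candidates),
        )
        topn = len(candidates)
    candidates.sort(key=lambda t: (-t[1], t[0]))
    return [g for g, _ in candidates[:topn]]


def build_corpus(
    expr: ExpressionMatrix,
    guide: MarkerGuide,
    topn: int,
    sigma: float | None = 2.0,
    scale_depth: float | None = None,
) -> tuple[CountCorpus, GeneFilterReport]:
    """Assemble the integer token corpus the Gibbs sampler consumes.

    Analysis genes = (markers present in ``expr``) ∪ (top-``topn`` high-CV
    genes after the outlier filter). With ``scale_depth`` set, each sample
    column is rescaled to sum to that depth before rounding; otherwise raw
    linear values are rounded half-up.
    """
    if sigma is not None:
        filtered, report = filter_outlier_genes(expr, sigma=sigma, guide=guide)
    else:
        filtered, report = expr, GeneFilterReport()

    present = {_norm(g): g for g in expr.gene_ids}
    marker_genes: list[str] = []
    seen: set[str] = set()
    for name, markers in zip(guide.topic_names, guide.marker_sets):
        found = [present[_norm(m)] for m in sorted(markers) if _norm(m) in present]
        missing = [m for m in sorted(markers) if _norm(m) not in present]
        report.markers_found[name] = len(found)
        report.markers_missing[name] = missing
        if not found:
            raise ValueError(
                f"guided cell type {name!r} has no marker genes present in the "
                "expression matrix"
            )
        for g in found:
            if _norm(g) not in seen:
                seen.add(_norm(g))
                marker_genes.append(g)

    cv_genes = select_high_cv_genes(filtered, topn, exclude=set(seen))
    report.cv_selected = list(cv_genes)
    genes = marker_genes + cv_genes

    sub = expr.subset_genes(genes)
    values = sub.values
    if scale_depth is not None:
        colsum = values.sum(axis=0)
        if np.any(colsum <= 0):
            raise ValueError("cannot rescale sample with zero total expression")
        values = values / colsum * scale_depth
    counts = np.floor(values + 0.5).astype(np.int64)  # round half-up
    corpus = CountCorpus(gene_ids=sub.gene_ids, sample_ids=sub.sample_ids, counts=counts)
    logger.info(
        "corpus: %d genes (%d marker, %d high-CV), %d samples, %d tokens",
        corpus.n_genes,
        len(marker_genes),
        len(cv_genes),
        corpus.n_samples,
        int(corpus.counts.sum()),
    )
    return corpus, report


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_expression(path: str | Path, fmt: str | None = None) -> ExpressionMatrix:
    """Read a genes × samples table (first column gene IDs, header sample IDs).

    ``fmt`` is ``"tsv"`` or ``"csv"``; inferred from the suffix when omitted.
    Duplicated gene rows are collapsed by sum with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression file not found: {path}")
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "tsv"
    if fmt not in ("tsv", "csv"):
        raise ValueError(f"unknown expression format {fmt!r} (expected tsv or csv)")
    sep = "\t" if fmt == "tsv" else ","
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    if not header.strip():
        raise ValueError(f"empty expression file: {path}")
    samples = header.split(sep)[1:]  # pandas would silently rename duplicates
    if len(set(samples)) != len(samples):
        dup = sorted({s for s in samples if samples.count(s) > 1})
        raise ValueError(f"duplicate sample names: {dup}")
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty expression file: {path}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"expression file has no data: {path}")
    bad = df.map(lambda x: not isinstance(x, (int, float, np.number)))
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at gene {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    if df.isna().to_numpy().any():
        i, j = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(
            f"missing value at gene {df.index[i]!r}, sample {df.columns[j]!r} "
            "(ragged row?)"
        )
    norm_index = pd.Index([_norm(str(g)) for g in df.index])
    if norm_index.duplicated().any():
        n_dup = int(norm_index.duplicated().sum())
        logger.warning("collapsing %d duplicated gene rows by sum", n_dup)
        first_name = {}
        for raw, key in zip(df.index, norm_index):
            first_name.setdefault(key, str(raw))
        df = df.groupby(norm_index, sort=False).sum()
        df.index = [first_name[k] for k in df.index]
    return ExpressionMatrix.from_frame(df)


def write_expression(expr: ExpressionMatrix, path: str | Path, fmt: str | None = None) -> None:
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "tsv"
    sep = "\t" if fmt == "tsv" else ","
    expr.to_frame().to_csv(path, sep=sep)


def read_marker_sets(path: str | Path, fmt: str | None = None) -> MarkerGuide:
    """Read cell-type marker gene names from GMT or JSON.

    GMT: ``name<TAB>description<TAB>gene1<TAB>gene2...`` per line.
    JSON: an object ``{"cell type": ["GENE1", ...], ...}``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"marker file not found: {path}")
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "gmt"
    if fmt == "json":
        data = json.loads(path.read_text())
        if not isinstance(data, dict) or not data:
            raise ValueError(f"marker JSON must be a non-empty object: {path}")
        names = list(data.keys())
        sets = [set(map(str, genes)) for genes in data.values()]
        return MarkerGuide(topic_names=names, marker_sets=sets)
    if fmt != "gmt":
        raise ValueError(f"unknown marker format {fmt!r} (expected gmt or json)")
    names: list[str] = []
    sets = []
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description, genes")
        names.append(fields[0])
        sets.append({g for g in fields[2:] if g.strip()})
    if not names:
        raise ValueError(f"empty marker file: {path}")
    return MarkerGuide(topic_names=names, marker_sets=sets)
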