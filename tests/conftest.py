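import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gldadec import (
    CountCorpus,
    ExpressionMatrix,
    MarkerGuide,
    SyntheticDesign,
    make_pseudo_bulk,
    make_signatures,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_corpus(counts, genes=None, samples=None) -> CountCorpus:
    """Small helper: counts is (genes × samples) array-like."""
    counts = np.asarray(counts)
    genes = genes or [f"g{i}" for i in range(counts.shape[0])]
    samples = samples or [f"s{j}" for j in range(counts.shape[1])]
    return CountCorpus(gene_ids=genes, sample_ids=samples, counts=counts)


@pytest.fixture
def tiny_expr() -> ExpressionMatrix:
    return ExpressionMatrix(
        gene_ids=["ACTB", "CD19", "MS4A1", "CD3E"],
        sample_ids=["s1", "s2"],
        values=np.array([[5.0, 7.0], [2.0, 0.0], [1.0, 3.0], [0.0, 4.0]]),
    )


@pytest.fixture
def two_type_guide() -> MarkerGuide:
    return MarkerGuide(
        topic_names=["B_cells", "T_cells"],
        marker_sets=[{"CD19", "MS4A1"}, {"CD3E"}],
    )


@pytest.fixture(scope="session")
def separable_bulk():
    """Default separable mixture: 5 types, disjoint markers, Poisson noise."""
    design = SyntheticDesign()
    signatures, guide = make_signatures(design)
    expr, truth = make_pseudo_bulk(signatures, 20, design)
    return design, expr, truth, guide
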