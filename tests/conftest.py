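"""Shared fixtures: small deterministic cohorts and matrices."""

import numpy as np
import pytest

from radcascade import CohortSpec, ExpressionMatrix, generate_cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def two_group_matrix(rng):
    """50 genes x (5 resistant + 5 sensitive), pure noise plus a few shifts."""
    x = rng.normal(8.0, 1.0, size=(10, 50))
    x[:5, :4] += 1.0  # first four genes elevated in the resistant group
    return ExpressionMatrix(
        sample_ids=[f"S{i:02d}" for i in range(10)],
        gene_ids=[f"G{i:02d}" for i in range(50)],
        values=x,
        labels=["resistant"] * 5 + ["sensitive"] * 5,
    )


@pytest.fixture()
def default_cohort():
    """The generator's default study conditions (n=30+30, effect 1.5 SD, 2 subtypes)."""
    return generate_cohort(CohortSpec(seed=7))


def make_marker_matrix(genes, n_per_group=8, seed=0, separation=3.0):
    """Labelled matrix over arbitrary ``genes`` where the first half of the
    genes are elevated in resistant samples — handy for cascades over the
    published marker names."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    x = rng.normal(8.0, 1.0, size=(n, len(genes)))
    half = len(genes) // 2
    x[n_per_group:, :half] += separation
    x[n_per_group:, half:] -= separation
    return ExpressionMatrix(
        sample_ids=[f"M{i:02d}" for i in range(n)],
        gene_ids=list(genes),
        values=x,
        labels=["sensitive"] * n_per_group + ["resistant"] * n_per_group,
    )
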