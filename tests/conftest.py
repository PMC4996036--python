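"""Shared fixtures.

The default synthetic dataset, its normalization, the trained SOM and
the NB-EM baseline are expensive enough to share at session scope; all
are fully seeded, so sharing does not couple tests through hidden state.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from somtopo import cluster_compare as cc
from somtopo import normalization, som, synthetic
from somtopo.io import ExpressionMatrix, SampleInfo

settings.register_profile("somtopo", derandomize=True, deadline=None)
settings.load_profile("somtopo")


@pytest.fixture(scope="session")
def default_dataset() -> synthetic.SyntheticDataset:
    return synthetic.generate(synthetic.SyntheticSpec())


@pytest.fixture(scope="session")
def default_nm(default_dataset):
    return normalization.normalize(default_dataset.em)


@pytest.fixture(scope="session")
def default_som(default_nm):
    return som.train(
        default_nm.values, som.SomConfig(seed=0), gene_ids=default_nm.gene_ids
    )


@pytest.fixture(scope="session")
def default_nbem(default_dataset, default_som):
    return cc.nbem_cluster(
        default_dataset.em, k=default_som.map_units, seed=0
    )


def small_matrix(counts, substrates=None, replicates=None) -> ExpressionMatrix:
    """Build a tiny ExpressionMatrix from a nested list of counts."""
    counts = np.asarray(counts)
    n_samples = counts.shape[1]
    substrates = substrates or [f"cond{j}" for j in range(n_samples)]
    replicates = replicates or [1] * n_samples
    samples = [
        SampleInfo(f"{s}_r{r}", s, r)
        for s, r in zip(substrates, replicates)
    ]
    return ExpressionMatrix(
        gene_ids=[f"g{i}" for i in range(counts.shape[0])],
        counts=counts,
        samples=samples,
    )


@pytest.fixture
def make_matrix():
    return small_matrix
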