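"""Shared fixtures: small synthetic datasets generated at test time."""

import os
import tempfile

# keep hypothesis' on-disk caches out of the repository
os.environ.setdefault(
    "HYPOTHESIS_STORAGE_DIRECTORY", os.path.join(tempfile.gettempdir(), "hypothesis")
)

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import chemofit as cf

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_catalog() -> cf.StrainCatalog:
    return cf.make_catalog(30, seed=11)


@pytest.fixture(scope="session")
def triplicate_design() -> cf.ScreenDesign:
    return cf.make_design(
        [("NDMA", "674.9uM", "DMSO"), ("NDEA", "489.5uM", "DMSO")],
        n_replicates=3,
        date="190801",
    )


@pytest.fixture(scope="session")
def full_catalog() -> cf.StrainCatalog:
    """Genome-scale catalog (4800 strains, 9600 tags at Hamming >= 5).

    Session-scoped: the catalog depends only on its own seed, so recovery
    runs across count-noise seeds can share it.
    """
    return cf.make_catalog(4800, seed=101)


def tag_matrix(counts: pd.DataFrame) -> cf.TagCountMatrix:
    """Wrap a simulated tag-count frame as an already-counted matrix."""
    qc = pd.DataFrame(
        {
            "total_reads": counts.sum(axis=0),
            "assigned": counts.sum(axis=0),
            "unmatched": 0,
            "ambiguous": 0,
        }
    )
    return cf.TagCountMatrix(counts=counts, qc=qc)


def quick_fd_table(
    catalog: cf.StrainCatalog,
    design: cf.ScreenDesign,
    truth: cf.TruthTable,
    seed: int,
    **nb_kwargs,
) -> cf.FitnessTable:
    """Simulated counts -> collapsed genes -> FD table, in one step."""
    params = cf.NBParams(seed=seed, **nb_kwargs)
    counts, _ = cf.simulate_counts(catalog, design, truth, params)
    gene_counts = cf.collapse_tags(tag_matrix(counts), catalog, design)
    return cf.fd_table(gene_counts, design)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
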