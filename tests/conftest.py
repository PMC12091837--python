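"""Shared fixtures.

Expensive artifacts (the 200-peptide study dataset and its RMSD matrix) are
session-scoped so the invariant and trend tests share one computation.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

import tcrsplit as t
from tcrsplit.synthetic import generate_study_dataset


def scaled_max_count(n_records: int) -> int:
    """Desk-scale analogue of the record-count cap on held-out peptides.

    The cap's job is to keep peptides that dominate the dataset out of the
    small test/validation budgets; it is kept proportional to the dataset
    (7.5% of records) so fixtures of any size behave alike.
    """
    return math.ceil(0.075 * n_records)


@pytest.fixture(scope="session")
def study200():
    """Positives + balanced shuffled negatives over 200 peptides."""
    spec = t.FixtureSpec(n_peptides=200, seed=0)
    ds, structures = generate_study_dataset(spec)
    return ds, structures


@pytest.fixture(scope="session")
def rmsd200(study200):
    ds, structures = study200
    return t.build_distance_matrix(ds.unique_peptides, "rmsd",
                                   structures=structures)


@pytest.fixture(scope="session")
def lev200(study200):
    ds, _ = study200
    return t.build_distance_matrix(ds.unique_peptides, "levenshtein")


@pytest.fixture()
def tiny_dataset():
    """Six records over three peptides, both labels present."""
    recs = [
        t.InteractionRecord("GILGFVFTL", "CASSLGF", label=1),
        t.InteractionRecord("GILGFVFTL", "CASSQETF", label=0),
        t.InteractionRecord("NLVPMVATV", "CASSLGF", label=1),
        t.InteractionRecord("NLVPMVATV", "CASRDSF", label=1),
        t.InteractionRecord("ELAGIGILTV", "CASSIRSSF", label=0),
        t.InteractionRecord("ELAGIGILTV", "CASSPGTF", label=1),
    ]
    return t.InteractionDataset.from_records(recs)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
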