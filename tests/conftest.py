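"""Shared fixtures: small hand-built alignments and a seeded simulated
study-scale dataset reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from barcodeid.core import AlignedDataset, AlignedSequence, RegionAnnotation
from barcodeid.distances import DistanceMatrix
from barcodeid.simulate import simulate_dataset, study_profile


def make_matrix(ids, entries, default=0.08, sites=100) -> DistanceMatrix:
    """Symmetric DistanceMatrix from a dict {(id_a, id_b): distance}."""
    n = len(ids)
    d = np.full((n, n), float(default))
    np.fill_diagonal(d, 0.0)
    idx = {s: i for i, s in enumerate(ids)}
    for (a, b), v in entries.items():
        d[idx[a], idx[b]] = d[idx[b], idx[a]] = float(v)
    return DistanceMatrix(tuple(ids), d, np.full((n, n), sites, dtype=int))


@pytest.fixture(scope="session")
def study_sim():
    """Study-profile simulation with outgroup: (dataset, species_map)."""
    return simulate_dataset(study_profile(seed=1, include_outgroup=True))


@pytest.fixture(scope="session")
def study_ingroup(study_sim):
    dataset, species_map = study_sim
    ids = [i for i in dataset.ids if not i.startswith("M_domestica")]
    return dataset.subset(ids)


@pytest.fixture
def toy_dataset() -> AlignedDataset:
    """Two species x two sequences, 20 columns, one annotated region."""
    rows = [
        ("a1", "spA", "ACGTACGTACGTACGTACGT"),
        ("a2", "spA", "ACGTACGTACGTACGTACGT"),
        ("b1", "spB", "ACGTACGTACATACGTACAT"),
        ("b2", "spB", "ACGTACGTACATACGTACAT"),
    ]
    return AlignedDataset(
        tuple(AlignedSequence(*r) for r in rows),
        regions=(RegionAnnotation("left", 1, 10),
                 RegionAnnotation("right", 11, 20)),
    )
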