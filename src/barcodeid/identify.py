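"""Identification-success criteria: Best Match, Best Close Match,
All Species Barcodes.

Every sequence in turn serves as a query against all remaining sequences
(self excluded). Under Best Match (BM) the query takes the species of its
nearest neighbour(s); an exact tie spanning several species is ambiguous.
Best Close Match (BCM) additionally requires the best match to lie within a
distance threshold — conventionally the 95th percentile of all conspecific
pairwise distances — otherwise the query is unidentified (``no_match``).
All Species Barcodes (ASB) inspects *every* sequence within the threshold
and is correct only when all of them are conspecific with the query.

``compat_singleton_ambiguous`` reproduces the behaviour of the classic
SpeciesIdentifier/TaxonDNA ASB scoring, in which a candidate set holding
exactly one conspecific (the query's species has no other representative
within the threshold, as happens for two-member species) is scored
ambiguous rather than correct. The rule is exposed as an explicit flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np

from barcodeid.core import AlignedDataset
from barcodeid.distances import DistanceMatrix, distance_matrix

Criterion = Literal["BM", "BCM", "ASB"]
Category = Literal["correct", "ambiguous", "incorrect", "no_match"]

CATEGORIES: tuple[Category, ...] = ("correct", "ambiguous", "incorrect",
                                    "no_match")


@dataclass(frozen=True)
class IdentificationResult:
    query_id: str
    criterion: Criterion
    category: Category
    best_distance: float
    matched_species: frozenset[str]


def compute_threshold(matrix: DistanceMatrix,
                      species_map: Mapping[str, str],
                      percentile: float = 95.0) -> float:
    """Distance threshold from the conspecific pairwise distance
    distribution: the given percentile, linearly interpolated."""
    values: list[float] = []
    ids = matrix.ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if species_map[ids[i]] == species_map[ids[j]]:
                v = float(matrix.d[i, j])
                if not math.isnan(v):
                    values.append(v)
    if not values:
        raise ValueError("no intraspecific pairwise distances: "
                         "every species is a singleton")
    return float(np.percentile(values, percentile))


def _neighbour_distances(query_id: str, matrix: DistanceMatrix):
    qi = matrix.index(query_id)
    others = [(j, float(matrix.d[qi, j]))
              for j in range(len(matrix.ids)) if j != qi]
    defined = [(j, v) for j, v in others if not math.isnan(v)]
    if not defined:
        raise ValueError(f"query {query_id!r} has no defined distance "
                         "to any other sequence")
    return defined


def _classify(query_species: str,
              candidate_species: frozenset[str]) -> Category:
    if candidate_species == {query_species}:
        return "correct"
    if query_species in candidate_species:
        return "ambiguous"
    return "incorrect"


def best_match(query_id: str, matrix: DistanceMatrix,
               species_map: Mapping[str, str]) -> IdentificationResult:
    """Best Match: species of the nearest non-self sequence(s).

    The match set is every sequence attaining the minimal distance (exact
    tie on the full-precision value).
    """
    defined = _neighbour_distances(query_id, matrix)
    best = min(v for _, v in defined)
    matched = frozenset(species_map[matrix.ids[j]]
                        for j, v in defined if v == best)
    return IdentificationResult(
        query_id, "BM", _classify(species_map[query_id], matched),
        best, matched)


def best_close_match(query_id: str, matrix: DistanceMatrix,
                     species_map: Mapping[str, str],
                     threshold: float) -> IdentificationResult:
    """Best Close Match: Best Match, unless the best distance exceeds the
    threshold, in which case the query is unidentified."""
    bm = best_match(query_id, matrix, species_map)
    if bm.best_distance > threshold:
        return IdentificationResult(query_id, "BCM", "no_match",
                                    bm.best_distance, frozenset())
    return IdentificationResult(query_id, "BCM", bm.category,
                                bm.best_distance, bm.matched_species)


def all_species_barcodes(query_id: str, matrix: DistanceMatrix,
                         species_map: Mapping[str, str],
                         threshold: float,
                         compat_singleton_ambiguous: bool = True,
                         ) -> IdentificationResult:
    """All Species Barcodes: consider every sequence within the threshold."""
    defined = _neighbour_distances(query_id, matrix)
    best = min(v for _, v in defined)
    candidates = [(j, v) for j, v in defined if v <= threshold]
    if not candidates:
        return IdentificationResult(query_id, "ASB", "no_match", best,
                                    frozenset())
    query_species = species_map[query_id]
    cand_species = frozenset(species_map[matrix.ids[j]]
                             for j, _ in candidates)
    category = _classify(query_species, cand_species)
    if (category == "correct" and compat_singleton_ambiguous
            and sum(1 for j, _ in candidates
                    if species_map[matrix.ids[j]] == query_species) == 1):
        category = "ambiguous"
    return IdentificationResult(query_id, "ASB", category, best,
                                cand_species)


@dataclass(frozen=True)
class IdentificationSummary:
    """Aggregate identification-success report.

    Counts and percentages per criterion and category; percentages are
    relative to ``n_sequences`` and printed with standard rounding to two
    decimals.
    """

    n_sequences: int
    n_with_conspecific: int
    n_closest_at_zero: int
    n_allospecific_at_zero: int
    threshold: float
    percentile: float
    compat_singleton_ambiguous: bool
    counts: dict[Criterion, dict[Category, int]]
    results: dict[Criterion, tuple[IdentificationResult, ...]]

    def percentages(self) -> dict[Criterion, dict[Category, float]]:
        return {
            crit: {cat: 100.0 * n / self.n_sequences
                   for cat, n in cats.items()}
            for crit, cats in self.counts.items()
        }

    def to_dict(self) -> dict:
        pct = self.percentages()
        return {
            "n_sequences": self.n_sequences,
            "n_with_conspecific": self.n_with_conspecific,
            "n_closest_at_zero": self.n_closest_at_zero,
            "n_allospecific_at_zero": self.n_allospecific_at_zero,
            "threshold_pct": round(100.0 * self.threshold, 2),
            "threshold": self.threshold,
            "percentile": self.percentile,
            "compat_singleton_ambiguous": self.compat_singleton_ambiguous,
            "criteria": {
                crit: {cat: {"count": self.counts[crit][cat],
                             "pct": round(pct[crit][cat], 2)}
                       for cat in CATEGORIES}
                for crit in self.counts
            },
        }

    def to_text(self) -> str:
        pct = self.percentages()
        lines = [
            f"No. of sequences\t{self.n_sequences}",
            "No. of sequences with at least 1 matching conspecific "
            f"sequence\t{self.n_with_conspecific}",
            f"No. of sequences with closest match at 0% difference\t"
            f"{self.n_closest_at_zero}",
            f"No. of allospecific matches at 0% difference\t"
            f"{self.n_allospecific_at_zero}",
            f"Calculated threshold\t{100.0 * self.threshold:.2f}%",
        ]
        names = {"correct": "Correct identifications",
                 "ambiguous": "Ambiguous identifications",
                 "incorrect": "Incorrect identifications",
                 "no_match": "No match closer than the calculated threshold"}
        for crit in ("BM", "BCM", "ASB"):
            lines.append(crit)
            cats = CATEGORIES if crit != "BM" else CATEGORIES[:3]
            for cat in cats:
                lines.append(f"  {names[cat]}\t"
                             f"{pct[crit][cat]:.2f}% "
                             f"({self.counts[crit][cat]})")
        return "\n".join(lines) + "\n"


def identification_summary(dataset: AlignedDataset | None,
                           species_map: Mapping[str, str] | None = None,
                           percentile: float = 95.0,
                           threshold: float | None = None,
                           compat_singleton_ambiguous: bool = True,
                           matrix: DistanceMatrix | None = None,
                           ) -> IdentificationSummary:
    """Run BM, BCM and ASB over every sequence as query and aggregate.

    Works from an aligned dataset, or directly from a precomputed distance
    matrix plus species map.
    """
    if dataset is None and (matrix is None or species_map is None):
        raise ValueError("need a dataset, or a matrix plus species map")
    species_map = dict(species_map or dataset.species_map)
    if matrix is None:
        matrix = distance_matrix(dataset)
    if threshold is None:
        threshold = compute_threshold(matrix, species_map, percentile)

    counts: dict[Criterion, dict[Category, int]] = {
        crit: {cat: 0 for cat in CATEGORIES} for crit in ("BM", "BCM", "ASB")}
    results: dict[Criterion, list[IdentificationResult]] = {
        "BM": [], "BCM": [], "ASB": []}
    n_with_conspecific = 0
    n_closest_at_zero = 0
    n_allospecific_at_zero = 0

    ids = matrix.ids
    for qi, query_id in enumerate(ids):
        sp = species_map[query_id]
        if any(species_map[o] == sp for o in ids if o != query_id):
            n_with_conspecific += 1
        bm = best_match(query_id, matrix, species_map)
        bcm = best_close_match(query_id, matrix, species_map, threshold)
        asb = all_species_barcodes(query_id, matrix, species_map, threshold,
                                   compat_singleton_ambiguous)
        if bm.best_distance == 0.0:
            n_closest_at_zero += 1
        n_allospecific_at_zero += sum(
            1 for j in range(len(ids))
            if j != qi and matrix.d[qi, j] == 0.0
            and species_map[ids[j]] != sp)
        for res in (bm, bcm, asb):
            counts[res.criterion][res.category] += 1
            results[res.criterion].append(res)

    # each allospecific zero-distance pair was seen from both ends
    n_allospecific_at_zero //= 2

    return IdentificationSummary(
        n_sequences=len(ids),
        n_with_conspecific=n_with_conspecific,
        n_closest_at_zero=n_closest_at_zero,
        n_allospecific_at_zero=n_allospecific_at_zero,
        threshold=threshold,
        percentile=percentile,
        compat_singleton_ambiguous=compat_singleton_ambiguous,
        counts=counts,
        results={k: tuple(v) for k, v in results.items()},
    )
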