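"""Region-wise variability analytics.

Covers the descriptive statistics reported for partitioned mitochondrial
barcode alignments: intergenic-spacer indel patterns per species,
reference-masked variable-position tables (the ``*`` = same-as-reference
convention), substitution typing, site classes (constant / variable /
parsimony-informative) and mean base composition.

Gaps never count as a character state for variability or informativeness;
indels are treated separately through the spacer pattern table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from barcodeid.core import BASES, AlignedDataset, extract_region

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def substitution_type(base_a: str, base_b: str) -> str:
    """Classify a base pair: ``identical``, ``transition`` or
    ``transversion``. Only unambiguous bases are accepted."""
    a, b = base_a.upper(), base_b.upper()
    for x in (a, b):
        if x not in BASES:
            raise ValueError(f"not an unambiguous base: {x!r}")
    if a == b:
        return "identical"
    if (a in _PURINES) == (b in _PURINES):
        return "transition"
    return "transversion"


def _sub_alignment(dataset: AlignedDataset,
                   region: str | None) -> AlignedDataset:
    return extract_region(dataset, region) if region else dataset


# ---------------------------------------------------------------------------
# spacer indel patterns

@dataclass(frozen=True)
class SpacerPatternTable:
    """Aligned spacer rows per species with ungapped lengths and the
    grouping of identical patterns across species."""

    region_name: str
    start: int                       # original 1-based coordinate
    width: int
    patterns: dict[str, str]         # species -> aligned row (with '-')
    ungapped_lengths: dict[str, int]
    shared: dict[str, tuple[str, ...]]  # pattern -> species sharing it

    def to_dataframe(self) -> pd.DataFrame:
        cols = [str(self.start + k) for k in range(self.width)]
        rows = [
            {"species": sp, **dict(zip(cols, pat)),
             "ungapped_length": self.ungapped_lengths[sp]}
            for sp, pat in self.patterns.items()
        ]
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def spacer_pattern_table(dataset: AlignedDataset,
                         region: str | None = "spacer",
                         collapse_to_species: bool = True,
                         ) -> SpacerPatternTable:
    """Per-species indel/nucleotide patterns of a (spacer) region.

    When collapsing to species, all conspecific rows must be identical in
    the region; a conflict raises an error listing the sequences involved.
    """
    sub = _sub_alignment(dataset, region)
    patterns: dict[str, str] = {}
    first_seq: dict[str, str] = {}
    for seq in sub.sequences:
        key = seq.species if collapse_to_species else seq.seq_id
        if key in patterns:
            if patterns[key] != seq.residues:
                raise ValueError(
                    f"species {seq.species!r} has conflicting spacer "
                    f"patterns: {first_seq[key]!r} ({patterns[key]}) vs "
                    f"{seq.seq_id!r} ({seq.residues})")
        else:
            patterns[key] = seq.residues
            first_seq[key] = seq.seq_id

    shared: dict[str, list[str]] = {}
    for key, pat in patterns.items():
        shared.setdefault(pat, []).append(key)
    return SpacerPatternTable(
        region_name=sub.regions[0].name if sub.regions else "alignment",
        start=sub.origin,
        width=sub.length,
        patterns=patterns,
        ungapped_lengths={k: len(p.replace("-", ""))
                          for k, p in patterns.items()},
        shared={p: tuple(sps) for p, sps in shared.items()},
    )


# ---------------------------------------------------------------------------
# reference-masked variability table

SAME_AS_REFERENCE = "*"


@dataclass(frozen=True)
class VariabilityTable:
    """Variable columns of a region with residues masked against a
    reference species (``*`` marks identity with the reference)."""

    reference_species: str
    columns: tuple[int, ...]             # original 1-based coordinates
    reference_row: dict[int, str]        # column -> reference residue
    rows: dict[str, dict[int, str]]      # species -> column -> residue or '*'

    def residues(self, species: str) -> dict[int, str]:
        """Unmasked residues of one species at the variable columns."""
        if species == self.reference_species:
            return dict(self.reference_row)
        return {col: (self.reference_row[col] if ch == SAME_AS_REFERENCE
                      else ch)
                for col, ch in self.rows[species].items()}

    def differences(self, species: str) -> dict[int, tuple[str, str]]:
        """Columns where a species differs from the reference, as
        (reference base, species base)."""
        res = self.residues(species)
        return {col: (self.reference_row[col], res[col])
                for col in self.columns
                if res[col] != self.reference_row[col]
                and res[col] in BASES and self.reference_row[col] in BASES}

    def to_dataframe(self) -> pd.DataFrame:
        cols = [str(c) for c in self.columns]
        rows = [{"species": self.reference_species,
                 **{str(c): self.reference_row[c] for c in self.columns}}]
        rows += [{"species": sp, **{str(c): r[c] for c in self.columns}}
                 for sp, r in self.rows.items()]
        return pd.DataFrame(rows, columns=["species", *cols])

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def variability_table(dataset: AlignedDataset,
                      region: str | None,
                      reference_species: str) -> VariabilityTable:
    """Variable positions of a region, masked against a reference species.

    A column is variable when it shows at least two distinct unambiguous
    non-gap states. Coordinates are reported in the original alignment
    numbering. One row per species (first sequence of each species).
    """
    sub = _sub_alignment(dataset, region)
    species_rows: dict[str, str] = {}
    for seq in sub.sequences:
        species_rows.setdefault(seq.species, seq.residues)
    if reference_species not in species_rows:
        raise ValueError(f"reference species {reference_species!r} "
                         "not present in dataset")

    variable: list[int] = []
    for k in range(sub.length):
        states = {row[k] for row in species_rows.values()} & BASES
        if len(states) >= 2:
            variable.append(k)

    columns = tuple(sub.origin + k for k in variable)
    ref = species_rows[reference_species]
    reference_row = {sub.origin + k: ref[k] for k in variable}
    rows = {
        sp: {sub.origin + k: (SAME_AS_REFERENCE if row[k] == ref[k]
                              else row[k])
             for k in variable}
        for sp, row in species_rows.items() if sp != reference_species
    }
    return VariabilityTable(reference_species, columns, reference_row, rows)


# ---------------------------------------------------------------------------
# site classes and composition

@dataclass(frozen=True)
class SiteClassReport:
    """Counts of constant / variable / parsimony-informative columns and
    mean base composition (percent, unweighted mean over sequences)."""

    length: int
    n_sequences: int
    constant_sites: int
    variable_sites: int
    parsimony_informative_sites: int
    composition_pct: dict[str, float]   # base -> percent

    def to_dict(self) -> dict:
        return {
            "length": self.length,
            "n_sequences": self.n_sequences,
            "constant_sites": self.constant_sites,
            "variable_sites": self.variable_sites,
            "parsimony_informative_sites": self.parsimony_informative_sites,
            "composition_pct": {b: round(p, 1)
                                for b, p in self.composition_pct.items()},
        }


def site_classes(dataset: AlignedDataset) -> SiteClassReport:
    """Classify every column and average base composition.

    Per column, only unambiguous non-gap residues are considered: the column
    is variable with >= 2 distinct states, and parsimony-informative with
    >= 2 states each carried by >= 2 sequences. Composition is the
    unweighted mean over sequences of each base's share of that sequence's
    unambiguous residues.
    """
    if len(dataset.sequences) < 2:
        raise ValueError("need at least 2 sequences")
    rows = [s.residues for s in dataset.sequences]
    variable = informative = constant = 0
    for k in range(dataset.length):
        counts: dict[str, int] = {}
        for row in rows:
            ch = row[k]
            if ch in BASES:
                counts[ch] = counts.get(ch, 0) + 1
        if len(counts) >= 2:
            variable += 1
            if sum(1 for c in counts.values() if c >= 2) >= 2:
                informative += 1
        elif counts:
            constant += 1

    per_seq = []
    for row in rows:
        n = {b: row.count(b) for b in "ACGT"}
        total = sum(n.values())
        if total:
            per_seq.append([100.0 * n[b] / total for b in "ACGT"])
    mean = np.mean(per_seq, axis=0) if per_seq else np.zeros(4)
    return SiteClassReport(
        length=dataset.length,
        n_sequences=len(rows),
        constant_sites=constant,
        variable_sites=variable,
        parsimony_informative_sites=informative,
        composition_pct=dict(zip("ACGT", (float(x) for x in mean))),
    )
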