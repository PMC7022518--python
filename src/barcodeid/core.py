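"""Data model and I/O for aligned barcode datasets.

An :class:`AlignedDataset` holds equal-length nucleotide rows (IUPAC codes,
``N`` and ``-`` allowed), a species label per sequence, and a set of named,
non-overlapping region annotations with 1-based inclusive coordinates — the
convention used throughout mitochondrial barcoding work (e.g. a COI-COII
alignment partitioned as COI 1–1495, tRNA-leu 1496–1561, spacer 1562–1568,
COII 1569–2218).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Unambiguous bases.
BASES = frozenset("ACGT")

#: IUPAC ambiguity codes (everything that is neither an unambiguous base,
#: ``N`` nor a gap).
AMBIGUITY_CODES = frozenset("RYSWKMBDHV")

#: Full residue alphabet accepted in an alignment row.
ALPHABET = BASES | AMBIGUITY_CODES | frozenset("N-")


class RaggedAlignmentError(ValueError):
    """Raised when rows of an alignment differ in length."""


class SpeciesMapError(ValueError):
    """Raised when sequence IDs cannot be resolved to species labels."""


def normalize_residues(residues: str) -> str:
    """Upper-case a residue string and map ``U``→``T``.

    Raises ``ValueError`` naming the first illegal character and its 1-based
    position.
    """
    norm = residues.upper().replace("U", "T")
    for pos, ch in enumerate(norm, start=1):
        if ch not in ALPHABET:
            raise ValueError(f"illegal residue {ch!r} at position {pos}")
    return norm


@dataclass(frozen=True)
class AlignedSequence:
    """One row of an alignment: unique ID, species label, residues."""

    seq_id: str
    species: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.seq_id}: empty residue string")
        object.__setattr__(self, "residues", normalize_residues(self.residues))

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class RegionAnnotation:
    """Named alignment region, 1-based inclusive coordinates."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"region {self.name!r}: need 1 <= start <= end, "
                             f"got {self.start}..{self.end}")

    @property
    def width(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class AlignedDataset:
    """Equal-length aligned sequences with species labels and regions.

    ``origin`` records the original 1-based coordinate of column 1, so that a
    sub-alignment cut out of a larger one can still report positions in the
    parent's numbering (``origin`` is 1 for a freshly read alignment).
    """

    sequences: tuple[AlignedSequence, ...]
    regions: tuple[RegionAnnotation, ...] = ()
    origin: int = 1

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("dataset needs at least one sequence")
        object.__setattr__(self, "sequences", tuple(self.sequences))
        object.__setattr__(self, "regions", tuple(self.regions))
        length = len(self.sequences[0])
        for seq in self.sequences:
            if len(seq) != length:
                raise RaggedAlignmentError(
                    f"sequence {seq.seq_id!r} has length {len(seq)}, "
                    f"expected {length}")
        seen: set[str] = set()
        for seq in self.sequences:
            if seq.seq_id in seen:
                raise ValueError(f"duplicate seq_id {seq.seq_id!r}")
            seen.add(seq.seq_id)
        spans = sorted((r.start, r.end, r.name) for r in self.regions)
        for (s, e, n) in spans:
            if e > length:
                raise ValueError(f"region {n!r} ends at {e}, beyond "
                                 f"alignment length {length}")
        for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"regions {n1!r} and {n2!r} overlap")

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.sequences[0])

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(s.seq_id for s in self.sequences)

    @property
    def species_map(self) -> dict[str, str]:
        return {s.seq_id: s.species for s in self.sequences}

    @property
    def species_order(self) -> tuple[str, ...]:
        """Distinct species labels in order of first appearance."""
        out: list[str] = []
        for s in self.sequences:
            if s.species not in out:
                out.append(s.species)
        return tuple(out)

    def region(self, name: str) -> RegionAnnotation:
        for r in self.regions:
            if r.name == name:
                return r
        known = ", ".join(r.name for r in self.regions) or "<none>"
        raise KeyError(f"unknown region {name!r}; known regions: {known}")

    def get(self, seq_id: str) -> AlignedSequence:
        for s in self.sequences:
            if s.seq_id == seq_id:
                return s
        raise KeyError(f"unknown seq_id {seq_id!r}")

    def subset(self, ids: Iterable[str]) -> "AlignedDataset":
        """Sub-dataset containing only ``ids``, in dataset order."""
        keep = set(ids)
        seqs = tuple(s for s in self.sequences if s.seq_id in keep)
        missing = keep - {s.seq_id for s in seqs}
        if missing:
            raise KeyError(f"unknown seq_ids: {sorted(missing)}")
        return replace(self, sequences=seqs)


def default_regions(length: int = 2218) -> tuple[RegionAnnotation, ...]:
    """The standard four-region COI-COII partition.

    COI 1–1495, tRNA-leu 1496–1561, spacer 1562–1568, COII 1569–``length``.
    Only defined for alignments of at least 1569 columns.
    """
    if length < 1569:
        raise ValueError("default partition requires >= 1569 columns")
    return (
        RegionAnnotation("COI", 1, 1495),
        RegionAnnotation("tRNA-leu", 1496, 1561),
        RegionAnnotation("spacer", 1562, 1568),
        RegionAnnotation("COII", 1569, length),
    )


def read_regions_json(path: str | Path) -> tuple[RegionAnnotation, ...]:
    """Read a region annotation file: JSON list of {name, start, end}."""
    entries = json.loads(Path(path).read_text())
    return tuple(RegionAnnotation(e["name"], int(e["start"]), int(e["end"]))
                 for e in entries)


def write_regions_json(regions: Sequence[RegionAnnotation],
                       path: str | Path) -> None:
    Path(path).write_text(json.dumps(
        [{"name": r.name, "start": r.start, "end": r.end} for r in regions],
        indent=2) + "\n")


def read_species_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV ``seq_id<TAB>species``."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise SpeciesMapError(
                f"{path}:{lineno}: expected 2 tab-separated columns")
        seq_id, species = (p.strip() for p in parts)
        if not species:
            raise SpeciesMapError(f"{path}:{lineno}: empty species label")
        mapping[seq_id] = species
    return mapping


def write_species_map(mapping: Mapping[str, str], path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{k}\t{v}\n" for k, v in mapping.items()))


def read_fasta_alignment(
    path: str | Path,
    species_map_path: str | Path | None = None,
    regions: Sequence[RegionAnnotation] | None = None,
) -> AlignedDataset:
    """Read an aligned FASTA into an :class:`AlignedDataset`.

    Species labels come from the TSV map when given; otherwise from the
    header convention ``id|species``. An explicit TSV overrides the header.
    Rows of unequal length raise :class:`RaggedAlignmentError` naming the
    offending record; IDs absent from the map raise
    :class:`SpeciesMapError` listing them.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    mapping = read_species_map(species_map_path) if species_map_path else None

    seqs: list[AlignedSequence] = []
    missing: list[str] = []
    length = len(records[0].seq)
    for rec in records:
        seq_id, _, header_species = rec.id.partition("|")
        if len(rec.seq) != length:
            raise RaggedAlignmentError(
                f"record {seq_id!r} has length {len(rec.seq)}, "
                f"expected {length}")
        if mapping is not None and seq_id in mapping:
            species = mapping[seq_id]
        elif header_species:
            species = header_species
        else:
            missing.append(seq_id)
            species = ""
        try:
            seqs.append(AlignedSequence(seq_id, species, str(rec.seq)))
        except ValueError as exc:
            raise ValueError(f"record {seq_id!r}: {exc}") from exc
    if missing:
        raise SpeciesMapError(f"no species label for seq_ids: {missing}")
    return AlignedDataset(tuple(seqs), tuple(regions or ()))


def write_fasta_alignment(dataset: AlignedDataset, path: str | Path,
                          encode_species: bool = True) -> None:
    """Write the dataset as sequential FASTA, headers ``id|species``."""
    records = [
        SeqRecord(Seq(s.residues),
                  id=f"{s.seq_id}|{s.species}" if encode_species else s.seq_id,
                  description="")
        for s in dataset.sequences
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta-2line")


def extract_region(dataset: AlignedDataset,
                   region_name: str) -> AlignedDataset:
    """Cut out one annotated region as a sub-alignment.

    The sub-alignment's columns are re-based to 1; the original coordinates
    remain recoverable through ``origin`` (original position of column 1).
    """
    region = dataset.region(region_name)
    lo, hi = region.start - 1, region.end  # python slice
    seqs = tuple(
        AlignedSequence(s.seq_id, s.species, s.residues[lo:hi])
        for s in dataset.sequences)
    return AlignedDataset(
        seqs,
        regions=(RegionAnnotation(region.name, 1, region.width),),
        origin=dataset.origin + region.start - 1,
    )
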