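"""Kimura 2-parameter distances and divergence summaries.

The K2P model corrects observed divergence separately for transitions
(purine<->purine, pyrimidine<->pyrimidine) and transversions::

    d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

where P and Q are the proportions of compared sites differing by a
transition and a transversion. Sites where either sequence carries a gap,
``N`` or an IUPAC ambiguity code are excluded pair by pair (pairwise
deletion). When the logarithm argument is non-positive (saturation) or no
sites are comparable, the distance is undefined and reported as NaN — never
silently zero.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from barcodeid.core import AlignedDataset

#: Marker for undefined (saturated / incomparable) distances.
UNDEFINED = float("nan")

# Residue codes: A=0, G=1 (purines), C=2, T=3 (pyrimidines); 255 = missing.
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("AGCT"):
    _CODE[ord(_b)] = _i


def encode(residues: str) -> np.ndarray:
    """Encode a residue string as uint8 codes (255 for gap/N/ambiguity)."""
    return _CODE[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]


def count_site_patterns(row_a: str | np.ndarray,
                        row_b: str | np.ndarray) -> tuple[int, int, int]:
    """Return (transitions, transversions, sites compared) for a pair."""
    a = encode(row_a) if isinstance(row_a, str) else row_a
    b = encode(row_b) if isinstance(row_b, str) else row_b
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    ok = (a != 255) & (b != 255)
    a, b = a[ok], b[ok]
    diff = a != b
    ts = int(np.count_nonzero(diff & ((a >> 1) == (b >> 1))))
    total = int(np.count_nonzero(diff))
    return ts, total - ts, int(a.size)


def k2p_from_counts(ts: int, tv: int, sites: int) -> float:
    """K2P distance from transition/transversion/site counts (NaN if undefined)."""
    if sites == 0:
        return UNDEFINED
    p, q = ts / sites, tv / sites
    w1, w2 = 1.0 - 2.0 * p - q, 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return UNDEFINED
    return -0.5 * math.log(w1 * math.sqrt(w2))


def k2p_distance(row_a: str, row_b: str) -> tuple[float, int]:
    """K2P distance (proportion) and sites compared for two aligned rows."""
    ts, tv, sites = count_site_patterns(row_a, row_b)
    return k2p_from_counts(ts, tv, sites), sites


def p_distance(row_a: str, row_b: str) -> tuple[float, int]:
    """Uncorrected proportion of differing compared sites."""
    ts, tv, sites = count_site_patterns(row_a, row_b)
    return ((ts + tv) / sites if sites else UNDEFINED), sites


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with per-pair site counts."""

    ids: tuple[str, ...]
    d: np.ndarray       # float, NaN where undefined
    sites: np.ndarray   # int, columns compared per pair

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n) or self.sites.shape != (n, n):
            raise ValueError("matrix shape does not match id count")

    def index(self, seq_id: str) -> int:
        try:
            return self.ids.index(seq_id)
        except ValueError:
            raise KeyError(f"unknown seq_id {seq_id!r}") from None

    def distance(self, id_a: str, id_b: str) -> float:
        return float(self.d[self.index(id_a), self.index(id_b)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=list(self.ids),
                            columns=list(self.ids))

    def write_tsv(self, path: str | Path) -> None:
        """Square TSV with ids as header and index."""
        self.to_dataframe().to_csv(path, sep="\t", float_format="%.8f")

    def write_phylip(self, path: str | Path) -> None:
        """Relaxed PHYLIP distance matrix (full square)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, seq_id in enumerate(self.ids):
                row = " ".join(f"{v:.8f}" for v in self.d[i])
                fh.write(f"{seq_id}  {row}\n")


def distance_matrix(dataset: AlignedDataset) -> DistanceMatrix:
    """Full symmetric K2P matrix over all unordered sequence pairs."""
    if len(dataset.sequences) < 2:
        raise ValueError("need at least 2 sequences")
    codes = [encode(s.residues) for s in dataset.sequences]
    n = len(codes)
    d = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=int)
    full = dataset.length
    for i in range(n):
        sites[i, i] = full
        for j in range(i + 1, n):
            ts, tv, L = count_site_patterns(codes[i], codes[j])
            d[i, j] = d[j, i] = k2p_from_counts(ts, tv, L)
            sites[i, j] = sites[j, i] = L
    return DistanceMatrix(dataset.ids, d, sites)


def _pairs_by_group(ids: Sequence[str], species_map: Mapping[str, str]):
    """Yield (i, j, same_species) over unordered index pairs."""
    labels = []
    for seq_id in ids:
        if seq_id not in species_map:
            raise KeyError(f"seq_id {seq_id!r} has no species label")
        labels.append(species_map[seq_id])
    for i, j in itertools.combinations(range(len(ids)), 2):
        yield i, j, labels[i] == labels[j]


@dataclass(frozen=True)
class DivergenceSummary:
    """Intra-/interspecific divergence summary (Table-4 style, proportions).

    ``intra_values``/``inter_values`` keep the raw pairwise distances so that
    barcode-gap assessment can use extremes rather than means.
    """

    species: tuple[str, ...]
    n_per_species: dict[str, int]
    intra_values: dict[str, np.ndarray]                # per species
    inter_values: dict[tuple[str, str], np.ndarray]    # per unordered pair
    intra_means: dict[str, float | None]               # None for singletons
    inter_means: dict[tuple[str, str], float]

    @property
    def singleton_species(self) -> tuple[str, ...]:
        return tuple(s for s in self.species if self.n_per_species[s] < 2)

    @property
    def all_intra(self) -> np.ndarray:
        vals = [v for v in self.intra_values.values() if v.size]
        return np.concatenate(vals) if vals else np.empty(0)

    @property
    def all_inter(self) -> np.ndarray:
        vals = [v for v in self.inter_values.values() if v.size]
        return np.concatenate(vals) if vals else np.empty(0)

    def extremes(self) -> dict:
        """Global min/max of the intra and inter means with attaining taxa."""
        defined = {s: m for s, m in self.intra_means.items() if m is not None}
        out: dict = {}
        if defined:
            out["min_intra_mean"] = min(defined.items(), key=lambda kv: kv[1])
            out["max_intra_mean"] = max(defined.items(), key=lambda kv: kv[1])
        if self.inter_means:
            out["min_inter_mean"] = min(self.inter_means.items(),
                                        key=lambda kv: kv[1])
            out["max_inter_mean"] = max(self.inter_means.items(),
                                        key=lambda kv: kv[1])
        return out

    def to_table(self) -> pd.DataFrame:
        """Triangular species x species table of mean interspecific
        percentages with N and mean-intra columns (printed to 2 decimals
        in the writer; values here keep full precision)."""
        rows = []
        for i, sp in enumerate(self.species):
            row: dict = {
                "species": sp,
                "N": self.n_per_species[sp],
                "mean_intra_pct": (None if self.intra_means[sp] is None
                                   else 100.0 * self.intra_means[sp]),
            }
            for other in self.species[:i]:
                key = tuple(sorted((sp, other)))
                row[other] = 100.0 * self.inter_means[key]
            rows.append(row)
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_table().to_csv(path, sep="\t", index=False,
                               float_format="%.2f")


def divergence_summary(matrix: DistanceMatrix,
                       species_map: Mapping[str, str],
                       skip_undefined: bool = False) -> DivergenceSummary:
    """Average conspecific and heterospecific pairwise distances.

    Species with a single sequence get no intraspecific mean (``None``).
    Undefined (NaN) distances inside any averaged cell raise unless
    ``skip_undefined`` drops them.
    """
    intra: dict[str, list[float]] = {}
    inter: dict[tuple[str, str], list[float]] = {}
    n_per: dict[str, int] = {}
    order: list[str] = []
    for seq_id in matrix.ids:
        sp = species_map[seq_id]
        if sp not in n_per:
            order.append(sp)
        n_per[sp] = n_per.get(sp, 0) + 1
    for sp in order:
        intra[sp] = []

    for i, j, same in _pairs_by_group(matrix.ids, species_map):
        val = float(matrix.d[i, j])
        sp_i, sp_j = species_map[matrix.ids[i]], species_map[matrix.ids[j]]
        if math.isnan(val):
            if skip_undefined:
                continue
            raise ValueError(
                f"undefined distance between {matrix.ids[i]!r} and "
                f"{matrix.ids[j]!r}; pass skip_undefined=True to drop it")
        if same:
            intra[sp_i].append(val)
        else:
            inter.setdefault(tuple(sorted((sp_i, sp_j))), []).append(val)

    intra_values = {s: np.asarray(v) for s, v in intra.items()}
    inter_values = {k: np.asarray(v) for k, v in inter.items()}
    return DivergenceSummary(
        species=tuple(order),
        n_per_species=n_per,
        intra_values=intra_values,
        inter_values=inter_values,
        intra_means={s: (float(v.mean()) if v.size else None)
                     for s, v in intra_values.items()},
        inter_means={k: float(v.mean()) for k, v in inter_values.items()},
    )


@dataclass(frozen=True)
class BarcodeGapReport:
    """Separation between largest conspecific and smallest heterospecific
    pairwise distance, computed from raw pairwise values (not means)."""

    max_intra: float
    min_inter: float
    gap_present: bool

    @property
    def gap_width(self) -> float:
        return self.min_inter - self.max_intra


def barcode_gap_report(summary: DivergenceSummary) -> BarcodeGapReport:
    intra, inter = summary.all_intra, summary.all_inter
    if intra.size == 0:
        raise ValueError("no intraspecific pairwise values "
                         "(no species with >= 2 sequences)")
    if inter.size == 0:
        raise ValueError("no interspecific pairwise values "
                         "(single-species dataset)")
    max_intra = float(intra.max())
    min_inter = float(inter.min())
    return BarcodeGapReport(max_intra, min_inter, max_intra < min_inter)
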