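"""Seeded synthetic barcode-alignment generator and packaged toy fixtures.

The generator emulates the data regime of a multi-species mitochondrial
barcoding study: a handful of species, a few sequences each, tight
within-species divergence (fractions of a percent), a clean gap to
between-species divergence (several percent), transition-biased
substitution, AT-rich composition, and a short indel-bearing intergenic
spacer whose per-species gap patterns are written verbatim.

Model
-----
A root sequence is drawn i.i.d. from the configured base composition. Each
species ancestor derives from the root, and each individual from its
species ancestor, by mutating a controlled number of sites: for a branch
with per-site hit probability ``p`` the mutation count is
``floor(p*L) + Bernoulli(frac)`` (randomized rounding), positions are
sampled without replacement, and each hit base is replaced through a
two-rate kernel giving the transition a relative weight of ``kappa``
against 1 for each transversion. Divergence targets are expressed as the
*expected observed pairwise difference* (what a distance estimator
consumes); branch hit probabilities are solved from the targets through the
exact per-site Markov expectation, so recovery tests can compare against a
closed-form expectation. Mutation-count dispersion is deliberately low
(only the rounding Bernoulli varies), keeping within-species distances in a
narrow band as observed in curated barcode datasets; see the methods note.

Intraspecific targets may be a single value or one per species; the study
profile (:func:`study_profile`) uses the per-species values observed for
the 14 flesh-fly species together with their sample sizes and spacer
patterns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib.resources import files
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from barcodeid.core import (
    AlignedDataset,
    AlignedSequence,
    RegionAnnotation,
    default_regions,
)
from barcodeid.distances import k2p_from_counts
from barcodeid.regions import substitution_type

# internal base order A, C, G, T; transitions are A<->G and C<->T
_BASES = "ACGT"
_TS_PARTNER = {0: 2, 1: 3, 2: 0, 3: 1}

#: Study sample-size profile: sequences per species, 43 in total.
STUDY_N_PROFILE = (3, 2, 2, 3, 3, 3, 2, 4, 6, 4, 2, 2, 3, 4)

#: Observed per-species mean intraspecific divergence (proportions) used by
#: the study profile; five species show none at all.
STUDY_INTRA_PROFILE = (0.0000, 0.0000, 0.0064, 0.0000, 0.0059, 0.0000,
                       0.0036, 0.0000, 0.0096, 0.0073, 0.0009, 0.0032,
                       0.0064, 0.0036)

STUDY_SPECIES = ("B_nathani", "F_ostindicae", "H_kempi", "L_ruficornis",
                 "L_pattoni", "L_saprianovae", "P_albiceps",
                 "P_brevicornis", "P_dux", "P_misera", "S_antilope",
                 "S_inextricata", "S_seniorwhitei", "S_princeps")

#: AT-rich default composition (A, C, G, T).
DEFAULT_COMPOSITION = (0.319, 0.157, 0.143, 0.381)


def _data_text(name: str) -> str:
    return files("barcodeid").joinpath(f"data/{name}").read_text()


def load_spacer_patterns() -> dict[str, str]:
    """Packaged per-species aligned spacer patterns (columns 1562-1568)."""
    out: dict[str, str] = {}
    for line in _data_text("spacer_patterns.tsv").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        sp, pat = line.split("\t")
        out[sp] = pat
    return out


def _load_trna_variants() -> tuple[tuple[int, ...], dict[str, tuple[str, ...]]]:
    columns = (1502, 1510, 1531, 1534)
    rows: dict[str, tuple[str, ...]] = {}
    for line in _data_text("trna_leu_variants.tsv").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        rows[parts[0]] = tuple(parts[1:])
    return columns, rows


def fixture_tables() -> dict[str, AlignedDataset]:
    """Packaged toy alignments for the spacer and tRNA-leu analytics.

    ``"spacer"``: the 14-species x 7-column intergenic-spacer alignment
    (original columns 1562-1568) with one row per species.

    ``"trna_leu"``: a 14-species x 66-column tRNA-leucine alignment
    (original columns 1496-1561). Only the four genuinely variable columns
    carry real per-species states; the conserved background is a synthetic
    stand-in (see ``data/trna_leu_background.synthetic.txt``).
    """
    spacer_patterns = load_spacer_patterns()
    spacer = AlignedDataset(
        tuple(AlignedSequence(sp, sp, pat)
              for sp, pat in spacer_patterns.items()),
        regions=(RegionAnnotation("spacer", 1, 7),),
        origin=1562,
    )

    background = _data_text("trna_leu_background.synthetic.txt").strip()
    columns, rows = _load_trna_variants()
    ref_species = next(iter(rows))
    ref_states = rows[ref_species]
    seqs = []
    for sp, states in rows.items():
        chars = list(background)
        for col, state, ref in zip(columns, states, ref_states):
            chars[col - 1496] = ref if state == "*" else state
        seqs.append(AlignedSequence(sp, sp, "".join(chars)))
    trna = AlignedDataset(
        tuple(seqs),
        regions=(RegionAnnotation("tRNA-leu", 1, 66),),
        origin=1496,
    )
    return {"spacer": spacer, "trna_leu": trna}


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for a synthetic barcode alignment.

    Divergence targets are expected observed pairwise difference
    proportions over the evolved (non-spacer) columns and must lie in
    [0, 0.5). ``intra_divergence`` is a single value or one per species.
    ``seed`` is mandatory; the generator is NumPy's default PCG64.
    """

    species: tuple[str, ...]
    sample_sizes: tuple[int, ...]
    seed: int
    intra_divergence: float | tuple[float, ...] = 0.005
    inter_divergence: float = 0.08
    kappa: float = 4.0
    composition: tuple[float, float, float, float] = DEFAULT_COMPOSITION
    length: int = 2218
    spacer_start: int = 1562
    spacer_patterns: Mapping[str, str] | None = None
    outgroup_name: str | None = None
    outgroup_n: int = 1
    outgroup_divergence: float = 0.12
    species_tree: Literal["star", "ultrametric"] = "star"
    regions: tuple[RegionAnnotation, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.species) != len(self.sample_sizes):
            raise ValueError("species and sample_sizes lengths differ")
        if any(n < 1 for n in self.sample_sizes):
            raise ValueError("sample sizes must be >= 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if abs(sum(self.composition) - 1.0) > 1e-6:
            raise ValueError("composition must sum to 1")
        for t in (*self.intra_targets, self.inter_divergence):
            if not (0.0 <= t < 0.5):
                raise ValueError(f"divergence target {t} outside [0, 0.5)")
        if self.spacer_patterns is not None:
            widths = {len(p) for p in self.spacer_patterns.values()}
            if len(widths) != 1:
                raise ValueError("spacer patterns must share one width")

    @property
    def intra_targets(self) -> tuple[float, ...]:
        if isinstance(self.intra_divergence, (int, float)):
            return tuple([float(self.intra_divergence)] * len(self.species))
        if len(self.intra_divergence) != len(self.species):
            raise ValueError("per-species intra_divergence length mismatch")
        return tuple(float(t) for t in self.intra_divergence)

    @property
    def spacer_width(self) -> int:
        if self.spacer_patterns is None:
            return 0
        return len(next(iter(self.spacer_patterns.values())))

    @property
    def evolved_length(self) -> int:
        return self.length - self.spacer_width

    @property
    def n_sequences(self) -> int:
        return int(sum(self.sample_sizes))

    def species_pattern(self, index: int) -> str | None:
        """Aligned spacer pattern for the index-th lineage (species by
        position, outgroup with index = n_species), cycling the pattern
        list when there are more lineages than patterns."""
        if self.spacer_patterns is None:
            return None
        pats = list(self.spacer_patterns.values())
        return pats[index % len(pats)]

    def lineage_pattern(self, species: str, index: int) -> str | None:
        if self.spacer_patterns is None:
            return None
        return self.spacer_patterns.get(species, self.species_pattern(index))


def study_profile(seed: int, include_outgroup: bool = False,
                  **overrides) -> SimulationConfig:
    """The study conditions: 14 flesh-fly species, 43 sequences, observed
    per-species intraspecific divergence, 8% interspecific target, the real
    spacer patterns, full 2218-column layout, and optionally a house-fly
    outgroup at 12% divergence."""
    cfg = SimulationConfig(
        species=STUDY_SPECIES,
        sample_sizes=STUDY_N_PROFILE,
        seed=seed,
        intra_divergence=STUDY_INTRA_PROFILE,
        inter_divergence=0.08,
        spacer_patterns=load_spacer_patterns(),
        outgroup_name="M_domestica" if include_outgroup else None,
    )
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# exact per-site expectations

def _kernel(kappa: float) -> np.ndarray:
    k = np.zeros((4, 4))
    for x in range(4):
        for y in range(4):
            if x == y:
                continue
            k[x, y] = kappa if _TS_PARTNER[x] == y else 1.0
        k[x] /= k[x].sum()
    return k


def _branch_matrix(p: float, kappa: float) -> np.ndarray:
    return (1.0 - p) * np.eye(4) + p * _kernel(kappa)


def _pair_site_probs(branches_a: Sequence[float], branches_b: Sequence[float],
                     kappa: float, pi: Sequence[float],
                     ) -> tuple[float, float]:
    """Per-site probabilities (transition-pair, transversion-pair) between
    two lineages descending from a common base drawn from ``pi``, each
    lineage passing through its listed branch hit probabilities."""
    ta = np.eye(4)
    for p in branches_a:
        ta = ta @ _branch_matrix(p, kappa)
    tb = np.eye(4)
    for p in branches_b:
        tb = tb @ _branch_matrix(p, kappa)
    joint = ta.T @ np.diag(np.asarray(pi, dtype=float)) @ tb
    p_same = float(np.trace(joint))
    p_ts = float(joint[0, 2] + joint[2, 0] + joint[1, 3] + joint[3, 1])
    return p_ts, 1.0 - p_same - p_ts


def _pair_diff(branches_a, branches_b, kappa, pi) -> float:
    ts, tv = _pair_site_probs(branches_a, branches_b, kappa, pi)
    return ts + tv


def _solve_branch_p(target: float, diff_of_p, what: str) -> float:
    """Invert a monotone-on-[0, 2/3] expected-difference function."""
    if target <= 0.0:
        return 0.0
    hi = 2.0 / 3.0
    if target >= diff_of_p(hi) - 1e-12:
        raise ValueError(
            f"infeasible {what} divergence target {target}: exceeds the "
            "saturation bound of the substitution process")
    return float(brentq(lambda p: diff_of_p(p) - target, 0.0, hi,
                        xtol=1e-14))


@dataclass(frozen=True)
class ExpectedStats:
    """Closed-form expectations for a (star-tree) simulated dataset, on the
    scale a distance analysis measures them: pairwise-deletion proportions
    over all comparable columns, spacer included."""

    intra_p: dict[str, float]                  # expected p-distance
    intra_k2p: dict[str, float]
    inter_p: dict[tuple[str, str], float]
    inter_k2p: dict[tuple[str, str], float]
    mean_intra_p: float
    mean_intra_k2p: float
    mean_inter_p: float
    mean_inter_k2p: float


def _spacer_pair_counts(pat_a: str | None,
                        pat_b: str | None) -> tuple[int, int, int]:
    """(ts, tv, comparable columns) contributed by the spacer patterns."""
    if pat_a is None or pat_b is None:
        return 0, 0, 0
    ts = tv = comp = 0
    for a, b in zip(pat_a, pat_b):
        if a == "-" or b == "-":
            continue
        comp += 1
        kind = substitution_type(a, b)
        ts += kind == "transition"
        tv += kind == "transversion"
    return ts, tv, comp


def _branch_probs(config: SimulationConfig) -> tuple[list[float], float,
                                                     float | None]:
    """Solve per-species individual-branch and the ancestor-branch hit
    probabilities (and the outgroup branch) from the divergence targets."""
    kappa, pi = config.kappa, config.composition
    p_ind = [
        _solve_branch_p(t, lambda p: _pair_diff([p], [p], kappa, pi),
                        f"intraspecific ({sp})")
        for sp, t in zip(config.species, config.intra_targets)
    ]

    weights = np.array([na * nb
                        for i, na in enumerate(config.sample_sizes)
                        for nb in config.sample_sizes[i + 1:]])

    def mean_inter(ps: float) -> float:
        vals = [
            _pair_diff([ps, p_ind[i]], [ps, p_ind[j]], kappa, pi)
            for i in range(len(config.species))
            for j in range(i + 1, len(config.species))
        ]
        return float(np.average(vals, weights=weights))

    # an inter target at or below the intra-noise floor (overlap regime)
    # clamps the ancestor branch to zero: species become indistinguishable
    if config.inter_divergence <= mean_inter(0.0):
        p_anc = 0.0
    else:
        p_anc = _solve_branch_p(config.inter_divergence, mean_inter,
                                "interspecific")

    p_out = None
    if config.outgroup_name is not None:
        n = np.asarray(config.sample_sizes, dtype=float)

        def mean_out(po: float) -> float:
            vals = [_pair_diff([po], [p_anc, p_ind[i]], kappa, pi)
                    for i in range(len(config.species))]
            return float(np.average(vals, weights=n))

        p_out = _solve_branch_p(config.outgroup_divergence, mean_out,
                                "outgroup")
    return p_ind, p_anc, p_out


def expected_stats(config: SimulationConfig) -> ExpectedStats:
    """Analytic expected pairwise p-distances and K2P distances (star tree).

    The K2P expectation is the K2P transform of the expected transition and
    transversion proportions; at the simulated alignment lengths the Jensen
    gap of the transform is orders of magnitude below sampling error.
    """
    if config.species_tree != "star":
        raise NotImplementedError("expected_stats is defined for the "
                                  "star species tree")
    kappa, pi = config.kappa, config.composition
    p_ind, p_anc, _ = _branch_probs(config)
    L = config.evolved_length

    intra_p: dict[str, float] = {}
    intra_k2p: dict[str, float] = {}
    for idx, sp in enumerate(config.species):
        ts, tv = _pair_site_probs([p_ind[idx]], [p_ind[idx]], kappa, pi)
        pat = config.lineage_pattern(sp, idx)
        w = len(pat.replace("-", "")) if pat is not None else 0
        comp = L + w
        intra_p[sp] = (ts + tv) * L / comp
        intra_k2p[sp] = k2p_from_counts(ts * L, tv * L, comp)

    inter_p: dict[tuple[str, str], float] = {}
    inter_k2p: dict[tuple[str, str], float] = {}
    for i in range(len(config.species)):
        for j in range(i + 1, len(config.species)):
            ts, tv = _pair_site_probs([p_anc, p_ind[i]], [p_anc, p_ind[j]],
                                      kappa, pi)
            s_ts, s_tv, s_comp = _spacer_pair_counts(
                config.lineage_pattern(config.species[i], i),
                config.lineage_pattern(config.species[j], j))
            comp = L + s_comp
            key = (config.species[i], config.species[j])
            inter_p[key] = ((ts + tv) * L + s_ts + s_tv) / comp
            inter_k2p[key] = k2p_from_counts(ts * L + s_ts, tv * L + s_tv,
                                             comp)

    sizes = config.sample_sizes
    w_intra = np.array([n * (n - 1) / 2 for n in sizes], dtype=float)
    w_inter = np.array([na * nb for i, na in enumerate(sizes)
                        for nb in sizes[i + 1:]], dtype=float)

    def wmean(values, weights):
        v = np.asarray(list(values), dtype=float)
        keep = weights > 0
        return float(np.average(v[keep], weights=weights[keep]))

    return ExpectedStats(
        intra_p=intra_p,
        intra_k2p=intra_k2p,
        inter_p=inter_p,
        inter_k2p=inter_k2p,
        mean_intra_p=wmean(intra_p.values(), w_intra),
        mean_intra_k2p=wmean(intra_k2p.values(), w_intra),
        mean_inter_p=wmean(inter_p.values(), w_inter),
        mean_inter_k2p=wmean(inter_k2p.values(), w_inter),
    )


# ---------------------------------------------------------------------------
# sequence generation

def _mutate(seq: np.ndarray, p: float, kernel_cum: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    """One branch: mutate ``floor(p*L) + Bernoulli(frac)`` distinct sites."""
    L = seq.size
    m_float = p * L
    m = int(math.floor(m_float))
    if rng.random() < m_float - m:
        m += 1
    child = seq.copy()
    if m == 0:
        return child
    positions = rng.choice(L, size=m, replace=False)
    draws = rng.random(m)
    for pos, u in zip(positions, draws):
        child[pos] = int(np.searchsorted(kernel_cum[child[pos]], u,
                                         side="right"))
    return child


def _ultrametric_heights(n: int, rng: np.random.Generator,
                         ) -> tuple[list[tuple[int, int, float]], float]:
    """Random ultrametric join sequence: (a, b, height) triples over cluster
    indices, heights normalized so the root sits at 1."""
    waits = rng.exponential(size=n - 1)
    heights = np.cumsum(waits) / np.sum(waits)
    clusters = list(range(n))
    joins: list[tuple[int, int, float]] = []
    next_id = n
    for h in heights:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        joins.append((clusters[i], clusters[j], float(h)))
        clusters[i] = next_id
        del clusters[j]
        next_id += 1
    return joins, 1.0


def simulate_dataset(config: SimulationConfig,
                     ) -> tuple[AlignedDataset, dict[str, str]]:
    """Generate an aligned dataset plus its sequence-to-species map.

    Deterministic for a given config (same seed, byte-identical output).
    Sequence IDs are ``<species>_<k>``.
    """
    rng = np.random.default_rng(config.seed)
    kappa, pi = config.kappa, np.asarray(config.composition)
    kernel_cum = np.cumsum(_kernel(kappa), axis=1)
    L = config.evolved_length
    if L <= 0:
        raise ValueError("alignment length does not accommodate the spacer")
    p_ind, p_anc, p_out = _branch_probs(config)

    root = rng.choice(4, size=L, p=pi)

    n_sp = len(config.species)
    if config.species_tree == "star":
        ancestors = [_mutate(root, p_anc, kernel_cum, rng)
                     for _ in range(n_sp)]
    else:
        # evolve down a random ultrametric species tree; per-branch hit
        # probability composes so a root-to-tip path totals p_anc
        joins, depth = _ultrametric_heights(n_sp, rng)
        survival = 1.0 - p_anc        # per-site non-hit over a full path

        def branch_p(span: float) -> float:
            return 1.0 - survival ** (span / depth)

        node_height = {k: 0.0 for k in range(n_sp)}
        children: dict[int, tuple[int, int]] = {}
        for a, b, h in joins:
            node = n_sp + len(children)
            children[node] = (a, b)
            node_height[node] = h
        root_node = n_sp + len(children) - 1
        seqs: dict[int, np.ndarray] = {}

        def descend(node: int, seq: np.ndarray) -> None:
            seqs[node] = seq
            if node in children:
                for ch in children[node]:
                    span = node_height[node] - node_height[ch]
                    descend(ch, _mutate(seq, branch_p(span), kernel_cum,
                                        rng))

        descend(root_node, _mutate(root, branch_p(depth - node_height[
            root_node]) if depth > node_height[root_node] else 0.0,
            kernel_cum, rng))
        ancestors = [seqs[k] for k in range(n_sp)]

    sequences: list[AlignedSequence] = []
    species_map: dict[str, str] = {}

    def finish(row: np.ndarray, pattern: str | None) -> str:
        chars = "".join(_BASES[c] for c in row)
        if pattern is None:
            return chars
        cut = config.spacer_start - 1
        return chars[:cut] + pattern + chars[cut:]

    for idx, (sp, n) in enumerate(zip(config.species, config.sample_sizes)):
        pattern = config.lineage_pattern(sp, idx)
        for k in range(n):
            row = _mutate(ancestors[idx], p_ind[idx], kernel_cum, rng)
            seq_id = f"{sp}_{k + 1}"
            sequences.append(AlignedSequence(seq_id, sp, finish(row,
                                                                pattern)))
            species_map[seq_id] = sp

    if config.outgroup_name is not None:
        anc = _mutate(root, p_out, kernel_cum, rng)
        pattern = config.species_pattern(n_sp)
        for k in range(config.outgroup_n):
            seq_id = f"{config.outgroup_name}_{k + 1}"
            sequences.append(AlignedSequence(seq_id, config.outgroup_name,
                                             finish(anc, pattern)))
            species_map[seq_id] = config.outgroup_name

    regions = config.regions
    if regions is None:
        if (config.spacer_patterns is not None
                and config.spacer_start == 1562
                and config.spacer_width == 7 and config.length >= 1569):
            regions = default_regions(config.length)
        elif config.spacer_patterns is not None:
            end = config.spacer_start + config.spacer_width - 1
            regions = tuple(r for r in (
                RegionAnnotation("left", 1, config.spacer_start - 1)
                if config.spacer_start > 1 else None,
                RegionAnnotation("spacer", config.spacer_start, end),
                RegionAnnotation("right", end + 1, config.length)
                if end < config.length else None) if r is not None)
        else:
            regions = (RegionAnnotation("alignment", 1, config.length),)
    return AlignedDataset(tuple(sequences), regions), species_map
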