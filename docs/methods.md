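# Methods

## Scope and data model

The package analyses one aligned nucleotide matrix at a time: equal-length
rows over `{A,C,G,T}`, IUPAC ambiguity codes, `N` and `-`, each row tagged
with a species label, plus named non-overlapping region annotations in
1-based inclusive coordinates. The default partition is the combined
COI–COII barcode layout (COI 1–1495, tRNA-leucine 1496–1561, intergenic
spacer 1562–1568, COII 1569–2218). Alignment itself is out of scope: inputs
arrive aligned, and consensus/assembly steps upstream of the alignment are
likewise not modelled.

## K2P distances

For each sequence pair, columns where either row carries a gap, `N` or an
ambiguity code are excluded (pairwise deletion). Over the remaining `L`
columns with transition proportion `P` and transversion proportion `Q`:

    d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

Design choices:

* **Pairwise rather than complete deletion.** Complete deletion discards a
  column for all pairs once any sequence is gapped there; pairwise deletion
  preserves information and is the common default in barcoding studies.
  The distance-matrix container records `L` per pair so either convention
  can be audited.
* **Ambiguity codes are missing data**, not fractional matches — the
  convention of standard distance software, avoiding arbitrary weighting.
* **Undefined distances are NaN**, produced when `L = 0` or a logarithm
  argument is non-positive (saturation). They propagate loudly: averaging
  raises unless explicitly told to skip, and neighbor joining refuses them.
* Reports print percentages with standard rounding to two decimals;
  internal computation keeps full precision. Note that some published
  tables truncate instead (10/43 appears as 23.25% rather than 23.26%);
  this package always rounds.

Divergence summaries average conspecific distances per species (species
with one sequence are flagged, not averaged) and heterospecific distances
per species pair. The barcode-gap report compares the raw extremes — the
largest conspecific and smallest heterospecific pairwise value — not the
means, since a gap between means can hide overlapping tails.

## Identification criteria

Every sequence acts once as a query against all others (self excluded).

* **Best Match (BM):** the match set is every sequence attaining the
  minimal distance, with ties detected by exact equality of the
  full-precision values (distances derive deterministically from integer
  site counts, so exact ties are well defined). Correct if the set is
  all-conspecific, ambiguous if it spans the query's species and others,
  incorrect otherwise.
* **Best Close Match (BCM):** BM, except queries whose best distance
  exceeds the threshold are `no_match`.
* **All Species Barcodes (ASB):** the candidate set is every sequence
  within the threshold; `no_match` if empty, incorrect without a
  conspecific, ambiguous when mixed. When the set is all-conspecific it is
  correct — except under the `compat_singleton_ambiguous` flag (default
  on), which scores a set containing exactly one conspecific as ambiguous.
  This reproduces the behaviour observable in classic
  SpeciesIdentifier/TaxonDNA output, where queries from two-member species
  are reported ambiguous under ASB; the exact internal rule of that program
  is not documented, so this flag is a reverse-engineered compatibility
  mode and is exposed, not hidden.
* **Threshold:** the 95th percentile (configurable) of all conspecific
  pairwise distances, linearly interpolated on the sorted values. Histogram
  -based variants in other tools can differ slightly; the percentile method
  is explicit and reproducible.

The summary also counts sequences with at least one conspecific (a
singleton query can never be correct), sequences whose closest match sits
at exactly zero distance, and allospecific zero-distance pairs.

## Region analytics

* **Spacer patterns:** one aligned row per species (conspecific rows must
  agree; conflicts are errors naming the sequences), ungapped length, and
  the grouping of identical patterns across species. Gaps are treated as
  pattern characters here — indels are the point of this table.
* **Variability table:** a region column is variable when it shows at
  least two distinct unambiguous bases across species; residues are masked
  with `*` where they equal the reference species, and coordinates are
  reported in the original alignment numbering.
* **Site classes:** per column over unambiguous residues only, a column is
  variable with ≥ 2 states and parsimony-informative with ≥ 2 states each
  in ≥ 2 sequences. Gaps never count as a state; indel variation is
  reported by the spacer table instead.
* **Composition:** unweighted mean over sequences of each base's share of
  that sequence's unambiguous residues. Pooled counting differs from this
  at roughly the 0.1% level; the per-sequence average matches the
  convention of common alignment software.

## Neighbor joining and monophyly

The tree stage is a deliberate desk-scale surrogate: likelihood and
Bayesian tree inference are external-tool analyses, while the claim worth
testing here — each species forms its own cluster — is distance-driven.
Saitou–Nei NJ is implemented directly: the Q-criterion minimum is selected
scanning index pairs in order, so exact ties break deterministically toward
the lowest pair; negative branch-length estimates are clamped to zero and
flagged; additive matrices are reconstructed exactly. For monophyly the
tree is rooted by making the outgroup leaf sister to everything else; a
species is monophyletic when some clade contains exactly its sequences,
and single-sequence species are trivially monophyletic (reported as such).
Note that exactly tied distances (identical sequences) make the local
arrangement of zero-length branches order-dependent; this does not affect
monophyly of the species involved.

## The synthetic-data generator

The generator emulates the statistical regime the analysis assumes, not
molecular evolution in general. Structure: a root sequence drawn i.i.d.
from the configured composition (default AT-rich: A 0.319, C 0.157,
G 0.143, T 0.381); species ancestors derived from the root (star topology
by default, all species equidistant); individuals derived from their
ancestor; an optional outgroup lineage straight from the root; and the
spacer region written verbatim from per-species aligned patterns, constant
within species — the only indels in the data, as in the real alignments.

**Substitution process.** Each branch mutates `floor(pL) + Bernoulli(frac)`
distinct positions (randomized rounding of the expected count `pL`),
replacing each hit base via a two-rate kernel: relative weight κ for the
transition, 1 for each transversion (default κ = 4, a typical insect
mitochondrial transition bias). Because the rounding Bernoulli is the only
count-level randomness, within-species distances sit in a narrow band — as
curated barcode datasets show, where most species have near-constant (often
zero) intraspecific divergence. A per-site i.i.d. process would be
overdispersed relative to that regime and would intermittently push a
two-member species' single pairwise distance beyond the 95th-percentile
threshold, creating spurious BCM no-matches that the emulated study design
does not exhibit.

**Calibration.** Divergence targets are expected *observed* pairwise
difference proportions (what a distance estimator consumes), not
substitutions per site; multiple hits are allowed and accounted for. Branch
hit probabilities are solved from the targets by Brent root-finding on the
exact per-site expectation: each branch is the Markov matrix
`M(p) = (1-p)I + pK`, expectations for a pair of lineages are products of
commuting branch matrices through the root distribution, and the expected
transition/transversion pair proportions follow directly. Multilinearity in
the per-site hit indicators makes these expectations exact under randomized
rounding and without-replacement placement. `expected_stats()` exposes the
resulting closed-form expected p-distances and K2P distances per species
and species pair — including the deterministic spacer contribution — and
the recovery tests compare simulation output against them. An
interspecific target at or below the intraspecific noise floor clamps the
ancestor branch to zero (a deliberate overlap regime); a target beyond the
process's saturation bound raises an error.

**Defaults are the study conditions.** `study_profile()` generates 14
species named after the flesh-fly dataset with sample sizes
(3,2,2,3,3,3,2,4,6,4,2,2,3,4) — 43 sequences — per-species intraspecific
targets equal to the observed means (five species at zero, up to 0.96%;
pairweighted mean ≈ 0.49%), a global 8% interspecific target, the real
spacer patterns, and optionally a house-fly outgroup at 12% divergence.
This per-species heterogeneity matters: the threshold is set by the most
variable well-sampled species (n = 6), while the two-member species sit
well below it, which is exactly what yields zero BCM no-matches and the
33/43 compatibility-mode ASB outcome deterministically.

An `ultrametric` species-tree mode (random coalescent-style join heights,
per-branch hit probabilities composing to the same root-to-tip total) is
available for monophyly stress tests; closed-form expectations are only
provided for the star topology.

**What the generator does not emulate:** among-site rate heterogeneity,
codon structure and selection, indel evolution outside the fixed spacer
masks, population-genetic (coalescent) structure within species, realistic
between-species tree shape under the default star topology, and the count
overdispersion of field data. Passing tests therefore demonstrate the
correctness and calibration of the analysis chain under the emulated
regime, not performance guarantees on arbitrary real datasets.

## Packaged fixtures

Two small alignments ship with the package: the 14-species × 7-column
spacer table (original columns 1562–1568) and a 14-species × 66-column
tRNA-leucine alignment (columns 1496–1561) whose four variable columns
(1502, 1510, 1531, 1534) carry the real per-species states. The conserved
tRNA background is a synthetic stand-in (the full gene sequence is not
part of the packaged tables) and is labelled as such in its filename.

## Numerical choices and problem sizes

* Percentile: NumPy linear interpolation; thresholds and distances compared
  with plain `<=`/`>` on full-precision floats.
* Root-finding: `scipy.optimize.brentq` on [0, 2/3] (the expected-difference
  curve is increasing there), `xtol = 1e-14`.
* RNG: NumPy `default_rng` (PCG64); a seed is mandatory and identical
  seeds give byte-identical datasets.
* Test/acceptance problem sizes: 2218-column alignments, 43–44 sequences,
  20 seeded replicates for calibration and identification checks; these
  sizes keep every check deterministic-in-distribution while matching the
  study-scale data shape.

## Known limitations

* Exact reproduction of published distance tables additionally depends on
  the original software's deletion option and rounding; pairwise deletion
  is assumed here and documented above.
* The ASB compatibility rule is reverse-engineered from reported outcomes,
  not from a published algorithm specification.
* NJ monophyly is a surrogate for model-based tree inference; it carries
  no support values.
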