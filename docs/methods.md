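# Methods

This note documents the models, criteria and numerical choices behind
`indelsig`, and what the synthetic experiments do and do not demonstrate.

## Conventions

The gap character is `-` throughout (`.` in inputs is normalised on read);
missing data in the super-matrix is also `-`. All reported coordinates —
alignment columns and reference-residue positions — are 1-based and
inclusive, matching the "2 aa Ins, 282–322" style of signature-indel
tables. `X` denotes an unknown residue and never counts as a match: not for
pairwise identity, not for AAI, not for flank conservation. An unknown
residue must not create signal.

## Protein families

Families are built in the CD-HIT tradition: sequences sorted by decreasing
length (ties broken lexicographically by id, making the procedure fully
deterministic), each joining the first existing family whose representative
it matches at both thresholds, else founding a new family. The
representative is therefore always the longest member. Identity and
coverage come from one global alignment per pair (BLOSUM62, affine gap open
10 / extend 1): identity = matching columns / columns where both sequences
hold a residue; coverage = those columns / length of the shorter sequence.
Coverage is measured against the *shorter* sequence deliberately — the
published criterion ("50 % sequence length and identity") names no
referent, and shorter-sequence coverage is the CD-HIT behaviour being
emulated. An edit-distance prefilter (edlib) skips pairs that provably
cannot pass: any alignment with unit-cost distance *d* has at most
(|a|+|b|−d)/2 matched columns, while identity ≥ 0.5 and coverage ≥ 0.5
jointly require at least 0.25·min(|a|,|b|) matches. The filter therefore
never changes the result, only the cost.

Core selection keeps families whose genome prevalence is ≥ 0.8 (so 31 of 38
genomes qualifies at 0.816, 30 of 38 does not at 0.789) and picks one
representative per genome — the member most identical to the family
representative, ties broken by length then id — so that downstream
alignments have at most one row per genome, as a species-level super-matrix
requires.

Alternatively, families can be formed as single-linkage components over
imported tabular BLAST hits that pass E ≤ 1e−20 *and* the same
identity/coverage thresholds; e-values are taken from the hit file, never
recomputed.

## Alignment, trimming, concatenation

The progressive aligner uses a UPGMA guide tree on cosine distances between
3-mer count vectors and merges sub-alignments by profile–profile global
alignment (column score = frequency-weighted BLOSUM62 dot product, gaps
carrying zero weight; affine penalties, first gap column −10, each further
−1; Gotoh three-state recursion with a deterministic tie order
align > gap-in-B > gap-in-A). De-gapping any output row reproduces its
input sequence exactly. Externally produced aligned FASTA can be dropped in
instead — downstream stages only see the `Msa` container.

Trimming is a pure gap-fraction threshold: a column is removed iff its gap
fraction exceeds 0.2. Published pipelines use heuristic trimmers whose
modes and versions are rarely stated; a single fully-specified rule is
reproducible, idempotent by construction, and equivalent on clean data.
Exact reproduction of any particular published column count is therefore
not a goal. Families are concatenated in lexicographic family-id order
(publication pipelines leave the order unstated; determinism requires
fixing one), a genome absent from a family contributing all-gap columns,
with a partition table (family, start, end) written alongside. PHYLIP
export uses the relaxed dialect (full names, `n_taxa n_cols` header).

## AAI

AAI between two genomes is 100 × matching columns / columns where both
rows hold a residue other than `X`, computed over the trimmed core
super-matrix. This equals the column-count-weighted mean of per-family
identities (asserted to 1e−12 relative error in the tests). Computing AAI
from core proteins rather than from whole-genome reciprocal BLAST follows
the practice of core-alignment studies; core-protein AAI tracks
whole-genome AAI closely while being less exposed to horizontal transfer.
Pairs with no qualifying columns are reported missing and refuse NJ tree
construction with advice to raise family prevalence.

The diagnostic tree is classical neighbor joining on `d = 1 − AAI/100`
(scikit-bio's implementation; negative branch lengths clamped to zero;
ties resolved by matrix row order). It is a clade-recovery diagnostic only
— proper ML inference belongs to external tools fed the exported
super-matrix.

## The CSI scan

A candidate indel is a **maximal block-consistent interval**: a run of
alignment columns over which every row is either all-gap or all-residue,
with both kinds present, that cannot be extended in either direction
without breaking this consistency. Block consistency is strict — a
partially gapped row disqualifies the interval — because genuine CSIs have
fixed lengths; ragged gaps indicate alignment noise. Blocks of 1–10 aa are
considered by default (published clade-specific indels are typically
1–4 aa).

Classification for a target clade: every clade member present in the family
must hold the same state (within-clade disagreement always fails — there is
no exception allowance *inside* the clade); genomes outside the clade
sharing the clade state are *isolated exceptions*, tolerated up to
`max_exceptions` (default 0) and reported, mirroring the footnote
convention of published CSI tables; at least one outside genome must hold
the opposite state. Clade genomes with no homologue in the family are
listed as missing — they neither support nor refute specificity — and a
scan requires at least two clade rows present. The state defines the type:
clade-residue = insertion, clade-gap = deletion, relative to the outgroup.
Note the complement identity: in a universe of exactly two clades, a clean
insertion for one clade is by definition a clean deletion for the other;
with three or more clades the exception count breaks the symmetry.

Flank conservation examines up to `flank_window` = 40 columns (allowed
40–50) immediately left and right of the block, clamped at alignment
edges: a column is conserved iff it is gap-free and a single non-`X`
residue reaches frequency ≥ `conserved_fraction` (default 1.0 — the
conservative reading of "conserved"; 0.8 is available for noisy data)
among the rows present. Both counts must reach `min_conserved_flank` = 4.
Windows are measured in alignment columns; reported regions are
reference-residue spans. The reference is the clade member with the
lexicographically smallest genome id, and `ref_region` is the flanked
span (block ± window) in its residue coordinates — the span a confirmatory
database search would use. A nr-wide confirmation step is replaced by
specificity within the supplied genome set, with an optional FASTA export
of each flanked region for external checking.

## The synthetic cohort

The generator emulates the study design, not sequence biology: a
clade-first balanced tree (root → clade ancestors → genomes) with two
branch parameters, `between_rate` (default 0.12) and `within_rate`
(default 0.03), as per-site substitution probabilities; a mutation replaces
a residue with one of the other 19 uniformly; root sequences are i.i.d.
uniform over the 20 residues, lengths uniform in 150–400 aa, 200 families,
30 genomes in five clades (8/7/6/5/4). The model is deliberately minimal —
no substitution matrix, no rate heterogeneity, no indel process unless
`background_indel_rate` > 0 — because it admits closed forms: two genomes
one branch of rate *p* each from their ancestor match per site with
probability (1−p)² + p²/19, which the tests use as an analytic oracle.
With the default rates the cohort's AAI ranges (within-clade mid-90s %,
between-clade low-70s %) fall inside the ranges reported for real
genus-level clades (79 to > 95 % intra, 58–81 % inter), so the AAI and
tree stages are exercised in a realistic regime.

Planting inserts one shared random motif per CSI into every clade member
(or gaps out a root run of 1–4 aa), optionally marks one outside genome
with the clade state (an isolated exception) or removes a named genome's
family member (a missing homologue). The `min_conserved_flank` columns
adjacent to the block on each side are reverted to the root residue in all
rows, so the flank criterion holds by construction and every manifest
record is detectable at default parameters; each manifest record is built
by running the scanner's own classification and flank measurement on the
mutated alignment, then re-checked by the validator. The detectability
guarantee assumes `background_indel_rate` = 0 (the default); background
deletions may overlap a flank and break it.

What passing these tests shows — and does not. Recovery with precision and
recall 1.0 shows the scanner implements its definition exactly (the
brute-force enumeration oracle shows the same independently); it does not
show that real alignments of real proteomes yield clean blocks, because
the generator's alignments are true by construction and its substitution
model is homogeneous. Aligner-induced artefacts, rate heterogeneity,
paralogy and contamination are outside the simulated regime; on real data
the scan's strictness (block consistency, unanimity, strict conservation)
is the guard against them.

## Numerical choices and degenerate inputs

* Greedy clustering, alignment, concatenation, scanning and rendering are
  deterministic; all simulation randomness flows from one integer seed
  through `numpy.random.default_rng`.
* A single-member family cannot be aligned (error); an alignment whose
  columns are all trimmed raises with advice rather than returning an
  empty matrix; an empty super-matrix refuses export.
* A block closer than `min_conserved_flank` columns to an alignment edge
  cannot pass the flank rule (windows clamp, counts fall short).
* Maximal blocks longer than `max_indel_len` are excluded, not truncated —
  a sub-interval of a longer run is never maximal.
* Terminal `*` in FASTA input is stripped silently; any other character
  outside the 20 amino acids plus `X` is an error naming the record.
* NJ requires a complete AAI matrix; missing entries raise.

## Problem sizes in the tests

The bundled experiments run the reference scenario at 200 families × 30
genomes (about 55 000 super-matrix columns), 10 cohorts for recovery, 50
for NJ clade recovery, 1000 random alignments for the enumeration oracle,
and a 10-genome × 40-family cohort for clustering recovery — sizes chosen
so the whole suite completes in a couple of minutes on one CPU while every
stage still runs at genuinely multi-genome scale. The acceptance script
uses the same scenario with 20 NJ cohorts.

## Known limitations

* The aligner is a straightforward progressive method without iterative
  refinement; for production phylogenomics, import alignments from a
  dedicated aligner instead (the adapter accepts aligned FASTA).
* AAI here is core-alignment AAI; genome-wide two-way BLAST AAI, ANI and
  POCP are different indices and out of scope.
* Clades are user input (as in GTDB-informed studies); the package scans
  for markers of given clades, it does not propose clades.
* Nucleotide sequences, GenBank/GFF parsing, HMM homology and
  conserved signature proteins (CSPs) are out of scope.
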