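# Methods

This note documents the models and numerical choices behind `enzselect`:
what is computed, with which parameters and defaults, where the design was
genuinely open, and what the synthetic fixtures do and do not exercise.

## Reaction representation

All four query forms (reaction SMILES, SMARTS/SMIRKS rule, MDL `.rxn`
V2000, EC/xref lookup) converge on one reaction value whose participants
carry RDKit-canonical SMILES; repeated identical structures on a side merge
into stoichiometric coefficients. Agents (the middle field of a three-part
`a>agents>b` string) are parsed for validity and discarded with a warning —
they play no role in similarity. Stereochemistry is preserved in the
canonical SMILES but ignored by the fingerprints: the similarity screen is
structural, and reaction rules mined from retrosynthesis tools rarely carry
stereo. EC matching is prefix-based with `-` as a wildcard field, on both
the stored and the query side, because partial EC numbers are pervasive in
reaction databases. V3000 molfiles are rejected with a clear error rather
than half-parsed.

A rule component that reads as a concrete SMILES (no query atoms needed to
interpret it) is canonicalized as SMILES, so a pattern-free SMARTS behaves
exactly like the equivalent reaction SMILES downstream. True patterns keep
a canonical SMARTS and are fingerprinted with a reserved Morgan atom
invariant (code 119) for wildcard atoms; this gives rules stable,
comparable fingerprints, but it is a documented in-house choice — there is
no community convention for fingerprinting query atoms, and no fidelity
claim is made relative to any other tool's treatment.

## Similarity model

Fingerprints are circular Morgan fingerprints, radius 2, folded to
1024 bits (configurable via `fingerprint.radius` / `fingerprint.nbits`).
Tanimoto similarity is computed on the on-bit sets.

The per-reaction aggregation is an in-house design (only per-compound
Tanimoto is externally prescribed): compounds of the two corresponding
sides are matched one-to-one by a greedy maximum assignment on the
pairwise Tanimoto matrix (repeatedly take the global maximum; ties go to
the lowest (query index, database index) pair so output is deterministic),
and the side score is the matched sum divided by the size of the *larger*
side. Normalizing by the larger side penalizes missing and extra
compounds symmetrically; unmatched compounds contribute zero. A molecule
with coefficient n counts as n assignable instances. The reaction score
is the arithmetic mean of the two side scores. Greedy assignment can be
suboptimal in principle; on realistic sides (≤ 4 compounds) it matches the
exhaustive-permutation optimum in ≥ 90% of sampled fixture pairs and never
exceeds it, which the tests assert.

Direction handling: `both` evaluates the query against the database
reaction as stored and with its sides swapped and keeps the larger score
(ties resolve to forward); `preferred_only` evaluates only the curated
consensus direction and falls back to `both` when no consensus entry
exists. The consensus table is consumed, not derived: its curation is out
of scope.

The currency-compound mask defaults to *empty*; a sample mask (water,
ammonia, CO2, phosphate/diphosphate, ATP/ADP/AMP, NAD(+/H), CoA) ships as
package data because cofactors otherwise dominate matching. Masking is
skipped for a side that it would empty.

## Host distance

Taxonomic distance is the path length between two taxa through their
lowest common ancestor on the database's taxonomy tree: summed branch
lengths when every edge carries one, edge count otherwise. This uses tree
topology, not sequence divergence — the taxonomy is the only organism
structure in the data model, and host compatibility is a property of the
source organism, not of the particular homolog. The distance is a metric
on the labelled taxa (verified exhaustively in tests).

## Physicochemistry

All residue tables are frozen TSV files in `enzselect/data/` so values
are reproducible bit-for-bit:

- **Molecular weight**: average residue masses plus one water
  (18.01528 Da); unknown residues (X) are skipped.
- **pI**: bisection on the Henderson–Hasselbalch net charge over the
  classic EMBOSS pKa set (N-term 8.6, C-term 3.6, C 8.5, D 3.9, E 4.1,
  H 6.5, K 10.8, R 12.5, Y 10.1) until |charge| < 1e-3; net charge is
  strictly decreasing in pH, so bisection converges.
- **GRAVY**: mean Kyte–Doolittle hydropathy.
- **Transmembrane segments**: sliding Kyte–Doolittle window of 19
  residues; maximal runs of window centers with mean > 1.6 are expanded to
  the full window extent, merged when overlapping, and discarded below 15
  residues. Window/threshold/minimum follow the standard hydropathy-plot
  convention. Note the prediction is only translation-invariant away from
  the sequence ends: windows are never evaluated past the termini, so a
  hydrophobic run flush against an end can yield a shorter segment.
- **Solubility**: `1 / (1 + exp(gravy − 2·|net charge at pH 7|/length))` —
  a deliberately simple logistic proxy (hydrophilic, charged sequences
  score high), clearly labelled heuristic and swappable via the
  `solubility=` hook of `physicochemical()`. It is a ranking aid, not a
  trained predictor.

## Alignment and conservation

Pairwise alignment is global Needleman–Wunsch/Gotoh with affine gaps over
a frozen BLOSUM62 table; a gap of length L costs
`gap_open + (L−1)·gap_extend` with defaults 10 / 0.5. Traceback ties
resolve diagonal > up > left. The multiple alignment is progressive:
3-mer set distance, UPGMA guide tree with lexicographic-accession tie
breaks, and profile–profile merges scoring a column pair as the average
BLOSUM62 value over residue cross-pairs (gap pairs contribute 0). Input
is sorted by accession first, so the result is independent of input order.
An external aligner can be substituted by constructing `Alignment` rows
directly.

Column conservation is the frequency of the modal non-gap residue among
non-gap entries; majority-gap columns (> 50% gaps) score 0, a conservative
choice that keeps sparse insertions from inflating scores. A sequence's
conservation is the mean over columns where it has a residue. Both the
alignment algorithm and the conservation definition are in-house
substitutes for external alignment tooling; they are deterministic and
oracle-tested (pairwise scores against an independent dynamic-programming
implementation), but not consistency-based like dedicated MSA programs.

## Candidate collection and scoring

Reactions are walked by decreasing similarity (ties by reaction id);
each linked sequence not yet collected joins the table with the similarity
of the reaction through which it was first reached; collection stops at a
reaction boundary once the requested candidate count is reached — one
reaction's sequence set is never split, so within-reaction ties are never
cut arbitrarily. EC/xref queries that resolve to several reactions fan
out into one screen each and merge by best similarity per accession.

The composite score min–max-normalizes each weighted column over the
result table, flips lower-is-better columns (host distance; evidence,
since level 1 is the strongest annotation), maps constant columns to 0.5
(avoiding division by zero while keeping them neutral), and takes the
weighted mean. Default weights are 1.0 on reaction similarity, host
distance, evidence and conservation; the default is equal weighting
because no authoritative weighting exists, and the CLI exposes
`--weights`. A column with no values in the table (conservation when the
MSA is disabled) is dropped from the weighting. Normalization is per
result table, not global — scores are relative ranks within one query's
candidates, matching how the table is read, and are not comparable across
queries.

Output rows sort by composite desc, similarity desc, accession asc; the
CSV column order is frozen and regression-tested; identical inputs yield
byte-identical files.

## Synthetic fixtures

`FixtureSpec` defaults: 40 reactions (including the five planted ones),
6 sequences per reaction, 32 taxa, per-residue mutation rate 0.1. The
generator draws reactions from a curated 30-compound pool of common small
metabolites with coefficients in {1, 2}, builds each reaction's sequence
family by mutating a random 120-residue parent (a mutated site always
changes, so expected pairwise identity is (1−µ)² + µ²/19), and grows a
random binary taxonomy with unit branch lengths. Defaults were chosen to
be large enough to exercise ranking, fan-out and MSA behaviour while
keeping the full test suite in seconds. The pinocembrin pathway (PAL,
4CL, CHS, CHI, plus a serine ammonia-lyase so EC prefix 4.3.1 fans out) is
always planted, with a four-member PAL family at mutation rate 0.05,
strong evidence levels (1,1,2,2) and one member in the host organism
(taxon 562, *E. coli*); pathway compound SMILES are frozen after
verification against structure lookups, with CoA thioesters truncated to a
methanethiol surrogate.

What the fixtures do **not** emulate: chemically balanced reactions, real
enzyme sequences or families, realistic taxonomies, or database-scale
sizes. Passing tests therefore demonstrate algorithmic correctness and
determinism, not retrieval quality on real reaction databases — on real
data the similarity screen's usefulness depends on fingerprint choice and
currency masking, both configurable.

## Determinism and problem sizes

Every stochastic step is seeded (fixture generation, test oracles); the
pipeline itself is deterministic, with all ties broken by explicit keys.
The acceptance script regenerates the default fixture (40 reactions, 238
sequences, 32 taxa), samples 100 assignment pairs and 50 alignment pairs,
and completes in a few seconds on one CPU; the full test suite runs in
well under a minute.
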