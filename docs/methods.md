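# Methods

## Search model

`tsss` performs translated (DNA query → protein database) local
homology search. Each read is translated in all six frames with the
standard genetic code; stop codons emit `*`, codons containing `N` emit
`X`, and trailing partial codons are dropped. Frames are searched
independently; frameshift-aware alignment across frames is out of
scope.

The database is held in memory as one concatenated string with `#`
delimiters between proteins, plus an offset table for mapping global
positions back to (protein, offset). Sequence windows containing the
delimiter can never seed or align across it.

### Reduced alphabets

A reduced alphabet of size *k* is a partition of the 20 standard amino
acids. It is derived from BLOSUM62 as follows: each residue is
represented by its score vector over the 20 standard residues
(self-score included); Pearson correlations *r* are computed for all
pairs; average-linkage agglomerative clustering on distance 1 − *r*
runs from 20 singletons down to 2 clusters; the *k*-cluster level of
this single dendrogram is the *k*-alphabet. Merge-order ties are broken
by the lexicographically smallest member of the merged cluster, so the
dendrogram — and every cut — is deterministic, and the *k*-partition
always refines the (*k*−1)-partition. A group's match score is the
maximum self-score among its members. Since neither the linkage nor the
correlation convention is canonical in the literature, this recipe is
pinned for reproducibility, and `load_fixed_alphabet` accepts an
explicit group listing for exact reproduction of any published table.

Ambiguity codes (`X`, `B`, `Z`) are scored during extension via their
BLOSUM62 rows but belong to no reduced group: in reduced sequences they
become a dedicated no-match symbol that can never seed.

### Two-step seed search

Seed parameters are `(H1, H2, L1, A1, L2, A2)`. On the database side,
an inverted index maps every `A1`-reduced core word of length `L1` to
its global positions; a core position is admitted only if the core and
both `L2` flanks lie inside one protein, because a hit that cannot
present both flanks can never pass step two. The index stores the
`A2`-reduced database text for the flank test; no second inverted index
is needed, since step two is a per-candidate comparison.

On the query side, every span of `L2 + L1 + L2` residues that contains
no stop and no ambiguity symbol yields a key. Step one retrieves the
postings of every word within Hamming distance `H1` of the query core
(neighborhood expansion happens on the query side only; the index
stores literal words). Step two keeps a candidate iff **both** flanks
are within Hamming distance `H2` under `A2`. Hits are deduplicated and
emitted in (query position, database position) order.

The CLI bounds `H ≤ 2` because the neighborhood size
Σᵢ C(L,i)(k−1)ⁱ grows exponentially in `H`; the library supports
general `H`.

### Extension

Ungapped extension starts from the seed span scored with the full
BLOSUM62 matrix (reduction plays no role past seeding) and extends one
residue at a time in each direction, keeping the best-prefix/suffix
extent, stopping a direction when the running score drops more than
`x_dropoff_ungapped` (default 20) below its peak or a delimiter/end is
reached. Stop codons in query frames are scored via the `*` row as a
virtual amino acid. HSPs must exceed `ungapped_cutoff` (default 40,
strict) to proceed.

Chain filtering merges same-diagonal HSPs that overlap, or whose
intervening bridge region scores at least `chain_link_threshold`
(default = the cutoff); merged scores are recomputed over the union
span. The bridge reading ("the score of the region between the two
segments") is one of two defensible readings of neighborhood chaining;
it is pinned and tunable. Cross-diagonal chaining is deliberately not
attempted — an ungapped score between segments is only well defined
along one diagonal.

Gapped extension is Gotoh affine-gap dynamic programming (gap of
length *k* costs `gap_open + k·gap_extend`, default 11 + k) with its
own X-dropoff (default 30), anchored at the midpoint of the chained
HSP and run independently leftward and rightward, BLAST-style; the
final score is the sum of the two halves. The subject window is capped
at the query-half length plus the longest gap that could survive the
dropoff. Because both halves are anchored, the result is a lower bound
on the Smith–Waterman optimum; it equals the optimum whenever the
optimal path passes through the anchor midpoint at a match column and
the dropoff is large enough (verified against the exact aligner in the
test suite).

### Statistics, ranking, output

Bit score = (λ·S − ln K)/ln 2 and E = K·m·n·e^(−λS) with the canonical
gapped constants for BLOSUM62/(11,1), λ = 0.267 and K = 0.041
(overridable), m the query-frame residue length and n the database
residue count. Using the frame length for m is an approximation chosen
for simplicity; per-read frameshift-aware statistics are a known
refinement left out of scope. Per query, the best alignment per subject
is kept, ranked by bit score (ties: E-value, then subject id), E > 10
dropped, and the top 10 reported as 12-column BLAST-style tabular
lines. DNA coordinates are 1-based; reverse frames report start > end.

### Accuracy metric and reference hits

Reference hits per query are the up-to-10 best subjects by exact
Smith–Waterman over all six frames, keeping E ≤ 1e-5. Accuracy is
pooled: (Σ per-query matches within the heuristic's top 10) / (Σ
per-query reference-hit counts). The pooled form (rather than a
per-query average) is pinned as the literal reading of a
matches-to-reference ratio over a whole run.

The exact aligner exists in two forms sharing one scoring table: a
plain DP with deterministic traceback (ties diagonal > up > left), and
a vectorized row-sweep score-only form used to sweep a query frame
across the entire concatenated database in one pass. The row-sweep
computes the horizontal-gap state with a prefix-maximum scan; a
per-segment offset of ±BIG makes any gap spanning a delimiter lose BIG
per wall crossed, so per-protein optima can be read off one sweep. Both
forms agree exactly (tested), and both are cross-checked against an
independent exhaustive path enumeration and Biopython's exact aligner.

## Synthetic data

The fixture generator emulates a prokaryotic metagenomic search
problem at desk scale. Defaults: 50 database proteins of 150–300
residues drawn from Robinson–Robinson background frequencies; 200
reads of 150 bases. A homologous read samples a 50-residue protein
window, substitutes residues at the stated rate (replacements drawn
∝ 2^BLOSUM62-score, i.e. biased toward similar residues), applies
indels at the stated rate, reverse-translates through uniformly random
synonymous codons, and lands on a random strand. Decoy reads are
uniform random DNA. All randomness flows from one seed; identical specs
give byte-identical FASTA.

What this does **not** emulate: real domain structure, low-complexity
regions, compositional bias, sequencing error profiles, and related
database sequences competing for the same read. Passing tests
therefore demonstrate algorithmic correctness and the expected
sensitivity ordering of the presets, not field accuracy on real
metagenomes. At the default rates (0 and 10% substitutions over a
50-residue window) every preset resolves the single true source, so
preset accuracies coincide at 1.0; the presets are still distinguished
by their candidate counts (stage summaries) and, adversarially, by the
seed-level monotonicity tests.

## Problem sizes in the validation suite

Oracle-equivalence checks run on ~100 random instances with database
texts up to 5,000 residues and query frames up to 60 residues;
alignment-bound checks on ~200 random pairs up to 60 residues;
end-to-end runs on the 50 × 200 fixture above. These sizes make the
quadratic oracles exact and fast while exercising every code path.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open internally; 1-based inclusive only
  in tabular output.
- Reads shorter than one codon are skipped with a warning; empty
  database sequences are skipped with a warning; duplicate ids are an
  error.
- A `*` in a database FASTA (unusual but legal) cannot seed, like the
  delimiter, but still scores during extension.
- The on-disk index is a NumPy `.npz` container with a JSON header and
  version magic; reload is bit-exact.
- The engine is single-threaded by design; its parallelism contract is
  that searching any partition of the reads and concatenating outputs
  reproduces the single run byte for byte (tested).

## Known limitations

Spaced seeds, query double-indexing, database redundancy clustering,
SEG/low-complexity masking and frameshift-aware E-values are all out of
scope. The index build is O(database); the reference-hit oracle is
quadratic and intended for desk-scale evaluation only.
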