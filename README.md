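# tsss — two-step seed search for translated protein homology

`tsss` is a blastx-style homology search engine for DNA sequencing
reads against a protein database, built around a **two-step seed
search** over two differently sized reduced amino-acid alphabets.

## The idea

Seed-and-extend search tools locate short matching words (*seeds*)
between query and database before spending effort on alignment.
Because functional residues are strongly conserved while their
surroundings drift, a seed whose **center** is tested strictly and
whose **flanks** are tested loosely separates true homologs from noise
with far fewer candidates than a uniform test.

A seed here spans `L2 + L1 + L2` residues:

- the **core** (length `L1`) is compared under a large reduced alphabet
  `A1` (e.g. 16–18 groups), allowing up to `H1` mismatches;
- both **flanks** (length `L2` each) are compared under a small reduced
  alphabet `A2` (e.g. 6–8 groups), each allowing up to `H2` mismatches.

Reduced alphabets are built Murphy-style from BLOSUM62: residues are
clustered by the Pearson correlation of their substitution-score
vectors, and a group's match score is the maximum self-score of its
members. Mismatch tolerance is implemented by expanding the query word
into its Hamming neighborhood and looking every variant up in an exact
inverted index of the concatenated database.

Surviving seed hits are refined classically: X-dropoff ungapped
extension with the full BLOSUM62 matrix (stop codons score as a virtual
amino acid), score-threshold and same-diagonal chain filtering, then
Gotoh affine-gap gapped extension anchored at the HSP midpoint. Raw
scores become bit scores and E-values through Karlin–Altschul
statistics (λ = 0.267, K = 0.041 for BLOSUM62 with gap costs 11/1).

An exact Smith–Waterman aligner is included as the internal oracle:
search accuracy is measured as the pooled fraction of each query's
up-to-10 optimal hits (E ≤ 1e-5) that the heuristic recovers in its own
top 10.

Three presets bundle `(H1, H2, L1, A1, L2, A2)`:

| preset    | H1 | H2 | L1 | A1 | L2 | A2 |
|-----------|----|----|----|----|----|----|
| fast      | 0  | 1  | 4  | 18 | 5  | 6  |
| middle    | 0  | 1  | 4  | 16 | 4  | 8  |
| sensitive | 0  | 1  | 2  | 18 | 5  | 8  |

## Worked example

Generate a small synthetic benchmark (20 random proteins, 5 reads of
150 bases carrying ~5% amino-acid substitutions) and search it:

```sh
tsss fixture --out-db db.faa --out-reads reads.fna --out-truth truth.tsv \
     --n-proteins 20 --n-reads 5 --substitution-rate 0.05 --seed 4
tsss --quiet search --db db.faa --query reads.fna --preset sensitive
```

Output (BLAST outfmt-6 columns: query, subject, %identity, alignment
length, mismatches, gap opens, query start/end on the DNA read, subject
start/end, E-value, bit score):

```
read0000	prot0002	92.00	50	4	0	1	150	29	78	2.39e-26	102.8
read0001	prot0016	98.00	50	1	0	1	150	33	82	4.5e-25	98.6
read0002	prot0015	96.00	50	2	0	1	150	39	88	9.07e-26	100.9
read0003	prot0016	98.00	50	1	0	1	150	95	144	1.19e-25	100.5
read0004	prot0000	90.00	50	5	0	1	150	129	178	4.07e-26	102.1
```

Every read maps back to its true source protein (compare `truth.tsv`)
at 90–98% identity over the full 50-residue translation, with E-values
around 1e-25 against this 4.5k-residue database.

Other verbs: `tsss index` builds a reusable on-disk seed index,
`tsss eval` scores the presets against the exact Smith–Waterman
reference on a fixture, and `tsss alphabet -k 10` prints a reduced
alphabet, e.g.

```
A,C,DNS,EKQR,FWY,G,H,ILMV,P,T
```

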