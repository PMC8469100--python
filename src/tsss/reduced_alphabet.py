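"""Reduced amino-acid alphabets.

A reduced alphabet partitions the 20 standard amino acids into ``k``
groups so that similar residues compare as equal during seed search.
Groups are derived in the Murphy style: each residue is represented by
its BLOSUM62 score vector over the 20 standard residues, pairwise
Pearson correlations ``r`` are computed, and average-linkage
agglomerative clustering on distance ``1 - r`` is cut at ``k`` clusters.
The match score of a group is the maximum self-score among its members.

Seed search only ever compares group identity; the match scores exist so
that a coarse alphabet can still rank candidate seeds if needed.

Two instances are used per search: a larger (tighter) alphabet for the
seed core and a smaller (looser) one for the flanks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .errors import AlphabetSpecError, ParameterError
from .scoring import (
    AMBIGUITY_CODES,
    DELIMITER,
    STANDARD_AMINO_ACIDS,
    STOP,
    SubstitutionMatrix,
)

#: Symbol a reduced sequence uses for residues outside every group
#: (ambiguity codes).  It matches nothing during seed search.
NO_MATCH = "?"


@dataclass(frozen=True)
class ReducedAlphabet:
    """Partition of the 20 standard amino acids into ``size`` groups."""

    size: int
    mapping: dict  # residue -> group id in [0, size)
    group_members: tuple  # group id -> sorted member string
    group_match_score: tuple  # group id -> int
    symbols: str = field(default="")  # group id -> 1-char display symbol

    def __post_init__(self) -> None:
        members = "".join(self.group_members)
        if sorted(members) != sorted(STANDARD_AMINO_ACIDS):
            raise AlphabetSpecError(
                "groups must partition the 20 standard amino acids; got "
                f"{''.join(sorted(members))!r}"
            )
        if len(self.group_members) != self.size or any(
            not g for g in self.group_members
        ):
            raise AlphabetSpecError("number of non-empty groups must equal size")
        if not self.symbols:
            object.__setattr__(
                self, "symbols", "".join(g[0].lower() for g in self.group_members)
            )
        trans = {c: self.symbols[g] for c, g in self.mapping.items()}
        trans[STOP] = STOP
        trans[DELIMITER] = DELIMITER
        for c in AMBIGUITY_CODES:
            trans[c] = NO_MATCH
        object.__setattr__(
            self,
            "_trans",
            str.maketrans({ord(k): v for k, v in trans.items()}),
        )

    def group_of(self, residue: str) -> int:
        return self.mapping[residue]

    def reduce(self, s: str) -> str:
        """Recode a protein string into group symbols.

        ``*`` and ``#`` pass through verbatim; ambiguity codes become the
        no-match symbol.  Length is preserved.
        """
        return s.translate(self._trans)


def group_match_score_of(a: ReducedAlphabet, g: int) -> int:
    """Match score of group ``g``: max member self-score."""
    if not 0 <= g < a.size:
        raise ParameterError(f"group id {g} outside [0, {a.size})")
    return a.group_match_score[g]


def reduce_sequence(a: ReducedAlphabet, s: str) -> str:
    return a.reduce(s)


def _finish(groups: list, m: SubstitutionMatrix) -> ReducedAlphabet:
    groups = sorted(("".join(sorted(g)) for g in groups), key=lambda g: g[0])
    mapping = {res: gid for gid, g in enumerate(groups) for res in g}
    scores = tuple(max(m.self_score(res) for res in g) for g in groups)
    return ReducedAlphabet(
        size=len(groups),
        mapping=mapping,
        group_members=tuple(groups),
        group_match_score=scores,
    )


def _correlation_distance(m: SubstitutionMatrix) -> np.ndarray:
    idx = [m.index_of(c) for c in STANDARD_AMINO_ACIDS]
    vectors = m.scores[np.ix_(idx, idx)].astype(float)
    r = np.corrcoef(vectors)
    return 1.0 - r


def _cluster_sequence(m: SubstitutionMatrix) -> list:
    """Full agglomerative merge sequence from 20 singletons down to 2 groups.

    Average linkage on 1 - Pearson r; merge-order ties broken by the
    lexicographically smallest merged cluster (then its partner), which
    makes the dendrogram — and every cut of it — deterministic.
    """
    dist = _correlation_distance(m)
    pos = {c: i for i, c in enumerate(STANDARD_AMINO_ACIDS)}
    clusters = [frozenset(c) for c in STANDARD_AMINO_ACIDS]
    levels = [list(clusters)]
    while len(clusters) > 2:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = clusters[i], clusters[j]
                d = np.mean([dist[pos[x], pos[y]] for x in a for y in b])
                merged = a | b
                key = (round(d, 12), min(merged), min(max(a), max(b)))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        merged = clusters[i] | clusters[j]
        clusters = [c for t, c in enumerate(clusters) if t not in (i, j)]
        clusters.append(merged)
        levels.append(list(clusters))
    return levels


@lru_cache(maxsize=32)
def _cached_build(matrix_name: str, k: int) -> ReducedAlphabet:
    # cache key includes the matrix name only; only BLOSUM62 ships
    from .scoring import load_blosum62

    m = load_blosum62()
    levels = _cluster_sequence(m)
    for level in levels:
        if len(level) == k:
            return _finish([set(c) for c in level], m)
    raise ParameterError(f"no dendrogram cut with {k} clusters")


def build_reduced_alphabet(m: SubstitutionMatrix, k: int) -> ReducedAlphabet:
    """Build the k-group reduced alphabet from the substitution matrix.

    Deterministic: repeated calls give identical partitions, and the
    k-cut always refines the (k-1)-cut of the same dendrogram.
    """
    if not 2 <= k <= 20:
        raise ParameterError(f"alphabet size k={k} outside [2, 20]")
    if m.name == "BLOSUM62":
        return _cached_build(m.name, k)
    levels = _cluster_sequence(m)
    for level in levels:
        if len(level) == k:
            return _finish([set(c) for c in level], m)
    raise ParameterError(f"no dendrogram cut with {k} clusters")


def load_fixed_alphabet(spec: str, m: SubstitutionMatrix) -> ReducedAlphabet:
    """Build an alphabet from an explicit group listing.

    ``spec`` is one line of comma-separated residue groups, e.g.
    ``"LVIM,C,A,G,ST,P,FYW,EDNQ,KR,H"``.  The groups must be disjoint
    and cover the 20 standard amino acids exactly.
    """
    groups = [g.strip().upper() for g in spec.strip().split(",") if g.strip()]
    seen: dict = {}
    unknown = []
    dupes = []
    for g in groups:
        for res in g:
            if res not in STANDARD_AMINO_ACIDS:
                unknown.append(res)
            elif res in seen:
                dupes.append(res)
            else:
                seen[res] = True
    missing = [c for c in STANDARD_AMINO_ACIDS if c not in seen]
    problems = []
    if unknown:
        problems.append(f"unknown residues {sorted(set(unknown))}")
    if dupes:
        problems.append(f"residues in multiple groups {sorted(set(dupes))}")
    if missing:
        problems.append(f"missing residues {missing}")
    if problems:
        raise AlphabetSpecError("; ".join(problems))
    return _finish([set(g) for g in groups], m)


def format_alphabet(a: ReducedAlphabet) -> str:
    """Inverse of :func:`load_fixed_alphabet`: one comma-separated line."""
    return ",".join(a.group_members)
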