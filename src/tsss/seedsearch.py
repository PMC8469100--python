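"""Two-step seed search.

The seed is a span of ``L2 + L1 + L2`` residues: a central core of
length ``L1`` compared under a large (tight) reduced alphabet A1, and
two flanks of length ``L2`` compared under a small (loose) reduced
alphabet A2.  Functional sites are strongly conserved while their
surroundings drift, so a tight test in the core plus loose tests on the
flanks finds significant seeds with far fewer candidates than a single
uniform test.

Step one looks the core word up in the database index, allowing up to
``H1`` mismatches by expanding the query word into its Hamming
neighborhood (the index itself stores literal words only).  Step two
keeps a candidate only if *both* flanks are within Hamming distance
``H2`` under A2.  Surviving (query, database) position pairs are the
seed hits handed to alignment extension.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import numpy as np

from .dbindex import SeedIndex
from .errors import ParameterError
from .reduced_alphabet import NO_MATCH, ReducedAlphabet
from .scoring import STOP
from .translation import QueryFrame


@dataclass(frozen=True)
class SeedParams:
    H1: int
    H2: int
    L1: int
    alphabet1: ReducedAlphabet
    L2: int
    alphabet2: ReducedAlphabet

    def __post_init__(self) -> None:
        if self.L1 < 1 or self.L2 < 0:
            raise ParameterError(f"need L1 >= 1 and L2 >= 0, got L1={self.L1}, L2={self.L2}")
        if not 0 <= self.H1 <= self.L1:
            raise ParameterError(f"need 0 <= H1 <= L1, got H1={self.H1}, L1={self.L1}")
        if not 0 <= self.H2 <= self.L2:
            raise ParameterError(f"need 0 <= H2 <= L2, got H2={self.H2}, L2={self.L2}")

    @property
    def span(self) -> int:
        return self.L1 + 2 * self.L2


@dataclass(frozen=True)
class SeedHit:
    """A surviving seed: coordinates name the start of the full span."""

    read_id: str
    frame: int
    q_start: int  # span start in the query frame (0-based)
    db_start: int  # span start in the concatenated database text
    span: int


@dataclass(frozen=True)
class QueryKey:
    q_start: int  # span start
    core: str  # A1-reduced core word
    left: str  # A2-reduced left flank
    right: str  # A2-reduced right flank


def enumerate_query_keys(frame: QueryFrame, p: SeedParams) -> list:
    """Keys for every position where the full span fits cleanly.

    Spans containing a stop codon or an ambiguity residue are discarded
    entirely — a stop can never seed (mirroring the delimiter rule on
    the database side) and an ambiguity symbol matches nothing.
    """
    s = frame.protein
    span = p.span
    n = len(s)
    if n < span:
        return []
    red1 = p.alphabet1.reduce(s)
    red2 = p.alphabet2.reduce(s)
    bad = np.fromiter(
        ((c == STOP or c == NO_MATCH) for c in red2), count=n, dtype=bool
    )
    csum = np.concatenate(([0], np.cumsum(bad)))
    keys = []
    for q in range(n - span + 1):
        if csum[q + span] - csum[q] != 0:
            continue
        keys.append(
            QueryKey(
                q_start=q,
                core=red1[q + p.L2 : q + p.L2 + p.L1],
                left=red2[q : q + p.L2],
                right=red2[q + p.L2 + p.L1 : q + span],
            )
        )
    return keys


def hamming_neighborhood(word: str, H: int, symbols: str) -> list:
    """All words over ``symbols`` within Hamming distance ``H`` of ``word``.

    Includes the word itself; size is sum_{i<=H} C(L,i) (k-1)^i.
    """
    L = len(word)
    if not 0 <= H <= L:
        raise ParameterError(f"need 0 <= H <= len(word)={L}, got H={H}")
    out = [word]
    chars = list(word)
    for d in range(1, H + 1):
        for positions in combinations(range(L), d):
            alternatives = [[c for c in symbols if c != word[i]] for i in positions]
            for repl in product(*alternatives):
                w = chars.copy()
                for i, c in zip(positions, repl):
                    w[i] = c
                out.append("".join(w))
    return out


def first_step(index: SeedIndex, seed1_word: str, H1: int) -> np.ndarray:
    """Candidate core positions: postings union over the Hamming neighborhood."""
    if H1 == 0:
        hits = index.postings.get(seed1_word)
        return hits if hits is not None else np.empty(0, dtype=np.int64)
    parts = []
    for w in hamming_neighborhood(seed1_word, H1, index.alphabet1.symbols):
        p = index.postings.get(w)
        if p is not None:
            parts.append(p)
    if not parts:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(parts))


def second_step(index: SeedIndex, q_left: str, q_right: str, candidate: int, H2: int) -> bool:
    """Both flanks within Hamming distance H2 under the flank alphabet."""
    if index.L2 == 0:
        return True
    L1, L2 = index.L1, index.L2
    text = index.reduced2
    d_left = sum(a != b for a, b in zip(q_left, text[candidate - L2 : candidate]))
    if d_left > H2:
        return False
    d_right = sum(
        a != b for a, b in zip(q_right, text[candidate + L1 : candidate + L1 + L2])
    )
    return d_right <= H2


def _second_step_bulk(
    index: SeedIndex, key: QueryKey, candidates: np.ndarray, H2: int
) -> np.ndarray:
    """Vectorized flank filter over all candidates of one key."""
    if index.L2 == 0 or candidates.size == 0:
        return candidates
    L1, L2 = index.L1, index.L2
    codes = index.reduced2_codes
    ql = np.frombuffer(key.left.encode("ascii"), dtype=np.uint8)
    qr = np.frombuffer(key.right.encode("ascii"), dtype=np.uint8)
    offs = np.arange(L2)
    left = codes[candidates[:, None] - L2 + offs]
    right = codes[candidates[:, None] + L1 + offs]
    ok = ((left != ql).sum(axis=1) <= H2) & ((right != qr).sum(axis=1) <= H2)
    return candidates[ok]


def two_step_seed_search(frame: QueryFrame, index: SeedIndex, p: SeedParams) -> list:
    """All seed hits of one query frame, ordered by (q_start, db_start)."""
    if (
        p.L1 != index.L1
        or p.L2 != index.L2
        or p.alphabet1.group_members != index.alphabet1.group_members
        or p.alphabet2.group_members != index.alphabet2.group_members
    ):
        raise ParameterError("seed parameters do not match the index they query")
    hits = []
    seen = set()
    for key in enumerate_query_keys(frame, p):
        candidates = first_step(index, key.core, p.H1)
        passed = _second_step_bulk(index, key, candidates, p.H2)
        for c in passed.tolist():
            pair = (key.q_start, c - p.L2)
            if pair not in seen:
                seen.add(pair)
                hits.append(
                    SeedHit(
                        read_id=frame.read_id,
                        frame=frame.frame,
                        q_start=key.q_start,
                        db_start=c - p.L2,
                        span=p.span,
                    )
                )
    hits.sort(key=lambda h: (h.q_start, h.db_start))
    return hits
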