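"""Independent brute-force oracles used across the test suite.

These deliberately re-derive results from first principles (exhaustive
scans, path enumeration, step-by-step simulation) without reusing the
package's search or alignment code paths.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from tsss.dbindex import ConcatenatedDatabase, enumerate_positions
from tsss.scoring import load_blosum62
from tsss.seedsearch import SeedParams, enumerate_query_keys
from tsss.translation import QueryFrame


def brute_force_seed_hits(frame: QueryFrame, db: ConcatenatedDatabase, p: SeedParams):
    """Double-Hamming scan over every admitted database position."""
    span_starts = enumerate_positions(db, p.span)
    cores = span_starts + p.L2
    red1d = np.frombuffer(p.alphabet1.reduce(db.text).encode(), dtype=np.uint8)
    red2d = np.frombuffer(p.alphabet2.reduce(db.text).encode(), dtype=np.uint8)
    L1, L2 = p.L1, p.L2
    hits = set()
    for key in enumerate_query_keys(frame, p):
        core = np.frombuffer(key.core.encode(), dtype=np.uint8)
        left = np.frombuffer(key.left.encode(), dtype=np.uint8)
        right = np.frombuffer(key.right.encode(), dtype=np.uint8)
        d1 = (red1d[cores[:, None] + np.arange(L1)] != core).sum(1)
        ok = d1 <= p.H1
        if L2:
            dl = (red2d[cores[:, None] + np.arange(-L2, 0)] != left).sum(1)
            dr = (red2d[cores[:, None] + np.arange(L1, L1 + L2)] != right).sum(1)
            ok &= (dl <= p.H2) & (dr <= p.H2)
        for c in cores[ok]:
            hits.add((key.q_start, int(c) - L2))
    return hits


def simulate_ungapped(q: str, d: str, q_start: int, db_start: int, span: int, x: int):
    """Step-by-step simulation of the X-dropoff stopping rule."""
    m = load_blosum62()
    seed = sum(m.score(q[q_start + i], d[db_start + i]) for i in range(span))

    def walk(positions):
        run, best = 0, 0
        best_steps = 0
        for step, (qi, di) in enumerate(positions, start=1):
            if d[di] == "#":
                break
            run += m.score(q[qi], d[di])
            if run > best:
                best, best_steps = run, step
            if best - run > x:
                break
        return best, best_steps

    lg, ls = walk(
        zip(range(q_start - 1, -1, -1), range(db_start - 1, -1, -1))
    )
    rg, rs = walk(
        zip(range(q_start + span, len(q)), range(db_start + span, len(d)))
    )
    return (
        q_start - ls,
        q_start + span + rs,
        db_start - ls,
        db_start + span + rs,
        seed + lg + rg,
    )


def exhaustive_local_score(q: str, s: str, gap_open: int, gap_extend: int) -> int:
    """Optimal local score by enumerating all gapped alignments.

    Every alignment of every substring pair is visited through a
    memoized recursion over (remaining query, remaining subject, state);
    no dynamic-programming matrix of the implementation kind is shared.
    """
    m = load_blosum62()

    @lru_cache(maxsize=None)
    def best_full(a: str, b: str, state: str) -> int:
        # best score aligning ALL of a against ALL of b, given the
        # preceding column state ('m' = start/match, 'q' = gap in b,
        # 's' = gap in a)
        if not a and not b:
            return 0
        options = []
        if a and b:
            options.append(m.score(a[0], b[0]) + best_full(a[1:], b[1:], "m"))
        if a:
            cost = gap_extend if state == "q" else gap_open + gap_extend
            options.append(-cost + best_full(a[1:], b, "q"))
        if b:
            cost = gap_extend if state == "s" else gap_open + gap_extend
            options.append(-cost + best_full(a, b[1:], "s"))
        return max(options)

    best = 0
    for i in range(len(q)):
        for j in range(i + 1, len(q) + 1):
            for k in range(len(s)):
                for l in range(k + 1, len(s) + 1):
                    best = max(best, best_full(q[i:j], s[k:l], "m"))
    return best
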