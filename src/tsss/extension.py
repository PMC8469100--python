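"""Seed extension and alignment.

Seed hits are refined in three stages, mirroring the classic
seed-and-extend pipeline:

1.  *Ungapped extension* with an X-dropoff rule: extend the seed span
    left and right one residue at a time, scoring with the full 20-letter
    matrix (the reduced alphabets play no role past seeding), and stop a
    direction once the running score drops more than ``x_dropoff_ungapped``
    below its peak.  Stop codons in a query frame are scored as a virtual
    amino acid via the ``*`` row of the matrix; the ``#`` database
    delimiter is a hard wall.
2.  *Chain filtering*: overlapping or bridgeable high-scoring segment
    pairs (HSPs) on the same diagonal are merged so that a long matching
    region triggers one gapped extension instead of many.
3.  *Gapped extension*: affine-gap (Gotoh) dynamic programming with its
    own X-dropoff, anchored at the midpoint of the chained HSP and run
    independently to the left and right, BLAST-style.

A full Smith–Waterman aligner (exact optimal local alignment) lives here
too: it is the internal accuracy oracle and the reference-hit generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scoring import DELIMITER, SubstitutionMatrix
from .seedsearch import SeedHit

NEG = -(10**9)


@dataclass(frozen=True)
class ExtensionParams:
    """Alignment-stage knobs (raw score units unless noted).

    Gap costs follow the canonical BLOSUM62 pairing (11 to open, 1 per
    residue).  A gap of length ``k`` costs ``gap_open + k * gap_extend``.
    """

    x_dropoff_ungapped: int = 20
    x_dropoff_gapped: int = 30
    ungapped_cutoff: int = 40
    gap_open: int = 11
    gap_extend: int = 1
    chain_link_threshold: int = 40

    def __post_init__(self) -> None:
        for name in (
            "x_dropoff_ungapped",
            "x_dropoff_gapped",
            "ungapped_cutoff",
            "gap_open",
            "gap_extend",
            "chain_link_threshold",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class UngappedHSP:
    q_start: int
    q_end: int
    db_start: int
    db_end: int
    score: int

    @property
    def diagonal(self) -> int:
        return self.db_start - self.q_start


@dataclass(frozen=True)
class GappedAlignment:
    """Final scored local alignment.

    Query coordinates are residue positions in the query frame (0-based,
    half-open); subject coordinates are global positions in the
    concatenated database text until the pipeline resolves them.
    Statistical fields (bit score, E-value) are attached by the report
    stage.
    """

    q_start: int
    q_end: int
    db_start: int
    db_end: int
    raw_score: int
    aligned_query: str
    aligned_subject: str
    query_id: str = ""
    frame: int = 0
    subject_id: str = ""
    s_start: int = -1  # subject-local residue coords, 0-based half-open
    s_end: int = -1
    bit_score: float = float("nan")
    evalue: float = float("nan")

    @property
    def length(self) -> int:
        return len(self.aligned_query)

    @property
    def identities(self) -> int:
        return sum(
            a == b and a != "-" for a, b in zip(self.aligned_query, self.aligned_subject)
        )

    @property
    def identity_fraction(self) -> float:
        return self.identities / self.length if self.length else 0.0

    @property
    def mismatches(self) -> int:
        return sum(
            a != b and a != "-" and b != "-"
            for a, b in zip(self.aligned_query, self.aligned_subject)
        )

    @property
    def gap_openings(self) -> int:
        opens = 0
        for s in (self.aligned_query, self.aligned_subject):
            in_gap = False
            for c in s:
                if c == "-":
                    if not in_gap:
                        opens += 1
                    in_gap = True
                else:
                    in_gap = False
        return opens


def _table(m: SubstitutionMatrix, table=None) -> np.ndarray:
    return m.char_table() if table is None else table


def ungapped_extend(
    q: str,
    d: str,
    hit: SeedHit,
    m: SubstitutionMatrix,
    params: ExtensionParams,
    table: np.ndarray | None = None,
) -> UngappedHSP:
    """X-dropoff ungapped extension around a seed hit.

    The seed span itself is always included; each direction keeps the
    prefix/suffix extent with the best running score seen before the
    dropoff fired.
    """
    t = _table(m, table)
    qs, db = hit.q_start, hit.db_start
    qe, de = qs + hit.span, hit.db_start + hit.span
    seed_score = int(
        sum(t[ord(q[i]), ord(d[db + (i - qs)])] for i in range(qs, qe))
    )
    x = params.x_dropoff_ungapped

    run = 0
    best_gain, best_q = 0, qs
    i, j = qs - 1, db - 1
    while i >= 0 and j >= 0 and d[j] != DELIMITER:
        run += int(t[ord(q[i]), ord(d[j])])
        if run > best_gain:
            best_gain, best_q = run, i
        if best_gain - run > x:
            break
        i -= 1
        j -= 1
    left_gain, left_q = best_gain, best_q

    run = 0
    best_gain, best_q = 0, qe
    i, j = qe, de
    while i < len(q) and j < len(d) and d[j] != DELIMITER:
        run += int(t[ord(q[i]), ord(d[j])])
        if run > best_gain:
            best_gain, best_q = run, i + 1
        if best_gain - run > x:
            break
        i += 1
        j += 1
    right_gain, right_q = best_gain, best_q

    diag = hit.db_start - hit.q_start
    return UngappedHSP(
        q_start=left_q,
        q_end=right_q,
        db_start=left_q + diag,
        db_end=right_q + diag,
        score=seed_score + left_gain + right_gain,
    )


def filter_hsps(hsps, cutoff: int):
    """Keep HSPs whose score strictly exceeds the cutoff (order preserved)."""
    return [h for h in hsps if h.score > cutoff]


def _span_score(q: str, d: str, q_start: int, q_end: int, diag: int, t: np.ndarray) -> int:
    return int(sum(t[ord(q[i]), ord(d[i + diag])] for i in range(q_start, q_end)))


def chain_filter(
    hsps,
    q: str,
    d: str,
    m: SubstitutionMatrix,
    params: ExtensionParams,
    table: np.ndarray | None = None,
):
    """Merge same-diagonal HSPs that overlap or have a high-scoring bridge.

    Two HSPs on one diagonal merge when their spans overlap, or when the
    ungapped score of the region between them is at least
    ``chain_link_threshold``.  Merged scores are recomputed over the
    union span.  HSPs on different diagonals are never merged.
    """
    t = _table(m, table)
    by_diag: dict = {}
    for h in hsps:
        by_diag.setdefault(h.diagonal, []).append(h)
    out = []
    for diag, group in sorted(by_diag.items()):
        group.sort(key=lambda h: (h.q_start, h.q_end))
        cur = group[0]
        for nxt in group[1:]:
            if nxt.q_start <= cur.q_end:
                merge = True
            else:
                bridge = _span_score(q, d, cur.q_end, nxt.q_start, diag, t)
                merge = bridge >= params.chain_link_threshold
            if merge:
                q0, q1 = cur.q_start, max(cur.q_end, nxt.q_end)
                cur = UngappedHSP(
                    q_start=q0,
                    q_end=q1,
                    db_start=q0 + diag,
                    db_end=q1 + diag,
                    score=_span_score(q, d, q0, q1, diag, t),
                )
            else:
                out.append(cur)
                cur = nxt
        out.append(cur)
    out.sort(key=lambda h: (h.q_start, h.db_start))
    return out


def _extend_half(qs: str, ds: str, t: np.ndarray, go: int, ge: int, x: int):
    """Anchored affine-gap extension of ``qs`` against ``ds`` from (0, 0).

    Returns (score, q_used, d_used, aligned_q, aligned_d).  The empty
    extension scores 0.  Cells falling more than ``x`` below the best
    score seen so far are abandoned; the DP stops when a whole row dies.
    """
    n = len(qs)
    max_gap = x // max(ge, 1) + 2
    mcap = min(len(ds), n + max_gap)
    ds = ds[:mcap]
    m_len = len(ds)
    if n == 0 or m_len == 0:
        return 0, 0, 0, "", ""

    M = [[NEG] * (m_len + 1) for _ in range(n + 1)]
    Iq = [[NEG] * (m_len + 1) for _ in range(n + 1)]  # consumes query (gap in subject)
    Id = [[NEG] * (m_len + 1) for _ in range(n + 1)]  # consumes subject (gap in query)
    # predecessor state per cell: 0=M, 1=Iq, 2=Id, -1=origin
    pM = [[-1] * (m_len + 1) for _ in range(n + 1)]
    pIq = [[-1] * (m_len + 1) for _ in range(n + 1)]
    pId = [[-1] * (m_len + 1) for _ in range(n + 1)]

    M[0][0] = 0
    best, best_cell = 0, (0, 0, 0)
    for j in range(1, m_len + 1):
        open_s = M[0][j - 1] - go - ge
        ext_s = Id[0][j - 1] - ge
        Id[0][j] = max(open_s, ext_s)
        pId[0][j] = 0 if open_s >= ext_s else 2
        if best - Id[0][j] > x:
            Id[0][j] = NEG
    alive_any = True
    for i in range(1, n + 1):
        qc = ord(qs[i - 1])
        open_s = M[i - 1][0] - go - ge
        ext_s = Iq[i - 1][0] - ge
        Iq[i][0] = max(open_s, ext_s)
        pIq[i][0] = 0 if open_s >= ext_s else 1
        if best - Iq[i][0] > x:
            Iq[i][0] = NEG
        alive_any = Iq[i][0] > NEG
        for j in range(1, m_len + 1):
            sub = int(t[qc, ord(ds[j - 1])])
            dm, diq, did = M[i - 1][j - 1], Iq[i - 1][j - 1], Id[i - 1][j - 1]
            prev = max(dm, diq, did)
            if prev > NEG:
                M[i][j] = prev + sub
                pM[i][j] = 0 if prev == dm else (1 if prev == diq else 2)
            o, e = M[i - 1][j] - go - ge, Iq[i - 1][j] - ge
            if max(o, e) > NEG // 2:
                Iq[i][j] = max(o, e)
                pIq[i][j] = 0 if o >= e else 1
            o, e = M[i][j - 1] - go - ge, Id[i][j - 1] - ge
            if max(o, e) > NEG // 2:
                Id[i][j] = max(o, e)
                pId[i][j] = 0 if o >= e else 2
            cell = max(M[i][j], Iq[i][j], Id[i][j])
            if cell > best:
                best = cell
                s = 0 if M[i][j] == cell else (1 if Iq[i][j] == cell else 2)
                best_cell = (i, j, s)
            if best - cell > x:
                M[i][j] = Iq[i][j] = Id[i][j] = NEG
            else:
                alive_any = True
        if not alive_any:
            break
        alive_any = False

    if best <= 0:
        return 0, 0, 0, "", ""
    i, j, state = best_cell
    qi, dj = i, j
    aq, ad = [], []
    while not (i == 0 and j == 0 and state == 0):
        if state == 0:
            prev = pM[i][j]
            if i == 0 and j == 0:
                break
            aq.append(qs[i - 1])
            ad.append(ds[j - 1])
            i, j = i - 1, j - 1
        elif state == 1:
            prev = pIq[i][j]
            aq.append(qs[i - 1])
            ad.append("-")
            i -= 1
        else:
            prev = pId[i][j]
            aq.append("-")
            ad.append(ds[j - 1])
            j -= 1
        state = prev
    return best, qi, dj, "".join(reversed(aq)), "".join(reversed(ad))


def gapped_extend(
    q: str,
    d: str,
    anchor: UngappedHSP,
    m: SubstitutionMatrix,
    params: ExtensionParams,
    table: np.ndarray | None = None,
) -> GappedAlignment:
    """Gotoh affine-gap extension anchored at the HSP midpoint.

    The anchor midpoint splits the problem into two independent
    half-extensions (left of the midpoint, run on reversed strings, and
    right of it); each half keeps its best X-dropoff-bounded score and
    the final alignment is their concatenation.  The ``#`` delimiter
    bounds the subject window on both sides.
    """
    t = _table(m, table)
    qm = (anchor.q_start + anchor.q_end) // 2
    dm = qm + (anchor.db_start - anchor.q_start)

    wall_left = d.rfind(DELIMITER, 0, dm) + 1  # 0 if none
    wall_right = d.find(DELIMITER, dm)
    if wall_right == -1:
        wall_right = len(d)

    ls, lq, ld, laq, lad = _extend_half(
        q[:qm][::-1], d[wall_left:dm][::-1], t, params.gap_open, params.gap_extend,
        params.x_dropoff_gapped,
    )
    rs, rq, rd, raq, rad = _extend_half(
        q[qm:], d[dm:wall_right], t, params.gap_open, params.gap_extend,
        params.x_dropoff_gapped,
    )
    return GappedAlignment(
        q_start=qm - lq,
        q_end=qm + rq,
        db_start=dm - ld,
        db_end=dm + rd,
        raw_score=ls + rs,
        aligned_query=laq[::-1] + raq,
        aligned_subject=lad[::-1] + rad,
    )


# ---------------------------------------------------------------------------
# Smith–Waterman oracle
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LocalAlignment:
    score: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    aligned_query: str
    aligned_subject: str


def smith_waterman(
    q: str,
    s: str,
    m: SubstitutionMatrix,
    gap_open: int = 11,
    gap_extend: int = 1,
    table: np.ndarray | None = None,
) -> LocalAlignment:
    """Exact optimal local alignment with affine gaps (Gotoh recurrences).

    Deterministic traceback: ties prefer diagonal over up (gap in
    subject) over left (gap in query); among equal-scoring end cells the
    smallest (row, column) wins.
    """
    t = _table(m, table)
    n, mm = len(q), len(s)
    H = [[0] * (mm + 1) for _ in range(n + 1)]
    E = [[NEG] * (mm + 1) for _ in range(n + 1)]  # gap in query (consumes s)
    F = [[NEG] * (mm + 1) for _ in range(n + 1)]  # gap in subject (consumes q)
    best, best_cell = 0, (0, 0)
    for i in range(1, n + 1):
        qc = ord(q[i - 1])
        row_h, row_e, row_f = H[i], E[i], F[i]
        prev_h, prev_f = H[i - 1], F[i - 1]
        for j in range(1, mm + 1):
            e = max(row_e[j - 1] - gap_extend, row_h[j - 1] - gap_open - gap_extend)
            f = max(prev_f[j] - gap_extend, prev_h[j] - gap_open - gap_extend)
            h = max(0, prev_h[j - 1] + int(t[qc, ord(s[j - 1])]), e, f)
            row_e[j], row_f[j], row_h[j] = e, f, h
            if h > best:
                best, best_cell = h, (i, j)
    if best == 0:
        return LocalAlignment(0, 0, 0, 0, 0, "", "")
    i, j = best_cell
    qe, se = i, j
    aq, asub = [], []
    # state 0=H, 1=F (up), 2=E (left); start in H at the best cell
    state = 0
    while i > 0 and j > 0:
        if state == 0:
            if H[i][j] == 0:
                break
            diag = H[i - 1][j - 1] + int(t[ord(q[i - 1]), ord(s[j - 1])])
            if H[i][j] == diag:
                aq.append(q[i - 1])
                asub.append(s[j - 1])
                i, j = i - 1, j - 1
            elif H[i][j] == F[i][j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            aq.append(q[i - 1])
            asub.append("-")
            came_open = H[i - 1][j] - gap_open - gap_extend
            state = 0 if F[i][j] == came_open else 1
            i -= 1
        else:
            aq.append("-")
            asub.append(s[j - 1])
            came_open = H[i][j - 1] - gap_open - gap_extend
            state = 0 if E[i][j] == came_open else 2
            j -= 1
    return LocalAlignment(
        score=best,
        q_start=i,
        q_end=qe,
        s_start=j,
        s_end=se,
        aligned_query="".join(reversed(aq)),
        aligned_subject="".join(reversed(asub)),
    )


def sw_segment_scores(
    q: str,
    dtext: str,
    m: SubstitutionMatrix,
    gap_open: int = 11,
    gap_extend: int = 1,
    table: np.ndarray | None = None,
) -> np.ndarray:
    """Best local alignment score of ``q`` ending at each database position.

    Vectorized row-sweep Smith–Waterman over a (possibly concatenated)
    subject text; ``#`` delimiters are impassable, so per-protein optima
    can be read off with a segment-wise maximum.  Scores are exact.
    """
    t = _table(m, table).astype(np.float64)
    dcodes = np.frombuffer(dtext.encode("ascii"), dtype=np.uint8)
    mlen = len(dtext)
    if mlen == 0 or not q:
        return np.zeros(mlen)
    wall = dcodes == ord(DELIMITER)
    seg_id = np.cumsum(wall).astype(np.float64)
    BIG = 1e9
    jj = np.arange(1, mlen + 1, dtype=np.float64)
    go_ge = float(gap_open + gap_extend)
    ge = float(gap_extend)

    H_prev = np.zeros(mlen + 1)
    F_prev = np.full(mlen + 1, -1e18)
    best_col = np.zeros(mlen)
    for ch in q:
        srow = t[ord(ch), dcodes]
        F = np.maximum(F_prev[1:] - ge, H_prev[1:] - go_ge)
        diag = H_prev[:-1] + srow
        H0 = np.maximum(np.maximum(diag, F), 0.0)
        # E[j] = max_{j'<j, same segment}(H[j'] + ge*j') - go - ge*j ;
        # the seg_id*BIG offset makes any gap spanning a delimiter lose
        # BIG per wall crossed, so it can never win
        T = H0 + ge * jj + seg_id * BIG
        P = np.empty(mlen)
        P[0] = -1e18
        np.maximum.accumulate(T[:-1], out=P[1:])
        E = P - seg_id * BIG - gap_open - ge * jj
        H_row = np.maximum(H0, E)
        best_col = np.maximum(best_col, H_row)
        H_prev = np.concatenate(([0.0], H_row))
        F_prev = np.concatenate(([-1e18], F))
    return best_col


def smith_waterman_score(
    q: str,
    s: str,
    m: SubstitutionMatrix,
    gap_open: int = 11,
    gap_extend: int = 1,
    table: np.ndarray | None = None,
) -> int:
    """Score-only Smith–Waterman (fast vectorized path)."""
    if not q or not s:
        return 0
    return int(round(sw_segment_scores(q, s, m, gap_open, gap_extend, table).max()))
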