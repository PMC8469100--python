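import numpy as np

from tsss.extension import (
    ExtensionParams,
    UngappedHSP,
    chain_filter,
    filter_hsps,
    gapped_extend,
    smith_waterman,
    smith_waterman_score,
    sw_segment_scores,
    ungapped_extend,
)
from tsss.seedsearch import SeedHit
from conftest import random_protein
from oracles import exhaustive_local_score, simulate_ungapped


def hit(q_start, db_start, span):
    return SeedHit(read_id="q", frame=1, q_start=q_start, db_start=db_start, span=span)


def rescore_alignment(aq, asub, m, go, ge):
    """Recompute an affine-gap score directly from aligned strings."""
    score = 0
    prev_gap = None
    for a, b in zip(aq, asub):
        if a == "-" or b == "-":
            which = "a" if a == "-" else "b"
            score -= ge + (go if prev_gap != which else 0)
            prev_gap = which
        else:
            score += m.score(a, b)
            prev_gap = None
    return score


# --- ungapped extension ----------------------------------------------------


def test_ungapped_no_room_to_extend(blosum62):
    # seed flanked by delimiters: HSP equals the seed span
    q = "MKVLA"
    d = "#MKVLA#"
    h = hit(0, 1, 5)
    out = ungapped_extend(q, d, h, blosum62, ExtensionParams())
    assert (out.q_start, out.q_end, out.db_start, out.db_end) == (0, 5, 1, 6)
    assert out.score == sum(blosum62.score(c, c) for c in q)


def test_ungapped_identical_sequences_grow_to_full_length(blosum62, rng):
    s = random_protein(rng, 40)
    out = ungapped_extend(s, s, hit(15, 15, 6), blosum62, ExtensionParams(x_dropoff_ungapped=0))
    assert (out.q_start, out.q_end) == (0, 40)
    assert out.score == sum(blosum62.score(c, c) for c in s)


def test_ungapped_matches_step_by_step_simulation(blosum62, rng):
    for _ in range(50):
        q = random_protein(rng, 30)
        d = random_protein(rng, 25) + "#" + random_protein(rng, 35)
        span = 4
        qs = int(rng.integers(0, len(q) - span))
        ds = int(rng.integers(0, len(d) - span))
        if "#" in d[ds : ds + span]:
            continue
        x = int(rng.integers(0, 15))
        params = ExtensionParams(x_dropoff_ungapped=x)
        out = ungapped_extend(q, d, hit(qs, ds, span), blosum62, params)
        assert (
            out.q_start,
            out.q_end,
            out.db_start,
            out.db_end,
            out.score,
        ) == simulate_ungapped(q, d, qs, ds, span, x)


def test_hsp_score_recomputable(blosum62, rng):
    q = random_protein(rng, 30)
    out = ungapped_extend(q, q, hit(10, 10, 5), blosum62, ExtensionParams())
    direct = sum(
        blosum62.score(q[i], q[i + out.diagonal]) for i in range(out.q_start, out.q_end)
    )
    assert out.score == direct


# --- HSP filtering and chaining -------------------------------------------


def test_filter_is_strict():
    hsps = [
        UngappedHSP(0, 5, 0, 5, score=41),
        UngappedHSP(1, 6, 1, 6, score=40),
        UngappedHSP(2, 7, 2, 7, score=39),
    ]
    kept = filter_hsps(hsps, 40)
    assert [h.score for h in kept] == [41]
    assert filter_hsps(hsps, 0) == hsps


def test_chain_merges_overlapping_same_diagonal(blosum62):
    q = "WWWWWWWWWW"
    d = q
    a = UngappedHSP(0, 5, 0, 5, score=55)
    b = UngappedHSP(3, 9, 3, 9, score=66)
    (merged,) = chain_filter([a, b], q, d, blosum62, ExtensionParams())
    assert (merged.q_start, merged.q_end) == (0, 9)
    assert merged.score == 9 * 11


def test_chain_keeps_different_diagonals(blosum62):
    q = "WWWWWWWWWW"
    a = UngappedHSP(0, 4, 0, 4, score=44)
    b = UngappedHSP(0, 4, 2, 6, score=44)  # different diagonal
    out = chain_filter([a, b], q, q + q, blosum62, ExtensionParams())
    assert len(out) == 2


def test_chain_bridges_high_scoring_gap(blosum62):
    # two disjoint HSPs separated by tryptophans: bridge score 3*11 >= 20
    q = "WWWWWWWWWWWW"
    a = UngappedHSP(0, 4, 0, 4, score=44)
    b = UngappedHSP(7, 12, 7, 12, score=55)
    params = ExtensionParams(chain_link_threshold=20)
    (merged,) = chain_filter([a, b], q, q, blosum62, params)
    assert (merged.q_start, merged.q_end) == (0, 12)
    assert merged.score == 12 * 11  # recomputed over the union span
    # with a higher threshold the pair stays split
    out = chain_filter([a, b], q, q, blosum62, ExtensionParams(chain_link_threshold=40))
    assert len(out) == 2


def test_chain_never_increases_count_or_decreases_max(blosum62, rng):
    q = random_protein(rng, 50)
    hsps = []
    for _ in range(6):
        s = int(rng.integers(0, 40))
        e = s + int(rng.integers(3, 10))
        sc = sum(blosum62.score(q[i], q[i]) for i in range(s, min(e, 50)))
        hsps.append(UngappedHSP(s, min(e, 50), s, min(e, 50), score=sc))
    out = chain_filter(hsps, q, q, blosum62, ExtensionParams())
    assert len(out) <= len(hsps)
    assert max(h.score for h in out) >= max(h.score for h in hsps)


# --- gapped extension ------------------------------------------------------


def test_gapped_identical_tryptophans(blosum62):
    aln = gapped_extend("WWW", "WWW", UngappedHSP(0, 3, 0, 3, 33), blosum62, ExtensionParams())
    assert aln.raw_score == 33
    assert aln.aligned_query == aln.aligned_subject == "WWW"


def test_gapped_score_recomputable_from_alignment(blosum62, rng):
    params = ExtensionParams()
    for _ in range(30):
        q = random_protein(rng, 40)
        mutated = list(q)
        for k in range(len(mutated)):
            if rng.random() < 0.15:
                mutated[k] = random_protein(rng, 1)
        d = "".join(mutated[:18]) + random_protein(rng, int(rng.integers(0, 4))) + "".join(mutated[18:])
        aln = gapped_extend(q, d, UngappedHSP(5, 12, 5, 12, 30), blosum62, params)
        if not aln.aligned_query:
            continue
        assert rescore_alignment(
            aln.aligned_query, aln.aligned_subject, blosum62, params.gap_open, params.gap_extend
        ) == aln.raw_score
        assert aln.aligned_query.replace("-", "") == q[aln.q_start : aln.q_end]
        assert aln.aligned_subject.replace("-", "") == d[aln.db_start : aln.db_end]


def test_gapped_never_exceeds_optimal(blosum62, rng):
    for _ in range(40):
        q = random_protein(rng, int(rng.integers(10, 60)))
        s = random_protein(rng, int(rng.integers(10, 60)))
        opt = smith_waterman(q, s, blosum62).score
        mid = min(len(q), len(s)) // 2
        aln = gapped_extend(
            q, s, UngappedHSP(max(0, mid - 2), mid + 2, max(0, mid - 2), mid + 2, 0),
            blosum62, ExtensionParams(),
        )
        assert aln.raw_score <= opt


def test_gapped_equals_optimal_through_anchor(blosum62, rng):
    """Anchored at a diagonal step of the optimal path, with a dropoff at
    least the optimal score, the two half-extensions recover the optimum."""
    checked = 0
    for _ in range(60):
        base = random_protein(rng, int(rng.integers(20, 50)))
        # make the pair clearly homologous so the optimum is non-trivial
        mutated = "".join(
            c if rng.random() > 0.2 else random_protein(rng, 1) for c in base
        )
        opt = smith_waterman(base, mutated, blosum62)
        if opt.score <= 0:
            continue
        # pick the middle aligned residue pair (a diagonal step)
        cols = [
            t
            for t, (a, b) in enumerate(zip(opt.aligned_query, opt.aligned_subject))
            if a != "-" and b != "-"
        ]
        if not cols:
            continue
        mid_col = cols[len(cols) // 2]
        qm = opt.q_start + sum(1 for c in opt.aligned_query[:mid_col] if c != "-")
        sm = opt.s_start + sum(1 for c in opt.aligned_subject[:mid_col] if c != "-")
        params = ExtensionParams(x_dropoff_gapped=2 * opt.score + 50)
        aln = gapped_extend(
            base, mutated, UngappedHSP(qm, qm + 1, sm, sm + 1, 0), blosum62, params
        )
        assert aln.raw_score == opt.score
        checked += 1
    assert checked >= 20


# --- Smith-Waterman oracle -------------------------------------------------


def test_sw_identical_alanines(blosum62):
    assert smith_waterman("AAAA", "AAAA", blosum62).score == 16


def test_sw_all_negative_pairs_floor_at_zero(blosum62):
    aln = smith_waterman("WWWW", "PPPP", blosum62)
    assert aln.score == 0 and aln.aligned_query == ""


def test_sw_matches_exhaustive_enumeration(blosum62):
    """Exact optimum vs full path enumeration on short 3-letter strings."""
    from itertools import product

    alphabet = "AGW"
    pairs = 0
    for n1 in range(1, 4):
        for n2 in range(1, 4):
            for q in map("".join, product(alphabet, repeat=n1)):
                for s in map("".join, product(alphabet, repeat=n2)):
                    expected = exhaustive_local_score(q, s, 11, 1)
                    assert smith_waterman(q, s, blosum62).score == expected
                    pairs += 1
    assert pairs == (3 + 9 + 27) ** 2


def test_sw_alignment_rescores_to_its_score(blosum62, rng):
    for _ in range(30):
        q = random_protein(rng, int(rng.integers(5, 50)))
        s = random_protein(rng, int(rng.integers(5, 50)))
        aln = smith_waterman(q, s, blosum62)
        if aln.score == 0:
            continue
        assert rescore_alignment(aln.aligned_query, aln.aligned_subject, blosum62, 11, 1) == aln.score
        assert aln.aligned_query.replace("-", "") == q[aln.q_start : aln.q_end]
        assert aln.aligned_subject.replace("-", "") == s[aln.s_start : aln.s_end]


def test_sw_matches_biopython(blosum62, rng):
    """Dual route: scores agree with Biopython's exact local aligner."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -1
    for _ in range(40):
        q = random_protein(rng, int(rng.integers(5, 60)))
        s = random_protein(rng, int(rng.integers(5, 60)))
        ours = smith_waterman(q, s, blosum62).score
        theirs = aligner.score(q, s)
        assert ours == max(0, int(theirs))


def test_vectorized_score_equals_dp(blosum62, rng):
    for _ in range(30):
        q = random_protein(rng, int(rng.integers(3, 40)))
        s = random_protein(rng, int(rng.integers(3, 60)))
        assert smith_waterman_score(q, s, blosum62) == smith_waterman(q, s, blosum62).score


def test_segment_scores_respect_walls(blosum62, rng):
    q = random_protein(rng, 15)
    segs = [random_protein(rng, int(rng.integers(5, 30))) for _ in range(4)]
    text = "#".join(segs)
    col = sw_segment_scores(q, text, blosum62)
    starts = [0]
    for s in segs[:-1]:
        starts.append(starts[-1] + len(s) + 1)
    per = np.maximum.reduceat(col, np.asarray(starts))
    for got, seg in zip(per, segs):
        assert int(round(got)) == smith_waterman(q, seg, blosum62).score
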