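"""Ranking, alignment statistics, tabular output and the accuracy metric.

Raw alignment scores are converted to bit scores and E-values with
Karlin–Altschul statistics using the canonical gapped parameters for
BLOSUM62 with gap costs (11, 1): lambda = 0.267, K = 0.041.  The search
space is ``m * n`` with ``m`` the query-frame residue length and ``n``
the total database residue count.

Accuracy follows the standard protocol for evaluating heuristic protein
search: reference hits are the up-to-10 best optimal (Smith–Waterman)
subjects per query at E <= 1e-5, and accuracy is the pooled fraction of
reference hits that the heuristic recovers in its own top 10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .dbindex import ConcatenatedDatabase
from .extension import GappedAlignment, sw_segment_scores
from .scoring import SubstitutionMatrix


@dataclass(frozen=True)
class SearchStats:
    """Karlin–Altschul parameters plus the database size."""

    lambda_g: float = 0.267
    K_g: float = 0.041
    db_residues: int = 0

    def __post_init__(self) -> None:
        if self.lambda_g <= 0 or self.K_g <= 0:
            raise ValueError("lambda and K must be positive")


def bit_score(raw: int, stats: SearchStats) -> float:
    return (stats.lambda_g * raw - math.log(stats.K_g)) / math.log(2)


def evalue(raw: int, stats: SearchStats, query_length: int) -> float:
    return stats.K_g * query_length * stats.db_residues * math.exp(-stats.lambda_g * raw)


def attach_statistics(aln: GappedAlignment, stats: SearchStats, query_length: int) -> GappedAlignment:
    return replace(
        aln,
        bit_score=bit_score(aln.raw_score, stats),
        evalue=evalue(aln.raw_score, stats, query_length),
    )


def rank_and_select(alignments, max_out: int = 10, evalue_cutoff: float = 10.0):
    """Best alignment per subject, ranked, truncated to ``max_out``.

    Sort order: bit score descending, then E-value ascending, then
    subject id lexicographic (a total, deterministic order).
    """
    best: dict = {}
    for a in alignments:
        b = best.get(a.subject_id)
        if b is None or (-a.bit_score, a.evalue) < (-b.bit_score, b.evalue):
            best[a.subject_id] = a
    ranked = sorted(best.values(), key=lambda a: (-a.bit_score, a.evalue, a.subject_id))
    ranked = [a for a in ranked if a.evalue <= evalue_cutoff]
    return ranked[:max_out]


def _dna_coords(aln: GappedAlignment, dna_length: int):
    """Map frame residue coordinates to 1-based DNA read coordinates.

    Forward frames report ascending coordinates; reverse frames report
    start > end, as translated-search tools conventionally do.
    """
    off = abs(aln.frame) - 1
    if aln.frame > 0:
        qstart = off + 3 * aln.q_start + 1
        qend = off + 3 * aln.q_end
    else:
        qstart = dna_length - (off + 3 * aln.q_start)
        qend = dna_length - (off + 3 * aln.q_end) + 1
    return qstart, qend


def _fmt_evalue(e: float) -> str:
    if e == 0.0 or e < 1e-180:
        return "0.0"
    if e < 1e-2:
        mant, exp = f"{e:.2e}".split("e")
        return f"{float(mant):g}e{int(exp):+03d}"
    return f"{e:.3g}"


def format_tabular_line(aln: GappedAlignment, dna_length: int) -> str:
    qstart, qend = _dna_coords(aln, dna_length)
    fields = [
        aln.query_id,
        aln.subject_id,
        f"{100.0 * aln.identity_fraction:.2f}",
        str(aln.length),
        str(aln.mismatches),
        str(aln.gap_openings),
        str(qstart),
        str(qend),
        str(aln.s_start + 1),
        str(aln.s_end),
        _fmt_evalue(aln.evalue),
        f"{aln.bit_score:.1f}",
    ]
    return "\t".join(fields)


def write_tabular(results, sink, dna_lengths: dict) -> int:
    """Write BLAST outfmt-6 style lines; returns the line count.

    ``results`` maps to one ranked alignment list per query, in query
    input order; ``dna_lengths`` maps read id to its DNA length.
    """
    n = 0
    for ranked in results:
        for aln in ranked:
            sink.write(format_tabular_line(aln, dna_lengths[aln.query_id]) + "\n")
            n += 1
    return n


@dataclass(frozen=True)
class ReferenceHitSet:
    """Up-to-10 optimal subjects per query id, in rank order."""

    hits: dict  # query id -> tuple of subject ids

    def __post_init__(self) -> None:
        for qid, subs in self.hits.items():
            if len(subs) > 10 or len(set(subs)) != len(subs):
                raise ValueError(f"bad reference hit list for {qid!r}")


def accuracy(results: dict, refs: ReferenceHitSet, top_k: int = 10) -> float:
    """Pooled recovery fraction of reference hits.

    ``results`` maps query id to an ordered subject id list.  Both the
    numerator (matches within the top ``top_k``) and the denominator
    (reference hit counts) are pooled over all queries.
    """
    matched = 0
    total = 0
    for qid, ref_subjects in refs.hits.items():
        total += len(ref_subjects)
        got = set(results.get(qid, ())[:top_k])
        matched += sum(1 for s in ref_subjects if s in got)
    return matched / total if total else 0.0


def build_reference_hits(
    db: ConcatenatedDatabase,
    query_frames: dict,
    m: SubstitutionMatrix,
    stats: SearchStats,
    gap_open: int = 11,
    gap_extend: int = 1,
    evalue_cutoff: float = 1e-5,
    max_hits: int = 10,
) -> ReferenceHitSet:
    """Optimal reference hits via exhaustive Smith–Waterman.

    For every query read, every translated frame is aligned against the
    whole database (one vectorized sweep per frame over the concatenated
    text); the best raw score per subject, over frames, is converted to
    an E-value with that frame's length.  Subjects with E <= cutoff are
    ranked by E (ties by subject id) and truncated to ``max_hits``.
    """
    import numpy as np

    table = m.char_table()
    starts = db.boundaries
    hits = {}
    for qid, frames in query_frames.items():
        best_scores = np.zeros(db.n_sequences)
        best_mlen = np.zeros(db.n_sequences, dtype=np.int64)
        for fr in frames:
            if not fr.protein:
                continue
            col = sw_segment_scores(fr.protein, db.text, m, gap_open, gap_extend, table)
            per_subject = np.maximum.reduceat(col, starts)
            better = per_subject > best_scores
            best_scores = np.where(better, per_subject, best_scores)
            best_mlen = np.where(better, len(fr.protein), best_mlen)
        ranked = []
        for i in range(db.n_sequences):
            if best_scores[i] <= 0:
                continue
            e = evalue(int(round(best_scores[i])), stats, int(best_mlen[i]))
            if e <= evalue_cutoff:
                ranked.append((e, -best_scores[i], db.ids[i]))
        ranked.sort()
        hits[qid] = tuple(sid for _, _, sid in ranked[:max_hits])
    return ReferenceHitSet(hits=hits)
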