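"""End-to-end search orchestration and evaluation.

The flow per query read: six-frame translation, two-step seed search of
every frame against the index, ungapped X-dropoff extension of each seed
hit, score-threshold and chain filtering, gapped extension, and finally
per-read ranking.  The engine is single-threaded; its parallelism
contract is that searching any partition of the query file and
concatenating the outputs reproduces the single run byte for byte.
"""

from __future__ import annotations

import logging
from collections import namedtuple
from dataclasses import dataclass, replace
from itertools import product

from .dbindex import SeedIndex, build_seed_index, concatenate
from .errors import ParameterError
from .extension import (
    ExtensionParams,
    chain_filter,
    filter_hsps,
    gapped_extend,
    ungapped_extend,
)
from .report import (
    SearchStats,
    accuracy,
    attach_statistics,
    build_reference_hits,
    rank_and_select,
    write_tabular,
)
from .reduced_alphabet import build_reduced_alphabet
from .scoring import load_blosum62
from .seedsearch import SeedParams, enumerate_query_keys, two_step_seed_search
from .translation import six_frame_translate

log = logging.getLogger(__name__)

#: Representative parameter presets (H1, H2, L1, A1, L2, A2): ``fast``
#: trades sensitivity for speed, ``sensitive`` the reverse.
PRESETS = {
    "fast": (0, 1, 4, 18, 5, 6),
    "middle": (0, 1, 4, 16, 4, 8),
    "sensitive": (0, 1, 2, 18, 5, 8),
}

GridPoint = namedtuple("GridPoint", "H1 H2 L1 A1 L2 A2")

#: Survey ranges for parameter exploration.
GRID_RANGES = {
    "H": [(0, 0), (0, 1), (1, 1)],
    "L1": [2, 4, 6, 8],
    "A1": [6, 8, 10, 12, 14, 16, 18],
    "L2": [2, 3, 4, 5],
    "A2": [4, 6, 8, 10],
}


def enumerate_parameter_grid(ranges: dict | None = None):
    """Cartesian product of the survey ranges, in deterministic order."""
    r = dict(GRID_RANGES)
    if ranges:
        r.update(ranges)
    for key in ("H", "L1", "A1", "L2", "A2"):
        if not r.get(key):
            raise ParameterError(f"empty range for {key}")
    return [
        GridPoint(h[0], h[1], l1, a1, l2, a2)
        for h, l1, a1, l2, a2 in product(r["H"], r["L1"], r["A1"], r["L2"], r["A2"])
    ]


def make_seed_params(preset_or_point) -> SeedParams:
    """Build :class:`SeedParams` from a preset name or an (H1,H2,L1,A1,L2,A2) tuple."""
    if isinstance(preset_or_point, str):
        try:
            point = PRESETS[preset_or_point]
        except KeyError:
            raise ParameterError(
                f"unknown preset {preset_or_point!r}; choose from {sorted(PRESETS)}"
            )
    else:
        point = tuple(preset_or_point)
    h1, h2, l1, a1, l2, a2 = point
    m = load_blosum62()
    return SeedParams(
        H1=h1,
        H2=h2,
        L1=l1,
        alphabet1=build_reduced_alphabet(m, a1),
        L2=l2,
        alphabet2=build_reduced_alphabet(m, a2),
    )


def build_index_for(db_seqs, params: SeedParams) -> SeedIndex:
    db = concatenate(db_seqs)
    return build_seed_index(db, params.alphabet1, params.L1, params.alphabet2, params.L2)


@dataclass
class RunSummary:
    reads: int = 0
    frames: int = 0
    keys: int = 0
    seed_hits: int = 0
    hsps_passing_cutoff: int = 0
    chained_hsps: int = 0
    gapped_alignments: int = 0
    reported_lines: int = 0

    def as_dict(self) -> dict:
        return dict(vars(self))


def _search_read(read_id, dna, index, matrix, params, ext_params, stats, table, summary):
    db = index.db
    alignments = []
    frames = six_frame_translate(read_id, dna)
    summary.frames += len(frames)
    for fr in frames:
        keys = enumerate_query_keys(fr, params)
        summary.keys += len(keys)
        if not keys:
            continue
        hits = two_step_seed_search(fr, index, params)
        summary.seed_hits += len(hits)
        if not hits:
            continue
        hsps = [
            ungapped_extend(fr.protein, db.text, h, matrix, ext_params, table)
            for h in hits
        ]
        hsps = filter_hsps(hsps, ext_params.ungapped_cutoff)
        summary.hsps_passing_cutoff += len(hsps)
        if not hsps:
            continue
        chained = chain_filter(hsps, fr.protein, db.text, matrix, ext_params, table)
        summary.chained_hsps += len(chained)
        for hsp in chained:
            aln = gapped_extend(fr.protein, db.text, hsp, matrix, ext_params, table)
            if aln.raw_score <= 0 or not aln.aligned_query:
                continue
            summary.gapped_alignments += 1
            sid, s_local = db.resolve(aln.db_start)
            aln = replace(
                aln,
                query_id=read_id,
                frame=fr.frame,
                subject_id=sid,
                s_start=s_local,
                s_end=s_local + (aln.db_end - aln.db_start),
            )
            alignments.append(attach_statistics(aln, stats, len(fr.protein)))
    return rank_and_select(alignments)


def search_reads(
    index: SeedIndex,
    reads,
    params: SeedParams,
    ext_params: ExtensionParams | None = None,
    max_out: int = 10,
):
    """Search (id, dna) reads against an index.

    Returns (list of ranked alignment lists in read order, RunSummary).
    """
    if ext_params is None:
        ext_params = ExtensionParams()
    matrix = load_blosum62()
    table = matrix.char_table()
    stats = SearchStats(db_residues=index.db.n_residues)
    summary = RunSummary()
    results = []
    for rid, dna in reads:
        summary.reads += 1
        ranked = _search_read(
            rid, dna, index, matrix, params, ext_params, stats, table, summary
        )
        results.append(ranked[:max_out])
    summary.reported_lines = sum(len(r) for r in results)
    return results, summary


def run_search(db_seqs, reads, preset_or_params, ext_params=None, sink=None):
    """Full pipeline from in-memory inputs to tabular lines.

    ``preset_or_params`` is a preset name, a grid tuple, or a ready
    :class:`SeedParams`.  If ``sink`` is given, outfmt-6 lines are
    written to it.  Returns (results, summary).
    """
    params = (
        preset_or_params
        if isinstance(preset_or_params, SeedParams)
        else make_seed_params(preset_or_params)
    )
    index = build_index_for(db_seqs, params)
    results, summary = search_reads(index, reads, params, ext_params)
    if sink is not None:
        dna_lengths = {rid: len(dna) for rid, dna in reads}
        summary.reported_lines = write_tabular(results, sink, dna_lengths)
    return results, summary


def results_to_subject_lists(results) -> dict:
    """Collapse ranked alignments to {query id: ordered subject ids}."""
    out: dict = {}
    for ranked in results:
        if ranked:
            out[ranked[0].query_id] = [a.subject_id for a in ranked]
    return out


def evaluate_run(
    db_seqs,
    reads,
    truth: dict,
    presets=("fast", "middle", "sensitive"),
    ext_params: ExtensionParams | None = None,
    reference_evalue: float = 1e-5,
):
    """Accuracy of each preset against the Smith–Waterman reference.

    Builds reference hits once with the exact-alignment oracle
    (E <= ``reference_evalue``), runs every preset, and reports the
    pooled accuracy plus the fraction of homologous reads whose top hit
    is their true source protein.
    """
    matrix = load_blosum62()
    db = concatenate(db_seqs)
    stats = SearchStats(db_residues=db.n_residues)
    frames = {rid: six_frame_translate(rid, dna) for rid, dna in reads}
    refs = build_reference_hits(db, frames, matrix, stats, evalue_cutoff=reference_evalue)

    rows = {}
    for name in presets:
        params = make_seed_params(name)
        results, summary = run_search(db_seqs, reads, params, ext_params)
        subjects = results_to_subject_lists(results)
        homologous = [rid for rid, src in truth.items() if src is not None]
        top_ok = sum(
            1
            for rid in homologous
            if subjects.get(rid) and subjects[rid][0] == truth[rid]
        )
        rows[name] = {
            "accuracy": accuracy(subjects, refs),
            "top_hit_rate": top_ok / len(homologous) if homologous else float("nan"),
            "summary": summary.as_dict(),
        }
    return rows, refs
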