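"""Concatenated protein database and the seed inverted index.

All database proteins are joined into one string with ``#`` delimiters.
Seed search then works on global positions in this string; an offset
table maps any position back to (sequence id, local offset).

The index maps every admissible seed-core word — recoded into the core
reduced alphabet A1 — to the sorted global positions where it occurs.
A core position is admissible only if the core window and both length-L2
flank windows lie inside one protein (no delimiter, no out-of-bounds):
a hit that cannot present both flanks can never pass the second seed
step, so it is excluded at build time.  The flank comparison itself runs
directly against the database text recoded into the flank alphabet A2,
which the index stores alongside the postings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import IndexFormatError, InputError, ParameterError, TsssError
from .reduced_alphabet import ReducedAlphabet, load_fixed_alphabet, format_alphabet
from .scoring import DELIMITER, STOP, load_blosum62

_MAGIC = "tsss-index-v1"


@dataclass(frozen=True)
class ConcatenatedDatabase:
    text: str
    ids: tuple
    lengths: tuple
    boundaries: np.ndarray  # start offset of each sequence, sorted

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def n_residues(self) -> int:
        return sum(self.lengths)

    def resolve(self, position: int):
        """Map a global position to (sequence id, local 0-based offset)."""
        if not 0 <= position < len(self.text):
            raise TsssError(f"position {position} out of range")
        if self.text[position] == DELIMITER:
            raise TsssError(f"position {position} is a delimiter")
        i = int(np.searchsorted(self.boundaries, position, side="right")) - 1
        return self.ids[i], position - int(self.boundaries[i])

    def sequence_index_at(self, position: int) -> int:
        return int(np.searchsorted(self.boundaries, position, side="right")) - 1

    def global_position(self, seq_index: int, offset: int) -> int:
        return int(self.boundaries[seq_index]) + offset


def concatenate(seqs) -> ConcatenatedDatabase:
    """Join (id, protein) pairs with the ``#`` delimiter."""
    import logging

    log = logging.getLogger(__name__)
    kept = []
    seen = set()
    for sid, seq in seqs:
        if sid in seen:
            raise InputError(f"duplicate sequence id {sid!r}")
        seen.add(sid)
        seq = seq.upper()
        if not seq:
            log.warning("empty sequence %s skipped", sid)
            continue
        kept.append((sid, seq))
    if not kept:
        raise InputError("database contains no non-empty sequences")
    boundaries = []
    pos = 0
    for sid, seq in kept:
        boundaries.append(pos)
        pos += len(seq) + 1
    return ConcatenatedDatabase(
        text=DELIMITER.join(seq for _, seq in kept),
        ids=tuple(sid for sid, _ in kept),
        lengths=tuple(len(seq) for _, seq in kept),
        boundaries=np.asarray(boundaries, dtype=np.int64),
    )


def _blocked_mask(text: str) -> np.ndarray:
    """Positions that can never participate in a seed word.

    The delimiter blocks by construction; a stop symbol in a database
    sequence (unusual, but legal FASTA) likewise cannot seed, though it
    still scores during extension.
    """
    arr = np.frombuffer(text.encode("ascii"), dtype=np.uint8)
    return (arr == ord(DELIMITER)) | (arr == ord(STOP))


def enumerate_positions(db: ConcatenatedDatabase, span: int) -> np.ndarray:
    """All global positions whose length-``span`` window is delimiter-free."""
    if span < 1:
        raise ParameterError(f"span must be >= 1, got {span}")
    n = len(db.text)
    if span > n:
        return np.empty(0, dtype=np.int64)
    blocked = _blocked_mask(db.text)
    csum = np.concatenate(([0], np.cumsum(blocked)))
    starts = np.arange(n - span + 1, dtype=np.int64)
    ok = (csum[starts + span] - csum[starts]) == 0
    return starts[ok]


@dataclass(frozen=True)
class SeedIndex:
    """Inverted index over A1-reduced core words plus the A2-reduced text."""

    db: ConcatenatedDatabase
    alphabet1: ReducedAlphabet
    L1: int
    alphabet2: ReducedAlphabet
    L2: int
    postings: dict  # core word -> sorted int64 array of core start positions
    reduced1: str
    reduced2: str
    reduced2_codes: np.ndarray  # uint8 view of reduced2 for fast Hamming

    @property
    def span(self) -> int:
        return self.L1 + 2 * self.L2


def build_seed_index(
    db: ConcatenatedDatabase,
    a1: ReducedAlphabet,
    L1: int,
    a2: ReducedAlphabet,
    L2: int,
) -> SeedIndex:
    if L1 < 1:
        raise ParameterError(f"L1 must be >= 1, got {L1}")
    if L2 < 0:
        raise ParameterError(f"L2 must be >= 0, got {L2}")
    # a core position is admissible iff the full span starting L2 to its
    # left is one clean window
    span_starts = enumerate_positions(db, L1 + 2 * L2)
    cores = span_starts + L2
    reduced1 = a1.reduce(db.text)
    reduced2 = a2.reduce(db.text)
    postings: dict = {}
    for c in cores.tolist():
        postings.setdefault(reduced1[c : c + L1], []).append(c)
    postings = {w: np.asarray(p, dtype=np.int64) for w, p in postings.items()}
    return SeedIndex(
        db=db,
        alphabet1=a1,
        L1=L1,
        alphabet2=a2,
        L2=L2,
        postings=postings,
        reduced1=reduced1,
        reduced2=reduced2,
        reduced2_codes=np.frombuffer(reduced2.encode("ascii"), dtype=np.uint8),
    )


def resolve(db: ConcatenatedDatabase, position: int):
    return db.resolve(position)


def save_index(index: SeedIndex, path) -> None:
    """Serialize to a single binary container (bit-exact reload)."""
    words = sorted(index.postings)
    counts = np.asarray([len(index.postings[w]) for w in words], dtype=np.int64)
    flat = (
        np.concatenate([index.postings[w] for w in words])
        if words
        else np.empty(0, dtype=np.int64)
    )
    header = json.dumps(
        {
            "magic": _MAGIC,
            "L1": index.L1,
            "L2": index.L2,
            "alphabet1": format_alphabet(index.alphabet1),
            "alphabet2": format_alphabet(index.alphabet2),
            "ids": list(index.db.ids),
            "lengths": list(index.db.lengths),
        }
    )
    with open(path, "wb") as fh:  # keep the exact filename (np.savez appends .npz)
        np.savez(
            fh,
            header=np.array(header),
            text=np.array(index.db.text),
            words=np.array(words),
            counts=counts,
            positions=flat,
        )


def load_index(path) -> SeedIndex:
    try:
        with np.load(path, allow_pickle=False) as z:
            header = json.loads(str(z["header"]))
            if header.get("magic") != _MAGIC:
                raise IndexFormatError(f"{path}: not a seed index file")
            text = str(z["text"])
            words = [str(w) for w in z["words"]]
            counts = z["counts"]
            flat = z["positions"]
    except (OSError, KeyError, ValueError) as exc:
        raise IndexFormatError(f"cannot read index {path}: {exc}")
    m = load_blosum62()
    a1 = load_fixed_alphabet(header["alphabet1"], m)
    a2 = load_fixed_alphabet(header["alphabet2"], m)
    boundaries = []
    pos = 0
    for ln in header["lengths"]:
        boundaries.append(pos)
        pos += ln + 1
    db = ConcatenatedDatabase(
        text=text,
        ids=tuple(header["ids"]),
        lengths=tuple(header["lengths"]),
        boundaries=np.asarray(boundaries, dtype=np.int64),
    )
    postings = {}
    off = 0
    for w, c in zip(words, counts.tolist()):
        postings[w] = flat[off : off + c].copy()
        off += c
    return SeedIndex(
        db=db,
        alphabet1=a1,
        L1=header["L1"],
        alphabet2=a2,
        L2=header["L2"],
        postings=postings,
        reduced1=a1.reduce(text),
        reduced2=a2.reduce(text),
        reduced2_codes=np.frombuffer(a2.reduce(text).encode("ascii"), dtype=np.uint8),
    )
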