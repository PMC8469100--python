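"""Six-frame translation of DNA reads and FASTA/FASTQ ingestion.

Queries are DNA reads; homology is assessed at the protein level, so
every read is translated in all six reading frames with the standard
genetic code (stop codons emit ``*``, codons containing ``N`` emit
``X``, trailing partial codons are dropped).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Data import CodonTable

from .errors import InputError, ParameterError

log = logging.getLogger(__name__)

FRAMES = (1, 2, 3, -1, -2, -3)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _codon_map() -> dict:
    table = CodonTable.unambiguous_dna_by_id[1]  # the standard code
    codons = dict(table.forward_table)
    for stop in table.stop_codons:
        codons[stop] = "*"
    return codons


_CODONS = _codon_map()


@dataclass(frozen=True)
class QueryFrame:
    """One reading frame of a translated DNA read."""

    read_id: str
    frame: int  # +1,+2,+3,-1,-2,-3
    protein: str
    dna_length: int


def reverse_complement(dna: str) -> str:
    dna = dna.upper()
    bad = set(dna) - set("ACGTN")
    if bad:
        raise InputError(f"non-DNA symbols {sorted(bad)} in sequence")
    return dna.translate(_COMPLEMENT)[::-1]


def translate_frame(dna: str, frame: int) -> str:
    """Translate one frame; negative frames read the reverse complement."""
    if frame not in FRAMES:
        raise ParameterError(f"frame {frame} not in {FRAMES}")
    s = reverse_complement(dna) if frame < 0 else dna.upper()
    off = abs(frame) - 1
    aa = []
    for i in range(off, len(s) - 2, 3):
        aa.append(_CODONS.get(s[i : i + 3], "X"))
    return "".join(aa)


def six_frame_translate(read_id: str, dna: str) -> list:
    """All six frames in fixed order +1,+2,+3,-1,-2,-3.

    Reads shorter than one codon yield no frames (warning logged).
    """
    if len(dna) < 3:
        log.warning("read %s shorter than 3 bases; skipped", read_id)
        return []
    return [
        QueryFrame(read_id=read_id, frame=f, protein=translate_frame(dna, f), dna_length=len(dna))
        for f in FRAMES
    ]


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_sequences(path, kind: str = "auto") -> list:
    """Read (id, upper-cased sequence) pairs from FASTA or FASTQ.

    ``kind`` is ``"fasta"``, ``"fastq"`` or ``"auto"`` (sniffed from the
    extension, FASTQ for .fq/.fastq).  Gzipped files are accepted.
    FASTQ quality strings are ignored.
    """
    path = Path(path)
    if kind == "auto":
        stem = path.name[: -len(".gz")] if path.suffix == ".gz" else path.name
        kind = "fastq" if stem.endswith((".fq", ".fastq")) else "fasta"
    if kind not in ("fasta", "fastq"):
        raise InputError(f"unknown sequence format {kind!r}")
    try:
        with _open_text(path) as fh:
            records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, kind)]
    except FileNotFoundError:
        raise InputError(f"no such file: {path}")
    except ValueError as exc:
        raise InputError(f"malformed {kind} file {path}: {exc}")
    return records
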