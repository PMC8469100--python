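"""Substitution matrix handling.

The package scores alignments with BLOSUM62 over the 20 standard amino
acids plus the stop codon ``*`` (treated as a scorable virtual amino acid)
and the ambiguity codes ``X``, ``B``, ``Z``.  The matrix ships as a plain
NCBI-style whitespace-delimited text table.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np

from .errors import ConfigurationError, ResidueError

#: The 20 standard amino acids in alphabetical order.
STANDARD_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Stop codon symbol; scored like a residue during extension.
STOP = "*"

#: Delimiter used between concatenated database / query sequences.
DELIMITER = "#"

#: Ambiguity codes accepted in input sequences.
AMBIGUITY_CODES = "XBZ"


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric integer substitution score table.

    Parameters
    ----------
    name:
        Human-readable label, e.g. ``"BLOSUM62"``.
    alphabet:
        Ordered residue symbols covered by the table.
    scores:
        Square integer array, ``scores[i, j]`` scoring
        ``alphabet[i]`` against ``alphabet[j]``.
    """

    name: str
    alphabet: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.alphabet)
        if self.scores.shape != (n, n):
            raise ConfigurationError(
                f"score table shape {self.scores.shape} does not match "
                f"alphabet of size {n}"
            )
        if not np.array_equal(self.scores, self.scores.T):
            raise ConfigurationError(f"matrix {self.name!r} is not symmetric")
        object.__setattr__(
            self, "_index", {sym: i for i, sym in enumerate(self.alphabet)}
        )

    def index_of(self, symbol: str) -> int:
        try:
            return self._index[symbol]
        except KeyError:
            raise ResidueError(
                f"symbol {symbol!r} is not in the {self.name} alphabet"
            ) from None

    def score(self, a: str, b: str) -> int:
        """Score a residue pair; raises :class:`ResidueError` on unknown symbols."""
        return int(self.scores[self.index_of(a), self.index_of(b)])

    def self_score(self, a: str) -> int:
        i = self.index_of(a)
        return int(self.scores[i, i])

    def char_table(self) -> np.ndarray:
        """128x128 int16 lookup table indexed by ASCII codes.

        Pairs outside the alphabet (notably the ``#`` delimiter) get a
        large negative sentinel so dynamic programming never aligns
        across them.
        """
        table = np.full((128, 128), -(10**4), dtype=np.int32)
        codes = np.array([ord(c) for c in self.alphabet])
        table[np.ix_(codes, codes)] = self.scores
        return table


def score_pair(m: SubstitutionMatrix, a: str, b: str) -> int:
    """Functional form of :meth:`SubstitutionMatrix.score`."""
    return m.score(a, b)


def parse_matrix(text: str, name: str = "matrix") -> SubstitutionMatrix:
    """Parse an NCBI whitespace-delimited matrix table.

    Lines starting with ``#`` are comments.  The first non-comment line
    lists the column symbols; each following line starts with a row
    symbol and carries one integer per column.
    """
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise ConfigurationError(f"matrix {name!r}: no content")
    columns = lines[0].split()
    n = len(columns)
    scores = np.zeros((n, n), dtype=np.int64)
    row_syms = []
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) != n + 1:
            raise ConfigurationError(
                f"matrix {name!r}: row {parts[0] if parts else '?'!r} has "
                f"{len(parts) - 1} entries, expected {n}"
            )
        row_syms.append(parts[0])
        try:
            scores[len(row_syms) - 1] = [int(v) for v in parts[1:]]
        except ValueError as exc:
            raise ConfigurationError(f"matrix {name!r}: non-integer score ({exc})")
    if row_syms != columns:
        raise ConfigurationError(
            f"matrix {name!r}: row symbols {row_syms} do not match columns {columns}"
        )
    return SubstitutionMatrix(name=name, alphabet="".join(columns), scores=scores)


@lru_cache(maxsize=1)
def load_blosum62() -> SubstitutionMatrix:
    """Load the bundled BLOSUM62 table (24 symbols including ``*``)."""
    text = resources.files("tsss.data").joinpath("blosum62.txt").read_text()
    m = parse_matrix(text, name="BLOSUM62")
    missing = [c for c in STANDARD_AMINO_ACIDS + STOP + AMBIGUITY_CODES if c not in m.alphabet]
    if missing:
        raise ConfigurationError(f"bundled BLOSUM62 lacks symbols {missing}")
    return m
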