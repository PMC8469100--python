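"""Synthetic protein databases and mutated DNA reads.

The generator emulates the shape of a prokaryotic metagenomic search
problem at desk scale: a database of random proteins drawn from
Robinson–Robinson background residue frequencies, and DNA reads that are
either homologous (a protein window with substitutions biased toward
BLOSUM62-similar residues plus rare indels, reverse-translated through
random synonymous codons and placed on a random strand) or decoys
(uniform random DNA).  A truth table maps every read to its source
protein, or to none.

Everything is driven by one seeded generator: the same spec always
yields byte-identical FASTA output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .scoring import STANDARD_AMINO_ACIDS, load_blosum62
from .translation import _CODONS, reverse_complement

# Robinson & Robinson amino-acid background frequencies (the standard
# composition used by protein search statistics), keyed in alphabetical
# residue order.
_BACKGROUND = {
    "A": 0.07805, "C": 0.01925, "D": 0.05364, "E": 0.06295, "F": 0.03856,
    "G": 0.07377, "H": 0.02199, "I": 0.05142, "K": 0.05744, "L": 0.09019,
    "M": 0.02243, "N": 0.04487, "P": 0.05203, "Q": 0.04264, "R": 0.05129,
    "S": 0.07120, "T": 0.05841, "V": 0.06441, "W": 0.01330, "Y": 0.03216,
}

_RESIDUES = np.array(list(STANDARD_AMINO_ACIDS))
_FREQS = np.array([_BACKGROUND[c] for c in STANDARD_AMINO_ACIDS])
_FREQS = _FREQS / _FREQS.sum()


def _codons_by_residue() -> dict:
    table: dict = {}
    for codon, aa in _CODONS.items():
        table.setdefault(aa, []).append(codon)
    return {aa: sorted(cs) for aa, cs in table.items()}


_SYNONYMS = _codons_by_residue()


def _substitution_weights():
    """Replacement distribution per residue: 2^score over the other 19."""
    m = load_blosum62()
    weights = {}
    for a in STANDARD_AMINO_ACIDS:
        w = np.array(
            [2.0 ** m.score(a, b) if b != a else 0.0 for b in STANDARD_AMINO_ACIDS]
        )
        weights[a] = w / w.sum()
    return weights


@dataclass(frozen=True)
class FixtureSpec:
    n_proteins: int = 50
    min_protein_length: int = 150
    max_protein_length: int = 300
    n_reads: int = 200
    read_length: int = 150
    substitution_rate: float = 0.0
    indel_rate: float = 0.0
    decoy_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "indel_rate", "decoy_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1]")
        if self.read_length < 3 or self.n_proteins < 1 or self.n_reads < 0:
            raise ParameterError("fixture sizes out of range")
        if self.min_protein_length > self.max_protein_length:
            raise ParameterError("min_protein_length > max_protein_length")


@dataclass(frozen=True)
class Fixture:
    proteins: tuple  # (id, sequence)
    reads: tuple  # (id, dna)
    truth: dict  # read id -> protein id or None


def generate_fixture(spec: FixtureSpec) -> Fixture:
    rng = np.random.default_rng(spec.seed)
    sub_w = _substitution_weights() if spec.substitution_rate > 0 else None

    proteins = []
    for i in range(spec.n_proteins):
        length = int(rng.integers(spec.min_protein_length, spec.max_protein_length + 1))
        seq = "".join(rng.choice(_RESIDUES, size=length, p=_FREQS))
        proteins.append((f"prot{i:04d}", seq))

    n_aa = spec.read_length // 3
    reads = []
    truth: dict = {}
    for r in range(spec.n_reads):
        rid = f"read{r:04d}"
        if rng.random() < spec.decoy_fraction:
            dna = "".join(rng.choice(list("ACGT"), size=spec.read_length))
            truth[rid] = None
        else:
            pi = int(rng.integers(spec.n_proteins))
            pid, pseq = proteins[pi]
            start = int(rng.integers(0, len(pseq) - n_aa + 1))
            pep = list(pseq[start : start + n_aa])
            for k in range(len(pep)):
                if rng.random() < spec.substitution_rate:
                    pep[k] = str(rng.choice(_RESIDUES, p=sub_w[pep[k]]))
            if spec.indel_rate > 0:
                mutated = []
                for c in pep:
                    u = rng.random()
                    if u < spec.indel_rate / 2:
                        continue  # deletion
                    mutated.append(c)
                    if u >= spec.indel_rate / 2 and u < spec.indel_rate:
                        mutated.append(str(rng.choice(_RESIDUES, p=_FREQS)))
                pep = mutated if mutated else pep
            dna = "".join(str(rng.choice(_SYNONYMS[aa])) for aa in pep)
            if rng.random() < 0.5:
                dna = reverse_complement(dna)
            truth[rid] = pid
        reads.append((rid, dna))
    return Fixture(proteins=tuple(proteins), reads=tuple(reads), truth=truth)


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        for rid in truth:
            fh.write(f"{rid}\t{truth[rid] if truth[rid] is not None else '-'}\n")


def read_truth(path) -> dict:
    truth = {}
    with open(path) as fh:
        for line in fh:
            rid, pid = line.rstrip("\n").split("\t")
            truth[rid] = None if pid == "-" else pid
    return truth
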