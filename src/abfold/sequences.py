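"""AB sequences: the two-letter alphabet, Fibonacci chains, and hydrophobicity mapping.

The AB off-lattice model reduces a protein to a chain of two monomer
species: ``A`` (hydrophobic) and ``B`` (hydrophilic).  Benchmark chains
come from two sources: the Fibonacci word family, and real amino-acid
sequences mapped onto {A, B} by a binary Kyte–Doolittle-style
hydrophobicity partition.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

__all__ = [
    "ABSequence",
    "fibonacci_sequence",
    "classify_kd",
    "read_fasta",
    "HYDROPHOBIC",
    "HYDROPHILIC",
]

#: One-letter codes treated as hydrophobic (mapped to A).
HYDROPHOBIC = frozenset("IVLPCMAG")
#: One-letter codes treated as hydrophilic (mapped to B).
HYDROPHILIC = frozenset("DEFHKNQRSTWY")


@dataclass(frozen=True)
class ABSequence:
    """An ordered chain of A/B monomer labels, at least three residues long.

    Three residues is the shortest chain with a defined bond angle and a
    nonbonded (j >= i+2) pair, i.e. the shortest chain with nonzero energy
    terms.
    """

    labels: str

    def __post_init__(self) -> None:
        bad = set(self.labels) - {"A", "B"}
        if bad:
            raise ValueError(f"sequence may contain only A and B, found {sorted(bad)!r}")
        if len(self.labels) < 3:
            raise ValueError(f"need at least 3 residues, got {len(self.labels)}")

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def __getitem__(self, i):
        return self.labels[i]

    def __str__(self) -> str:
        return self.labels

    @property
    def n_bond_angles(self) -> int:
        return len(self.labels) - 2

    @property
    def n_torsion_angles(self) -> int:
        return len(self.labels) - 3


def fibonacci_sequence(index: int) -> ABSequence:
    """Return the ``index``-th Fibonacci AB word.

    The family is defined by S0 = "A", S1 = "B" and the concatenation
    rule S_{i+1} = S_{i-1} + S_i, so lengths follow the Fibonacci
    numbers 1, 1, 2, 3, 5, 8, 13, 21, ...  Indices 6 and 7 give the
    classic 13- and 21-residue benchmark chains.

    Note the words of index < 3 are shorter than 3 residues and cannot
    be wrapped in :class:`ABSequence`; they are returned as the raw
    string in that case.
    """
    if index < 0:
        raise ValueError(f"Fibonacci index must be non-negative, got {index}")
    prev, cur = "A", "B"
    if index == 0:
        word = prev
    elif index == 1:
        word = cur
    else:
        for _ in range(index - 1):
            prev, cur = cur, prev + cur
        word = cur
    return ABSequence(word) if len(word) >= 3 else word  # type: ignore[return-value]


def classify_kd(aa_sequence: str) -> ABSequence:
    """Map a one-letter amino-acid string onto the AB alphabet.

    I, V, L, P, C, M, A, G are taken as hydrophobic (A); the remaining
    twelve standard residues as hydrophilic (B).  Case-insensitive.

    Raises
    ------
    ValueError
        If any character is not a standard one-letter code; the message
        reports the 1-based position and the offending character.
    """
    out = []
    for pos, ch in enumerate(aa_sequence.upper(), start=1):
        if ch in HYDROPHOBIC:
            out.append("A")
        elif ch in HYDROPHILIC:
            out.append("B")
        else:
            raise ValueError(
                f"non-standard amino-acid code {ch!r} at position {pos}"
            )
    return ABSequence("".join(out))


def read_fasta(source: str | Path | io.TextIOBase, record_id: str | None = None) -> str:
    """Read an amino-acid sequence from a FASTA file.

    Returns the first record unless ``record_id`` names a specific one.
    """
    from Bio import SeqIO

    handle = open(source) if isinstance(source, (str, Path)) else source
    try:
        records = list(SeqIO.parse(handle, "fasta"))
    finally:
        if isinstance(source, (str, Path)):
            handle.close()
    if not records:
        raise ValueError(f"no FASTA records found in {source!r}")
    if record_id is None:
        return str(records[0].seq)
    for rec in records:
        if rec.id == record_id:
            return str(rec.seq)
    raise KeyError(f"record {record_id!r} not found ({len(records)} records present)")
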