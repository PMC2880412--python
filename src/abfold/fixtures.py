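"""Bundled benchmark data: Fibonacci chains and three small real proteins.

The package ships the published benchmark records as a small versioned
JSON file: for each of the four Fibonacci chains (N = 13, 21, 34, 55)
the sequence, the lowest energies reported by five optimizers (SA, ELP,
CSA, TS, GATS) and the angle vectors at the GATS minimum; for the three
real proteins (1BXL, 1EDP, 1AGT) the amino-acid sequence and the TS and
GATS reference energies.  The file's checksum is pinned so accidental
edits are detected at load time.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .geometry import Conformation
from .sequences import ABSequence, classify_kd

__all__ = ["FixtureRecord", "load_fibonacci_fixtures", "load_protein_fixtures", "FIXTURE_VERSION"]

_SHA256 = "5ebf0127e1ce02f50a648c8de87b46346c1457679882ca5f2a3061adfb8688a8"

FIXTURE_VERSION = "1"


@dataclass(frozen=True, eq=False)
class FixtureRecord:
    """One benchmark row: a chain, its reference energies, optional angle vectors."""

    label: str
    sequence: ABSequence
    reference_energies: dict = field(default_factory=dict)
    conformation: Conformation | None = None
    aa_sequence: str | None = None

    @property
    def n(self) -> int:
        return len(self.sequence)


def _raw(verify: bool = True) -> dict:
    data = resources.files("abfold.data").joinpath("tables.json").read_bytes()
    if verify and hashlib.sha256(data).hexdigest() != _SHA256:
        raise RuntimeError(
            "bundled fixture file tables.json fails its pinned checksum; "
            "the benchmark data has been modified"
        )
    return json.loads(data)


def load_fibonacci_fixtures(verify: bool = True) -> list[FixtureRecord]:
    """The four Fibonacci benchmark rows, with angle vectors at the GATS minima."""
    out = []
    for row in _raw(verify)["fibonacci"]:
        conf = Conformation(np.asarray(row["bond_angles"]), np.asarray(row["torsion_angles"]))
        if conf.n != row["n"]:
            raise RuntimeError(f"fixture {row['label']}: angle counts inconsistent with n")
        out.append(
            FixtureRecord(
                label=row["label"],
                sequence=ABSequence(row["sequence"]),
                reference_energies=dict(row["reference_energies"]),
                conformation=conf,
            )
        )
    return out


def load_protein_fixtures(verify: bool = True) -> list[FixtureRecord]:
    """The three real-protein rows; sequences mapped to AB via the K-D partition."""
    out = []
    for row in _raw(verify)["proteins"]:
        out.append(
            FixtureRecord(
                label=row["label"],
                sequence=classify_kd(row["aa_sequence"]),
                reference_energies=dict(row["reference_energies"]),
                aa_sequence=row["aa_sequence"],
            )
        )
    return out
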