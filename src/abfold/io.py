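"""File formats: angle files, XYZ/PDB coordinate export, run-result JSON.

The angle file is a three-line plain-text dialect:

    line 1: the AB sequence string
    line 2: whitespace-separated bond angles (radians)
    line 3: whitespace-separated torsion angles (radians)

Coordinate exports are toy-model geometries in dimensionless model
units, not stereochemically valid proteins: XYZ uses element C for A
monomers and O for B; the minimal PDB dialect writes CA-only ATOM
records with residue names ALA (A) and GLY (B) and model units written
verbatim in the coordinate fields.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .geometry import DEFAULT_CONVENTION, Conformation, build_coordinates
from .sequences import ABSequence

__all__ = [
    "write_angle_file",
    "read_angle_file",
    "write_xyz",
    "write_pdb",
    "result_to_json",
]

_ELEMENT = {"A": "C", "B": "O"}
_RESNAME = {"A": "ALA", "B": "GLY"}


def write_angle_file(path: str | Path, seq: ABSequence | str, conf: Conformation) -> None:
    theta = " ".join(f"{x:.9g}" for x in conf.theta)
    beta = " ".join(f"{x:.9g}" for x in conf.beta)
    Path(path).write_text(f"{seq}\n{theta}\n{beta}\n")


def read_angle_file(path: str | Path) -> tuple[ABSequence, Conformation]:
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise ValueError(f"{path}: expected 3 lines (sequence, bond angles, torsions), got {len(lines)}")
    seq = ABSequence(lines[0].strip())
    try:
        theta = np.array([float(x) for x in lines[1].split()])
    except ValueError as exc:
        raise ValueError(f"{path}: line 2 (bond angles): {exc}") from None
    try:
        beta = np.array([float(x) for x in lines[2].split()])
    except ValueError as exc:
        raise ValueError(f"{path}: line 3 (torsion angles): {exc}") from None
    if len(theta) != len(seq) - 2 or len(beta) != len(seq) - 3:
        raise ValueError(
            f"{path}: expected {len(seq) - 2} bond angles and {len(seq) - 3} torsions "
            f"for a {len(seq)}-residue sequence, got {len(theta)} and {len(beta)}"
        )
    return seq, Conformation(theta, beta)


def write_xyz(path: str | Path, seq: ABSequence | str, conf: Conformation,
              convention=DEFAULT_CONVENTION, comment: str = "AB-model chain (model units)") -> None:
    coords = build_coordinates(conf, convention)
    lines = [str(len(coords)), comment]
    for label, (x, y, z) in zip(str(seq), coords):
        lines.append(f"{_ELEMENT[label]} {x:12.6f} {y:12.6f} {z:12.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_pdb(path: str | Path, seq: ABSequence | str, conf: Conformation,
              convention=DEFAULT_CONVENTION) -> None:
    coords = build_coordinates(conf, convention)
    lines = ["REMARK   1 COARSE-GRAINED AB-MODEL CHAIN; COORDINATES IN MODEL UNITS"]
    for i, (label, (x, y, z)) in enumerate(zip(str(seq), coords), start=1):
        lines.append(
            f"ATOM  {i:5d}  CA  {_RESNAME[label]} A{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def result_to_json(result, path: str | Path | None = None) -> str:
    """Serialize a RunResult (angles, energy, trajectory, seed, config echo)."""
    config = dataclasses.asdict(result.config) if result.config is not None else None
    payload = {
        "sequence": result.sequence,
        "best_energy": result.best_energy,
        "bond_angles": result.best_conf.theta.tolist(),
        "torsion_angles": result.best_conf.beta.tolist(),
        "evaluations": result.evaluations,
        "seed": result.seed,
        "trajectory": result.trajectory,
        "config": config,
    }
    text = json.dumps(payload, indent=1)
    if path is not None:
        Path(path).write_text(text)
    return text
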