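"""The AB off-lattice energy functional.

For an n-residue chain the energy is

    E = sum_{i=1}^{n-2} (1/4) (1 - cos theta_i)
      + 4 sum_{j >= i+2} [ r_ij^{-12} - C(xi_i, xi_j) r_ij^{-6} ]

where theta_i are the bond-angle parameters of the conformation, r_ij
the inter-residue distances of the constructed chain, and the species
coefficient C is +1 for AA, +1/2 for BB and -1/2 for mixed pairs — so
hydrophobic pairs attract strongly, hydrophilic pairs weakly, and mixed
pairs are (weakly) repelled at medium range.  Overlapping residues give
a +infinity sentinel rather than an overflow.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist

from .geometry import (
    DEFAULT_CONVENTION,
    Conformation,
    GeometryConvention,
    bond_vectors,
)
from .sequences import ABSequence

__all__ = ["pair_coefficient", "EnergyModel", "total_energy", "OVERLAP_DISTANCE"]

#: Distances below this are treated as an overlap (divergent energy).
OVERLAP_DISTANCE = 1e-8

_COEFF = {("A", "A"): 1.0, ("B", "B"): 0.5, ("A", "B"): -0.5, ("B", "A"): -0.5}


def pair_coefficient(a: str, b: str) -> float:
    """Species coefficient of the attractive r^-6 term: AA +1, BB +1/2, mixed -1/2."""
    try:
        return _COEFF[(a, b)]
    except KeyError:
        raise ValueError(f"monomer types must be A or B, got {(a, b)!r}") from None


class EnergyModel:
    """Energy evaluator for one sequence, with precomputed pair bookkeeping.

    Caches the condensed-distance indices and species coefficients of the
    nonbonded pairs (j >= i+2) so repeated evaluations inside the
    optimizer stay cheap.  Every evaluation increments ``evaluations``;
    the optimizer reports that count as its budget accounting.
    """

    def __init__(self, seq: ABSequence, convention: GeometryConvention = DEFAULT_CONVENTION):
        if isinstance(seq, str):
            seq = ABSequence(seq)
        self.seq = seq
        self.convention = convention
        self.evaluations = 0
        n = len(seq)
        self.n = n
        idx, coeff = [], []
        for i in range(n - 2):
            base = n * i - (i * (i + 1)) // 2 - i - 1  # condensed index offset
            for j in range(i + 2, n):
                idx.append(base + j)
                coeff.append(pair_coefficient(seq[i], seq[j]))
        self._pair_idx = np.asarray(idx, dtype=np.intp)
        self._pair_coeff = np.asarray(coeff)

    def energy_of_arrays(self, theta: np.ndarray, beta: np.ndarray) -> float:
        """Energy from raw angle arrays (assumed correct lengths, finite)."""
        self.evaluations += 1
        conv = self.convention
        if conv.construction == "fixed-axis":
            ct, st = np.cos(theta), np.sin(theta)
            bonds = np.empty((self.n - 1, 3))
            bonds[0] = (0.0, 1.0, 0.0)
            bonds[1] = (ct[0], st[0], 0.0)
            cb, sb = np.cos(beta), conv.torsion_sign * np.sin(beta)
            bonds[2:, 0] = ct[1:] * cb
            bonds[2:, 1] = st[1:] * cb
            bonds[2:, 2] = sb
        else:
            bonds = bond_vectors(Conformation(theta, beta), conv)
        coords = np.vstack([np.zeros(3), np.cumsum(bonds, axis=0)])
        r = pdist(coords)[self._pair_idx]
        if np.any(r < OVERLAP_DISTANCE):
            return float("inf")
        bend = 0.25 * float(np.sum(1.0 - np.cos(theta)))
        r6 = r ** -6
        nonbonded = 4.0 * float(np.sum(r6 * r6 - self._pair_coeff * r6))
        return bend + nonbonded

    def __call__(self, conf: Conformation) -> float:
        if conf.n != self.n:
            raise ValueError(f"conformation has n={conf.n}, sequence has n={self.n}")
        return self.energy_of_arrays(conf.theta, conf.beta)

    def energy_terms(self, conf: Conformation) -> dict:
        """Breakdown: bend term, nonbonded term, and minimum nonbonded distance."""
        from .geometry import build_coordinates

        coords = build_coordinates(conf, self.convention)
        r = pdist(coords)[self._pair_idx]
        bend = 0.25 * float(np.sum(1.0 - np.cos(conf.theta)))
        if np.any(r < OVERLAP_DISTANCE):
            nonbonded = float("inf")
        else:
            r6 = r ** -6
            nonbonded = 4.0 * float(np.sum(r6 * r6 - self._pair_coeff * r6))
        return {
            "bend": bend,
            "nonbonded": nonbonded,
            "total": bend + nonbonded,
            "min_nonbonded_distance": float(r.min()) if len(r) else float("nan"),
        }


def total_energy(
    seq: ABSequence | str,
    conf: Conformation,
    convention: GeometryConvention = DEFAULT_CONVENTION,
) -> float:
    """One-shot AB-model energy of ``conf`` for ``seq`` under ``convention``."""
    return EnergyModel(seq, convention)(conf)
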