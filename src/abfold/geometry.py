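"""Chain geometry: angle-vector conformations and Cartesian construction.

A conformation of an n-residue chain is parameterized by (n-2) "bond
angles" theta and (n-3) "torsional angles" beta.  Two ways of turning
those parameters into unit-bond 3D coordinates are supported:

``fixed-axis``
    Each bond direction is given in lab-frame spherical coordinates:
    bond 1 is (0, 1, 0), bond 2 is (cos t1, sin t1, 0) and bond i (>= 3)
    is (cos t_{i-1} cos b_{i-2}, sin t_{i-1} cos b_{i-2}, sin b_{i-2}).
    Coordinates are the cumulative sum of the bonds.  This is the
    convention selected by calibration against the published benchmark
    minima (see :mod:`abfold.calibration`); it is the package default.

``relative``
    Classic internal coordinates: theta_i is the angle between
    successive bond vectors and beta_i the dihedral of three successive
    bonds.  Kept as the alternative family that the calibration
    enumerates (and rejects).

Under either convention every bond has unit length and the first three
residues sit in a canonical frame: residue 0 at the origin, residue 1 at
(0, 1, 0), residue 2 in the z = 0 plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "wrap_angle",
    "Conformation",
    "GeometryConvention",
    "DEFAULT_CONVENTION",
    "build_coordinates",
    "bond_vectors",
    "pairwise_distances",
    "bond_angles_from_coords",
    "torsion_angles_from_coords",
]

TWO_PI = 2.0 * np.pi


def wrap_angle(x):
    """Wrap angles to the canonical interval (-pi, pi]."""
    x = np.asarray(x, dtype=float)
    w = x - TWO_PI * np.floor((x + np.pi) / TWO_PI)
    # floor maps +pi to -pi; put it back on the closed end
    w = np.where(w <= -np.pi, np.pi, w)
    return w if w.ndim else float(w)


@dataclass(frozen=True, eq=False)
class Conformation:
    """Angle-vector representation of an n-residue chain shape.

    theta : (n-2,) bond-angle parameters, radians, stored in (-pi, pi]
    beta  : (n-3,) torsion parameters, radians, stored in (-pi, pi]
    """

    theta: np.ndarray
    beta: np.ndarray

    def __post_init__(self):
        theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        beta = np.atleast_1d(np.asarray(self.beta, dtype=float)) if np.size(self.beta) else np.empty(0)
        if not (np.all(np.isfinite(theta)) and np.all(np.isfinite(beta))):
            raise ValueError("conformation angles must be finite")
        if len(beta) != len(theta) - 1:
            raise ValueError(
                f"expected one fewer torsion than bond angles, got "
                f"{len(theta)} bond angles and {len(beta)} torsions"
            )
        object.__setattr__(self, "theta", wrap_angle(theta))
        object.__setattr__(self, "beta", wrap_angle(beta))

    @property
    def n(self) -> int:
        """Residue count."""
        return len(self.theta) + 2

    @property
    def vector(self) -> np.ndarray:
        """Concatenated (theta, beta) vector of length 2n-5."""
        return np.concatenate([self.theta, self.beta])

    @classmethod
    def from_vector(cls, x: np.ndarray, n: int) -> "Conformation":
        x = np.asarray(x, dtype=float)
        if len(x) != 2 * n - 5:
            raise ValueError(f"expected {2 * n - 5} parameters for n={n}, got {len(x)}")
        return cls(x[: n - 2], x[n - 2:])

    @classmethod
    def random(cls, n: int, rng: np.random.Generator) -> "Conformation":
        """Angles drawn uniformly from (-pi, pi]."""
        return cls.from_vector(np.pi - rng.uniform(0.0, TWO_PI, size=2 * n - 5), n)


@dataclass(frozen=True)
class GeometryConvention:
    """Resolves the freedoms in mapping angle parameters to coordinates.

    construction : "fixed-axis" (lab-frame spherical bonds) or
                   "relative" (internal bond/dihedral angles)
    supplement   : interpret theta as pi - theta (relative family only)
    torsion_sign : +1 right-handed, -1 left-handed torsion
    """

    construction: str = "fixed-axis"
    supplement: bool = False
    torsion_sign: int = 1

    def __post_init__(self):
        if self.construction not in ("fixed-axis", "relative"):
            raise ValueError(f"unknown construction {self.construction!r}")
        if self.torsion_sign not in (1, -1):
            raise ValueError("torsion_sign must be +1 or -1")
        if self.construction == "fixed-axis" and self.supplement:
            raise ValueError("supplement flag applies to the relative construction only")


#: Convention selected by calibration against the published benchmark minima.
DEFAULT_CONVENTION = GeometryConvention()


def bond_vectors(conf: Conformation, convention: GeometryConvention = DEFAULT_CONVENTION) -> np.ndarray:
    """Unit bond vectors (n-1, 3) for a conformation under a convention."""
    if convention.construction == "fixed-axis":
        return _bonds_fixed_axis(conf.theta, conf.beta, convention.torsion_sign)
    return _bonds_relative(conf.theta, conf.beta, convention.supplement, convention.torsion_sign)


def build_coordinates(conf: Conformation, convention: GeometryConvention = DEFAULT_CONVENTION) -> np.ndarray:
    """Cartesian coordinates (n, 3) in the canonical frame, unit bonds."""
    bonds = bond_vectors(conf, convention)
    coords = np.zeros((len(bonds) + 1, 3))
    np.cumsum(bonds, axis=0, out=coords[1:])
    return coords


def _bonds_fixed_axis(theta: np.ndarray, beta: np.ndarray, torsion_sign: int) -> np.ndarray:
    n_bonds = len(theta) + 1
    bonds = np.empty((n_bonds, 3))
    bonds[0] = (0.0, 1.0, 0.0)
    ct, st = np.cos(theta), np.sin(theta)
    bonds[1] = (ct[0], st[0], 0.0)
    if len(beta):
        cb, sb = np.cos(beta), torsion_sign * np.sin(beta)
        bonds[2:, 0] = ct[1:] * cb
        bonds[2:, 1] = st[1:] * cb
        bonds[2:, 2] = sb
    return bonds


def _bonds_relative(theta, beta, supplement, torsion_sign):
    if supplement:
        theta = np.pi - theta
    n_bonds = len(theta) + 1
    bonds = np.empty((n_bonds, 3))
    bonds[0] = (0.0, 1.0, 0.0)
    t = theta[0]
    # third residue in the z = 0 plane; positive theta bends toward +x
    bonds[1] = (np.sin(t), np.cos(t), 0.0)
    for i in range(1, len(theta)):
        t = theta[i]
        # sign chosen so torsion_angles_from_coords recovers +beta when torsion_sign=+1
        b = -torsion_sign * beta[i - 1]
        u = bonds[i]
        axis = np.cross(bonds[i - 1], u)
        norm = np.linalg.norm(axis)
        if norm < 1e-12:  # collinear previous bonds: dihedral plane undefined
            axis = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
            axis = axis - np.dot(axis, u) * u
            axis /= np.linalg.norm(axis)
        else:
            axis /= norm
        m = np.cross(axis, u)
        bonds[i + 1] = np.cos(t) * u + np.sin(t) * (np.cos(b) * m + np.sin(b) * axis)
    return bonds


def pairwise_distances(coords: np.ndarray) -> np.ndarray:
    """Symmetric Euclidean distance matrix with zero diagonal."""
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 2:
        raise ValueError("need at least 2 points")
    return squareform(pdist(coords))


def bond_angles_from_coords(coords: np.ndarray) -> np.ndarray:
    """Angles in [0, pi] between successive bond vectors of a chain."""
    b = np.diff(np.asarray(coords, dtype=float), axis=0)
    b /= np.linalg.norm(b, axis=1, keepdims=True)
    cosines = np.clip(np.einsum("ij,ij->i", b[:-1], b[1:]), -1.0, 1.0)
    return np.arccos(cosines)


def torsion_angles_from_coords(coords: np.ndarray) -> np.ndarray:
    """Signed dihedral angles in (-pi, pi] of successive bond-vector triples."""
    b = np.diff(np.asarray(coords, dtype=float), axis=0)
    b1, b2, b3 = b[:-2], b[1:-1], b[2:]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2u = b2 / np.linalg.norm(b2, axis=1, keepdims=True)
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", np.cross(n1, b2u), n2)
    return wrap_angle(np.arctan2(y, x))
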