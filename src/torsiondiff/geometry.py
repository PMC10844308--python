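"""Conversion between Cartesian protein backbones and the six-angle internal representation.

A backbone of N residues (atoms N, CA, C per residue) is described by an
(N-1) x 6 matrix of wrapped radians.  Row ``i`` holds, in this fixed order:

========  =====================================  ==========
column    definition                             kind
========  =====================================  ==========
psi       N_i - CA_i - C_i - N_{i+1}             dihedral
omega     CA_i - C_i - N_{i+1} - CA_{i+1}        dihedral
phi       C_i - N_{i+1} - CA_{i+1} - C_{i+1}     dihedral
theta1    N_i - CA_i - C_i                       bond angle
theta2    CA_i - C_i - N_{i+1}                   bond angle
theta3    C_i - N_{i+1} - CA_{i+1}               bond angle
========  =====================================  ==========

Because every residue carries its own reference frame, the representation is
invariant under rigid motion; Cartesian coordinates are recovered by natural
extension of reference frame (NeRF): each atom is placed at a fixed bond
length, at the stored bond angle to the two preceding atoms, and at the
stored torsion to the three preceding atoms.

Bond lengths are fixed to average values (Engh-Huber-style defaults,
configurable).  Note one edge effect of the (N-1) x 6 layout: the bond angle
N-CA-C of the *final* residue has no slot of its own, so reconstruction
reuses the final row's theta1 when placing the last C atom.  The angle
round-trip featurize(reconstruct(A)) == A is exact regardless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

TWO_PI = 2.0 * np.pi

#: Column order of the angle matrix.
ANGLE_NAMES = ("psi", "omega", "phi", "theta1", "theta2", "theta3")
DIHEDRAL_COLUMNS = (0, 1, 2)
BOND_ANGLE_COLUMNS = (3, 4, 5)


class DegenerateGeometryError(ValueError):
    """Raised when collinear/coincident points make an angle undefined."""


class IncompleteResidueError(ValueError):
    """Raised when a residue lacks one of its N/CA/C backbone atoms."""


@dataclass(frozen=True)
class BondLengthConstants:
    """Average backbone bond lengths in Angstrom (Engh-Huber-style values)."""

    n_ca: float = 1.458
    ca_c: float = 1.525
    c_n: float = 1.329
    #: carbonyl geometry, used only for oxygen placement
    c_o: float = 1.231
    o_c_n_angle: float = np.deg2rad(122.7)

    def __post_init__(self) -> None:
        for name in ("n_ca", "ca_c", "c_n", "c_o"):
            v = getattr(self, name)
            if not (1.0 <= v <= 2.0):
                raise ValueError(f"bond length {name}={v} outside [1.0, 2.0] A")


DEFAULT_BOND_LENGTHS = BondLengthConstants()


@dataclass
class BackboneStructure:
    """Ordered per-residue N/CA/C (optionally O) coordinates in Angstrom."""

    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray
    o: np.ndarray | None = None
    chain_id: str = "A"

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=np.float64)
        self.ca = np.asarray(self.ca, dtype=np.float64)
        self.c = np.asarray(self.c, dtype=np.float64)
        if self.o is not None:
            self.o = np.asarray(self.o, dtype=np.float64)
        shapes = {a.shape for a in (self.n, self.ca, self.c)}
        if len(shapes) != 1 or self.n.ndim != 2 or self.n.shape[1] != 3:
            raise ValueError("n, ca, c must share shape (residue_count, 3)")
        if self.residue_count < 2:
            raise ValueError("a backbone needs at least 2 residues")
        coords = [self.n, self.ca, self.c] + ([self.o] if self.o is not None else [])
        # NaN is tolerated as an explicit missing-atom marker (featurization
        # rejects it with a residue index); infinities are always invalid.
        if any(np.isinf(a).any() for a in coords):
            raise ValueError("non-finite coordinates")

    @property
    def residue_count(self) -> int:
        return self.n.shape[0]

    def atoms(self) -> np.ndarray:
        """Backbone atoms in chain order N_0, CA_0, C_0, N_1, ... shape (3N, 3)."""
        return np.stack([self.n, self.ca, self.c], axis=1).reshape(-1, 3)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "BackboneStructure":
        """Apply a rigid transform ``x -> x @ R.T + t``."""
        rot = np.asarray(rotation, dtype=np.float64)
        t = np.asarray(translation, dtype=np.float64)
        return BackboneStructure(
            n=self.n @ rot.T + t,
            ca=self.ca @ rot.T + t,
            c=self.c @ rot.T + t,
            o=None if self.o is None else self.o @ rot.T + t,
            chain_id=self.chain_id,
        )


@dataclass
class AngleFeaturization:
    """(N-1) x 6 matrix of wrapped radians in ANGLE_NAMES column order."""

    angles: np.ndarray

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=np.float64)
        if self.angles.ndim != 2 or self.angles.shape[1] != 6:
            raise ValueError("angles must have shape (residue_count - 1, 6)")
        if not np.isfinite(self.angles).all():
            raise ValueError("non-finite angles")
        if (self.angles < -np.pi).any() or (self.angles >= np.pi).any():
            raise ValueError("angles must lie in [-pi, pi)")

    @property
    def residue_count(self) -> int:
        return self.angles.shape[0] + 1

    def to_csv(self, path: str | Path) -> None:
        header = ",".join(ANGLE_NAMES)
        np.savetxt(path, self.angles, delimiter=",", header=header, comments="")

    @classmethod
    def from_csv(cls, path: str | Path) -> "AngleFeaturization":
        return cls(np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2))

    def to_npy(self, path: str | Path) -> None:
        np.save(path, self.angles)

    @classmethod
    def from_npy(cls, path: str | Path) -> "AngleFeaturization":
        return cls(np.load(path))


def wrap_angles(x: np.ndarray | float) -> np.ndarray | float:
    """Wrap values into [-pi, pi): w(x) = ((x + pi) mod 2pi) - pi."""
    return np.mod(np.asarray(x) + np.pi, TWO_PI) - np.pi


def bond_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    """Angle at p1 between p1->p0 and p1->p2, in [0, pi]."""
    p0, p1, p2 = (np.asarray(p, dtype=np.float64) for p in (p0, p1, p2))
    u = p0 - p1
    v = p2 - p1
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-10 or nv < 1e-10:
        raise DegenerateGeometryError("coincident points in bond angle")
    # atan2 form is numerically stable near 0 and pi
    return float(np.arctan2(np.linalg.norm(np.cross(u, v)), np.dot(u, v)))


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed torsion of p0-p1-p2-p3 in [-pi, pi), IUPAC sign convention.

    Looking along p1->p2, a clockwise rotation carrying the projection of
    p1->p0 onto the projection of p2->p3 is positive.  Matches
    ``biotite.structure.dihedral``.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=np.float64) for p in (p0, p1, p2, p3))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm_b2 = np.linalg.norm(b2)
    if norm_b2 < 1e-10:
        raise DegenerateGeometryError("coincident central atoms in dihedral")
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise DegenerateGeometryError("collinear points make the torsion undefined")
    value = np.arctan2(np.dot(np.cross(n1, n2), b2 / norm_b2), np.dot(n1, n2))
    return float(wrap_angles(value))


def featurize_backbone(structure: BackboneStructure) -> AngleFeaturization:
    """Compute the (N-1) x 6 internal-angle matrix of a backbone.

    Row ``i`` depends only on atoms of residues ``i`` and ``i+1``.
    """
    n_res = structure.residue_count
    N, CA, C = structure.n, structure.ca, structure.c
    missing = np.isnan(N).any(axis=1) | np.isnan(CA).any(axis=1) | np.isnan(C).any(axis=1)
    if missing.any():
        raise IncompleteResidueError(
            f"residue {int(np.flatnonzero(missing)[0])} misses a backbone atom")
    out = np.empty((n_res - 1, 6), dtype=np.float64)
    for i in range(n_res - 1):
        out[i, 0] = dihedral_angle(N[i], CA[i], C[i], N[i + 1])
        out[i, 1] = dihedral_angle(CA[i], C[i], N[i + 1], CA[i + 1])
        out[i, 2] = dihedral_angle(C[i], N[i + 1], CA[i + 1], C[i + 1])
        out[i, 3] = bond_angle(N[i], CA[i], C[i])
        out[i, 4] = bond_angle(CA[i], C[i], N[i + 1])
        out[i, 5] = bond_angle(C[i], N[i + 1], CA[i + 1])
    return AngleFeaturization(wrap_angles(out))


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                length: float, theta: float, torsion: float) -> np.ndarray:
    """NeRF placement: new atom d with |c-d| = length, angle(b,c,d) = theta,
    dihedral(a,b,c,d) = torsion (same sign convention as :func:`dihedral_angle`).

    If a, b, c are collinear the torsion azimuth is undefined; it is resolved
    as 0 about an arbitrary perpendicular axis.
    """
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n_norm = np.linalg.norm(n)
    if n_norm < 1e-9:
        # degenerate reference plane: pick any unit vector perpendicular to bc
        helper = np.array([1.0, 0.0, 0.0])
        if abs(bc[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(bc, helper)
        n_norm = np.linalg.norm(n)
    n = n / n_norm
    m = np.cross(n, bc)
    d_local = np.array([
        -length * np.cos(theta),
        length * np.sin(theta) * np.cos(torsion),
        length * np.sin(theta) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def reconstruct_backbone(
    angles: AngleFeaturization,
    lengths: BondLengthConstants = DEFAULT_BOND_LENGTHS,
) -> BackboneStructure:
    """Rebuild Cartesian N/CA/C coordinates from internal angles.

    Seed-frame convention (makes the output deterministic): residue 0's N sits
    at the origin, its CA on the +x axis, and its C in the xy-plane with
    positive y.  The bond angle used for the last residue's C atom is the
    final row's theta1 (see module docstring).
    """
    A = angles.angles
    n_res = angles.residue_count
    N = np.empty((n_res, 3))
    CA = np.empty((n_res, 3))
    C = np.empty((n_res, 3))
    theta1_0 = A[0, 3]
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (lengths.n_ca, 0.0, 0.0)
    C[0] = CA[0] + lengths.ca_c * np.array([-np.cos(theta1_0), np.sin(theta1_0), 0.0])
    for i in range(n_res - 1):
        psi, omega, phi, _, theta2, theta3 = A[i]
        # theta1 governing C_{i+1} lives in row i+1; the final C reuses row i's
        theta1_next = A[i + 1, 3] if i + 1 < n_res - 1 else A[i, 3]
        N[i + 1] = _place_atom(N[i], CA[i], C[i], lengths.c_n, theta2, psi)
        CA[i + 1] = _place_atom(CA[i], C[i], N[i + 1], lengths.n_ca, theta3, omega)
        C[i + 1] = _place_atom(C[i], N[i + 1], CA[i + 1], lengths.ca_c, theta1_next, phi)
    return BackboneStructure(n=N, ca=CA, c=C)


def place_oxygens(
    structure: BackboneStructure,
    lengths: BondLengthConstants = DEFAULT_BOND_LENGTHS,
) -> BackboneStructure:
    """Add carbonyl O atoms in the peptide plane, trans to the next N.

    O_i lies in the CA_i-C_i-N_{i+1} plane at the configured C=O length and
    O-C-N angle, on the opposite side of the C=O axis from N_{i+1} -- i.e. the
    standard trans carbonyl.  The final residue has no N_{i+1}; its O is
    placed by the same rule using a virtual N extrapolated from the last
    peptide unit's geometry.
    """
    n_res = structure.residue_count
    N, CA, C = structure.n, structure.ca, structure.c
    O = np.empty((n_res, 3))
    for i in range(n_res):
        if i < n_res - 1:
            next_n = N[i + 1]
        else:
            # virtual N: extend from the last placed frame with idealized psi
            next_n = _place_atom(N[i], CA[i], C[i], DEFAULT_BOND_LENGTHS.c_n,
                                 np.deg2rad(116.2), np.deg2rad(135.0))
        # O in the CA-C-N plane: torsion(CA_i, ?, ...) -- build O at angle
        # o_c_n to next_n, in-plane, on the far side of next_n.
        O[i] = _place_atom(CA[i], next_n, C[i], lengths.c_o,
                           lengths.o_c_n_angle, np.pi)
    return BackboneStructure(n=N.copy(), ca=CA.copy(), c=C.copy(), o=O,
                             chain_id=structure.chain_id)


def superimpose_rmsd(a: BackboneStructure, b: BackboneStructure) -> float:
    """RMSD over all backbone atoms after optimal rigid superposition (Kabsch)."""
    from scipy.spatial.transform import Rotation

    pa, pb = a.atoms(), b.atoms()
    if pa.shape != pb.shape:
        raise ValueError("structures differ in residue count")
    pa = pa - pa.mean(axis=0)
    pb = pb - pb.mean(axis=0)
    rot, _ = Rotation.align_vectors(pa, pb)
    diff = pa - rot.apply(pb)
    return float(np.sqrt((diff ** 2).sum() / len(pa)))


# ---------------------------------------------------------------------------
# PDB I/O (via biotite)
# ---------------------------------------------------------------------------

_BACKBONE_ATOMS = ("N", "CA", "C")


def read_pdb(path: str | Path) -> list[BackboneStructure]:
    """Parse ATOM records into one BackboneStructure per chain.

    Only the primary altloc is used.  Chains containing residues with missing
    N/CA/C atoms, or fewer than 2 complete residues, are skipped with a
    logged warning.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    array = pdb.get_structure(model=1, altloc="first")
    array = array[struc.filter_amino_acids(array)]
    structures: list[BackboneStructure] = []
    for chain_id in np.unique(array.chain_id):
        chain = array[array.chain_id == chain_id]
        starts = struc.get_residue_starts(chain)
        coords = {name: [] for name in _BACKBONE_ATOMS}
        oxygens: list[np.ndarray | None] = []
        ok = True
        bounds = list(starts) + [len(chain)]
        for ri, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
            res = chain[lo:hi]
            names = list(res.atom_name)
            try:
                for name in _BACKBONE_ATOMS:
                    coords[name].append(res.coord[names.index(name)])
            except ValueError:
                logger.warning(
                    "chain %s of %s: residue %d misses a backbone atom; chain skipped",
                    chain_id, path, ri)
                ok = False
                break
            oxygens.append(res.coord[names.index("O")] if "O" in names else None)
        if not ok or len(coords["N"]) < 2:
            if ok:
                logger.warning("chain %s of %s: fewer than 2 complete residues; skipped",
                               chain_id, path)
            continue
        o = (np.array(oxygens, dtype=np.float64)
             if all(x is not None for x in oxygens) else None)
        structures.append(BackboneStructure(
            n=np.array(coords["N"]), ca=np.array(coords["CA"]),
            c=np.array(coords["C"]), o=o, chain_id=str(chain_id)))
    return structures


def write_pdb(structure: BackboneStructure, path: str | Path) -> None:
    """Emit standard ATOM records (N, CA, C and O when present) as poly-glycine."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n_res = structure.residue_count
    names = list(_BACKBONE_ATOMS) + (["O"] if structure.o is not None else [])
    n_atoms_per_res = len(names)
    array = struc.AtomArray(n_res * n_atoms_per_res)
    coord_sets = [structure.n, structure.ca, structure.c]
    if structure.o is not None:
        coord_sets.append(structure.o)
    for ri in range(n_res):
        for ai, name in enumerate(names):
            idx = ri * n_atoms_per_res + ai
            array.coord[idx] = coord_sets[ai][ri]
            array.chain_id[idx] = structure.chain_id
            array.res_id[idx] = ri + 1
            array.res_name[idx] = "GLY"
            array.atom_name[idx] = name
            array.element[idx] = name[0]
            array.hetero[idx] = False
    pdb = PDBFile()
    pdb.set_structure(array)
    pdb.write(str(path))
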