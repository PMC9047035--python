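"""Shared geometric primitives: rigid transforms, dihedrals, Kabsch
superposition, and ideal/NeRF backbone construction.

All coordinates are in Angstroms; all angles in degrees unless noted.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Ideal alpha-helix, cylindrical backbone parameters about the helix axis.
# Radius (A), azimuthal offset from CA (deg), axial offset from CA (A),
# derived once from a standard-bond-geometry helix. Twist is fixed at
# +100 deg/residue and rise at 1.5 A/residue.
HELIX_RISE = 1.5
HELIX_TWIST = 100.0
_HELIX_ATOM_PARAMS = {
    "N": (1.511, -26.32, -0.919),
    "CA": (2.267, 0.0, 0.0),
    "C": (1.693, 27.35, 1.067),
    "O": (2.135, 97.22, 1.412),
}

# Standard backbone internal coordinates used by the NeRF chain builder.
BOND_N_CA, BOND_CA_C, BOND_C_N, BOND_C_O = 1.458, 1.525, 1.329, 1.231
ANGLE_N_CA_C, ANGLE_CA_C_N, ANGLE_C_N_CA = 111.2, 116.2, 121.7
OMEGA_TRANS = 180.0

PHI_HELIX, PSI_HELIX = -57.8, -47.0
PHI_EXTENDED, PSI_EXTENDED = -120.0, 120.0


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-8):
            raise ValueError("rotation matrix is not proper (det != +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying `other` first, then `self`."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform()


def unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector")
    return v / n


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    a = unit(axis)
    t = np.radians(angle_deg)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)

def rotation_aligning(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping unit vector a onto unit vector b."""
    a, b = unit(a), unit(b)
    c = float(np.dot(a, b))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        # antiparallel: rotate pi about any axis orthogonal to a
        helper = np.eye(3)[int(np.argmin(np.abs(a)))]
        axis = unit(np.cross(a, helper))
        return rotation_about_axis(axis, 180.0)
    axis = np.cross(a, b)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + K + K @ K / (1 + c)


def dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle in degrees in (-180, 180]."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1u = unit(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if np.isclose(ang, -180.0) else float(ang)


def angle_in_range(angle: float, lo: float, hi: float) -> bool:
    """Circular membership test for an angular interval given in degrees."""
    for a in (angle, angle + 360.0, angle - 360.0):
        if lo <= a <= hi:
            return True
    return False


def principal_axis(coords: np.ndarray) -> np.ndarray:
    """First principal axis of a point cloud (unit vector, arbitrary sign)."""
    X = np.asarray(coords, dtype=float)
    X = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    return vt[0]


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of `mobile` onto `target`.

    Returns the proper rigid transform T minimizing ||T(mobile) - target||
    and the resulting RMSD. Reflections are corrected by sign flip of the
    smallest singular vector so det(R) = +1 always.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("paired coordinate sets of equal shape (n,3) required")
    if len(P) < 3:
        raise ValueError("at least 3 paired atoms required")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    T = RigidTransform(R, t)
    diff = T.apply(P) - Q
    rmsd = float(np.sqrt((diff**2).sum() / len(P)))
    return T, rmsd


def rmsd_static(A: np.ndarray, B: np.ndarray) -> float:
    """RMSD of two paired sets without superposition."""
    A, B = np.asarray(A, float), np.asarray(B, float)
    return float(np.sqrt(((A - B) ** 2).sum() / len(A)))


# ---------------------------------------------------------------------------
# Backbone construction
# ---------------------------------------------------------------------------

def ideal_helix_backbone(n_residues: int) -> dict[str, np.ndarray]:
    """Parametric ideal alpha-helix backbone with axis along +z.

    Exactly 1.5 A rise and 100 deg twist per residue for the CA trace;
    N, C and O are placed by fixed cylindrical offsets. The CA z midpoint
    sits at z = 0 and the N-terminus is at negative z.
    """
    i = np.arange(n_residues, dtype=float)
    z_mid = HELIX_RISE * (n_residues - 1) / 2.0
    atoms = {}
    for name, (r, dphi, dz) in _HELIX_ATOM_PARAMS.items():
        phi = np.radians(HELIX_TWIST * i + dphi)
        atoms[name] = np.column_stack(
            [r * np.cos(phi), r * np.sin(phi), HELIX_RISE * i + dz - z_mid]
        )
    return atoms


def _nerf_place(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    angle, torsion = np.radians(angle_deg), np.radians(torsion_deg)
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def nerf_backbone(torsions: list[tuple[float, float]]) -> dict[str, np.ndarray]:
    """Build an N/CA/C/O backbone from per-residue (phi, psi) torsions.

    phi of the first residue and psi of the last are unused (no flanking
    atoms to define them). Trans peptide bonds throughout.
    """
    n = len(torsions)
    if n < 1:
        raise ValueError("at least one residue required")
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([BOND_N_CA, 0.0, 0.0])]
    ang = np.radians(ANGLE_N_CA_C)
    C = [CA[0] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])]
    for k in range(1, n):
        psi_prev = torsions[k - 1][1]
        N.append(_nerf_place(N[k - 1], CA[k - 1], C[k - 1], BOND_C_N, ANGLE_CA_C_N, psi_prev))
        CA.append(_nerf_place(CA[k - 1], C[k - 1], N[k], BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS))
        C.append(_nerf_place(C[k - 1], N[k], CA[k], BOND_CA_C, ANGLE_N_CA_C, torsions[k][0]))
    O = []
    for k in range(n):
        if k + 1 < n:
            O.append(_nerf_place(CA[k], C[k], N[k + 1], BOND_C_O, 122.7, 180.0))
        else:
            # terminal carbonyl: place trans to CA about the last psi direction
            O.append(_nerf_place(N[k], CA[k], C[k], BOND_C_O, 120.8, torsions[k][1] + 180.0))
    return {"N": np.array(N), "CA": np.array(CA), "C": np.array(C), "O": np.array(O)}
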