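"""Implicit membrane slab positioning.

The membrane is a planar slab of half-thickness d (hydrocarbon core)
with a smooth 3 A interfacial ramp. A structure is positioned by
minimizing the sum of per-residue water-to-membrane transfer free
energies weighted by a depth profile f(z):

    E(n, c, d) = sum_i dG(aa_i) * f(z_i),   z_i = CA_i . n - c

with f = 1 inside |z| <= d, decaying to 0 over the 3 A interface as
cos^2. The search is a deterministic coarse grid over the slab normal
(10 deg), center offset (1 A) and d in [10, 20] A (1 A), followed by
local simplex refinement, so identical inputs give identical results.

This is a deliberately simple CA-level profile model: its contract is
correct sidedness, tilt and boundary placement on structures with a
hydrophobic membrane-spanning stretch, not a physical free energy.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize

from .errors import ContractError
from .geometry import RigidTransform, principal_axis, rotation_aligning, unit
from .structures import ChainModel
from .tm import HydrophobicityScale, TMSegment, default_scale

logger = logging.getLogger("memprep")

INTERFACE_RAMP = 3.0  # A, half-width of the boundary smoothing


@dataclass
class MembraneSlab:
    """Implicit planar membrane: boundaries at +-half_thickness along
    `normal`, center displaced by `center_offset` along the normal."""

    half_thickness: float
    normal: np.ndarray = None
    center_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.normal is None:
            self.normal = np.array([0.0, 0.0, 1.0])
        self.normal = np.asarray(self.normal, dtype=float)
        if not np.isclose(np.linalg.norm(self.normal), 1.0, atol=1e-9):
            raise ValueError("slab normal must be a unit vector")
        if not 5.0 <= self.half_thickness <= 30.0:
            raise ValueError(f"implausible half-thickness {self.half_thickness}")


@dataclass
class PositioningResult:
    slab: MembraneSlab
    transform: RigidTransform       # structure frame -> membrane frame
    transfer_energy: float          # kcal/mol at the optimum
    tilt: float                     # deg between principal axis and normal
    non_tm: bool = False            # no favorable membrane placement


def depth_profile(z: np.ndarray, half_thickness: float,
                  ramp: float = INTERFACE_RAMP) -> np.ndarray:
    """Membrane weight f(z): 1 in the core, cos^2 ramp at the interface."""
    az = np.abs(np.asarray(z, dtype=float))
    f = np.zeros_like(az)
    f[az <= half_thickness] = 1.0
    sel = (az > half_thickness) & (az < half_thickness + ramp)
    f[sel] = np.cos(np.pi * (az[sel] - half_thickness) / (2.0 * ramp)) ** 2
    return f


def transfer_energy(model: ChainModel, slab: MembraneSlab,
                    scale: Optional[HydrophobicityScale] = None) -> float:
    """Profile-weighted transfer energy of a chain in a slab, kcal/mol."""
    scale = scale or default_scale()
    ca = model.ca_coords()
    if not np.all(np.isfinite(ca)):
        raise ContractError("non-finite coordinates")
    z = ca @ slab.normal - slab.center_offset
    dg = np.array([scale[r.aa] for r in model.residues])
    return float(dg @ depth_profile(z, slab.half_thickness))


def _normal_from_angles(theta_deg: float, phi_deg: float) -> np.ndarray:
    t, p = np.radians(theta_deg), np.radians(phi_deg)
    return np.array([np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)])


def position_in_membrane(
    model: ChainModel,
    scale: Optional[HydrophobicityScale] = None,
    d_bounds: tuple[float, float] = (10.0, 20.0),
    angle_step: float = 10.0,
    offset_step: float = 1.0,
    d_step: float = 1.0,
) -> PositioningResult:
    """Optimal slab placement by exhaustive coarse grid + local refinement.

    Searches the slab normal over spherical angles (theta in [0, 90],
    phi in [0, 360) — the opposite hemisphere is equivalent under a sign
    flip of the offset), the center offset along the normal, and the
    half-thickness. Flags the model as non-TM when even the optimal
    placement is unfavorable (energy >= 0).
    """
    if len(model) < 15:
        raise ContractError("at least 15 residues required for positioning")
    scale = scale or default_scale()
    ca = model.ca_coords()
    dg = np.array([scale[r.aa] for r in model.residues])

    thetas = np.arange(0.0, 90.0 + 1e-9, angle_step)
    phis = np.arange(0.0, 360.0, angle_step)
    ds = np.arange(d_bounds[0], d_bounds[1] + 1e-9, d_step)

    best = (np.inf, None)  # energy, (theta, phi, c, d)
    for theta in thetas:
        for phi in (phis if theta > 0 else phis[:1]):
            n = _normal_from_angles(theta, phi)
            proj = ca @ n
            cs = np.arange(np.floor(proj.min()) - 5.0,
                           np.ceil(proj.max()) + 5.0 + 1e-9, offset_step)
            depth = proj[:, None] - cs[None, :]
            for d in ds:
                e = dg @ depth_profile(depth, d)
                k = int(np.argmin(e))
                if e[k] < best[0] - 1e-12:
                    best = (float(e[k]), (theta, phi, float(cs[k]), float(d)))
    e_grid, x0 = best

    def objective(x):
        n = _normal_from_angles(x[0], x[1])
        z = ca @ n - x[2]
        return float(dg @ depth_profile(z, x[3]))

    res = minimize(
        objective, x0=np.array(x0), method="Nelder-Mead",
        bounds=[(0.0, 180.0), (-360.0, 720.0),
                (x0[2] - 10.0, x0[2] + 10.0), d_bounds],
        options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 2000},
    )
    if res.fun <= e_grid:
        theta, phi, c, d = res.x
        energy = float(res.fun)
    else:
        logger.warning("local refinement failed to improve on the grid optimum")
        theta, phi, c, d = x0
        energy = e_grid

    normal = _normal_from_angles(theta, phi)
    R = rotation_aligning(normal, np.array([0.0, 0.0, 1.0]))
    transform = RigidTransform(R, -R @ (c * normal))
    axis = principal_axis(ca)
    tilt = float(np.degrees(np.arccos(np.clip(abs(axis @ normal), -1.0, 1.0))))
    slab = MembraneSlab(float(d), normal, float(c))
    return PositioningResult(slab, transform, energy, tilt, non_tm=energy >= 0.0)


_FLIP = np.diag([1.0, -1.0, -1.0])  # rotation by pi about x: z -> -z


def orient_by_topology(result: PositioningResult, tm: TMSegment,
                       topology: str,
                       model: Optional[ChainModel] = None) -> PositioningResult:
    """Resolve the +-normal ambiguity from the curated topology.

    In the membrane frame the extracellular side is z > 0, so the TM
    N-terminal end must lie at z > 0 for N_out proteins and z < 0 for
    N_in. When the current frame has it on the wrong side the whole frame
    is rotated by pi about x (a proper rotation flipping z).
    """
    if topology not in ("N_out", "N_in"):
        raise ContractError(f"topology must be N_out or N_in, got {topology!r}")
    if model is not None:
        n_end = model.residue_by_index(tm.start).ca
    else:
        span = (tm.n_residues - 1) * 1.5
        n_end = tm.center - tm.axis * span / 2.0
    z_n = float(result.transform.apply(n_end[None, :])[0, 2])
    want_positive = topology == "N_out"
    if (z_n > 0) == want_positive:
        return result
    flip = RigidTransform(_FLIP, np.zeros(3))
    new_transform = flip.compose(result.transform)
    slab = MembraneSlab(result.slab.half_thickness, -result.slab.normal,
                        -result.slab.center_offset)
    return PositioningResult(slab, new_transform, result.transfer_energy,
                             result.tilt, result.non_tm)
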