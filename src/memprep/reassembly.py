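"""Rigid-body reassembly of a bitopic model around its membrane-framed TM
helix.

The TM segment is superposed onto a membrane-oriented reference helix
(an ideal helix when the model's own TM is distorted), then the
extracellular and intracellular parts are moved as rigid bodies onto
their correct membrane sides. Domains are never deformed: linker loops
are not remodeled, and a stretched linker is reported rather than
rebuilt.
"""
from __future__ import annotations

import logging
import numpy as np

from .errors import ContractError
from .geometry import (
    RigidTransform,
    kabsch,
    rotation_aligning,
    rotation_about_axis,
)
from .membrane import MembraneSlab
from .structures import ChainModel
from .tm import assign_secondary_structure, build_ideal_helix, helicity_fraction
from .trimming import DomainPartition

logger = logging.getLogger("memprep")

ATOM_CLEARANCE = 0.5   # A, minimum atom height above the boundary plane
LINKER_BOND = 3.8      # A, ideal CA-CA distance across the linker junction
CLASH_DISTANCE = 3.0   # A, CA-CA closer than this counts as a clash


def _ca_set(obj) -> np.ndarray:
    if isinstance(obj, ChainModel):
        return obj.ca_coords()
    return np.asarray(obj, dtype=float)


def superpose_tm_onto_reference(model_tm, reference_helix) -> RigidTransform:
    """Kabsch superposition of the model TM CA trace onto the reference.

    Requires equal residue counts. Near-collinear CA traces (degenerate
    for a rotation about the helix axis) fall back to all backbone atoms
    when both inputs are chain models.
    """
    P, Q = _ca_set(model_tm), _ca_set(reference_helix)
    if len(P) != len(Q):
        raise ContractError("model TM and reference helix differ in length")
    if len(P) < 3:
        raise ContractError("at least 3 paired CA atoms required")
    s = np.linalg.svd(P - P.mean(axis=0), compute_uv=False)
    if s[1] < 1e-6 and isinstance(model_tm, ChainModel) and isinstance(
        reference_helix, ChainModel
    ):
        logger.warning("collinear CA trace; superposing on all backbone atoms")
        P = model_tm.all_coords()
        Q = reference_helix.all_coords()
        if len(P) != len(Q):
            raise ContractError("backbone fallback requires matching atom sets")
    transform, _ = kabsch(P, Q)
    return transform


def _domain_positions(model: ChainModel, rng) -> list[int]:
    return [k for k, r in enumerate(model.residues) if rng[0] <= r.seq_index <= rng[1]]


def _apply_to_positions(model: ChainModel, positions, transform: RigidTransform):
    for k in positions:
        r = model.residues[k]
        r.atoms = {name: transform.apply(v[None, :])[0] for name, v in r.atoms.items()}


def place_domains(
    partition: DomainPartition,
    model: ChainModel,
    slab: MembraneSlab,
    clearance: float = 3.0,
    max_gap: float = 12.0,
) -> tuple[ChainModel, dict]:
    """Move ECD and ICD rigidly onto their membrane sides.

    The model must already be in the membrane frame (TM across z = 0).
    A domain that already satisfies the side constraint (centroid at
    least `clearance` beyond the boundary) and the linker-gap cap is left
    untouched. Otherwise the domain is rotated about its linker-end CA so
    its centroid points away from the membrane, and placed above the
    adjacent TM end with the smallest linker gap that keeps the centroid
    clear of the boundary and every atom out of the slab core. Gaps
    exceeding `max_gap` are flagged, never remodeled.
    """
    model = model.copy()
    d = slab.half_thickness
    tm_lo, tm_hi = partition.tmd_range
    flags: dict = {"stretched_linker": False, "steric_relief": False}

    n_side = "ecd" if partition.topology == "N_out" else "icd"
    jobs = []  # (range, side_sign, domain_is_n_side)
    if partition.ecd_range is not None:
        jobs.append((partition.ecd_range, +1.0, n_side == "ecd"))
    if partition.icd_range is not None:
        jobs.append((partition.icd_range, -1.0, n_side == "icd"))

    placed_positions: list[list[int]] = []
    for rng, s, is_n_side in jobs:
        pos = _domain_positions(model, rng)
        if not pos:
            raise ContractError(f"domain range {rng} outside the model")
        ca = np.array([model.residues[k].ca for k in pos])
        centroid = ca.mean(axis=0)
        anchor = model.residues[pos[-1] if is_n_side else pos[0]].ca.copy()
        tm_end = model.residue_by_index(tm_lo if is_n_side else tm_hi).ca
        gap = float(np.linalg.norm(anchor - tm_end))
        if s * centroid[2] >= d + clearance and gap <= max_gap:
            placed_positions.append(pos)
            continue

        v = centroid - anchor
        norm_v = float(np.linalg.norm(v))
        if norm_v > 1e-6:
            R = rotation_aligning(v / norm_v, np.array([0.0, 0.0, s]))
        else:
            R = np.eye(3)
        # rotate about the anchor, then choose the anchor's new position
        all_pos = [(k, name) for k in pos for name in model.residues[k].atoms]
        coords = np.array([model.residues[k].atoms[name] for k, name in all_pos])
        rotated = (coords - anchor) @ R.T
        min_w = float((s * rotated[:, 2]).min())
        w_anchor = max(
            s * tm_end[2] + LINKER_BOND,      # smallest gap, straight above TM end
            d + clearance - norm_v,            # centroid clearance
            d + ATOM_CLEARANCE - min_w,        # no atom inside the slab core
        )
        target = np.array([tm_end[0], tm_end[1], s * w_anchor])
        new_coords = rotated + target
        for (k, name), xyz in zip(all_pos, new_coords):
            model.residues[k].atoms[name] = xyz
        gap = float(np.linalg.norm(target - tm_end))
        if gap > max_gap:
            flags["stretched_linker"] = True
            logger.warning(
                "linker gap %.1f A to domain %s exceeds %.1f A; "
                "loop not remodeled", gap, rng, max_gap,
            )
        placed_positions.append(pos)

    # steric relief between the two domains: extra z-translation only
    if len(placed_positions) == 2:
        a = np.array([model.residues[k].ca for k in placed_positions[0]])
        shift = 0.0
        sign = jobs[1][1]
        while True:
            b = np.array([model.residues[k].ca for k in placed_positions[1]])
            dmin = float(np.min(np.linalg.norm(a[:, None] - b[None, :], axis=2)))
            if dmin >= CLASH_DISTANCE:
                break
            shift += 0.5
            _apply_to_positions(
                model, placed_positions[1],
                RigidTransform(np.eye(3), np.array([0.0, 0.0, sign * 0.5])),
            )
        if shift > 0:
            flags["steric_relief"] = True
            logger.warning("domain clash relieved by %.1f A z-shift", shift)
    return model, flags


def reassemble_model(
    model: ChainModel,
    partition: DomainPartition,
    slab: MembraneSlab,
    idealize_helicity_threshold: float = 0.8,
    clearance: float = 3.0,
    max_gap: float = 12.0,
) -> tuple[ChainModel, dict]:
    """Superpose the TM onto its membrane-oriented reference and place the
    domains; the model must already be in the membrane frame.

    When fewer than `idealize_helicity_threshold` of the TM residues are
    helical the TM is treated as distorted and the whole model is first
    superposed onto an ideal helix spanning the slab, oriented to keep
    the N-terminal end on its topological side.
    """
    if any(r.ss is None for r in model.residues):
        model = assign_secondary_structure(model)
    tm_lo, tm_hi = partition.tmd_range
    tm_model = model.subset(tm_lo, tm_hi)
    if len(tm_model) == 0:
        raise ContractError("TM range outside the model")

    class _Rng:  # minimal stand-in with start/end for helicity_fraction
        start, end = tm_lo, tm_hi

    flags: dict = {"tm_idealized": False}
    frac = helicity_fraction(model, _Rng)
    if frac < idealize_helicity_threshold:
        reference = build_ideal_helix(tm_model.sequence(), start_index=tm_lo)
        # built helix has its N-terminus at -z; N_out topologies need it at +z
        if partition.topology == "N_out":
            flip = RigidTransform(rotation_about_axis([1.0, 0.0, 0.0], 180.0),
                                  np.zeros(3))
            reference = reference.transformed(flip)
        transform = superpose_tm_onto_reference(tm_model, reference)
        model = model.transformed(transform)
        flags["tm_idealized"] = True
        logger.info("TM helicity %.0f%% below threshold; superposed onto "
                    "ideal helix", 100 * frac)

    placed, place_flags = place_domains(partition, model, slab,
                                        clearance=clearance, max_gap=max_gap)
    flags.update(place_flags)
    placed.residues.sort(key=lambda r: r.seq_index)
    return placed, flags
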