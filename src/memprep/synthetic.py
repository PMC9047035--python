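"""Synthetic bitopic-protein fixtures with exact ground truth.

Generates single-chain models that emulate the inputs the pipeline is
built for: a hydrophobic membrane-spanning ideal helix, helical folded
domains on either side, disordered low-confidence terminal tails, and an
optional signal peptide. The `intertwined` geometry places both domains
on the same side of the membrane midplane — the characteristic failure
mode of predicted full-length single-pass models, which reassembly must
fix. Every stage of the pipeline has its ground truth returned alongside
the model.

Fixtures are CA-complete backbones (N, CA, C, O) with locally ideal
geometry; they are statistical stand-ins, not physical folds. All
randomness flows from the single seed in the FixtureSpec.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ContractError
from .geometry import (
    PHI_EXTENDED,
    PHI_HELIX,
    PSI_EXTENDED,
    PSI_HELIX,
    ideal_helix_backbone,
    nerf_backbone,
    rotation_about_axis,
    rotation_aligning,
)
from .membrane import MembraneSlab
from .structures import ChainModel, ResidueRecord
from .tm import TMSegment
from .trimming import DomainPartition

Range = tuple[int, int]

HYDROPHOBIC_POOL = "LLLIIVF"      # TM segment
POLAR_POOL = "DEKRNQSTHG"         # folded domains (all unfavorable in membrane)
TAIL_POOL = "GSTNQDE"             # disordered tails
SIGNAL_POOL = "ASTG"              # mildly polar stand-in signal peptide


@dataclass
class FixtureSpec:
    """Blueprint of one synthetic bitopic model."""

    n_residues: int
    tm_range: Range
    seed: int
    topology: str = "N_out"
    signal_range: Optional[Range] = None
    tail_n_len: int = 12
    tail_c_len: int = 12
    domain_geometry: str = "compact_globule"   # or "intertwined"
    plddt_tail: Range = (30, 65)
    plddt_confident: Range = (75, 95)
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.topology not in ("N_out", "N_in"):
            raise ContractError(f"bad topology {self.topology!r}")
        if self.domain_geometry not in ("compact_globule", "intertwined"):
            raise ContractError(f"bad domain_geometry {self.domain_geometry!r}")
        lo, hi = self.tm_range
        if not 15 <= hi - lo + 1 <= 35:
            raise ContractError("TM length must be 15-35 residues")
        sig_end = self.signal_range[1] if self.signal_range else 0
        if self.signal_range and self.signal_range[0] != 1:
            raise ContractError("signal range must start at residue 1")
        if not (sig_end + self.tail_n_len < lo and
                hi + self.tail_c_len <= self.n_residues):
            raise ContractError("ranges inconsistent with n_residues")

    @property
    def domain_n_range(self) -> Optional[Range]:
        start = (self.signal_range[1] if self.signal_range else 0) + self.tail_n_len + 1
        end = self.tm_range[0] - 1
        return (start, end) if start <= end else None

    @property
    def domain_c_range(self) -> Optional[Range]:
        start = self.tm_range[1] + 1
        end = self.n_residues - self.tail_c_len
        return (start, end) if start <= end else None


@dataclass
class GroundTruth:
    partition: DomainPartition
    slab: MembraneSlab
    tm: TMSegment


def _domain_torsions(n: int, rng: np.random.Generator) -> list:
    """Helix segments joined by short turns: a compact helical bundle."""
    torsions: list = []
    while len(torsions) < n:
        seg = int(rng.integers(8, 15))
        torsions.extend([(PHI_HELIX, PSI_HELIX)] * seg)
        torsions.extend([(-70.0, 140.0), (60.0, 30.0), (-90.0, 0.0)])
    return torsions[:n]


def _tail_torsions(n: int, rng: np.random.Generator) -> list:
    jitter = rng.uniform(-10, 10, size=(n, 2))
    return [(PHI_EXTENDED + a, PSI_EXTENDED + b) for a, b in jitter]


def _attach(part: dict, anchor_end: str, attach_point: np.ndarray,
            direction: np.ndarray, rng: np.random.Generator) -> dict:
    """Rigidly place a backbone part: its anchor CA at `attach_point`,
    body (centroid) pointing along `direction`, random spin about it."""
    ca = part["CA"]
    anchor = ca[-1] if anchor_end == "last" else ca[0]
    centroid = ca.mean(axis=0)
    v = centroid - anchor
    nv = np.linalg.norm(v)
    direction = direction / np.linalg.norm(direction)
    R = rotation_aligning(v / nv, direction) if nv > 1e-6 else np.eye(3)
    R = rotation_about_axis(direction, float(rng.uniform(0, 360))) @ R
    return {k: (v_ - anchor) @ R.T + attach_point for k, v_ in part.items()}


def _lateral(rng: np.random.Generator) -> np.ndarray:
    ang = rng.uniform(0, 2 * np.pi)
    return np.array([np.cos(ang), np.sin(ang), 0.0])


def generate_synthetic_bitopic(spec: FixtureSpec) -> tuple[ChainModel, GroundTruth]:
    """Build the model and its exact per-stage ground truth."""
    rng = np.random.default_rng(spec.seed)
    tm_lo, tm_hi = spec.tm_range
    n_tm = tm_hi - tm_lo + 1

    # --- sequence ------------------------------------------------------
    seq = ["G"] * spec.n_residues  # 1-based ranges; overwritten below

    def fill(rng_, pool, r):
        if r is None:
            return
        for i in range(r[0], r[1] + 1):
            seq[i - 1] = pool[int(rng_.integers(len(pool)))]

    fill(rng, SIGNAL_POOL, spec.signal_range)
    tail_n_start = (spec.signal_range[1] if spec.signal_range else 0) + 1
    tail_n = (tail_n_start, tail_n_start + spec.tail_n_len - 1) if spec.tail_n_len else None
    tail_c = (spec.n_residues - spec.tail_c_len + 1, spec.n_residues) if spec.tail_c_len else None
    fill(rng, TAIL_POOL, tail_n)
    fill(rng, POLAR_POOL, spec.domain_n_range)
    fill(rng, HYDROPHOBIC_POOL, spec.tm_range)
    fill(rng, POLAR_POOL, spec.domain_c_range)
    fill(rng, TAIL_POOL, tail_c)

    # --- geometry ------------------------------------------------------
    # TM helix along z, midpoint at z = 0; extracellular side is z > 0,
    # so the TM N-terminal end goes up for N_out and down for N_in.
    tm_atoms = ideal_helix_backbone(n_tm)
    s_n = 1.0 if spec.topology == "N_out" else -1.0
    if spec.topology == "N_out":  # built helix has N at -z: flip
        F = rotation_about_axis([1.0, 0.0, 0.0], 180.0)
        tm_atoms = {k: v @ F.T for k, v in tm_atoms.items()}
    half_thickness = 1.5 * (n_tm - 1) / 2.0
    intertwined = spec.domain_geometry == "intertwined"

    parts: dict[Range, dict] = {spec.tm_range: tm_atoms}

    def build_part(r, torsion_fn):
        return nerf_backbone(torsion_fn(r[1] - r[0] + 1, rng))

    # N side, outward from the TM
    attach_at = tm_atoms["CA"][0]
    direction = s_n * np.array([0.0, 0.0, 1.0])
    for r, kind in ((spec.domain_n_range, "domain"), (tail_n, "tail"),
                    (spec.signal_range, "tail")):
        if r is None:
            continue
        part = build_part(r, _domain_torsions if kind == "domain" else _tail_torsions)
        if kind == "domain":
            dirn = s_n * np.array([0.0, 0.0, 1.0]) + 0.4 * _lateral(rng)
        else:
            dirn = direction + 0.8 * _lateral(rng)
        placed = _attach(part, "last", attach_at + 3.8 * dirn / np.linalg.norm(dirn),
                         dirn, rng)
        parts[r] = placed
        attach_at = placed["CA"][0]
        direction = dirn

    # C side
    attach_at = tm_atoms["CA"][-1]
    direction = -s_n * np.array([0.0, 0.0, 1.0])
    for r, kind in ((spec.domain_c_range, "domain"), (tail_c, "tail")):
        if r is None:
            continue
        part = build_part(r, _domain_torsions if kind == "domain" else _tail_torsions)
        if kind == "domain":
            side = s_n if intertwined else -s_n  # wrong side when intertwined
            dirn = side * np.array([0.0, 0.0, 1.0]) + 0.4 * _lateral(rng)
        else:
            dirn = direction + 0.8 * _lateral(rng)
        placed = _attach(part, "first", attach_at + 3.8 * dirn / np.linalg.norm(dirn),
                         dirn, rng)
        parts[r] = placed
        attach_at = placed["CA"][-1]
        direction = dirn

    # --- assemble residues --------------------------------------------
    lo_t, hi_t = spec.plddt_tail
    lo_c, hi_c = spec.plddt_confident
    residues = []
    for r, atoms in sorted(parts.items()):
        confident = r == spec.tm_range or r in (spec.domain_n_range,
                                                spec.domain_c_range,
                                                spec.signal_range)
        for k, i in enumerate(range(r[0], r[1] + 1)):
            plddt = float(rng.uniform(lo_c, hi_c) if confident
                          else rng.uniform(lo_t, hi_t))
            residues.append(
                ResidueRecord(i, seq[i - 1],
                              {name: atoms[name][k].copy() for name in atoms},
                              plddt)
            )
    residues.sort(key=lambda rr: rr.seq_index)
    if spec.noise_sigma > 0:
        for rr in residues:
            for name in rr.atoms:
                rr.atoms[name] = rr.atoms[name] + rng.normal(
                    0.0, spec.noise_sigma, size=3
                )
    model = ChainModel(residues, source_id=f"synthetic-{spec.seed}")

    # --- ground truth --------------------------------------------------
    ecd, icd = ((spec.domain_n_range, spec.domain_c_range)
                if spec.topology == "N_out"
                else (spec.domain_c_range, spec.domain_n_range))
    partition = DomainPartition(
        tmd_range=spec.tm_range, topology=spec.topology,
        ecd_range=ecd, icd_range=icd,
        signal_range=spec.signal_range, trimmed_n=tail_n, trimmed_c=tail_c,
    )
    tm_ca = parts[spec.tm_range]["CA"]
    # N -> C axis: for N_out the N-end is at +z, so the axis points down.
    truth_tm = TMSegment(
        start=tm_lo, end=tm_hi,
        axis=np.array([0.0, 0.0, -s_n]),
        center=tm_ca.mean(axis=0),
        score=0.0,
    )
    slab = MembraneSlab(half_thickness, np.array([0.0, 0.0, 1.0]), 0.0)
    return model, GroundTruth(partition, slab, truth_tm)


def generate_positioned_helix(
    tilt_deg: float,
    seed: int,
    half_thickness: float = 15.0,
    n_flank: int = 6,
    flank_pool: str = "DEK",
) -> tuple[ChainModel, MembraneSlab, np.ndarray]:
    """A hydrophobic helix at a known tilt inside a slab of known thickness.

    The helix axis is tilted from the membrane normal (z) by `tilt_deg`
    about y, sized so every CA stays inside the hydrocarbon core
    (|z| <= half_thickness). Polar juxtamembrane tails leave the membrane
    straight along the normal on both sides — the shortest path to water,
    as real juxtamembrane segments do — starting with mildly polar
    threonines at the interface and strongly polar residues beyond.
    Returns the model, the ground-truth slab (normal z, center 0) and the
    constructed helix axis (unit vector).
    """
    rng = np.random.default_rng(seed)
    rise, wobble = 1.5, 2.267
    t = np.radians(tilt_deg)
    # largest helix whose CA |z| (axial extent plus lateral wobble) fits in d
    n_core = int(2 * (half_thickness - wobble * np.sin(t)) / (rise * np.cos(t))) + 1
    atoms = ideal_helix_backbone(n_core)
    R = rotation_about_axis([0.0, 1.0, 0.0], tilt_deg)
    atoms = {k: v @ R.T for k, v in atoms.items()}

    def tail(attach, sign, n):
        ca = attach + np.outer(np.arange(1, n + 1), [0.0, 0.0, sign * 3.8])
        jitter = rng.normal(0.0, 0.05, size=(n, 3))
        return {
            "N": ca + [0.8, 0.0, -1.0] + jitter,
            "CA": ca,
            "C": ca + [-0.8, 0.2, 1.0] + jitter,
            "O": ca + [-0.7, 0.8, 1.6] + jitter,
        }

    tail_seq = ["T", "T"] + [
        flank_pool[int(rng.integers(len(flank_pool)))] for _ in range(n_flank - 2)
    ]
    n_tail = tail(atoms["CA"][0], -1.0, n_flank)    # N side, going down
    c_tail = tail(atoms["CA"][-1], +1.0, n_flank)   # C side, going up
    seq = tail_seq[::-1] + ["L"] * n_core + tail_seq
    coords = {
        k: np.vstack([n_tail[k][::-1], atoms[k], c_tail[k]]) for k in atoms
    }
    residues = [
        ResidueRecord(i + 1, seq[i], {k: coords[k][i].copy() for k in coords},
                      90.0)
        for i in range(len(seq))
    ]
    model = ChainModel(residues, source_id=f"tilted-helix-{tilt_deg:g}")
    slab = MembraneSlab(half_thickness, np.array([0.0, 0.0, 1.0]), 0.0)
    axis = R @ np.array([0.0, 0.0, 1.0])
    return model, slab, axis
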