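"""Transmembrane-segment detection and the ideal reference helix.

The single membrane-spanning helix of a bitopic protein is found by a
sliding-window scan of whole-residue water-to-membrane transfer free
energies combined with a backbone-dihedral secondary-structure check.
A parametric ideal alpha-helix, oriented along the membrane normal,
serves as the superposition reference for models whose TM helix is
distorted or partially unfolded.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import ContractError, NoTMFoundError
from .geometry import (
    angle_in_range,
    dihedral,
    ideal_helix_backbone,
    principal_axis,
)
from .structures import ChainModel, ResidueRecord

logger = logging.getLogger("memprep")

# Whole-residue water -> n-octanol transfer free energies (kcal/mol),
# Wimley & White; negative = partitioning into the membrane is favorable.
# Charged forms for D, E, K, R, H.
WW_OCTANOL_SCALE: dict[str, float] = {
    "A": 0.50, "R": 1.81, "N": 0.85, "D": 3.64, "C": -0.02,
    "E": 3.63, "Q": 0.77, "G": 1.15, "H": 2.33, "I": -1.12,
    "L": -1.25, "K": 2.80, "M": -0.67, "F": -1.71, "P": 0.14,
    "S": 0.46, "T": 0.25, "W": -2.09, "Y": -0.71, "V": -0.46,
}

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class HydrophobicityScale:
    """Per-residue transfer free energy, kcal/mol (water -> membrane)."""

    values: dict

    def __post_init__(self) -> None:
        missing = [a for a in STANDARD_AA if a not in self.values]
        if missing:
            raise ValueError(f"scale lacks amino acids: {missing}")
        if not all(math.isfinite(v) for v in self.values.values()):
            raise ValueError("scale contains non-finite values")

    def __getitem__(self, aa: str) -> float:
        return self.values.get(aa, 0.0)  # unknown residue: neutral


def default_scale() -> HydrophobicityScale:
    return HydrophobicityScale(dict(WW_OCTANOL_SCALE))


def load_scale(path: str | Path) -> HydrophobicityScale:
    """Two-column TSV: one-letter residue code, delta-G in kcal/mol."""
    values = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        aa, dg = line.split("\t")[:2]
        values[aa.strip().upper()] = float(dg)
    return HydrophobicityScale(values)


@dataclass
class TMSegment:
    """Detected membrane-spanning segment (author numbering, inclusive)."""

    start: int
    end: int
    axis: np.ndarray          # unit helix axis, N -> C, structure frame
    center: np.ndarray        # CA centroid, structure frame
    score: float              # summed transfer energy, kcal/mol

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        if not np.isclose(np.linalg.norm(self.axis), 1.0, atol=1e-9):
            raise ValueError("TM axis must be a unit vector")

    @property
    def n_residues(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# Secondary structure by backbone dihedrals
# ---------------------------------------------------------------------------

HELIX_PHI, HELIX_PSI = (-100.0, -30.0), (-80.0, -5.0)
STRAND_PHI, STRAND_PSI = (-180.0, -90.0), (90.0, 180.0)
MIN_HELIX_RUN, MIN_STRAND_RUN = 4, 3


def assign_secondary_structure(model: ChainModel) -> ChainModel:
    """Label each residue helix/strand/coil from phi/psi windows.

    Helix: phi in [-100, -30] and psi in [-80, -5] for >= 4 consecutive
    residues; strand: phi in [-180, -90] and psi in [90, 180] for >= 3;
    everything else coil. Angular windows are tested circularly so the
    +-180 wrap of fully extended chains falls inside the strand window.
    Residues lacking the flanking atoms needed for a dihedral are coil.
    """
    model = model.copy()
    res = model.residues
    n = len(res)
    phi = [None] * n
    psi = [None] * n
    for i in range(n):
        contiguous_prev = i > 0 and res[i - 1].seq_index == res[i].seq_index - 1
        contiguous_next = i + 1 < n and res[i + 1].seq_index == res[i].seq_index + 1
        a = res[i].atoms
        try:
            if contiguous_prev and "C" in res[i - 1].atoms and all(k in a for k in ("N", "CA", "C")):
                phi[i] = dihedral(res[i - 1].atoms["C"], a["N"], a["CA"], a["C"])
            if contiguous_next and "N" in res[i + 1].atoms and all(k in a for k in ("N", "CA", "C")):
                psi[i] = dihedral(a["N"], a["CA"], a["C"], res[i + 1].atoms["N"])
        except ValueError:
            logger.warning("degenerate backbone geometry at residue %d", res[i].seq_index)

    def run_label(pred, min_run, label, labels):
        i = 0
        while i < n:
            if pred(i):
                j = i
                while j < n and pred(j):
                    j += 1
                if j - i >= min_run:
                    for k in range(i, j):
                        labels[k] = label
                i = j
            else:
                i += 1

    def is_helix(i):
        return (
            phi[i] is not None and psi[i] is not None
            and angle_in_range(phi[i], *HELIX_PHI)
            and angle_in_range(psi[i], *HELIX_PSI)
        )

    def is_strand(i):
        return (
            phi[i] is not None and psi[i] is not None
            and angle_in_range(phi[i], *STRAND_PHI)
            and angle_in_range(psi[i], *STRAND_PSI)
        )

    labels = ["coil"] * n
    run_label(is_strand, MIN_STRAND_RUN, "strand", labels)
    run_label(is_helix, MIN_HELIX_RUN, "helix", labels)  # helix wins overlaps
    for r, lab in zip(res, labels):
        r.ss = lab
    return model


# ---------------------------------------------------------------------------
# TM segment detection
# ---------------------------------------------------------------------------

def detect_tm_segment(
    model: ChainModel,
    scale: Optional[HydrophobicityScale] = None,
    window: int = 21,
    score_threshold: float = -8.0,
    min_helix_fraction: float = 0.6,
    max_length: int = 35,
) -> TMSegment:
    """Find the single TM segment by minimal-window transfer energy.

    Scans all contiguous windows of the stated length; a window qualifies
    if its summed transfer energy is <= score_threshold and >= 60% of its
    residues carry a helix label. The qualifying window with the lowest
    (most favorable) score wins, ties going to the N-terminal-most window.
    The winner is extended outward one residue at a time while the added
    residue's transfer energy is negative, up to max_length residues.
    """
    scale = scale or default_scale()
    if len(model) < window:
        raise ContractError(f"model shorter than the scan window ({window})")
    if any(r.ss is None for r in model.residues):
        model = assign_secondary_structure(model)
    res = model.residues
    n = len(res)
    dg = np.array([scale[r.aa] for r in res])
    helix = np.array([r.ss == "helix" for r in res], dtype=float)

    kernel = np.ones(window)
    scores = np.convolve(dg, kernel, mode="valid")
    helix_frac = np.convolve(helix, kernel, mode="valid") / window
    qualifying = (scores <= score_threshold) & (helix_frac >= min_helix_fraction)
    if not qualifying.any():
        raise NoTMFoundError(
            "no window passes the TM thresholds; the model may be the "
            "water-soluble form of this protein"
        )
    order = np.where(qualifying)[0]
    # N-terminal-most among (numerically) tied minimal scores
    m = scores[order].min()
    best = int(order[scores[order] <= m + 1e-9].min())
    lo, hi = best, best + window - 1  # list positions, inclusive

    # outward extension while the added residue is hydrophobic
    while hi - lo + 1 < max_length:
        left = dg[lo - 1] if lo > 0 else np.inf
        right = dg[hi + 1] if hi + 1 < n else np.inf
        if left >= 0 and right >= 0:
            break
        if left <= right:
            lo -= 1
        else:
            hi += 1

    ca = np.array([r.ca for r in res[lo:hi + 1]])
    axis = principal_axis(ca)
    if np.dot(ca[-1] - ca[0], axis) < 0:
        axis = -axis
    return TMSegment(
        start=res[lo].seq_index,
        end=res[hi].seq_index,
        axis=axis,
        center=ca.mean(axis=0),
        score=float(dg[lo:hi + 1].sum()),
    )


def helicity_fraction(model: ChainModel, tm: TMSegment) -> float:
    """Fraction of TM residues labeled helix (model must carry ss labels)."""
    if any(r.ss is None for r in model.residues):
        model = assign_secondary_structure(model)
    inside = [r for r in model.residues if tm.start <= r.seq_index <= tm.end]
    if not inside:
        raise ContractError("TM range outside the model")
    return sum(r.ss == "helix" for r in inside) / len(inside)


# ---------------------------------------------------------------------------
# Ideal reference helix
# ---------------------------------------------------------------------------

def build_ideal_helix(sequence: str, slab=None, start_index: int = 1) -> ChainModel:
    """Ideal alpha-helix along +z: rise 1.5 A, twist 100 deg per residue.

    The CA midpoint sits at z = 0 (the slab center) and the N-terminal end
    at negative z; the final sign is chosen later from the protein's
    topology. Lengths outside the canonical single-TM range are rejected.
    """
    n = len(sequence)
    if not 15 <= n <= 35:
        raise ContractError(f"ideal TM helix length must be 15-35, got {n}")
    atoms = ideal_helix_backbone(n)
    residues = [
        ResidueRecord(
            start_index + i, sequence[i],
            {name: atoms[name][i] for name in atoms},
            plddt=100.0, ss="helix",
        )
        for i in range(n)
    ]
    return ChainModel(residues, source_id="ideal-helix")
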