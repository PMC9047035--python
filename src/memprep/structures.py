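"""Structure I/O and the in-memory chain container.

Reads predicted single-chain models from PDB or mmCIF (per-residue model
confidence, pLDDT, taken from the B-factor column), writes membrane-
positioned PDB files in the OPM dialect (planes of DUM dummy atoms marking
the membrane boundaries), and selects the TM-containing fragment window
for very long sequences that are only available as tiled partial models.

Author residue numbering is preserved everywhere; nothing is renumbered.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import gemmi
import numpy as np

from .errors import ContractError, FormatError, InfeasibleWindowError, TooShortError
from .geometry import RigidTransform

logger = logging.getLogger("memprep")

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class ResidueRecord:
    """One residue: author numbering, identity, coordinates, confidence."""

    seq_index: int
    aa: str
    atoms: dict[str, np.ndarray]
    plddt: float
    ss: Optional[str] = None  # {"helix", "strand", "coil"} once assigned

    def __post_init__(self) -> None:
        self.atoms = {k: np.asarray(v, dtype=float) for k, v in self.atoms.items()}
        if not 0.0 <= self.plddt <= 100.0:
            raise ValueError(f"pLDDT {self.plddt} outside [0, 100] at residue {self.seq_index}")

    @property
    def ca(self) -> np.ndarray:
        return self.atoms["CA"]

    def copy(self) -> "ResidueRecord":
        return ResidueRecord(
            self.seq_index, self.aa, {k: v.copy() for k, v in self.atoms.items()},
            self.plddt, self.ss,
        )


@dataclass
class ChainModel:
    """Ordered residues of one protein chain."""

    residues: list[ResidueRecord]
    source_id: str = ""

    def __post_init__(self) -> None:
        idx = [r.seq_index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("seq_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def seq_indices(self) -> list[int]:
        return [r.seq_index for r in self.residues]

    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues])

    def all_coords(self) -> np.ndarray:
        return np.concatenate([[a for a in r.atoms.values()] for r in self.residues])

    def residue_by_index(self, seq_index: int) -> ResidueRecord:
        for r in self.residues:
            if r.seq_index == seq_index:
                return r
        raise KeyError(seq_index)

    def subset(self, start: int, end: int) -> "ChainModel":
        """Residues with start <= seq_index <= end (author numbering)."""
        kept = [r.copy() for r in self.residues if start <= r.seq_index <= end]
        return ChainModel(kept, self.source_id)

    def drop_range(self, start: int, end: int) -> "ChainModel":
        kept = [r.copy() for r in self.residues if not start <= r.seq_index <= end]
        return ChainModel(kept, self.source_id)

    def transformed(self, transform: RigidTransform) -> "ChainModel":
        out = []
        for r in self.residues:
            out.append(
                ResidueRecord(
                    r.seq_index, r.aa,
                    {k: transform.apply(v[None, :])[0] for k, v in r.atoms.items()},
                    r.plddt, r.ss,
                )
            )
        return ChainModel(out, self.source_id)

    def copy(self) -> "ChainModel":
        return ChainModel([r.copy() for r in self.residues], self.source_id)


@dataclass(frozen=True)
class FragmentWindow:
    """1-based inclusive residue window of a tiled long-sequence model."""

    start: int
    end: int

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2.0


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def read_structure(
    path: str | Path,
    format: str = "auto",
    chain_id: Optional[str] = None,
) -> ChainModel:
    """Read one protein chain with pLDDT taken from the B-factor column.

    Takes the first chain unless `chain_id` names one. Alternate locations
    other than ''/'A' are skipped; insertion codes are rejected (predicted
    models have none). Residues without a CA atom are excluded with a
    warning. pLDDT is the CA B-factor.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt_map = {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "auto": gemmi.CoorFormat.Detect,
    }
    if format not in fmt_map:
        raise ContractError(f"unknown format {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt_map[format])
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0 or len(st[0]) == 0:
        raise FormatError(f"{path} contains no chains")
    model = st[0]
    chain = None
    if chain_id is not None:
        chain = model.find_chain(chain_id)
        if chain is None:
            raise FormatError(f"chain {chain_id!r} not found in {path}")
    else:
        chain = model[0]

    residues: list[ResidueRecord] = []
    for res in chain:
        info = gemmi.find_tabulated_residue(res.name)
        if info is None or not info.is_amino_acid():
            continue
        if res.seqid.icode not in (" ", "\x00", ""):
            raise FormatError(
                f"insertion code {res.seqid.icode!r} at residue {res.seqid.num}: "
                "insertion codes are not supported"
            )
        atoms: dict[str, np.ndarray] = {}
        ca_b = None
        for atom in res:
            if atom.altloc not in ("\x00", "", "A"):
                continue
            if atom.name in BACKBONE_ATOMS and atom.name not in atoms:
                atoms[atom.name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                if atom.name == "CA":
                    ca_b = atom.b_iso
        if "CA" not in atoms:
            logger.warning(
                "residue %s%d has no CA atom; excluded", res.name, res.seqid.num
            )
            continue
        one = info.one_letter_code.upper()
        aa = one if one.isalpha() else "X"
        residues.append(
            ResidueRecord(res.seqid.num, aa, atoms, float(np.clip(ca_b, 0.0, 100.0)))
        )
    if len(residues) < 3:
        raise TooShortError(f"{path}: fewer than 3 usable residues")
    return ChainModel(residues, source_id=path.stem)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _pdb_atom_line(serial, name, resname, chain, resnum, xyz, b, element, het=False):
    record = "HETATM" if het else "ATOM  "
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"{record}{serial:>5d} {name_field}{'':1s}{resname:>3s} {chain:1s}"
        f"{resnum:>4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{1.00:6.2f}{b:6.2f}          {element:>2s}"
    )


def write_pdb(
    model: ChainModel,
    path: str | Path,
    slab=None,
    grid_spacing: float = 10.0,
    box_size: Optional[float] = None,
) -> None:
    """Write a chain as PDB; optionally add OPM-style DUM boundary planes.

    When `slab` is given the model must already be in the membrane frame
    (slab normal along z, center at z = 0); two square grids of DUM dummy
    HETATM records are written at z = +d and z = -d. `box_size` is the full
    width of the grid; by default it covers the protein's xy extent.
    """
    path = Path(path)
    lines = []
    serial = 1
    for r in model.residues:
        resname = _ONE_TO_THREE.get(r.aa, "UNK")
        for name in BACKBONE_ATOMS:
            if name not in r.atoms:
                continue
            lines.append(
                _pdb_atom_line(serial, name, resname, "A", r.seq_index,
                               r.atoms[name], r.plddt, name[0])
            )
            serial += 1
    lines.append("TER")
    if slab is not None:
        if abs(slab.center_offset) > 1e-6 or not np.allclose(
            slab.normal, [0.0, 0.0, 1.0], atol=1e-6
        ):
            raise ContractError(
                "model must be in the membrane frame (normal = z, center at z = 0) "
                "before writing boundary planes"
            )
        if box_size is None:
            xy = model.ca_coords()[:, :2]
            extent = 2.0 * float(np.abs(xy).max()) + 2.0 * grid_spacing
            box_size = grid_spacing * math.ceil(extent / grid_spacing)
        half = box_size / 2.0
        ticks = np.arange(-half, half + 1e-9, grid_spacing)
        resnum = 1
        for z, atom_name in ((slab.half_thickness, "N"), (-slab.half_thickness, "O")):
            for x in ticks:
                for y in ticks:
                    lines.append(
                        _pdb_atom_line(serial, atom_name, "DUM", " ",
                                       min(resnum, 9999), (x, y, z), 0.0,
                                       atom_name, het=True)
                    )
                    serial += 1
                    resnum += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def write_positioned_structure(model: ChainModel, slab, path: str | Path,
                               grid_spacing: float = 10.0,
                               box_size: Optional[float] = None) -> None:
    """Write a membrane-positioned model with DUM boundary planes."""
    if slab is None:
        raise ContractError("a membrane slab is required")
    write_pdb(model, path, slab=slab, grid_spacing=grid_spacing, box_size=box_size)


_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL", "X": "UNK",
}


def write_sidecar(path: str | Path, *, partition=None, slab=None, tm=None,
                  flags: Optional[dict] = None) -> None:
    """JSON sidecar with the domain partition, slab parameters and flags."""
    def rng(r):
        return None if r is None else [int(r[0]), int(r[1])]

    payload: dict = {}
    if partition is not None:
        payload["partition"] = {
            "signal_range": rng(partition.signal_range),
            "trimmed_n": rng(partition.trimmed_n),
            "trimmed_c": rng(partition.trimmed_c),
            "ecd_range": rng(partition.ecd_range),
            "tmd_range": rng(partition.tmd_range),
            "icd_range": rng(partition.icd_range),
            "topology": partition.topology,
        }
    if slab is not None:
        payload["slab"] = {
            "half_thickness": float(slab.half_thickness),
            "normal": [float(x) for x in slab.normal],
            "center_offset": float(slab.center_offset),
        }
    if tm is not None:
        payload["tm_segment"] = {
            "start": int(tm.start), "end": int(tm.end),
            "score": float(tm.score),
        }
    payload["flags"] = flags or {}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


# ---------------------------------------------------------------------------
# Fragment-window selection for very long sequences
# ---------------------------------------------------------------------------

def tiling_windows(sequence_length: int, window_length: int = 1400,
                   step: int = 200) -> list[FragmentWindow]:
    """Tiled windows starting at 1, 1+step, ...; the last one is clipped.

    Tiling stops with the first window that reaches the sequence end.
    """
    windows = []
    start = 1
    while True:
        end = min(start + window_length - 1, sequence_length)
        windows.append(FragmentWindow(start, end))
        if end >= sequence_length:
            break
        start += step
    return windows


def select_fragment_window(sequence_length: int, tm, window_length: int = 1400,
                           step: int = 200) -> FragmentWindow:
    """Pick the tiling window that fully contains the TM segment.

    Among containing windows, the one whose center is nearest the TM-segment
    center; ties go to the smaller start. Full-length prediction covers
    sequences up to the window length, so this applies only beyond it.
    """
    if sequence_length <= window_length:
        raise ContractError("sequence not longer than one window; no tiling needed")
    if not (1 <= tm.start <= tm.end <= sequence_length):
        raise ContractError("TM segment outside the sequence")
    tm_center = (tm.start + tm.end) / 2.0
    candidates = [
        w for w in tiling_windows(sequence_length, window_length, step)
        if w.start <= tm.start and tm.end <= w.end
    ]
    if not candidates:
        raise InfeasibleWindowError(
            "no tiling window fully contains the TM segment "
            f"({tm.start}-{tm.end}, window {window_length})"
        )
    return min(candidates, key=lambda w: (abs(w.center - tm_center), w.start))
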