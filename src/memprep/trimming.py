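"""Signal-sequence removal, low-confidence terminal trimming, and the
partition of a bitopic chain into extracellular / TM / intracellular parts.

Trimming follows the confidence rule used for predicted models: terminal
residues are removed until the first run of `min_confident_run` residues
that are all confident (pLDDT >= 70) and not uniformly coil; internal
low-confidence stretches are connecting loops and are never removed. The
short-run requirement keeps a single stray confident residue inside a
disordered tail from blocking the trim.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from .errors import AllTrimmedError, ContractError
from .structures import ChainModel
from .tm import TMSegment, assign_secondary_structure

logger = logging.getLogger("memprep")

Range = tuple[int, int]  # 1-based inclusive, author numbering

PLDDT_CONFIDENT = 70.0


@dataclass
class DomainPartition:
    """Split of a chain into signal / trimmed tails / ECD / TMD / ICD."""

    tmd_range: Range
    topology: str                      # "N_out" | "N_in"
    ecd_range: Optional[Range] = None
    icd_range: Optional[Range] = None
    signal_range: Optional[Range] = None
    trimmed_n: Optional[Range] = None
    trimmed_c: Optional[Range] = None

    def __post_init__(self) -> None:
        if self.topology not in ("N_out", "N_in"):
            raise ValueError(f"topology must be N_out or N_in, got {self.topology!r}")

    def retained_ranges(self) -> list[Range]:
        n_side = self.ecd_range if self.topology == "N_out" else self.icd_range
        c_side = self.icd_range if self.topology == "N_out" else self.ecd_range
        return [r for r in (n_side, self.tmd_range, c_side) if r is not None]


def remove_signal_sequence(model: ChainModel,
                           signal_range: Optional[Range] = None) -> ChainModel:
    """Drop an annotated N-terminal signal peptide; no-op without annotation.

    The range must start at the chain's first residue — signal peptides are
    N-terminal by definition.
    """
    if signal_range is None:
        return model.copy()
    start, end = signal_range
    first = model.residues[0].seq_index
    if start != first:
        raise ContractError(
            f"signal range {start}-{end} is not anchored at the N-terminus "
            f"(first residue {first})"
        )
    if end >= model.residues[-1].seq_index:
        raise ContractError("signal range covers the whole chain")
    out = model.drop_range(start, end)
    logger.info("removed signal sequence %d-%d (%d residues)", start, end,
                len(model) - len(out))
    return out


def _first_qualifying_run(residues, threshold: float, run: int) -> Optional[int]:
    """List position of the first run of `run` residues all confident and
    not all coil; None if no such run exists."""
    n = len(residues)
    for i in range(n - run + 1):
        window = residues[i:i + run]
        if all(r.plddt >= threshold for r in window) and not all(
            r.ss == "coil" for r in window
        ):
            return i
    return None


def trim_low_confidence_termini(
    model: ChainModel,
    threshold: float = PLDDT_CONFIDENT,
    min_confident_run: int = 3,
) -> tuple[ChainModel, Optional[Range], Optional[Range]]:
    """Remove unstructured low-confidence tails from both termini.

    Returns the trimmed model and the removed N- and C-terminal ranges
    (author numbering, None when nothing was removed). Residues interior
    to the first/last qualifying confident run are always kept, including
    low-confidence connecting loops.
    """
    if len(model) == 0:
        raise ContractError("empty model")
    if any(r.ss is None for r in model.residues):
        model = assign_secondary_structure(model)
    res = model.residues
    i = _first_qualifying_run(res, threshold, min_confident_run)
    if i is None:
        raise AllTrimmedError(
            "no confident run of length "
            f"{min_confident_run} at pLDDT >= {threshold}; nothing would remain"
        )
    j_rev = _first_qualifying_run(res[::-1], threshold, min_confident_run)
    j = len(res) - 1 - j_rev  # list position of last retained residue
    trimmed_n = (res[0].seq_index, res[i - 1].seq_index) if i > 0 else None
    trimmed_c = (res[j + 1].seq_index, res[-1].seq_index) if j < len(res) - 1 else None
    kept = ChainModel([r.copy() for r in res[i:j + 1]], model.source_id)
    if trimmed_n or trimmed_c:
        logger.info("trimmed termini: N %s, C %s", trimmed_n, trimmed_c)
    return kept, trimmed_n, trimmed_c


def parse_domains(model: ChainModel, tm: TMSegment, topology: str,
                  signal_range: Optional[Range] = None,
                  trimmed_n: Optional[Range] = None,
                  trimmed_c: Optional[Range] = None) -> DomainPartition:
    """Partition retained residues into ECD / TMD / ICD by the TM range.

    Residues before the TM form the N-side part and residues after it the
    C-side part; topology decides which side is extracellular. Empty parts
    are allowed (e.g. type II proteins without an N-terminal ectodomain).
    """
    if topology not in ("N_out", "N_in"):
        raise ContractError(f"topology must be N_out or N_in, got {topology!r}")
    idx = model.seq_indices()
    if tm.start not in idx or tm.end not in idx:
        raise ContractError(
            f"TM range {tm.start}-{tm.end} outside the retained residues"
        )
    before = [i for i in idx if i < tm.start]
    after = [i for i in idx if i > tm.end]
    n_side = (before[0], before[-1]) if before else None
    c_side = (after[0], after[-1]) if after else None
    if topology == "N_out":
        ecd, icd = n_side, c_side
    else:
        ecd, icd = c_side, n_side
    return DomainPartition(
        tmd_range=(tm.start, tm.end), topology=topology,
        ecd_range=ecd, icd_range=icd, signal_range=signal_range,
        trimmed_n=trimmed_n, trimmed_c=trimmed_c,
    )
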