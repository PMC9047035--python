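"""Superposition statistics between prepared models and reference
structures: overlapping residue count, overlap percentage, CA RMSD and
sequence identity, in sequence-dependent and sequence-independent modes.

The sequence-dependent mode pairs residues by global Needleman-Wunsch
alignment and refines the pair set by iteratively discarding pairs more
than 5 A apart after superposition. The sequence-independent mode seeds
a correspondence from gapless fragment superpositions and refines it by
dynamic programming on an inter-CA distance score, so it succeeds on
pairs whose sequences cannot be aligned (e.g. permuted constructs).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
import numpy as np
import pandas as pd
from Bio import Align

from .errors import AlignmentFailedError, ContractError
from .geometry import RigidTransform, kabsch
from .structures import ChainModel

logger = logging.getLogger("memprep")

PAIR_CUTOFF = 5.0    # A, iterative pair-rejection distance
SEED_RMSD_MAX = 4.0  # A, acceptance threshold for a fragment seed
DP_D0 = 5.0          # A, distance scale of the DP score 1/(1+(d/d0)^2)


@dataclass
class SuperpositionResult:
    transform: RigidTransform
    n_overlap: int
    overlap_pct: float        # % of model residues in the final pair set
    rmsd_ca: float            # A over the final pair set
    seq_identity_pct: float   # % identical residues among final pairs
    mode: str                 # "sequence_dependent" | "sequence_independent"
    model_id: str = ""
    reference_id: str = ""
    n_model: int = 0
    n_reference: int = 0
    group: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.overlap_pct <= 100 and 0 <= self.seq_identity_pct <= 100):
            raise ValueError("percentages must lie in [0, 100]")
        if self.rmsd_ca < 0:
            raise ValueError("rmsd must be non-negative")


def kabsch_superpose(coords_a, coords_b) -> tuple[RigidTransform, float]:
    """Optimal rigid superposition of paired CA sets; see geometry.kabsch."""
    return kabsch(coords_a, coords_b)


def _refine_pairs(model_ca, ref_ca, pairs, cutoff=PAIR_CUTOFF, max_iter=50):
    """Iteratively superpose and discard pairs farther than `cutoff`."""
    pairs = list(pairs)
    transform = rmsd = None
    for _ in range(max_iter):
        if len(pairs) < 3:
            raise AlignmentFailedError("fewer than 3 alignable residue pairs")
        P = model_ca[[i for i, _ in pairs]]
        Q = ref_ca[[j for _, j in pairs]]
        transform, rmsd = kabsch(P, Q)
        dist = np.linalg.norm(transform.apply(P) - Q, axis=1)
        kept = [p for p, dd in zip(pairs, dist) if dd <= cutoff]
        if len(kept) == len(pairs):
            break
        pairs = kept
    if len(pairs) < 3:
        raise AlignmentFailedError("fewer than 3 alignable residue pairs")
    return pairs, transform, rmsd


def _result(model, reference, pairs, transform, rmsd, mode) -> SuperpositionResult:
    seq_m, seq_r = model.sequence(), reference.sequence()
    ident = sum(seq_m[i] == seq_r[j] for i, j in pairs)
    return SuperpositionResult(
        transform=transform,
        n_overlap=len(pairs),
        overlap_pct=100.0 * len(pairs) / len(model),
        rmsd_ca=float(rmsd),
        seq_identity_pct=100.0 * ident / len(pairs),
        mode=mode,
        model_id=model.source_id,
        reference_id=reference.source_id,
        n_model=len(model),
        n_reference=len(reference),
    )


# ---------------------------------------------------------------------------
# Sequence-dependent alignment
# ---------------------------------------------------------------------------

def align_sequence_dependent(model: ChainModel,
                             reference: ChainModel) -> SuperpositionResult:
    """Pair residues by global identity-scored alignment, then refine.

    Needleman-Wunsch with match +1, mismatch 0, linear gap penalty -0.5
    and free end gaps; aligned pairs are superposed and pairs beyond 5 A
    discarded iteratively until the pair set is stable.
    """
    if len(model) == 0 or len(reference) == 0:
        raise ContractError("empty chain")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -0.5
    aligner.extend_gap_score = -0.5
    # free end gaps: a fragment reference must not distort terminal pairing
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    aln = aligner.align(model.sequence(), reference.sequence())[0]
    pairs = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        pairs.extend(zip(range(a0, a1), range(b0, b1)))
    pairs, transform, rmsd = _refine_pairs(model.ca_coords(),
                                           reference.ca_coords(), pairs)
    return _result(model, reference, pairs, transform, rmsd,
                   "sequence_dependent")


# ---------------------------------------------------------------------------
# Sequence-independent (structural) alignment
# ---------------------------------------------------------------------------

def _dp_align(S: np.ndarray) -> list[tuple[int, int]]:
    """Monotone pairing maximizing the summed score with free gaps."""
    n, m = S.shape
    H = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        cand = np.maximum(H[i - 1, :-1] + S[i - 1], H[i - 1, 1:])
        H[i, 1:] = np.maximum.accumulate(np.maximum(cand, H[i, 0]))
    pairs = []
    i, j = n, m
    while i > 0 and j > 0:
        if np.isclose(H[i, j], H[i - 1, j - 1] + S[i - 1, j - 1]):
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif np.isclose(H[i, j], H[i - 1, j]):
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return pairs


def _helix_segments(model: ChainModel, min_len: int = 6) -> list[int]:
    """Start list-positions of helical runs (secondary-structure seeds)."""
    segs, run = [], 0
    for k, r in enumerate(model.residues):
        if r.ss == "helix":
            run += 1
            if run == min_len:
                segs.append(k - min_len + 1)
        else:
            run = 0
    return segs


def align_sequence_independent(
    model: ChainModel,
    reference: ChainModel,
    fragment_length: int = 12,
    fragment_stride: int = 4,
    n_seeds: int = 3,
    max_iter: int = 30,
) -> SuperpositionResult:
    """Structural alignment without using the sequences.

    Gapless fragments of the two CA traces are superposed pairwise (plus
    seeds pairing secondary-structure elements); each seed below the
    4 A RMSD threshold starts an iterative refinement that alternates
    dynamic-programming re-pairing on the distance score with Kabsch
    superposition. The refinement with the most pairs (ties: lowest RMSD)
    is reported. Identical structures return the identity correspondence.
    """
    if len(model) < 20 or len(reference) < 20:
        raise ContractError("both chains must have at least 20 residues")
    A, B = model.ca_coords(), reference.ca_coords()
    L = fragment_length
    starts_a = list(range(0, len(A) - L + 1, fragment_stride))
    starts_b = list(range(0, len(B) - L + 1, fragment_stride))
    seeds = []
    for ia in starts_a:
        for jb in starts_b:
            _, r = kabsch(A[ia:ia + L], B[jb:jb + L])
            seeds.append((r, ia, jb))
    for ia in _helix_segments(model):
        for jb in _helix_segments(reference):
            if ia + L <= len(A) and jb + L <= len(B):
                _, r = kabsch(A[ia:ia + L], B[jb:jb + L])
                seeds.append((r, ia, jb))
    seeds.sort(key=lambda s: (s[0], s[1], s[2]))
    seeds = [s for s in seeds if s[0] < SEED_RMSD_MAX][:n_seeds]
    if not seeds:
        raise AlignmentFailedError(
            f"no gapless fragment superposes below {SEED_RMSD_MAX} A"
        )

    best = None
    for _, ia, jb in seeds:
        transform, _ = kabsch(A[ia:ia + L], B[jb:jb + L])
        pairs = None
        try:
            for _ in range(max_iter):
                D = np.linalg.norm(
                    transform.apply(A)[:, None, :] - B[None, :, :], axis=2
                )
                S = 1.0 / (1.0 + (D / DP_D0) ** 2)
                new_pairs = [(i, j) for i, j in _dp_align(S) if D[i, j] < PAIR_CUTOFF]
                if len(new_pairs) < 3:
                    raise AlignmentFailedError("refinement collapsed")
                P = A[[i for i, _ in new_pairs]]
                Q = B[[j for _, j in new_pairs]]
                transform, rmsd = kabsch(P, Q)
                if new_pairs == pairs:
                    break
                pairs = new_pairs
        except AlignmentFailedError:
            continue
        key = (-len(pairs), rmsd)
        if best is None or key < best[0]:
            best = (key, pairs, transform, rmsd)
    if best is None:
        raise AlignmentFailedError("no seed refinement produced an alignment")
    _, pairs, transform, rmsd = best
    return _result(model, reference, pairs, transform, rmsd,
                   "sequence_independent")


# ---------------------------------------------------------------------------
# Summary across proteins
# ---------------------------------------------------------------------------

def summarize_validation(
    results: list[SuperpositionResult],
    min_reference_residues: int = 45,
) -> pd.DataFrame:
    """Per-group mean +- SD statistics over the best reference per protein.

    For each protein the reference with the largest overlapping-residue
    count is selected (ties: lower RMSD). References shorter than
    `min_reference_residues` are excluded beforehand. SD is the
    population standard deviation (0 for a single protein).
    """
    rows = [
        r for r in results
        if r.n_reference == 0 or r.n_reference >= min_reference_residues
    ]
    if not rows:
        return pd.DataFrame(
            columns=["group", "n_proteins", "n_overlap_mean", "n_overlap_sd",
                     "overlap_pct_mean", "overlap_pct_sd", "rmsd_mean",
                     "rmsd_sd", "identity_mean", "identity_sd"]
        )
    df = pd.DataFrame(
        {
            "model_id": r.model_id, "reference_id": r.reference_id,
            "group": r.group, "n_overlap": r.n_overlap,
            "overlap_pct": r.overlap_pct, "rmsd": r.rmsd_ca,
            "identity": r.seq_identity_pct,
        }
        for r in rows
    )
    best = (
        df.sort_values(["model_id", "n_overlap", "rmsd"],
                       ascending=[True, False, True])
        .groupby("model_id", as_index=False)
        .first()
    )
    out = (
        best.groupby("group")
        .agg(
            n_proteins=("model_id", "count"),
            n_overlap_mean=("n_overlap", "mean"),
            n_overlap_sd=("n_overlap", lambda x: float(np.std(x))),
            overlap_pct_mean=("overlap_pct", "mean"),
            overlap_pct_sd=("overlap_pct", lambda x: float(np.std(x))),
            rmsd_mean=("rmsd", "mean"),
            rmsd_sd=("rmsd", lambda x: float(np.std(x))),
            identity_mean=("identity", "mean"),
            identity_sd=("identity", lambda x: float(np.std(x))),
        )
        .reset_index()
    )
    out.attrs["selected"] = best
    return out
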