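"""Shared fixtures: hand-written PDB text and synthetic chain builders."""
import numpy as np
import pytest

from memprep import ChainModel, ResidueRecord
from memprep.geometry import nerf_backbone, PHI_HELIX, PSI_HELIX

# Minimal 3-residue PDB with pLDDT in the B-factor column.
MINIMAL_PDB = """\
ATOM      1  N   MET A   1      11.104   6.134  -6.504  1.00 91.50           N
ATOM      2  CA  MET A   1      11.639   6.071  -5.147  1.00 91.50           C
ATOM      3  C   MET A   1      12.759   7.095  -4.974  1.00 91.50           C
ATOM      4  O   MET A   1      13.092   7.877  -5.864  1.00 91.50           O
ATOM      5  N   ALA A   2      13.364   7.089  -3.790  1.00 85.25           N
ATOM      6  CA  ALA A   2      14.468   7.988  -3.465  1.00 85.25           C
ATOM      7  C   ALA A   2      15.785   7.487  -4.052  1.00 85.25           C
ATOM      8  O   ALA A   2      16.092   6.296  -3.960  1.00 85.25           O
ATOM      9  N   GLY A   3      16.567   8.398  -4.630  1.00 67.00           N
ATOM     10  CA  GLY A   3      17.868   8.064  -5.208  1.00 67.00           C
ATOM     11  C   GLY A   3      18.959   8.125  -4.141  1.00 67.00           C
ATOM     12  O   GLY A   3      18.721   8.631  -3.041  1.00 67.00           O
END
"""

# Same three residues, numbered 5, 6, 9 (numbering gap, no renumbering).
GAPPED_PDB = MINIMAL_PDB.replace("MET A   1", "MET A   5").replace(
    "ALA A   2", "ALA A   6").replace("GLY A   3", "GLY A   9")


@pytest.fixture
def minimal_pdb(tmp_path):
    p = tmp_path / "minimal.pdb"
    p.write_text(MINIMAL_PDB)
    return p


@pytest.fixture
def gapped_pdb(tmp_path):
    p = tmp_path / "gapped.pdb"
    p.write_text(GAPPED_PDB)
    return p


def chain_from_ca(ca, sequence=None, plddt=90.0, start=1):
    """ChainModel with CA-only coordinates (geometry-only tests)."""
    ca = np.asarray(ca, dtype=float)
    n = len(ca)
    seq = sequence or "A" * n
    res = [
        ResidueRecord(start + i, seq[i], {"CA": ca[i]},
                      plddt if np.isscalar(plddt) else plddt[i])
        for i in range(n)
    ]
    return ChainModel(res)


def chain_from_backbone(atoms, sequence=None, plddt=90.0, start=1):
    n = len(atoms["CA"])
    seq = sequence or "A" * n
    if np.isscalar(plddt):
        plddt = [plddt] * n
    res = [
        ResidueRecord(start + i, seq[i],
                      {k: atoms[k][i] for k in atoms}, plddt[i])
        for i in range(n)
    ]
    return ChainModel(res)


def helical_chain(n, sequence=None, plddt=90.0, start=1):
    """NeRF-built alpha-helix (classic torsions), for SS/trim tests."""
    bb = nerf_backbone([(PHI_HELIX, PSI_HELIX)] * n)
    return chain_from_backbone(bb, sequence, plddt, start)
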