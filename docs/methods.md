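# Methods

This note documents the models, rules and numerical choices behind
`memprep`, what the synthetic fixtures do and do not emulate, and the
known limitations.

## The preparation problem

Bitopic (single-pass) membrane proteins cross the membrane once through
a single TM α-helix, with folded domains on both sides connected by
flexible linkers. Full-length predicted models of such proteins are
reliable within folded domains but carry systematic artifacts relevant
to membrane-frame analysis: long disordered tails predicted at low
confidence, signal peptides that are absent from the mature protein,
and domains placed without any notion of a membrane — frequently
intertwined on one side of the would-be bilayer. The pipeline repairs
these artifacts with deliberately conservative, fully deterministic
operations: nothing is remodeled, only removed (annotated signal,
low-confidence tails) or moved rigidly (whole domains).

## Confidence trimming

Terminal residues are removed until the first run of
`min_confident_run = 3` residues that are all confident
(pLDDT ≥ `plddt_threshold = 70`) **and** not uniformly coil. Everything
interior to the first/last such run is kept, including low-confidence
internal loops — those are connecting loops, not tails. Two details are
our own operationalization of "unstructured low-confidence termini":

- *Run length 3.* A single stray high-pLDDT residue inside a disordered
  tail should not block trimming; a 3-residue confident, non-coil run is
  the shortest signal we accept as "structure starts here". Consequence:
  an isolated confident residue inside a tail **is** removed even though
  its own pLDDT is ≥ 70; every confident run of length ≥ 3 is provably
  never touched (property-tested on random profiles).
- *"Unstructured" = coil.* Secondary structure is assigned from backbone
  dihedrals (helix: φ ∈ [−100°, −30°], ψ ∈ [−80°, −5°], runs ≥ 4;
  strand: φ ∈ [−180°, −90°], ψ ∈ [90°, 180°], runs ≥ 3; else coil;
  angular windows tested circularly so ±180° wraps count). A
  dihedral-window assignment is dependency-free and adequate for
  distinguishing tails from structure; it is *not* a DSSP replacement —
  hydrogen-bond-defined edge cases (bulged strands, 3₁₀ caps) land in
  coil.

Because trimming consumes secondary-structure labels, the pipeline
assigns them before trimming.

Signal peptides are removed by annotation only (range must start at the
chain's first residue). No de novo signal prediction is attempted: the
annotation is curated upstream, and a heuristic detector would silently
eat N-terminal ectodomains when wrong.

## TM-segment detection

All contiguous 21-residue windows are scored by summed whole-residue
water→octanol transfer free energies (Wimley–White; charged forms for
D/E/K/R/H). A window qualifies if its score is ≤ −8 kcal/mol and ≥ 60%
of its residues carry a helix label; the lowest-scoring qualifying
window wins, ties to the N-terminal-most (with a 1 × 10⁻⁹ kcal/mol
numerical tie band, since two windows over a 2-decimal scale often tie
exactly). The winner is extended one residue at a time while the added
residue's transfer energy is negative, capped at 35 residues. Window 21
and cap 35 bracket canonical single-TM helix lengths; −8 kcal/mol keeps
amphipathic surface helices out while every poly-Leu-like TM segment
scores far below it. Failure to find a qualifying window raises a
distinct error: some families (scramblases, BCL-2-like regulators)
genuinely exist in water-soluble forms, and the caller must decide.

The scale is configurable (two-column TSV); the detection is a
single-pass design by construction — multi-pass topology prediction is
out of scope.

## Implicit membrane and positioning

The membrane is a planar slab: half-thickness d, unit normal n̂, center
offset c. The positioning objective is

    E(n̂, c, d) = Σᵢ ΔG(aaᵢ) · f(zᵢ),   zᵢ = CAᵢ·n̂ − c,

with f = 1 for |z| ≤ d, f = cos²(π(|z| − d)/6 Å) on the 3 Å interface,
0 beyond. This is a CA-level surrogate profile, not a physical free
energy: no atomic solvation, no dipole or ionizable-group terms, no
leaflet asymmetry. Its contract — verified on synthetic ground truth —
is correct sidedness, tilt and boundary placement for structures with a
genuine hydrophobic membrane-spanning stretch.

Optimization is a deterministic coarse grid (normal every 10°, offset
every 1 Å, d every 1 Å in [10, 20] Å — the range of typical hydrocarbon
core half-thicknesses) followed by local Nelder–Mead refinement, so
identical inputs give identical results and the optimum provably beats
any point of an independent brute-force grid. Strictly-first tie
breaking on the grid prefers the smallest tilt and thinnest consistent
slab where the energy is flat — a straight uniform hydrophobic helix
has a degenerate optimum, and this choice makes the result reproducible
and physically conservative. The tilt of the final placement is
energy-driven only through the depth profile; a model with no favorable
placement (E ≥ 0 at the optimum) is flagged non-TM rather than forced
into the membrane.

The sign of the normal is not identifiable from the energy; it is fixed
afterwards from curated topology by rotating the frame π about x so the
TM N-terminal end lies at z > 0 for N_out proteins (extracellular side
is always z > 0 in the membrane frame).

## Reassembly

With the TM positioned across z = 0, the chain is parsed at the TM
boundaries: N-side and C-side parts, mapped to ECD/ICD by topology.
When fewer than 80% of TM residues are helical (the model's TM is
"distorted"), the whole model is first superposed (Kabsch, CA atoms)
onto an ideal helix — rise 1.5 Å, twist 100°/residue, backbone atoms at
fixed cylindrical offsets derived from a standard-geometry helix —
spanning the slab with the topologically correct N→C direction. The 80%
threshold is exposed in config; the underlying criterion for "distorted"
is a design choice of this package.

Each domain is then moved as one rigid body: rotated about its linker-
end CA so the centroid points away from the membrane, and translated to
sit above the adjacent TM end with the smallest linker gap satisfying
(i) centroid at least `clearance = 3 Å` beyond the boundary, (ii) no
atom inside the hydrocarbon core, (iii) gap ≥ one CA–CA bond (3.8 Å).
This closed-form placement (align-centroid + z-translation) replaces any
grid search: it is exact for the stated objective and has no resolution
parameter. Gaps exceeding `max_gap = 12 Å` are flagged as stretched
linkers, never rebuilt — loop modeling is explicitly out of scope, and a
flag is more honest than an invented loop. Residual domain–domain
clashes (CA pairs < 3 Å) are relieved by additional outward
z-translation only. Intra-part geometry is bitwise untouched; the
pipeline is deterministic end to end.

Whether the original pipeline repositions domains jointly against the
membrane energy or sequentially is unknowable from the outside; this
package positions the TM first and places domains relative to it, which
is simpler and makes each step independently testable.

## Validation statistics

Both alignment modes report the same statistics over the final residue
pair set: overlapping residue count, overlap % (denominator = prepared
model length; the other reading — reference length — is a one-line
change and documented here for comparability), Cα RMSD, and sequence
identity among aligned pairs.

- *Sequence-dependent*: global Needleman–Wunsch (match +1, mismatch 0,
  linear gap −0.5, free end gaps so fragment references pair cleanly),
  then iterative Kabsch superposition discarding pairs > 5 Å until the
  pair set is stable.
- *Sequence-independent*: gapless 12-residue fragment pairs (stride 4)
  plus helix-element pairs are superposed; seeds under 4 Å RMSD start an
  iterative refinement alternating dynamic programming on the distance
  score 1/(1 + (d/5 Å)²) with Kabsch superposition; the refinement with
  the most pairs (ties: lowest RMSD) is reported. On identical
  structures this returns the identity correspondence; it also aligns
  sequence-permuted constructs where the sequence mode cannot.

Summary tables select, per protein, the reference with the largest
overlapping-residue count (ties: lower RMSD), exclude references
shorter than 45 residues (configurable), and report mean ± population
SD per species group.

The superposition core (Kabsch with SVD sign correction, det = +1
always) is cross-checked in the tests against an independent
quaternion-parametrized brute-force search, not against another SVD.

## Synthetic fixtures

The generator builds single chains with exact per-stage ground truth:
an ideal hydrophobic TM helix (pool LLLIIVF) across z = 0; helical-
bundle domains from polar residues (all membrane-unfavorable on the
shipped scale) attached on either side; extended low-pLDDT tails
(uniform [30, 65]) and an optional signal peptide; confident regions at
pLDDT uniform [75, 95]. The `intertwined` mode attaches the C-side
domain on the same side as the N-side domain, reproducing the failure
geometry the reassembly must fix. The ground-truth slab half-thickness
is half the TM CA z-span (15 Å for a 21-residue TM). All randomness
flows from one explicit seed; consecutive CA–CA distances are 3.8 ± 0.2 Å
throughout, junctions included.

A second fixture produces a hydrophobic helix at a known tilt inside a
known slab, with polar juxtamembrane tails leaving the membrane straight
along the normal — the shortest path to water — and two threonines at
the interface before strongly polar residues. Positioned this way, the
constructed placement attains the exact energy floor (every favorable
residue fully inside, every unfavorable one fully outside), so the
deterministic optimizer provably recovers the constructed tilt and
thickness; recovery is measured as the angle between the recovered
normal and the constructed helix axis.

What the fixtures do **not** emulate: real side chains (everything is
backbone-level), realistic domain folds or packing, membrane-adsorbed
amphipathic segments, signal peptides with genuinely hydrophobic cores
(the stand-in signal is mildly polar so it cannot shadow the TM in
detection — real inputs rely on the annotation being applied before
detection, as the pipeline does), and B-factor columns that mean
anything but pLDDT. Passing tests therefore demonstrate that the rules
are implemented exactly as specified and are internally consistent —
not that the thresholds are optimal for any particular predictor's
output.

## Numerical choices and degenerate inputs

- All grids and tie-breaks are deterministic; no stochastic optimizer
  anywhere in the pipeline. Byte-identical reruns are tested.
- Kabsch requires ≥ 3 pairs; collinear CA traces (rotation about the
  helix axis undetermined) fall back to all backbone atoms.
- Dihedrals at chain breaks (non-consecutive author numbering) are
  undefined; affected residues are labeled coil.
- Residues without CA are excluded at parse time with a warning;
  insertion codes are rejected (predicted models have none); altloc
  'A'/blank only. Author numbering is preserved end to end — outputs
  must map back to full-length sequence positions.
- Very long sequences arrive as 1,400-residue tiled fragments shifted by
  200; the window whose center is nearest the detected TM center (ties:
  smaller start; last window clipped to the sequence end) is selected.
  The tie rule and clipping are this package's choices.
- PDB output uses fixed 8.3 precision, hence the 10⁻³ Å round-trip
  guarantee; pLDDT is written back to the B-factor column at 2 decimals.

## Problem sizes

Tests and the acceptance script run on desk-scale synthetic problems:
chains of 60–200 residues, 500 random trimming profiles, 200 detection
fixtures, 20 positioning fixtures against a 20×20×20×10 brute-force
grid, 50 random point sets against the quaternion oracle, 1,000
fragment-window cases. These sizes exercise every rule and boundary
condition of the method; database-scale validation against experimental
structures is out of scope for this package.

## Known limitations

- The positioning energy is a surrogate; absolute transfer energies and
  tilts of marginal (barely hydrophobic) helices are not meaningful, and
  charged-residue snorkeling, aromatic-belt anchoring and curved or
  asymmetric membranes are not modeled.
- Rigid reassembly can leave stretched linkers (flagged, not fixed) and
  makes no attempt at inter-domain packing beyond clash relief.
- The sequence-independent aligner is a lightweight structural aligner,
  not a TM-score implementation; its statistics are comparable, its
  optimal-alignment guarantees are not.
- Exactly one TM segment per chain by design; multi-pass proteins and
  re-entrant loops are out of scope, as are GPI anchors.
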