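"""Kabsch superposition, domain placement and full reassembly."""
import numpy as np
import pytest

from memprep import (
    ContractError,
    build_ideal_helix,
    place_domains,
    reassemble_model,
    superpose_tm_onto_reference,
)
from memprep.geometry import RigidTransform, kabsch, rotation_about_axis
from memprep.synthetic import FixtureSpec, generate_synthetic_bitopic
from memprep.trimming import trim_low_confidence_termini


def quaternion_oracle_rmsd(P, Q, n_samples=4000, seed=0):
    """Brute-force best-fit RMSD: random quaternion starts + local simplex."""
    from scipy.optimize import minimize

    P = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)
    rng = np.random.default_rng(seed)

    def rot(q):
        q = q / np.linalg.norm(q)
        w, x, y, z = q
        return np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])

    def cost(q):
        return float(((P @ rot(q).T - Q0) ** 2).sum())

    qs = rng.normal(size=(n_samples, 4))
    costs = np.array([cost(q) for q in qs])
    best = np.inf
    for idx in np.argsort(costs)[:3]:
        res = minimize(cost, qs[idx], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 5000})
        best = min(best, res.fun)
    return float(np.sqrt(best / len(P)))


class TestSuperposeTM:
    def test_identity_on_equal_inputs(self):
        h = build_ideal_helix("L" * 21)
        t = superpose_tm_onto_reference(h, h)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(t.translation, 0.0, atol=1e-9)

    def test_recovers_known_transform(self):
        h = build_ideal_helix("L" * 21)
        R = rotation_about_axis([1.0, 2.0, 0.5], 73.0)
        t_vec = np.array([4.0, -7.0, 11.0])
        moved = h.transformed(RigidTransform(R, t_vec))
        t = superpose_tm_onto_reference(h, moved)
        assert np.allclose(t.rotation, R, atol=1e-6)
        assert np.allclose(t.translation, t_vec, atol=1e-6)

    def test_noisy_copy_rmsd_range(self):
        h = build_ideal_helix("L" * 21)
        ca = h.ca_coords()
        rmsds = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            noisy = ca + rng.normal(0, 0.3, size=ca.shape)
            _, rmsd = kabsch(noisy, ca)
            rmsds.append(rmsd)
        assert all(0.3 <= r <= 0.8 for r in rmsds)

    def test_matches_quaternion_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            P = rng.normal(size=(10, 3)) * 5
            Q = rng.normal(size=(10, 3)) * 5
            _, rmsd = kabsch(P, Q)
            assert abs(rmsd - quaternion_oracle_rmsd(P, Q)) < 1e-3

    def test_too_few_atoms_rejected(self):
        h = build_ideal_helix("L" * 21)
        with pytest.raises((ContractError, ValueError)):
            superpose_tm_onto_reference(h.ca_coords()[:2], h.ca_coords()[:2])


def _intertwined(seed, **kw):
    spec = FixtureSpec(n_residues=150, tm_range=(70, 90), seed=seed,
                       domain_geometry="intertwined", **kw)
    return generate_synthetic_bitopic(spec)


def _retained(model, truth):
    trimmed, _, _ = trim_low_confidence_termini(model)
    return trimmed


class TestPlaceDomains:
    def test_intertwined_domains_end_on_correct_sides(self):
        model, truth = _intertwined(seed=21)
        trimmed = _retained(model, truth)
        placed, flags = place_domains(truth.partition, trimmed, truth.slab)
        d = truth.slab.half_thickness
        for rng_, sign in ((truth.partition.ecd_range, 1),
                           (truth.partition.icd_range, -1)):
            ca = np.array([r.ca for r in placed.residues
                           if rng_[0] <= r.seq_index <= rng_[1]])
            assert sign * ca[:, 2].mean() >= d

    def test_satisfied_input_is_identity(self):
        model, truth = _intertwined(seed=22)
        trimmed = _retained(model, truth)
        placed, _ = place_domains(truth.partition, trimmed, truth.slab)
        again, _ = place_domains(truth.partition, placed, truth.slab)
        for a, b in zip(placed.residues, again.residues):
            for name in a.atoms:
                assert np.allclose(a.atoms[name], b.atoms[name], atol=1e-12)

    def test_domains_move_rigidly(self):
        model, truth = _intertwined(seed=23)
        trimmed = _retained(model, truth)
        placed, _ = place_domains(truth.partition, trimmed, truth.slab)
        for rng_ in (truth.partition.ecd_range, truth.partition.icd_range):
            before = np.array([r.ca for r in trimmed.residues
                               if rng_[0] <= r.seq_index <= rng_[1]])
            after = np.array([r.ca for r in placed.residues
                              if rng_[0] <= r.seq_index <= rng_[1]])
            db = np.linalg.norm(before[:, None] - before[None, :], axis=2)
            da = np.linalg.norm(after[:, None] - after[None, :], axis=2)
            assert np.abs(db - da).max() <= 1e-6


class TestReassembleModel:
    def test_residue_count_and_numbering_conserved(self):
        model, truth = _intertwined(seed=24)
        trimmed = _retained(model, truth)
        out, flags = reassemble_model(trimmed, truth.partition, truth.slab)
        assert out.seq_indices() == trimmed.seq_indices()

    def test_no_domain_atoms_inside_slab_core(self):
        model, truth = _intertwined(seed=25)
        trimmed = _retained(model, truth)
        out, _ = reassemble_model(trimmed, truth.partition, truth.slab)
        d = truth.slab.half_thickness
        for rng_ in (truth.partition.ecd_range, truth.partition.icd_range):
            ca = np.array([r.ca for r in out.residues
                           if rng_[0] <= r.seq_index <= rng_[1]])
            assert np.all(np.abs(ca[:, 2]) >= d - 1e-9)

    def test_deterministic(self):
        model, truth = _intertwined(seed=26)
        trimmed = _retained(model, truth)
        out1, _ = reassemble_model(trimmed, truth.partition, truth.slab)
        out2, _ = reassemble_model(trimmed.copy(), truth.partition, truth.slab)
        for a, b in zip(out1.residues, out2.residues):
            for name in a.atoms:
                assert np.array_equal(a.atoms[name], b.atoms[name])

    def test_distorted_tm_superposed_onto_ideal_helix(self):
        model, truth = _intertwined(seed=27, noise_sigma=0.0)
        trimmed = _retained(model, truth)
        # melt the TM: offset alternate CA positions to break helicity
        rng = np.random.default_rng(0)
        lo, hi = truth.partition.tmd_range
        for r in trimmed.residues:
            if lo <= r.seq_index <= hi:
                for name in r.atoms:
                    r.atoms[name] = r.atoms[name] + rng.normal(0, 1.2, 3)
        from memprep.tm import assign_secondary_structure
        trimmed = assign_secondary_structure(trimmed)
        out, flags = reassemble_model(trimmed, truth.partition, truth.slab)
        assert flags["tm_idealized"]
        tm_ca = np.array([r.ca for r in out.residues
                          if lo <= r.seq_index <= hi])
        # TM spans the slab after idealized superposition
        assert tm_ca[:, 2].min() < -10 and tm_ca[:, 2].max() > 10
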