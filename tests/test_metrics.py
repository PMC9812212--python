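import math

import numpy as np
import pytest

from xtalsim.crystal_model import Ensemble, LabeledAtomSet
from xtalsim.fixtures import make_gaussian_ensemble, make_point_lattice
from xtalsim.geometry import axis_rotation
from xtalsim.metrics import (
    HBondCriteria,
    b_from_rmsf,
    b_profile,
    b_profile_correlation,
    best_fit_rmsd,
    hbond,
    lattice_rmsd,
    match_ordered_waters,
    rmsf,
    rmsf_from_b,
    unwrap_periodic,
)


def _mol(xyz, molecule=0, element="C", residue="UNK"):
    n = len(xyz)
    return LabeledAtomSet.from_arrays(
        element=[element] * n, xyz=xyz,
        molecule=np.full(n, molecule, dtype=int),
        resseq=np.arange(1, n + 1))


class TestUnwrap:
    def test_continuous_trajectory_unchanged(self, rng):
        base = _mol(rng.uniform(0, 5, (4, 3)))
        coords = base.xyz[None] + rng.normal(0, 0.1, (6, 4, 3))
        ens = Ensemble(base, coords)
        out = unwrap_periodic(ens, (20, 20, 20))
        np.testing.assert_array_equal(out.coords, coords)

    def test_exact_box_jump_removed(self, rng):
        base = _mol(rng.uniform(0, 5, (4, 3)))
        box = np.array([20.0, 25.0, 30.0])
        frames = [base.xyz, base.xyz + np.array([box[0], 0, 0]), base.xyz]
        out = unwrap_periodic(Ensemble(base, np.stack(frames)), box)
        np.testing.assert_allclose(out.coords[1], out.coords[0], atol=1e-12)

    def test_random_walk_with_injected_jumps(self, rng):
        """Matches an explicit cumulative-shift-tracking oracle exactly."""
        base = _mol(rng.uniform(0, 5, (3, 3)))
        box = np.array([15.0, 15.0, 15.0])
        n_frames = 40
        steps = rng.normal(0, 0.4, (n_frames, 3))
        true_path = np.cumsum(steps, axis=0)
        wrapped = []
        shifts = np.zeros((n_frames, 3))
        jump_frames = rng.choice(np.arange(2, n_frames), 5, replace=False)
        acc = np.zeros(3)
        for t in range(n_frames):
            if t in jump_frames:
                acc += rng.choice([-1.0, 1.0]) * np.eye(3)[rng.integers(3)] \
                    * box
            shifts[t] = acc
            wrapped.append(base.xyz + true_path[t] + acc)
        ens = Ensemble(base, np.stack(wrapped))
        out = unwrap_periodic(ens, box)
        expected = np.stack([base.xyz + true_path[t] + shifts[0]
                             for t in range(n_frames)])
        np.testing.assert_allclose(out.coords, expected, atol=1e-9)

    def test_bad_box_rejected(self, rng):
        ens = make_gaussian_ensemble(_mol(rng.uniform(0, 3, (3, 3))), 0.1, 3)
        with pytest.raises(ValueError):
            unwrap_periodic(ens, (0, 10, 10))


def _kabsch_oracle(moving, target):
    """Independent SVD superposition, bypassing the scipy route."""
    mc = moving - moving.mean(axis=0)
    tc = target - target.mean(axis=0)
    u, _, vt = np.linalg.svd(mc.T @ tc)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = mc @ rot.T - tc
    return math.sqrt((diff ** 2).sum() / len(diff))


class TestRmsd:
    def test_identity_gives_zero(self, rng):
        ref = _mol(rng.uniform(0, 8, (10, 3)))
        per_mol, mean = best_fit_rmsd(ref, ref)
        assert mean == pytest.approx(0.0, abs=1e-12)
        assert lattice_rmsd(ref, ref) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_removed_by_superposition(self, rng):
        ref = _mol(rng.uniform(0, 8, (10, 3)))
        rot = axis_rotation((0.3, 0.5, 0.81), 37.0)
        moved = ref.with_xyz(ref.xyz @ rot.T + np.array([3.0, -4.0, 9.0]))
        _, mean = best_fit_rmsd(moved, ref)
        assert mean < 1e-9

    def test_single_displaced_atom_matches_svd_oracle(self, rng):
        ref_xyz = rng.uniform(0, 8, (12, 3))
        moved_xyz = ref_xyz.copy()
        moved_xyz[4] += np.array([0.9, -0.2, 0.4])
        _, mean = best_fit_rmsd(_mol(moved_xyz), _mol(ref_xyz))
        assert mean == pytest.approx(_kabsch_oracle(moved_xyz, ref_xyz),
                                     abs=1e-9)

    def test_uniform_translation_invisible_to_lattice_metric(self, rng):
        ref = _mol(rng.uniform(0, 8, (10, 3)))
        moved = ref.with_xyz(ref.xyz + np.array([5.0, 5.0, -2.0]))
        assert lattice_rmsd(moved, ref) == pytest.approx(0.0, abs=1e-12)

    def test_rotation_retained_by_lattice_metric(self, rng):
        ref = _mol(rng.uniform(-4, 4, (10, 3)))
        rot = axis_rotation((0, 0, 1), 25.0)
        moved = ref.with_xyz(ref.xyz @ rot.T)
        lat = lattice_rmsd(moved, ref)
        _, best = best_fit_rmsd(moved, ref)
        assert lat > best
        assert lat > 0.1

    def test_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            best_fit_rmsd(_mol(rng.uniform(0, 5, (4, 3))),
                          _mol(rng.uniform(0, 5, (5, 3))))


class TestRmsf:
    def test_static_ensemble_is_zero(self, rng):
        base = _mol(rng.uniform(0, 6, (5, 3)))
        ens = make_gaussian_ensemble(base, 0.0, 4)
        assert np.allclose(rmsf(ens, base, mode="lattice"), 0.0)

    def test_gaussian_displacements_recover_sigma_sqrt3(self):
        base = make_point_lattice(3, 3, 3, 4.0)
        sigma = 0.25
        ens = make_gaussian_ensemble(base, sigma, 1000, seed=5)
        values = rmsf(ens, base, mode="lattice")
        # pooled over 27 single-atom molecules x 1000 frames
        assert np.mean(values) == pytest.approx(sigma * math.sqrt(3),
                                                rel=0.05)

    def test_best_fit_rmsf_invariant_under_global_rotation(self, rng):
        base = _mol(rng.uniform(0, 6, (8, 3)))
        ens = make_gaussian_ensemble(base, 0.2, 30, seed=2)
        rot = axis_rotation((1, 1, 0), 63.0)
        rotated = Ensemble(base, ens.coords @ rot.T)
        a = rmsf(ens, base, mode="best-fit")
        b = rmsf(rotated, base, mode="best-fit")
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_single_frame_rejected(self, rng):
        base = _mol(rng.uniform(0, 6, (5, 3)))
        ens = make_gaussian_ensemble(base, 0.1, 1)
        with pytest.raises(ValueError):
            rmsf(ens, base)


class TestBFactors:
    def test_unit_rmsf_gives_canonical_constant(self):
        assert b_from_rmsf(1.0) == pytest.approx(8 * math.pi ** 2 / 3,
                                                 abs=1e-12)
        assert b_from_rmsf(0.0) == 0.0

    def test_roundtrip_identity(self, rng):
        x = rng.uniform(0, 2, 20)
        np.testing.assert_allclose(rmsf_from_b(b_from_rmsf(x)), x,
                                   atol=1e-12)

    def test_profile_correlation_limits(self, rng):
        p = rng.uniform(5, 50, 40)
        assert b_profile_correlation(p, 2 * p + 3) == pytest.approx(1.0)
        assert b_profile_correlation(p, -p) == pytest.approx(-1.0)

    def test_profile_correlation_matches_textbook_oracle(self, rng):
        a = rng.uniform(0, 30, 25)
        b = rng.uniform(0, 30, 25)
        am, bm = a.mean(), b.mean()
        oracle = (((a - am) * (b - bm)).sum()
                  / math.sqrt(((a - am) ** 2).sum() * ((b - bm) ** 2).sum()))
        assert b_profile_correlation(a, b) == pytest.approx(oracle,
                                                            abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            b_profile_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_b_profile_selections(self):
        atoms = LabeledAtomSet.from_arrays(
            element=["N", "C", "C", "O", "C", "C"],
            name=["N", "CA", "C", "O", "CB", "CG"],
            residue=["ALA"] * 6,
            resseq=[1] * 6,
            xyz=np.zeros((6, 3)),
            b_factor=[10.0, 20.0, 30.0, 40.0, 50.0, 70.0],
        )
        assert b_profile(atoms, "CA").loc[1] == 20.0
        assert b_profile(atoms, "sidechain").loc[1] == 60.0  # mean(CB, CG)


class TestHBond:
    @staticmethod
    def _geometry(distance, angle_deg):
        """D at origin; H 1 A away; A placed to realize the D-H...A angle."""
        theta = math.radians(angle_deg)
        # law of cosines for |H-A| given |D-H| = 1 and |D-A| = distance
        r = math.cos(theta) + math.sqrt(
            math.cos(theta) ** 2 + distance ** 2 - 1.0)
        d = np.zeros(3)
        h = np.array([1.0, 0.0, 0.0])
        # H->A makes the angle theta with H->D = (-1, 0, 0)
        a = h + r * np.array([-math.cos(theta), math.sin(theta), 0.0])
        assert abs(np.linalg.norm(d - a) - distance) < 1e-12
        return d, h, a

    def test_truth_table(self):
        crit = HBondCriteria()
        d, h, a = self._geometry(2.8, 165.0)
        assert hbond(d, h, a, crit) is True
        d, h, a = self._geometry(3.6, 179.0)
        assert hbond(d, h, a, crit) is False
        d, h, a = self._geometry(2.9, 140.0)
        assert hbond(d, h, a, crit) is False

    def test_coincident_atoms_rejected(self):
        with pytest.raises(ValueError):
            hbond(np.zeros(3), np.zeros(3), np.ones(3))


def _structure_with_waters(offsets, with_h=True):
    """One protein strand of polar atoms plus waters near chosen partners.

    offsets maps water index -> (partner index, O distance).
    """
    protein_xyz = np.array([[4.0 * i, 0.0, 0.0] for i in range(6)])
    cols = {
        "element": ["N" if i % 2 else "O" for i in range(6)],
        "name": [f"P{i}" for i in range(6)],
        "residue": ["GLY"] * 6,
        "resseq": list(range(1, 7)),
        "molecule": [0] * 6,
    }
    xyz = [protein_xyz]
    for w, (pidx, dist) in offsets.items():
        o = protein_xyz[pidx] + np.array([0.0, dist, 0.0])
        entries = [o]
        names = ["O"]
        els = ["O"]
        if with_h:
            entries.append(o + (protein_xyz[pidx] - o)
                           / np.linalg.norm(protein_xyz[pidx] - o))
            names.append("H1")
            els.append("H")
        xyz.append(np.array(entries))
        cols["element"] += els
        cols["name"] += names
        cols["residue"] += ["HOH"] * len(els)
        cols["resseq"] += [100 + w] * len(els)
        cols["molecule"] += [10 + w] * len(els)
    return LabeledAtomSet.from_arrays(
        element=cols["element"], xyz=np.vstack(xyz), name=cols["name"],
        residue=cols["residue"], resseq=cols["resseq"],
        molecule=cols["molecule"])


class TestWaterMatching:
    def test_identical_structures_match_all_bonded_waters(self):
        s = _structure_with_waters({i: (i, 2.8) for i in range(5)})
        result = match_ordered_waters(s, s)
        assert result.count == 5

    def test_displaced_waters_match_nothing(self):
        a = _structure_with_waters({i: (i, 2.8) for i in range(4)})
        b = _structure_with_waters({i: (i, 13.0) for i in range(4)})
        assert match_ordered_waters(a, b).count == 0

    def test_constructed_partial_overlap_counts_two(self):
        """A and B share protein partners for exactly 2 of 4 waters."""
        a = _structure_with_waters({0: (0, 2.8), 1: (1, 2.9),
                                    2: (2, 2.8), 3: (3, 2.9)})
        b = _structure_with_waters({0: (0, 3.0), 1: (1, 2.7),
                                    2: (4, 2.8), 3: (5, 2.9)})
        result = match_ordered_waters(a, b)
        assert result.count == 2

    def test_missing_protein_rejected(self):
        waters = LabeledAtomSet.from_arrays(
            element=["O"], xyz=[[0.0, 0.0, 0.0]],
            residue=["HOH"], resseq=[1], molecule=[0])
        with pytest.raises(ValueError):
            match_ordered_waters(waters, waters)

    def test_generated_hydrogens_are_flagged(self):
        a = _structure_with_waters({0: (0, 2.8)}, with_h=False)
        result = match_ordered_waters(a, a)
        assert result.generated_hydrogens
        assert result.count == 1
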