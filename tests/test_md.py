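"""Trajectory-analysis tests: geometry, energetics, superposition, clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from hvgating import md
from hvgating.errors import (
    DegenerateGeometryError,
    InvalidInputError,
    SelectionError,
)
from hvgating.units import COULOMB_KCAL_A


def simple_traj(coords, names=None, resids=None):
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[1]
    atoms = pd.DataFrame(
        {
            "resid": resids if resids is not None else np.arange(n) + 1,
            "name": names if names is not None else [f"X{i}" for i in range(n)],
            "resname": ["UNK"] * n,
            "chain": ["A"] * n,
        }
    )
    return md.FrameSeries(coords=coords, atoms=atoms)


class TestSelections:
    def test_mini_language_and_clauses(self):
        traj = simple_traj(
            np.zeros((1, 4, 3)),
            names=["OD1", "OD2", "NE", "CZ"],
            resids=[160, 160, 258, 258],
        )
        idx = md.select_atoms(traj.atoms, "resid 160 and name OD1 OD2")
        np.testing.assert_array_equal(idx, [0, 1])
        idx = md.select_atoms(traj.atoms, "resid 258")
        np.testing.assert_array_equal(idx, [2, 3])

    def test_unknown_selection_rejected(self):
        traj = simple_traj(np.zeros((1, 2, 3)))
        with pytest.raises(SelectionError):
            md.select_atoms(traj.atoms, "resid 999")
        with pytest.raises(SelectionError):
            md.select_atoms(traj.atoms, "occupancy 1")


class TestDistances:
    def test_single_atom_pythagoras(self):
        traj = simple_traj([[[0, 0, 0], [3, 4, 0]]])
        d = md.group_distance_series(traj, [0], [1])
        assert d[0] == pytest.approx(5.0)

    def test_coincident_groups_zero(self):
        traj = simple_traj([[[1, 2, 3], [1, 2, 3]]])
        assert md.group_distance_series(traj, [0], [1])[0] == pytest.approx(0.0)

    def test_four_atom_com_distance_matches_hand_computation(self):
        g1 = np.array([[0, 0, 0], [2, 0, 0], [0, 2, 0], [0, 0, 2]], dtype=float)
        g2 = g1 + np.array([10.0, -3.0, 4.0])
        traj = simple_traj(np.concatenate([g1, g2])[None, :, :])
        d = md.group_distance_series(traj, list(range(4)), list(range(4, 8)))
        expected = np.linalg.norm(g2.mean(axis=0) - g1.mean(axis=0))
        assert d[0] == pytest.approx(expected, abs=1e-9)

    def test_distance_invariant_to_rigid_motion(self):
        rng = np.random.default_rng(4)
        coords = rng.normal(size=(5, 8, 3))
        traj = simple_traj(coords)
        d0 = md.group_distance_series(traj, list(range(4)), list(range(4, 8)))
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        moved = coords @ rot.T + np.array([5.0, -2.0, 7.0])
        d1 = md.group_distance_series(simple_traj(moved), list(range(4)), list(range(4, 8)))
        np.testing.assert_allclose(d0, d1, atol=1e-10)


class TestDistributionsAndOccupancy:
    def test_constant_series_single_bin(self):
        edges, p = md.distance_distribution(np.full(50, 4.0), bin_width=0.5)
        assert p.sum() == pytest.approx(1.0)
        assert np.count_nonzero(p) == 1

    def test_bimodal_modes_recovered(self):
        rng = np.random.default_rng(9)
        series = np.concatenate(
            [rng.normal(4.0, 0.1, 500), rng.normal(8.0, 0.1, 500)]
        )
        edges, p = md.distance_distribution(series, bin_width=0.25)
        centers = 0.5 * (edges[:-1] + edges[1:])
        # two local maxima, near 4 and 8 Angstrom
        peaks = centers[p > 0.5 * p.max()]
        assert np.any(np.abs(peaks - 4.0) < 0.3)
        assert np.any(np.abs(peaks - 8.0) < 0.3)

    def test_mass_conserved_under_bin_width_change(self):
        rng = np.random.default_rng(2)
        series = rng.uniform(3, 9, 200)
        for bw in (0.1, 0.5, 1.3):
            _, p = md.distance_distribution(series, bin_width=bw)
            assert p.sum() == pytest.approx(1.0)

    def test_occupancy_limits(self):
        assert md.salt_bridge_occupancy(np.full(20, 3.5)) == 1.0
        assert md.salt_bridge_occupancy(np.full(20, 8.0)) == 0.0

    def test_occupancy_counts_threshold_fraction(self):
        series = np.array([3.0] * 7 + [9.0] * 3)
        assert md.salt_bridge_occupancy(series) == pytest.approx(0.7)


class TestZDensity:
    def test_static_atom_delta_peak(self):
        traj = simple_traj(np.tile(np.array([[[0.0, 0.0, 10.2]]]), (5, 1, 1)))
        centers, dens = md.z_density_profile(traj, [0], bin_width=1.0)
        assert dens.max() == 1.0
        assert abs(centers[np.argmax(dens)] - 10.2) <= 0.5

    def test_translation_equivariance(self):
        rng = np.random.default_rng(6)
        coords = rng.normal(0, 3, size=(20, 10, 3))
        traj = simple_traj(coords)
        c0, d0 = md.z_density_profile(traj, list(range(10)), bin_width=0.5)
        shifted = coords + np.array([0.0, 0.0, 5.0])
        c1, d1 = md.z_density_profile(simple_traj(shifted), list(range(10)), bin_width=0.5)
        np.testing.assert_allclose(c1, c0 + 5.0, atol=1e-9)
        np.testing.assert_allclose(d1, d0)


class TestCoulomb:
    def test_closed_form_salt_bridge_energy(self):
        pair = md.ChargedGroupPair("D160", "R258", q_a=-1.0, q_b=1.0,
                                   distance_series=np.full(10, 4.0))
        e = md.coulomb_energy(pair, epsilon_r=1.0)
        assert e == pytest.approx(-COULOMB_KCAL_A / 4.0, rel=1e-12)
        assert e == pytest.approx(-83.02, abs=0.01)

    def test_zero_charge_gives_zero(self):
        pair = md.ChargedGroupPair("a", "b", q_a=0.0, q_b=1.0,
                                   distance_series=np.full(10, 4.0))
        assert md.coulomb_energy(pair, epsilon_r=2.0) == 0.0

    def test_epsilon_scaling(self):
        pair = md.ChargedGroupPair("a", "b", q_a=1.0, q_b=1.0,
                                   distance_series=np.full(10, 5.0))
        assert md.coulomb_energy(pair, 4.0) == pytest.approx(
            md.coulomb_energy(pair, 2.0) / 2.0
        )

    def test_magnitude_decreases_with_distance(self):
        energies = [
            abs(
                md.coulomb_energy(
                    md.ChargedGroupPair("a", "b", 1.0, -1.0, np.full(5, r)), 2.0
                )
            )
            for r in (3.0, 4.0, 6.0, 10.0)
        ]
        assert np.all(np.diff(energies) < 0)


class TestCycle:
    @staticmethod
    def triad(total_split, state, variant):
        return md.TriadEnergy(
            pair_energies=tuple(zip(("D160-R258", "D160-R261", "R261-R258"), total_split)),
            state=state,
            variant=variant,
        )

    def test_identical_states_give_zero_delta(self):
        tr = [
            self.triad((-1.0, -2.0, 0.5), s, v)
            for s in ("A_I", "A_F")
            for v in ("N264R", "WT")
        ]
        res = md.cycle_energy(tr, variant="N264R", reference="WT")
        assert res.delta_e_variant == 0.0
        assert res.ddelta_e == 0.0

    def test_extra_bridges_match_hand_summed_oracle(self):
        # variant gains two 4-Angstrom bridges in the intermediate-active state
        bridge = -COULOMB_KCAL_A / (2.0 * 4.0)  # q=+1,-1, eps_r=2, r=4
        tr = [
            self.triad((bridge, bridge, 0.1), "A_I", "N264R"),
            self.triad((0.0, 0.0, 0.1), "A_F", "N264R"),
            self.triad((0.0, 0.0, 0.1), "A_I", "WT"),
            self.triad((0.0, 0.0, 0.1), "A_F", "WT"),
        ]
        res = md.cycle_energy(tr, variant="N264R", reference="WT")
        assert res.delta_e_variant == pytest.approx(2.0 * bridge, abs=1e-9)
        assert res.ddelta_e == pytest.approx(2.0 * bridge, abs=1e-9)

    def test_antisymmetric_under_state_swap(self):
        tr = [
            self.triad((-3.0, -1.0, 0.4), "A_I", "N264R"),
            self.triad((-0.5, -0.2, 0.3), "A_F", "N264R"),
            self.triad((-1.0, -0.1, 0.2), "A_I", "WT"),
            self.triad((-0.9, -0.3, 0.1), "A_F", "WT"),
        ]
        res = md.cycle_energy(tr, variant="N264R", reference="WT")
        swapped = [
            md.TriadEnergy(t.pair_energies, state="A_I" if t.state == "A_F" else "A_F",
                           variant=t.variant)
            for t in tr
        ]
        res2 = md.cycle_energy(swapped, variant="N264R", reference="WT")
        assert res2.ddelta_e == pytest.approx(-res.ddelta_e, abs=1e-12)

    def test_missing_state_rejected(self):
        tr = [self.triad((0, 0, 0), "A_I", "N264R")]
        with pytest.raises(InvalidInputError):
            md.cycle_energy(tr, variant="N264R", reference="WT")


class TestKabsch:
    def test_identical_frames(self):
        rng = np.random.default_rng(10)
        a = rng.normal(size=(6, 3))
        rot, trans, rmsd = md.kabsch_superpose(a, a)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-10)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_recovers_constructed_transform(self):
        rng = np.random.default_rng(13)
        a = rng.normal(size=(8, 3))
        true_rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        b = (a - a.mean(0)) @ true_rot.T + np.array([1.0, -2.0, 3.0]) + a.mean(0)
        rot, trans, rmsd = md.kabsch_superpose(a, b)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(b @ rot.T + trans, a, atol=1e-9)

    def test_rmsd_symmetric(self):
        rng = np.random.default_rng(14)
        a, b = rng.normal(size=(2, 7, 3))
        _, _, d_ab = md.kabsch_superpose(a, b)
        _, _, d_ba = md.kabsch_superpose(b, a)
        assert d_ab == pytest.approx(d_ba, abs=1e-10)

    def test_matches_scipy_align_vectors_oracle(self):
        rng = np.random.default_rng(15)
        a, b = rng.normal(size=(2, 9, 3))
        _, _, rmsd = md.kabsch_superpose(a, b)
        rot, rssd = Rotation.align_vectors(a - a.mean(0), b - b.mean(0))
        assert rmsd == pytest.approx(rssd / np.sqrt(9), rel=1e-9)

    def test_collinear_atoms_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            md.kabsch_superpose(line, line)


class TestClustering:
    def test_single_cluster(self):
        rng = np.random.default_rng(16)
        traj = simple_traj(rng.normal(size=(10, 5, 3)))
        labels, centroids = md.cluster_frames(traj, k=1, seed=0)
        assert set(labels) == {0}
        assert len(centroids) == 1

    def test_two_separated_conformations_partitioned(self):
        rng = np.random.default_rng(17)
        base = rng.normal(size=(6, 3))
        frames = []
        truth = []
        for i in range(40):
            conf = base.copy()
            if i % 2:
                conf[0] += np.array([12.0, 0.0, 0.0])  # large internal change
            frames.append(conf + rng.normal(scale=0.05, size=(6, 3)))
            truth.append(i % 2)
        traj = simple_traj(np.stack(frames))
        labels, centroids = md.cluster_frames(traj, k=2, seed=1)
        truth = np.array(truth)
        same = (labels == truth).mean()
        assert same in (0.0, 1.0)  # perfect partition up to label permutation
        assert labels[centroids[0]] == 0 and labels[centroids[1]] == 1

    def test_partition_stable_across_seeds(self):
        rng = np.random.default_rng(18)
        base = rng.normal(size=(4, 3))
        frames = np.stack(
            [base + (10.0 if i >= 20 else 0.0) * np.eye(1, 3, 0)[0] for i in range(40)]
        )
        traj = simple_traj(frames)
        l1, _ = md.cluster_frames(traj, k=2, seed=0)
        l2, _ = md.cluster_frames(traj, k=2, seed=99)
        agree = (l1 == l2).mean()
        assert agree in (0.0, 1.0)

    def test_k_exceeding_frames_rejected(self):
        traj = simple_traj(np.random.default_rng(0).normal(size=(3, 4, 3)))
        with pytest.raises(InvalidInputError):
            md.cluster_frames(traj, k=5, seed=0)
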