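import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from mdscape.geometry import (
    average_structure,
    classify_open_closed,
    domain_rmsd,
    find_hydrophobic_contacts,
    find_salt_bridges,
    fraction_below,
    internal_rmsd,
    kabsch,
    min_interdomain_distance,
    superpose_on_core,
)
from mdscape.structure_model import DomainMap, Structure, Trajectory


def _rmsd_oracle_by_optimization(mobile, reference):
    """Numerically minimize RMSD over rotations+translations (independent route)."""

    def cost(params):
        rot = Rotation.from_rotvec(params[:3]).as_matrix()
        moved = mobile @ rot.T + params[3:]
        return np.sqrt(((moved - reference) ** 2).sum(axis=1).mean())

    best = np.inf
    for seed in range(6):
        rng = np.random.default_rng(seed)
        x0 = np.concatenate([rng.uniform(-np.pi, np.pi, 3), rng.uniform(-5, 5, 3)])
        res = minimize(cost, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        best = min(best, res.fun)
    return best


class TestKabsch:
    def test_identical_sets(self, rng):
        pts = rng.normal(size=(6, 3))
        result = kabsch(pts, pts)
        assert result.rmsd_on_fit_atoms < 1e-10
        np.testing.assert_allclose(result.rotation, np.eye(3), atol=1e-8)

    def test_exact_recovery_of_rigid_motion(self, rng):
        pts = rng.normal(size=(8, 3)) * 5
        rot = Rotation.random(rng=rng).as_matrix()
        moved = pts @ rot.T + [3.0, -7.0, 1.5]
        result = kabsch(pts, moved)
        assert result.rmsd_on_fit_atoms <= 1e-8
        np.testing.assert_allclose(result.apply(pts), moved, atol=1e-8)

    def test_rotation_is_proper(self, rng):
        pts = rng.normal(size=(5, 3))
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        result = kabsch(pts, mirrored)
        assert np.linalg.det(result.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_matches_numerical_optimization_oracle(self):
        mobile = np.array(
            [[0.0, 0, 0], [1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]]
        )
        reference = mobile.copy()
        reference[3] = [0.4, 0.3, 1.2]  # one displaced vertex
        ours = kabsch(mobile, reference).rmsd_on_fit_atoms
        oracle = _rmsd_oracle_by_optimization(mobile, reference)
        assert ours == pytest.approx(oracle, abs=1e-6)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_flagged(self):
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.warns(UserWarning, match="collinear"):
            kabsch(line, line + 1.0)


class TestSuperposeOnCore:
    def test_global_rigid_motion_removed(self, two_domain_spec, rng):
        topology, dmap = two_domain_spec
        frames = []
        for _ in range(4):
            rot = Rotation.random(rng=rng).as_matrix()
            frames.append(topology.coords @ rot.T + rng.uniform(-30, 30, 3))
        traj = Trajectory(topology, np.stack(frames))
        aligned = superpose_on_core(traj, dmap.atom_indices(topology, "A"), topology)
        np.testing.assert_allclose(
            aligned.coords, np.repeat(topology.coords[None], 4, 0), atol=1e-8
        )

    def test_alignment_never_increases_core_rmsd(self, two_domain_spec, rng):
        topology, dmap = two_domain_spec
        core = dmap.atom_indices(topology, "A")
        coords = topology.coords[None] + rng.normal(0, 2, size=(6, 20, 3))
        traj = Trajectory(topology, coords)
        aligned = superpose_on_core(traj, core, topology)
        before = np.sqrt(((coords[:, core] - topology.coords[core]) ** 2).sum(-1).mean(-1))
        after = np.sqrt(((aligned.coords[:, core] - topology.coords[core]) ** 2).sum(-1).mean(-1))
        assert np.all(after <= before + 1e-12)


class TestAverageStructure:
    def test_identical_frames_fixed_point(self, two_domain_spec):
        topology, dmap = two_domain_spec
        traj = Trajectory(topology, np.repeat(topology.coords[None], 3, 0))
        avg = average_structure(traj, dmap.atom_indices(topology, "A"))
        np.testing.assert_allclose(avg.coords, topology.coords, atol=1e-10)

    def test_mirror_displacement_gives_midpoint(self, two_domain_spec):
        topology, dmap = two_domain_spec
        delta = np.zeros_like(topology.coords)
        delta[dmap.atom_indices(topology, "B")] = [0.0, 2.5, 0.0]
        traj = Trajectory(
            topology, np.stack([topology.coords + delta, topology.coords - delta])
        )
        avg = average_structure(traj, dmap.atom_indices(topology, "A"))
        np.testing.assert_allclose(avg.coords, topology.coords, atol=1e-6)

    def test_average_reference_tightens_rmsd_on_drifting_ensembles(self, two_domain_spec):
        # when a domain drifts away from its starting position, the average
        # structure sits inside the explored region and gives smaller mean
        # RMSDs than the initial structure (the reference lies at the edge)
        topology, dmap = two_domain_spec
        idx = dmap.atom_indices(topology, "B")
        core = dmap.atom_indices(topology, "A")
        for seed in (3, 11, 42):
            rng = np.random.default_rng(seed)
            n_frames = 60
            coords = np.repeat(topology.coords[None], n_frames, 0)
            drift = np.linspace(0, 1, n_frames)[:, None, None] * np.array([8.0, 4.0, 0.0])
            coords[:, idx, :] += drift
            coords += rng.normal(0, 0.3, size=coords.shape)
            traj = superpose_on_core(Trajectory(topology, coords), core, topology)
            avg = average_structure(traj, core)
            to_initial = domain_rmsd(traj, topology, idx).mean
            to_average = domain_rmsd(traj, avg, idx).mean
            assert to_average <= to_initial


class TestDomainRMSD:
    def test_reference_frame_scores_zero(self, two_domain_spec):
        topology, dmap = two_domain_spec
        traj = Trajectory(topology, topology.coords[None])
        series = domain_rmsd(traj, topology, dmap.atom_indices(topology, "B"))
        assert series.values[0] == 0.0

    def test_pure_translation_analytic(self, two_domain_spec):
        topology, dmap = two_domain_spec
        coords = topology.coords.copy()
        coords[dmap.atom_indices(topology, "B")] += [3.0, 4.0, 0.0]
        traj = Trajectory(topology, np.repeat(coords[None], 2, 0))
        series = domain_rmsd(traj, topology, dmap.atom_indices(topology, "B"))
        np.testing.assert_allclose(series.values, 5.0, atol=1e-12)

    def test_matches_per_atom_sum_oracle(self, two_domain_spec, rng):
        topology, dmap = two_domain_spec
        coords = topology.coords[None] + rng.normal(size=(3, 20, 3))
        traj = Trajectory(topology, coords)
        idx = dmap.atom_indices(topology, "B")
        series = domain_rmsd(traj, topology, idx)
        for f in range(3):
            total = sum(
                np.sum((coords[f, i] - topology.coords[i]) ** 2) for i in idx
            )
            assert series.values[f] == pytest.approx(np.sqrt(total / len(idx)), abs=1e-10)

    def test_empty_selection_rejected(self, two_domain_spec):
        topology, _ = two_domain_spec
        traj = Trajectory(topology, topology.coords[None])
        with pytest.raises(ValueError):
            domain_rmsd(traj, topology, np.array([], dtype=int))


class TestInternalRMSD:
    def test_rigidly_moved_domain_scores_zero(self, two_domain_spec, rng):
        topology, dmap = two_domain_spec
        idx = dmap.atom_indices(topology, "B")
        coords = topology.coords.copy()
        rot = Rotation.random(rng=rng).as_matrix()
        centroid = coords[idx].mean(axis=0)
        coords[idx] = (coords[idx] - centroid) @ rot.T + centroid + [8.0, -3.0, 2.0]
        traj = Trajectory(topology, coords[None])
        series = internal_rmsd(traj, idx, topology)
        assert series.values[0] <= 1e-8

    def test_never_exceeds_core_aligned_rmsd(self, two_domain_spec, rng):
        topology, dmap = two_domain_spec
        idx = dmap.atom_indices(topology, "B")
        coords = topology.coords[None] + rng.normal(0, 2, size=(5, 20, 3))
        traj = Trajectory(topology, coords)
        internal = internal_rmsd(traj, idx, topology).values
        unrefit = domain_rmsd(traj, topology, idx).values
        assert np.all(internal <= unrefit + 1e-10)

    def test_grows_with_planted_jitter(self, two_domain_spec):
        topology, dmap = two_domain_spec
        idx = dmap.atom_indices(topology, "B")
        means = []
        for sigma in (0.5, 1.0, 2.0):
            rng = np.random.default_rng(99)
            coords = np.repeat(topology.coords[None], 50, 0)
            coords[:, idx, :] += rng.normal(0, sigma, size=(50, len(idx), 3))
            means.append(internal_rmsd(Trajectory(topology, coords), idx, topology).mean)
        assert means[0] < means[1] < means[2]


class TestMinInterdomainDistance:
    def test_single_atom_domains(self, ca_chain):
        coords = np.zeros((1, 10, 3))
        coords[0, 5] = [3.0, 4.0, 0.0]
        traj = Trajectory(ca_chain, coords)
        series = min_interdomain_distance(traj, np.array([0]), np.array([5]))
        assert series.values[0] == pytest.approx(5.0)

    def test_coincident_atoms_give_zero(self, ca_chain):
        traj = Trajectory(ca_chain, np.zeros((1, 10, 3)))
        series = min_interdomain_distance(traj, np.array([0, 1]), np.array([8, 9]))
        assert series.values[0] == 0.0

    def test_matches_double_loop_oracle(self, ca_chain, rng):
        coords = rng.normal(0, 5, size=(3, 10, 3))
        traj = Trajectory(ca_chain, coords)
        idx_a, idx_b = np.array([0, 1, 2]), np.array([6, 7])
        series = min_interdomain_distance(traj, idx_a, idx_b)
        for f in range(3):
            expected = min(
                np.linalg.norm(coords[f, i] - coords[f, j])
                for i in idx_a
                for j in idx_b
            )
            assert series.values[f] == pytest.approx(expected, abs=1e-10)

    def test_symmetry_in_domain_order(self, ca_chain, rng):
        coords = rng.normal(size=(2, 10, 3))
        traj = Trajectory(ca_chain, coords)
        a, b = np.array([0, 1]), np.array([5, 6])
        np.testing.assert_array_equal(
            min_interdomain_distance(traj, a, b).values,
            min_interdomain_distance(traj, b, a).values,
        )

    def test_overlapping_selections_rejected(self, ca_chain):
        traj = Trajectory(ca_chain, np.zeros((1, 10, 3)))
        with pytest.raises(ValueError, match="overlap"):
            min_interdomain_distance(traj, np.array([0, 1]), np.array([1, 2]))


class TestStateClassification:
    def test_fraction_below_examples(self):
        assert fraction_below(np.array([7.0, 9.0, 7.0, 9.0]), 8.0) == 0.5
        assert fraction_below(np.array([8.0, 9.0]), 8.0) == 0.0

    def test_fraction_empty_rejected(self):
        with pytest.raises(ValueError):
            fraction_below(np.array([]), 8.0)

    def test_strict_threshold_boundary(self):
        states = classify_open_closed(np.array([7.9, 8.0]), threshold=8.0)
        assert list(states) == ["closed", "open"]

    def test_classification_consistent_with_fraction(self, rng):
        values = rng.uniform(2, 14, size=200)
        states = classify_open_closed(values, threshold=8.0)
        assert (states == "closed").mean() == fraction_below(values, 8.0)


def _sidechain_structure(entries):
    """entries: (residue_index, residue_name, atom_name, xyz)."""
    return Structure(
        [e[0] for e in entries],
        [e[1] for e in entries],
        [e[2] for e in entries],
        np.array([e[3] for e in entries], dtype=float),
    )


class TestContacts:
    dmap = DomainMap({"A": (1, 10), "B": (11, 20)})

    def test_salt_bridge_within_cutoff(self):
        structure = _sidechain_structure(
            [
                (1, "LYS", "CA", (0, 0, 0)),
                (1, "LYS", "NZ", (1, 0, 0)),
                (12, "ASP", "CA", (6, 0, 0)),
                (12, "ASP", "OD1", (4.5, 0, 0)),
            ]
        )
        bridges = find_salt_bridges(structure, self.dmap, "A", "B")
        assert len(bridges) == 1
        row = bridges.iloc[0]
        assert (row.res_basic, row.res_acidic) == (1, 12)
        assert row.distance == pytest.approx(3.5)

    def test_salt_bridge_beyond_cutoff(self):
        structure = _sidechain_structure(
            [
                (1, "LYS", "NZ", (0, 0, 0)),
                (1, "LYS", "CB", (0, 1, 0)),
                (12, "ASP", "OD1", (4.5, 0, 0)),
            ]
        )
        assert len(find_salt_bridges(structure, self.dmap, "A", "B", cutoff=4.0)) == 0

    def test_salt_bridge_symmetric_in_domain_order(self):
        structure = _sidechain_structure(
            [
                (2, "ARG", "NH1", (0, 0, 0)),
                (2, "ARG", "CB", (1, 1, 1)),
                (15, "GLU", "OE2", (3.0, 0, 0)),
            ]
        )
        ab = find_salt_bridges(structure, self.dmap, "A", "B")
        ba = find_salt_bridges(structure, self.dmap, "B", "A")
        assert ab.to_dict() == ba.to_dict()

    def test_ca_only_structure_warns_and_skips(self, ca_chain):
        dmap = DomainMap({"A": (1, 5), "B": (6, 10)})
        with pytest.warns(UserWarning, match="CA"):
            bridges = find_salt_bridges(ca_chain, dmap, "A", "B")
        assert bridges.empty

    def test_unknown_domain_rejected(self, ca_chain):
        with pytest.raises(KeyError):
            find_salt_bridges(ca_chain, self.dmap, "A", "Z")

    def test_hydrophobic_contact_within_cutoff(self):
        structure = _sidechain_structure(
            [
                (3, "LEU", "CD1", (0, 0, 0)),
                (14, "ILE", "CD1", (4.0, 0, 0)),
            ]
        )
        contacts = find_hydrophobic_contacts(structure, self.dmap, "A", "B")
        assert len(contacts) == 1
        assert contacts.iloc[0].distance == pytest.approx(4.0)

    def test_hydrophobic_contact_beyond_cutoff(self):
        structure = _sidechain_structure(
            [
                (3, "LEU", "CD1", (0, 0, 0)),
                (14, "ILE", "CD1", (5.0, 0, 0)),
            ]
        )
        assert find_hydrophobic_contacts(structure, self.dmap, "A", "B").empty

    def test_hydrophobic_symmetric_in_domain_order(self):
        structure = _sidechain_structure(
            [
                (3, "PHE", "CZ", (0, 0, 0)),
                (14, "VAL", "CG1", (3.0, 0, 0)),
            ]
        )
        ab = find_hydrophobic_contacts(structure, self.dmap, "A", "B")
        ba = find_hydrophobic_contacts(structure, self.dmap, "B", "A")
        assert ab.to_dict() == ba.to_dict()


class TestRigidMotionInvariance:
    def test_rmsd_and_distance_invariant_under_global_transform(self, two_domain_spec, rng):
        topology, dmap = two_domain_spec
        coords = topology.coords[None] + rng.normal(0, 1.5, size=(4, 20, 3))
        moved = np.empty_like(coords)
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.uniform(-40, 40, 3)
        for f in range(4):
            moved[f] = coords[f] @ rot.T + shift
        core = dmap.atom_indices(topology, "A")
        idx_b = dmap.atom_indices(topology, "B")
        r1 = domain_rmsd(
            superpose_on_core(Trajectory(topology, coords), core, topology), topology, idx_b
        )
        r2 = domain_rmsd(
            superpose_on_core(Trajectory(topology, moved), core, topology), topology, idx_b
        )
        np.testing.assert_allclose(r1.values, r2.values, atol=1e-8)
        d1 = min_interdomain_distance(Trajectory(topology, coords), core, idx_b)
        d2 = min_interdomain_distance(Trajectory(topology, moved), core, idx_b)
        np.testing.assert_allclose(d1.values, d2.values, atol=1e-8)
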