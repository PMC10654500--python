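"""Superposition, dihedrals, SASA, orientation and trajectory I/O."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from strandgate import synthetic_data as sd
from strandgate.errors import (DegenerateGeometryError, FormatError,
                               TopologyError)
from strandgate.structure_core import (AtomTable, StructureFrame, Trajectory,
                                       classify_orientation, dihedral,
                                       isomer_state, read_trajectory,
                                       relative_sasa, rmsd_series, sasa,
                                       superpose, write_trajectory)

RNG = np.random.default_rng(20230907)


def _cloud_frame(coords, element="C"):
    n = len(coords)
    table = AtomTable([f"C{i}" for i in range(n)], [element] * n,
                      np.arange(1, n + 1), ["ALA"] * n, ["A"] * n)
    return StructureFrame(table, np.asarray(coords, dtype=float))


def _rigid(coords, seed=0):
    rng = np.random.default_rng(seed)
    rot = Rotation.random(random_state=rng).as_matrix()
    return coords @ rot.T + rng.normal(0, 5.0, 3)


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

class TestSuperpose:
    def test_self_superposition_is_zero(self):
        frame = _cloud_frame(RNG.normal(0, 3, (10, 3)))
        transform, rmsd = superpose(frame, frame, "all")
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(transform.apply(frame.coords), frame.coords, atol=1e-9)

    def test_rigid_motion_invariance(self):
        coords = RNG.normal(0, 3, (12, 3))
        moved = _cloud_frame(_rigid(coords, seed=4))
        _, rmsd = superpose(moved, _cloud_frame(coords), "all")
        assert rmsd <= 1e-6

    def test_symmetry_of_rmsd(self):
        a = _cloud_frame(RNG.normal(0, 3, (8, 3)))
        b = _cloud_frame(RNG.normal(0, 3, (8, 3)))
        assert superpose(a, b, "all")[1] == pytest.approx(
            superpose(b, a, "all")[1], abs=1e-6)

    def test_matches_brute_force_rotation_search(self):
        """Kabsch equals direct minimization over rotations (grid + refine)."""
        a = RNG.normal(0, 3, (10, 3))
        b = RNG.normal(0, 3, (10, 3))
        _, rmsd = superpose(_cloud_frame(b), _cloud_frame(a), "all")

        a_c = a - a.mean(axis=0)
        b_c = b - b.mean(axis=0)

        def cost(euler):
            rot = Rotation.from_euler("xyz", euler).as_matrix()
            return np.sqrt(np.mean(np.sum((a_c - b_c @ rot.T) ** 2, axis=1)))

        best = np.inf
        grid = np.linspace(-np.pi, np.pi, 7)
        for ex in grid:
            for ey in grid[:4]:
                for ez in grid:
                    res = minimize(cost, [ex, ey, ez], method="Nelder-Mead",
                                   options={"xatol": 1e-8, "fatol": 1e-12})
                    best = min(best, res.fun)
        assert rmsd == pytest.approx(best, abs=1e-3)

    def test_too_few_atoms_rejected(self):
        frame = _cloud_frame(RNG.normal(0, 3, (2, 3)))
        with pytest.raises(DegenerateGeometryError):
            superpose(frame, frame, "all")

    def test_collinear_selection_rejected(self):
        coords = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        frame = _cloud_frame(coords)
        with pytest.raises(DegenerateGeometryError):
            superpose(frame, frame, "all")


class TestRmsdSeries:
    def test_reference_frame_gives_zero(self, cis_fixture):
        _, traj, _ = cis_fixture
        series = rmsd_series(traj, traj.frame(0), "heavy")
        assert series[0] == pytest.approx(0.0, abs=1e-9)

    def test_zero_noise_fixture_is_flat(self):
        spec = sd.BarrelFixtureSpec()
        traj, _ = sd.generate_barrel_trajectory(spec, 5, 0.0)
        assert np.allclose(rmsd_series(traj, traj.frame(0), "heavy"), 0.0,
                           atol=1e-6)

    def test_mean_rmsd_grows_with_noise(self):
        means = []
        for sigma in (0.1, 0.2, 0.4):
            spec = sd.BarrelFixtureSpec(seed=11)
            traj, _ = sd.generate_barrel_trajectory(spec, 6, sigma)
            means.append(rmsd_series(traj, traj.frame(0), "heavy")[1:].mean())
        assert means[0] < means[1] < means[2]


# ---------------------------------------------------------------------------
# dihedrals
# ---------------------------------------------------------------------------

def _dihedral_frame(fourth):
    coords = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 0.0],
                       [1.5, 0.0, 0.0], fourth])
    return _cloud_frame(coords), [(i + 1, f"C{i}") for i in range(4)]


class TestDihedral:
    def test_planar_trans_is_180(self):
        frame, spec = _dihedral_frame([1.5, -1.0, 0.0])
        assert dihedral(frame, spec) == pytest.approx(180.0)

    def test_planar_cis_is_0(self):
        frame, spec = _dihedral_frame([1.5, 1.0, 0.0])
        assert dihedral(frame, spec) == pytest.approx(0.0)

    def test_invariant_under_rigid_motion(self):
        for seed in range(5):
            fourth = RNG.normal(0, 2, 3)
            frame, spec = _dihedral_frame(fourth)
            angle = dihedral(frame, spec)
            moved = _cloud_frame(_rigid(frame.coords, seed))
            assert dihedral(moved, spec) == pytest.approx(angle, abs=1e-8)

    def test_changes_sign_under_mirror(self):
        frame, spec = _dihedral_frame([1.5, 0.5, 0.8])
        angle = dihedral(frame, spec)
        mirrored = _cloud_frame(frame.coords * [1.0, 1.0, -1.0])
        assert dihedral(mirrored, spec) == pytest.approx(-angle, abs=1e-8)

    def test_coincident_atoms_rejected(self):
        frame, spec = _dihedral_frame([1.5, 0.0, 0.0])
        coords = frame.coords.copy()
        coords[3] = coords[2]
        with pytest.raises(DegenerateGeometryError):
            dihedral(_cloud_frame(coords), spec)

    def test_160_degrees_bins_to_trans_side(self):
        """Mirrors treating the 160-degree complex as trans-like."""
        assert isomer_state(160.0) == "trans"
        assert isomer_state(20.0) == "cis"
        assert isomer_state(-160.0) == "trans"


# ---------------------------------------------------------------------------
# solvent accessibility
# ---------------------------------------------------------------------------

class TestSasa:
    def test_isolated_atom_matches_sphere_area(self):
        frame = _cloud_frame([[0.0, 0.0, 0.0]], element="C")
        probe, radius = 1.4, 1.70
        area = sasa(frame, probe_radius=probe)[1]
        assert area == pytest.approx(4 * np.pi * (radius + probe) ** 2, rel=0.02)

    def test_probe_radius_monotonic_for_isolated_atom(self):
        frame = _cloud_frame([[0.0, 0.0, 0.0]], element="N")
        assert sasa(frame, probe_radius=2.8)[1] >= sasa(frame, probe_radius=1.4)[1]

    def test_buried_residue_less_exposed_than_terminal(self, cis_fixture):
        _, traj, _ = cis_fixture
        rel = relative_sasa(traj.frame(0), residues=[203, 209], point_number=480)
        assert rel[203] < rel[209]

    def test_total_sasa_invariant_under_rigid_motion(self):
        coords = RNG.normal(0, 4, (20, 3))
        frame = _cloud_frame(coords)
        total = sum(sasa(frame).values())
        moved = _cloud_frame(_rigid(coords, seed=2))
        assert sum(sasa(moved).values()) == pytest.approx(total, rel=0.02)

    def test_unknown_element_reported(self):
        table = AtomTable(["X1"], ["XX"], [1], ["ALA"], ["A"])
        frame = StructureFrame(table, np.zeros((1, 3)))
        with pytest.raises(DegenerateGeometryError, match="X1"):
            sasa(frame)


# ---------------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------------

class TestOrientation:
    def test_parity_rule_on_dissociating_strand(self, cis_fixture):
        """Odd residues point into the barrel, even residues out; the
        cleaved-terminus residue is solvent-exposed."""
        _, traj, topo = cis_fixture
        labels = classify_orientation(traj.frame(0), topo)
        for res in topo.residues_of("10"):
            if res == 209:
                assert labels[res] == "exposed"
            elif res % 2 == 1:
                assert labels[res] == "in"
            else:
                assert labels[res] == "out"

    def test_labels_invariant_under_global_rotation(self, cis_fixture):
        _, traj, topo = cis_fixture
        frame = traj.frame(0)
        labels = classify_orientation(frame, topo, point_number=240)
        moved = StructureFrame(frame.table, _rigid(frame.coords, seed=9))
        assert classify_orientation(moved, topo, point_number=240) == labels

    def test_constructed_all_inward_sidechains(self, cis_fixture):
        """Moving every CB onto the axis-facing side labels everything in."""
        from strandgate.structure_core import barrel_axis

        _, traj, topo = cis_fixture
        frame = traj.frame(0)
        centroid, axis = barrel_axis(frame, topo)
        coords = frame.coords.copy()
        table = frame.table
        for res in topo.strand_of:
            if topo.strand_of[res] not in topo.strand_labels:
                continue
            mask_cb = table.residue_mask(res) & (table.atom_names == "CB")
            mask_ca = table.residue_mask(res) & (table.atom_names == "CA")
            if mask_cb.any():
                ca = coords[mask_ca][0]
                radial = ca - (centroid + ((ca - centroid) @ axis) * axis)
                coords[mask_cb] = ca - 1.5 * radial / np.linalg.norm(radial)
        labels = classify_orientation(
            StructureFrame(table, coords), topo, exposure_threshold=1.01)
        strand_labels = [labels[r] for r, s in topo.strand_of.items()
                         if s in topo.strand_labels]
        assert set(strand_labels) == {"in"}

    def test_axis_needs_three_calpha(self):
        frame = _cloud_frame(RNG.normal(0, 3, (4, 3)))
        from strandgate.structure_core import StrandTopology, barrel_axis
        topo = StrandTopology({1: "10", 2: "7", 3: "11"}, "10", (1, 3))
        with pytest.raises(DegenerateGeometryError):
            barrel_axis(frame, topo)  # no CA atoms at all


# ---------------------------------------------------------------------------
# trajectory I/O
# ---------------------------------------------------------------------------

class TestTrajectoryIO:
    def test_round_trip_preserves_coordinates_at_pdb_precision(
            self, tmp_path, annealing_fixture):
        _, _, traj, topo = annealing_fixture
        sub = Trajectory(traj.table, traj.coords[:4])
        write_trajectory(sub, topo, tmp_path / "t.pdb", tmp_path / "t.json")
        back, topo2 = read_trajectory(tmp_path / "t.pdb", tmp_path / "t.json")
        assert back.n_frames == 4
        assert np.abs(back.coords - sub.coords).max() <= 1.5e-3
        assert topo2.dissociating_strand == topo.dissociating_strand
        assert topo2.strand_of == topo.strand_of

    def test_single_model_file_gives_one_frame(self, tmp_path, cis_fixture):
        _, traj, topo = cis_fixture
        one = Trajectory(traj.table, traj.coords[:1])
        write_trajectory(one, topo, tmp_path / "one.pdb", tmp_path / "one.json")
        back, _ = read_trajectory(tmp_path / "one.pdb", tmp_path / "one.json")
        assert back.n_frames == 1

    def test_schedule_round_trips(self, tmp_path, annealing_fixture):
        _, _, traj, topo = annealing_fixture
        write_trajectory(traj, topo, tmp_path / "s.pdb", tmp_path / "s.json")
        back, _ = read_trajectory(tmp_path / "s.pdb", tmp_path / "s.json")
        assert back.schedule.segments == traj.schedule.segments

    def test_model_with_missing_atom_is_format_error(self, tmp_path, cis_fixture):
        _, traj, topo = cis_fixture
        two = Trajectory(traj.table, traj.coords[:2])
        write_trajectory(two, topo, tmp_path / "bad.pdb", tmp_path / "bad.json")
        lines = (tmp_path / "bad.pdb").read_text().splitlines()
        # drop one ATOM record from the second model
        second_atoms = [i for i, l in enumerate(lines) if l.startswith("ATOM")]
        del lines[second_atoms[len(second_atoms) // 2 + 3]]
        (tmp_path / "bad.pdb").write_text("\n".join(lines) + "\n")
        with pytest.raises(FormatError):
            read_trajectory(tmp_path / "bad.pdb", tmp_path / "bad.json")

    def test_unresolvable_dihedral_atoms_is_topology_error(
            self, tmp_path, cis_fixture):
        import json
        _, traj, topo = cis_fixture
        one = Trajectory(traj.table, traj.coords[:1])
        write_trajectory(one, topo, tmp_path / "t.pdb", tmp_path / "t.json")
        data = json.loads((tmp_path / "t.json").read_text())
        data["dihedral_specs"]["phi_I"][0] = [66, "ZZ"]
        (tmp_path / "t.json").write_text(json.dumps(data))
        with pytest.raises(TopologyError):
            read_trajectory(tmp_path / "t.pdb", tmp_path / "t.json")
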