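"""Forward solver: assembly consistency, patch test, uniaxial oracle,
contact behaviour and material linearity."""

import numpy as np
import pytest
from scipy.optimize import brentq

from tissuecal import (
    DeformationState,
    Material,
    ProbeSpec,
    assemble,
    cauchy_stress,
    max_volume_change,
    solve_indentation,
    solve_prescribed,
    surface_fields,
)
from tissuecal.errors import ContactError, SolverError
from tissuecal.fem import element_stresses, total_strain_energy
from tissuecal.synthetic import make_box_mesh

MAT = Material.coupled(0.01, k_ratio=1000.0)


class TestAssembly:
    def test_zero_displacement_zero_force(self, unit_box_coarse):
        f, K, Jel = assemble(unit_box_coarse, MAT, np.zeros(3 * unit_box_coarse.n_nodes))
        assert np.allclose(f, 0.0)
        assert np.allclose(Jel, 1.0)

    def test_rigid_translation_zero_force(self, unit_box_coarse):
        u = np.tile([0.3, -0.2, 0.1], unit_box_coarse.n_nodes)
        f, _, _ = assemble(unit_box_coarse, MAT, u)
        assert np.abs(f).max() < 1e-12

    def test_internal_force_is_energy_gradient(self, unit_box_coarse, rng):
        mesh = unit_box_coarse
        u = 0.02 * rng.standard_normal(3 * mesh.n_nodes)
        f, _, _ = assemble(mesh, MAT, u)
        h = 1e-6
        ffd = np.zeros_like(f)
        for i in range(len(u)):
            up, um = u.copy(), u.copy()
            up[i] += h
            um[i] -= h
            ffd[i] = (
                total_strain_energy(mesh, MAT, up) - total_strain_energy(mesh, MAT, um)
            ) / (2 * h)
        assert np.abs(f - ffd).max() / np.abs(ffd).max() < 1e-5

    def test_tangent_is_symmetric_and_consistent(self, unit_box_coarse, rng):
        mesh = unit_box_coarse
        u = 0.02 * rng.standard_normal(3 * mesh.n_nodes)
        _, K, _ = assemble(mesh, MAT, u)
        Kd = K.toarray()
        assert np.abs(Kd - Kd.T).max() / np.abs(Kd).max() < 1e-12
        h = 1e-6
        for i in (2, 17, 40):
            up, um = u.copy(), u.copy()
            up[i] += h
            um[i] -= h
            col = (assemble(mesh, MAT, up)[0] - assemble(mesh, MAT, um)[0]) / (2 * h)
            assert np.abs(Kd[:, i] - col).max() / np.abs(Kd).max() < 1e-6


class TestPatchTest:
    def test_affine_displacement_gives_homogeneous_stress(self, unit_box):
        mesh = unit_box
        A = np.array([[0.02, 0.01, 0.0], [0.0, -0.015, 0.005], [0.0, 0.0, 0.01]])
        u = (mesh.nodes @ A.T).ravel()
        stresses = element_stresses(mesh, MAT, u)
        F = np.eye(3) + A
        sigma_exact = cauchy_stress(DeformationState.from_F(F), MAT)
        assert np.abs(stresses - sigma_exact).max() < 1e-12 * max(
            1.0, np.abs(sigma_exact).max() / 1e-3
        )
        # interior nodes must be in equilibrium under the affine field
        f, _, _ = assemble(mesh, MAT, u)
        boundary = set()
        for name in ("xmin", "xmax", "ymin", "ymax", "zmin", "zmax"):
            boundary.update(mesh.node_sets[name].tolist())
        interior = [n for n in range(mesh.n_nodes) if n not in boundary]
        assert interior, "patch test needs interior nodes"
        f_int = f.reshape(-1, 3)[interior]
        assert np.abs(f_int).max() < 1e-12


class TestUniaxialOracle:
    def test_prescribed_compression_matches_closed_form(self, unit_box):
        """lambda_z = 0.9 with free lateral faces: the homogeneous uncoupled
        Neo-Hookean solution (lateral stretch from sigma_xx = 0) is an
        independent oracle for the reaction force."""
        lam_z = 0.9

        def lateral_stress(lam_lat):
            F = np.diag([lam_lat, lam_lat, lam_z])
            return cauchy_stress(DeformationState.from_F(F), MAT)[0, 0]

        lam_lat = brentq(lateral_stress, 0.8, 1.5, xtol=1e-14)
        F = np.diag([lam_lat, lam_lat, lam_z])
        sigma_zz = cauchy_stress(DeformationState.from_F(F), MAT)[2, 2]
        force_exact = sigma_zz * lam_lat**2  # unit cross-section

        mesh = unit_box
        dirichlet = {}
        for n in mesh.node_sets["xmin"]:
            dirichlet[(int(n), 0)] = 0.0
        for n in mesh.node_sets["ymin"]:
            dirichlet[(int(n), 1)] = 0.0
        for n in mesh.node_sets["zmin"]:
            dirichlet[(int(n), 2)] = 0.0
        for n in mesh.node_sets["zmax"]:
            dirichlet[(int(n), 2)] = lam_z - 1.0
        u, fint, Jel = solve_prescribed(mesh, MAT, dirichlet, n_increments=4)
        force_fe = sum(fint[3 * int(n) + 2] for n in mesh.node_sets["zmax"])
        assert force_fe == pytest.approx(force_exact, rel=1e-2)
        assert np.allclose(Jel, lam_lat**2 * lam_z, rtol=1e-6)


def box_probe(total=0.2, n_inc=4, half=(0.3, 0.3)):
    return ProbeSpec(
        face_center=(0.5, 0.5, 1.0),
        face_normal=(0.0, 0.0, -1.0),
        face_half_lengths=half,
        total_displacement=total,
        n_increments=n_inc,
    )


class TestIndentation:
    def test_zero_displacement_zero_reaction(self, unit_box):
        res = solve_indentation(unit_box, MAT, box_probe(total=0.0, n_inc=1))
        assert np.allclose(res.curve.force, 0.0)
        assert max_volume_change(res) == pytest.approx(0.0, abs=1e-12)

    def test_reaction_monotone_under_monotone_advance(self, unit_box):
        res = solve_indentation(unit_box, MAT, box_probe())
        assert not res.failed
        assert np.all(np.diff(res.curve.force) > 0)
        assert np.all(np.diff(res.curve.displacement) > 0)
        assert len(res.curve) == res.converged_increments + 1

    def test_contact_force_is_purely_normal(self, unit_box):
        """Frictionless node-to-plane contact transmits no tangential load."""
        res = solve_indentation(unit_box, MAT, box_probe())
        fc = res.contact_forces[-1]
        total = fc.sum(axis=0)
        assert abs(total[0]) < 1e-12 and abs(total[1]) < 1e-12
        assert total[2] < 0  # pushes into the tissue

    def test_penalty_reaction_exactly_linear_in_c1(self, unit_box):
        """The auto-penalty scales with c1, so the whole displacement-driven
        problem is homogeneous of degree one in (C1, K)."""
        res1 = solve_indentation(unit_box, Material.coupled(0.005), box_probe())
        res2 = solve_indentation(unit_box, Material.coupled(0.010), box_probe())
        ratio = res2.curve.force[1:] / res1.curve.force[1:]
        assert np.allclose(ratio, 2.0, rtol=1e-9)

    def test_prescribed_patch_reaction_exactly_linear_in_c1(self, unit_box):
        probe = box_probe(total=0.1, n_inc=2)
        res1 = solve_indentation(
            unit_box, Material.coupled(0.005), probe, contact_mode="prescribed_patch"
        )
        res2 = solve_indentation(
            unit_box, Material.coupled(0.010), probe, contact_mode="prescribed_patch"
        )
        assert np.allclose(res2.curve.force[1:] / res1.curve.force[1:], 2.0, rtol=1e-9)

    def test_initial_penetration_rejected(self, unit_box):
        probe = ProbeSpec(
            face_center=(0.5, 0.5, 0.8),  # starts inside the cube
            face_normal=(0, 0, -1),
            face_half_lengths=(0.3, 0.3),
            total_displacement=0.1,
            n_increments=2,
        )
        with pytest.raises(ContactError):
            solve_indentation(unit_box, MAT, probe)

    def test_unsolvable_indentation_returns_flagged_partial_result(self, unit_box_coarse):
        # crushing the cube to 3x its height cannot converge
        res = solve_indentation(
            unit_box_coarse, MAT, box_probe(total=3.0, n_inc=3), min_substep_frac=0.25
        )
        assert res.failed
        assert res.converged_increments < 3
        assert len(res.curve) == res.converged_increments + 1

    def test_max_volume_change_requires_converged_increment(self, unit_box_coarse):
        res = solve_indentation(
            unit_box_coarse, MAT, box_probe(total=3.0, n_inc=1), min_substep_frac=0.5
        )
        assert res.failed and res.converged_increments == 0
        with pytest.raises(SolverError):
            max_volume_change(res)


class TestSurfaceFields:
    def test_zero_state_maps_are_zero(self, unit_box):
        res = solve_indentation(unit_box, MAT, box_probe())
        vm, pressure = surface_fields(res, 0)
        assert np.allclose(vm, 0.0) and np.allclose(pressure, 0.0)

    def test_pressure_nonnegative_and_localised(self, unit_box):
        res = solve_indentation(unit_box, MAT, box_probe())
        vm, pressure = surface_fields(res, res.n_recorded - 1)
        assert np.all(pressure >= 0.0)
        assert pressure.max() > 0.0
        skin = unit_box.node_sets["skin_surface"]
        off_skin = np.setdiff1d(np.arange(unit_box.n_nodes), skin)
        assert np.allclose(pressure[off_skin], 0.0)
        assert np.allclose(vm[off_skin], 0.0)

    def test_pressure_map_equivariant_under_mirror_rerun(self, unit_box):
        """Reflecting the mesh about x = 0.5 and rerunning the centred
        probe must reflect the contact pressure map (the tet split itself
        is chirality-breaking, so symmetry is checked by rerun, not within
        one mesh)."""
        from tissuecal import TetMesh

        res = solve_indentation(unit_box, MAT, box_probe())
        _, pressure = surface_fields(res, res.n_recorded - 1)

        nodes_m = unit_box.nodes.copy()
        nodes_m[:, 0] = 1.0 - nodes_m[:, 0]
        # swapping corners 2 and 3 restores positive orientation; mid-edge
        # nodes follow the edge relabelling of the VTK tet10 convention
        perm = [0, 1, 3, 2, 4, 8, 7, 6, 5, 9]
        mesh_m = TetMesh(
            nodes=nodes_m,
            elements=unit_box.elements[:, perm],
            node_sets=unit_box.node_sets,
        )
        mesh_m.validate()
        res_m = solve_indentation(mesh_m, MAT, box_probe())
        _, pressure_m = surface_fields(res_m, res_m.n_recorded - 1)
        assert pressure_m == pytest.approx(pressure, rel=1e-6, abs=1e-10)

    def test_tilted_probe_loads_leading_edge(self, tiny_phantom):
        """A probe face tilted about the phantom axis concentrates effective
        stress on the edge that meets the tissue first."""
        tilt = np.deg2rad(8.0)
        normal = np.array([-np.cos(tilt), -np.sin(tilt), 0.0])
        probe = ProbeSpec(
            face_center=(33.5, 0.0, 20.0),
            face_normal=normal,
            face_half_lengths=(15.0, 5.0),
            displacement_axis=(-1.0, 0.0, 0.0),
            total_displacement=3.0,
            n_increments=4,
        )
        res = solve_indentation(tiny_phantom, Material.coupled(0.005), probe)
        assert not res.failed
        vm, _ = surface_fields(res, res.n_recorded - 1)
        skin = tiny_phantom.node_sets["skin_surface"]
        y = tiny_phantom.nodes[skin, 1]
        leading = vm[skin][y > 0.5]
        trailing = vm[skin][y < -0.5]
        assert leading.max() > trailing.max()
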