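"""Micro-FE verification: lattice arithmetic, closed-form elasticity, and
the linearity that underpins load-ratio scaling of strain summaries."""

import numpy as np
import pytest

from osteoadapt.microfe import (
    LoadCase,
    apply_axial_compression,
    assign_materials,
    element_strains,
    hex_stiffness,
    reaction_forces,
    solve_linear_elasticity,
    voxel_mesh,
)
from osteoadapt.phantoms import make_tube_phantom
from osteoadapt.strainstats import strain_field_from_solution
from osteoadapt.volumes import BoneMask, segment


def _block(shape, voxel_size=10.0):
    return voxel_mesh(BoneMask(np.ones(shape, bool), voxel_size))


class TestVoxelMesh:
    def test_single_voxel(self):
        mesh = _block((1, 1, 1))
        assert mesh.n_elements == 1 and mesh.n_nodes == 8

    def test_2x2x2_conforming_nodes(self):
        mesh = _block((2, 2, 2))
        assert mesh.n_elements == 8 and mesh.n_nodes == 27

    @pytest.mark.parametrize("shape", [(3, 4, 5), (1, 6, 2)])
    def test_block_node_count_closed_form(self, shape):
        mesh = _block(shape)
        l, m, n = shape
        assert mesh.n_nodes == (l + 1) * (m + 1) * (n + 1)
        assert mesh.n_elements == l * m * n

    def test_floating_voxels_removed_and_reported(self):
        m = np.zeros((5, 5, 5), bool)
        m[0:3, 0:3, 0:3] = True
        m[4, 4, 4] = True  # disconnected floater
        with pytest.warns(UserWarning, match="floating"):
            mesh = voxel_mesh(BoneMask(m, 10.0))
        assert mesh.n_removed_voxels == 1
        assert mesh.n_elements == 27

    def test_element_volume_equals_voxel_volume(self):
        mesh = _block((2, 3, 2), voxel_size=25.0)
        e0 = mesh.elements[0]
        ext = mesh.nodes[e0].max(axis=0) - mesh.nodes[e0].min(axis=0)
        assert np.allclose(ext, mesh.h)

    def test_empty_mask_fails(self):
        with pytest.raises(ValueError):
            voxel_mesh(BoneMask(np.zeros((3, 3, 3), bool), 10.0))


class TestMaterials:
    def test_homogeneous_map(self):
        mesh = _block((2, 2, 2))
        mats = assign_materials(None, mesh, e0=17000.0, nu=0.3)
        assert np.all(mats.e == 17000.0) and mats.nu == 0.3

    def test_power_law_arithmetic_and_scaling(self):
        from osteoadapt.volumes import VoxelVolume

        mesh = _block((2, 2, 2))
        vol = VoxelVolume(np.full((2, 2, 2), 1.0, np.float32), 10.0)
        mats = assign_materials(vol, mesh, model="power_law", a=15000.0, b=2.0)
        assert np.allclose(mats.e, 15000.0)
        vol2 = VoxelVolume(np.full((2, 2, 2), 2.0, np.float32), 10.0)
        mats2 = assign_materials(vol2, mesh, model="power_law", a=15000.0, b=2.0)
        assert np.allclose(mats2.e, 4 * mats.e)  # doubling density quadruples E at b=2

    def test_nonpositive_density_clamped_and_counted(self):
        from osteoadapt.volumes import VoxelVolume

        mesh = _block((1, 1, 2))
        vol = VoxelVolume(np.array([[[0.5, -0.1]]], np.float32).reshape(1, 1, 2) * np.ones((1, 1, 1), np.float32), 10.0)
        vol = VoxelVolume(np.array([0.5, -0.1], np.float32).reshape(1, 1, 2), 10.0)
        mats = assign_materials(vol, mesh, model="power_law", e_min=1.0)
        assert mats.n_clamped == 1
        assert np.all(mats.e > 0)

    def test_invalid_poisson_rejected(self):
        mesh = _block((1, 1, 1))
        with pytest.raises(ValueError):
            assign_materials(None, mesh, nu=0.5)


class TestLoadCase:
    def test_uniform_force_per_node(self):
        mesh = _block((4, 4, 4))
        lc = apply_axial_compression(mesh, -3.5)
        fz = lc.forces[2::3]
        loaded = fz[fz != 0]
        assert len(loaded) == 25  # 5x5 proximal face nodes
        assert np.allclose(loaded, 3.5 / 25)  # compressive load pushes distally

    def test_total_force_matches_load_to_machine_precision(self):
        mesh = _block((3, 5, 4))
        for dist in ("uniform", "consistent"):
            lc = apply_axial_compression(mesh, -7.0, distribution=dist)
            assert lc.forces[2::3].sum() == pytest.approx(7.0, abs=1e-12)

    def test_fixed_and_loaded_sets_disjoint(self):
        mesh = _block((4, 3, 3))
        lc = apply_axial_compression(mesh, -5.2)
        assert np.intersect1d(lc.fixed_nodes, lc.loaded_nodes).size == 0

    def test_single_slice_structure_has_distinct_faces(self):
        # one voxel layer still has two distinct node planes along z
        mesh = _block((1, 3, 3))
        lc = apply_axial_compression(mesh, -1.0)
        assert lc.fixed_nodes.size == lc.loaded_nodes.size == 16
        assert np.intersect1d(lc.fixed_nodes, lc.loaded_nodes).size == 0


class TestSolver:
    def test_single_element_uniaxial_closed_form(self):
        mesh = _block((1, 1, 1))
        mats = assign_materials(None, mesh, e0=1000.0, nu=0.0)
        sigma = -1.0  # MPa
        lc = apply_axial_compression(mesh, sigma * mesh.h**2)
        disp = solve_linear_elasticity(mesh, mats, lc, rel_tol=1e-12)
        strains = element_strains(mesh, disp) * 1e6
        assert strains[0, 2] == pytest.approx(-1000.0, abs=1e-6)

    def test_bar_axial_strain_closed_form(self, solved_bar):
        mesh, mats = solved_bar["mesh"], solved_bar["materials"]
        field = strain_field_from_solution(mesh, solved_bar["displacement"])
        area = solved_bar["mask"].values[5].sum() * mesh.h**2
        expected = -3.5 / (area * 17000.0) * 1e6
        assert field.voigt[:, 2].mean() == pytest.approx(expected, rel=0.005)

    def test_poisson_lateral_contraction(self):
        mesh = _block((6, 4, 4))
        mats = assign_materials(None, mesh, e0=1000.0, nu=0.3)
        area = 16 * mesh.h**2
        lc = apply_axial_compression(
            mesh, -1.0 * area, distal_constraint="roller", distribution="consistent"
        )
        disp = solve_linear_elasticity(mesh, mats, lc, rel_tol=1e-10)
        s = element_strains(mesh, disp)
        ratio = s[:, 0].mean() / s[:, 2].mean()
        assert ratio == pytest.approx(-0.3, rel=0.01)

    def test_patch_test_reproduces_uniform_strain_exactly(self):
        mesh = _block((4, 4, 4), voxel_size=100.0)
        a = np.array([[1e-4, 2e-5, 0.0], [2e-5, -5e-5, 1e-5], [0.0, 1e-5, 3e-5]])
        u_exact = mesh.nodes @ a.T
        xyz = mesh.nodes
        lo, hi = xyz.min(axis=0), xyz.max(axis=0)
        on_bd = np.any(np.isclose(xyz, lo) | np.isclose(xyz, hi), axis=1)
        bd = np.flatnonzero(on_bd)
        fixed = (3 * bd[:, None] + np.arange(3)).ravel()
        lc = LoadCase(0.0, fixed, u_exact[bd].ravel(), np.zeros(3 * mesh.n_nodes))
        mats = assign_materials(None, mesh, e0=17000.0, nu=0.3)
        disp = solve_linear_elasticity(mesh, mats, lc, rel_tol=1e-12)
        assert np.abs(disp.u - u_exact).max() < 1e-12

    def test_reaction_balances_applied_load(self, solved_bar):
        r = reaction_forces(solved_bar["mesh"], solved_bar["materials"], solved_bar["displacement"])
        lc = solved_bar["loadcase"]
        # support reaction cancels the resultant of the applied nodal forces
        assert r[lc.fixed_nodes, 2].sum() == pytest.approx(lc.applied_load, abs=1e-5)

    def test_linearity_and_superposition(self):
        vol = make_tube_phantom(0.08, 0.05, 0.12, voxel_size=10.0)
        mesh = voxel_mesh(segment(vol, 0.34))
        mats = assign_materials(None, mesh, e0=17000.0, nu=0.3)
        u = {}
        for load in (-3.5, -5.2, -7.0):
            lc = apply_axial_compression(mesh, load)
            u[load] = solve_linear_elasticity(mesh, mats, lc, rel_tol=1e-11).u
        assert np.allclose(u[-7.0], 2.0 * u[-3.5], rtol=1e-6, atol=1e-12)
        # superposition: u(-3.5) + u(-5.2) ~ u at the summed load by linearity
        lc = apply_axial_compression(mesh, -8.7)
        u_sum = solve_linear_elasticity(mesh, mats, lc, rel_tol=1e-11).u
        assert np.allclose(u_sum, u[-3.5] + u[-5.2], rtol=1e-6, atol=1e-12)

    def test_rigid_body_invariance_of_strains(self):
        m = np.zeros((4, 8, 8), bool)
        m[:, 1:4, 1:4] = True
        m2 = np.roll(m, (3, 4), axis=(1, 2))  # translated copy
        strains = []
        for mask in (m, m2):
            mesh = voxel_mesh(BoneMask(mask, 10.0))
            mats = assign_materials(None, mesh, e0=1000.0, nu=0.3)
            lc = apply_axial_compression(mesh, -2.0)
            disp = solve_linear_elasticity(mesh, mats, lc, rel_tol=1e-11)
            strains.append(element_strains(mesh, disp))
        assert np.allclose(strains[0], strains[1], rtol=1e-8, atol=1e-14)

    def test_mesh_convergence_on_hollow_tube(self):
        errs = []
        for vs in (40.0, 20.0, 10.0):
            vol = make_tube_phantom(0.24, 0.14, 0.12, voxel_size=vs)
            mask = segment(vol, 0.34)
            mesh = voxel_mesh(mask)
            mats = assign_materials(None, mesh, e0=17000.0, nu=0.0)
            lc = apply_axial_compression(mesh, -3.5)
            disp = solve_linear_elasticity(mesh, mats, lc, rel_tol=1e-10)
            s = element_strains(mesh, disp)
            area = np.pi * (0.24**2 - 0.14**2)
            expected = -3.5 / (area * 17000.0)
            errs.append(abs(s[:, 2].mean() / expected - 1))
        assert errs[0] > errs[1] > errs[2]

    def test_determinism(self):
        mesh = _block((3, 3, 3))
        mats = assign_materials(None, mesh, e0=1000.0, nu=0.3)
        lc = apply_axial_compression(mesh, -1.0)
        u1 = solve_linear_elasticity(mesh, mats, lc).u
        u2 = solve_linear_elasticity(mesh, mats, lc).u
        assert np.array_equal(u1, u2)

    def test_nonconvergence_raises(self):
        mesh = _block((4, 4, 4))
        mats = assign_materials(None, mesh, e0=1000.0, nu=0.3)
        lc = apply_axial_compression(mesh, -1.0)
        with pytest.raises(RuntimeError, match="residual"):
            solve_linear_elasticity(mesh, mats, lc, rel_tol=1e-14, max_iter=2)


def test_hex_stiffness_is_symmetric_positive_semidefinite():
    k = hex_stiffness(17000.0, 0.3, 0.01)
    assert np.allclose(k, k.T, atol=1e-9)
    w = np.linalg.eigvalsh(k)
    assert w[0] > -1e-6 * w[-1]
    # exactly six rigid-body modes
    assert (np.abs(w) < 1e-6 * w[-1]).sum() == 6
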