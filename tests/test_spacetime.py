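"""Space-time solver: element matrices, assembly, stepping, conservation."""

import numpy as np
import pytest

import softimpact as si
from softimpact.spacetime import (
    PicardError,
    SolverConfig,
    SolverState,
    Stepper,
    element_matrices,
    incompressibility_residual,
    kinetic_energy,
    total_momentum,
)

REF_TET = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]]) * 0.05


class TestElementMatrices:
    def test_mass_block_matches_symbolic_spacetime_integral(self):
        """Inertia block vs exact symbolic integration of the slab integral.

        The test functions carry the end-of-slab time shape tau, the trial
        velocity is linear in time, so the block multiplying the unknown end
        values is rho * int_V N_a N_b dV * int_0^h tau * (1/h) dt.  Both
        integrals are evaluated with sympy, independently of the solver.
        """
        import sympy as sp

        x, y, z, t = sp.symbols("x y z t")
        h = sp.Rational(1, 100)
        N = [1 - x - y - z, x, y, z]
        rho = 1040
        scale = sp.Rational(5, 100)  # edge length of REF_TET

        mat = si.ViscoplasticMaterial(K_viscosity=20.0, m_sensitivity=-0.5, rho=float(rho))
        _, Me, _, _ = element_matrices(REF_TET, mat, float(h))

        tau = t / h
        time_factor = sp.integrate(tau * (1 / h), (t, 0, h))
        for (a, b) in [(0, 0), (0, 1), (2, 3)]:
            spatial = sp.integrate(
                sp.integrate(sp.integrate(N[a] * N[b], (z, 0, 1 - x - y)),
                             (y, 0, 1 - x)), (x, 0, 1))
            exact = float(rho * spatial * scale**3 * time_factor)
            for comp in range(3):
                assert Me[3 * a + comp, 3 * b + comp] == pytest.approx(exact, rel=1e-12)
            assert Me[3 * a, 3 * b + 1] == 0.0

    def test_rigid_translation_annihilated(self):
        """K applied to a uniform nodal velocity gives (near) zero forces."""
        mat = si.ViscoplasticMaterial(K_viscosity=20.0, m_sensitivity=-0.5)
        Ke, _, _, _ = element_matrices(REF_TET, mat, 1e-4)
        v = np.tile([1.0, -2.0, 0.5], 4)
        out = Ke @ v
        assert np.abs(out).max() < 1e-8 * np.abs(Ke).max()

    def test_zero_velocity_state_regularised_and_finite(self):
        mat = si.ViscoplasticMaterial(K_viscosity=20.0, m_sensitivity=-0.5)
        Ke, Me, Ze, Fe = element_matrices(REF_TET, mat, 1e-4)
        for A in (Ke, Me, Ze, Fe):
            assert np.all(np.isfinite(A))
        assert np.abs(Ke).max() > 0  # floor viscosity, not zero

    def test_damping_block_scales_with_c(self):
        m0 = si.ViscoplasticMaterial(K_viscosity=20.0, m_sensitivity=-0.5, c_damping=0.0)
        m1 = si.ViscoplasticMaterial(K_viscosity=20.0, m_sensitivity=-0.5, c_damping=12.0)
        _, _, Z0, _ = element_matrices(REF_TET, m0, 1e-4)
        _, _, Z1, _ = element_matrices(REF_TET, m1, 1e-4)
        assert np.allclose(Z0, 0)
        assert np.abs(Z1).max() > 0

    def test_degenerate_element_rejected(self):
        flat = REF_TET.copy()
        flat[3] = flat[0]
        mat = si.ViscoplasticMaterial(K_viscosity=20.0, m_sensitivity=-0.5)
        with pytest.raises((RuntimeError, ValueError),
                           match="degenerate|inverted|volume"):
            element_matrices(flat, mat, 1e-4)


class TestAssembly:
    def test_single_element_mesh_equals_element_matrices(self):
        mesh = si.Mesh(REF_TET, np.arange(4).reshape(1, 4),
                       {"measurement_point": np.array([0])})
        mat = si.ViscoplasticMaterial(K_viscosity=20.0, m_sensitivity=-0.5, c_damping=12.0)
        st = SolverState.initial(mesh)
        sysm = si.assemble(mesh, {1: mat}, st, 1e-4)
        Ke, Me, Ze, Fe = element_matrices(REF_TET, mat, 1e-4)
        assert np.allclose(sysm.K_stiffness.toarray(), Ke)
        assert np.allclose(sysm.M_inertia.toarray(), Me)
        assert np.allclose(sysm.Z_damping.toarray(), Ze)
        assert np.allclose(sysm.F_load, Fe)

    def test_permutation_equivariance(self, tiny_bar):
        """Renumbering the nodes permutes the assembled operators."""
        mat = si.ViscoplasticMaterial(K_viscosity=20.0, m_sensitivity=-0.5, c_damping=5.0)
        rng = np.random.default_rng(0)
        perm = rng.permutation(tiny_bar.n_nodes)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        permuted = si.Mesh(
            tiny_bar.nodes[perm],
            inv[tiny_bar.tets],
            {k: inv[v] for k, v in tiny_bar.node_sets.items()},
            tiny_bar.element_tags,
        )
        A = si.assemble(tiny_bar, {1: mat}, SolverState.initial(tiny_bar), 1e-4)
        B = si.assemble(permuted, {1: mat}, SolverState.initial(permuted), 1e-4)
        # original dof (node i, comp c) lives at permuted dof (3*inv[i] + c)
        p = (3 * inv[:, None] + np.arange(3)).ravel()
        sel = np.ix_(p, p)
        assert np.allclose(B.M_inertia.toarray()[sel], A.M_inertia.toarray())
        assert np.allclose(B.K_stiffness.toarray()[sel], A.K_stiffness.toarray())

    def test_zero_damping_gives_zero_Z(self, tiny_bar):
        mat = si.ViscoplasticMaterial(K_viscosity=20.0, m_sensitivity=-0.5, c_damping=0.0)
        sysm = si.assemble(tiny_bar, {1: mat}, SolverState.initial(tiny_bar), 1e-4)
        assert sysm.Z_damping.nnz == 0 or np.abs(sysm.Z_damping.data).max() == 0

    def test_missing_material_tag_rejected(self, tiny_bar):
        with pytest.raises(ValueError, match="tag"):
            Stepper(tiny_bar, {7: si.ViscoplasticMaterial(K_viscosity=1, m_sensitivity=0.5)})


class TestStepping:
    def test_equilibrium_is_fixed_point(self, tiny_bar):
        """Zero force, zero velocity: state unchanged except time."""
        mat = si.ViscoplasticMaterial(K_viscosity=20.0, m_sensitivity=-0.5, c_damping=12.0)
        st = SolverState.initial(tiny_bar)
        new = si.step(st, tiny_bar, {1: mat}, 1e-4)
        assert np.array_equal(new.v, st.v)
        assert np.array_equal(new.u, st.u)
        assert new.t == pytest.approx(1e-4)

    def test_force_free_flight_preserves_velocity_exactly(self, tiny_bar):
        mat = si.ViscoplasticMaterial(K_viscosity=20.0, m_sensitivity=-0.5, c_damping=0.0)
        v0 = np.tile([-7.5, 0.0, 0.0], tiny_bar.n_nodes)
        st = SolverState.initial(tiny_bar, v0)
        stp = Stepper(tiny_bar, {1: mat})
        for _ in range(20):
            st = stp.step(st, 1e-4)
        assert np.array_equal(st.v, v0)
        # displacement grows linearly: u = v0 * t
        assert st.u[0] == pytest.approx(-7.5 * 20e-4, rel=1e-12)

    def test_momentum_conservation_force_free(self, bar_mesh):
        mats = {1: si.ViscoplasticMaterial(K_viscosity=20.0, m_sensitivity=-0.5,
                                           c_damping=0.0)}
        rng = np.random.default_rng(3)
        v0 = np.tile([-7.5, 0, 0], bar_mesh.n_nodes) + 0.1 * rng.normal(
            size=3 * bar_mesh.n_nodes)
        st = SolverState.initial(bar_mesh, v0)
        p0 = total_momentum(st, bar_mesh, mats, current_geometry=False)
        stp = Stepper(bar_mesh, mats)
        for _ in range(30):
            st = stp.step(st, 5e-5)
        p1 = total_momentum(st, bar_mesh, mats, current_geometry=False)
        assert np.linalg.norm(p1 - p0) / np.linalg.norm(p0) < 1e-10

    def test_kinetic_energy_nonincreasing_force_free(self, tiny_bar):
        """Viscous dissipation only: KE decays monotonically (fixed geometry)."""
        mats = {1: si.ViscoplasticMaterial(K_viscosity=20.0, m_sensitivity=-0.5)}
        v0 = np.zeros((tiny_bar.n_nodes, 3))
        v0[:, 0] = -1.0 - 5.0 * tiny_bar.nodes[:, 0]
        st = SolverState.initial(tiny_bar, v0.ravel())
        stp = Stepper(tiny_bar, mats, SolverConfig(update_geometry=False))
        ke = [kinetic_energy(st, tiny_bar, mats, current_geometry=False)]
        for _ in range(40):
            st = stp.step(st, 1e-4)
            ke.append(kinetic_energy(st, tiny_bar, mats, current_geometry=False))
        assert np.all(np.diff(ke) <= 1e-12 * ke[0])

    def test_bit_identical_trajectories(self, tiny_bar):
        mats = {1: si.ViscoplasticMaterial(K_viscosity=20.0, m_sensitivity=-0.5,
                                           c_damping=12.0)}
        v0 = np.zeros((tiny_bar.n_nodes, 3))
        v0[:, 0] = -1.0 - 5.0 * tiny_bar.nodes[:, 0]

        def run():
            st = SolverState.initial(tiny_bar, v0.ravel())
            stp = Stepper(tiny_bar, mats)
            for _ in range(10):
                st = stp.step(st, 1e-4)
            return st.v

        assert np.array_equal(run(), run())

    def test_picard_failure_carries_history(self, tiny_bar):
        mats = {1: si.ViscoplasticMaterial(K_viscosity=20.0, m_sensitivity=-0.5)}
        v0 = np.zeros((tiny_bar.n_nodes, 3))
        v0[:, 0] = -1.0 - 50.0 * tiny_bar.nodes[:, 0]
        st = SolverState.initial(tiny_bar, v0.ravel())
        stp = Stepper(tiny_bar, mats,
                      SolverConfig(picard_tol=1e-15, picard_max_iter=2))
        with pytest.raises(PicardError) as err:
            stp.step(st, 1e-4)
        assert len(err.value.history) == 2

    def test_updated_geometry_moves_coordinates(self, tiny_bar):
        mats = {1: si.ViscoplasticMaterial(K_viscosity=20.0, m_sensitivity=-0.5)}
        v0 = np.tile([-1.0, 0, 0], tiny_bar.n_nodes)
        st = SolverState.initial(tiny_bar, v0)
        stp = Stepper(tiny_bar, mats, SolverConfig(update_geometry=True))
        st = stp.step(st, 1e-3)
        assert np.allclose(st.coords[:, 0], tiny_bar.nodes[:, 0] - 1e-3)


class TestIncompressibility:
    def test_rigid_translation_zero_residual(self, tiny_bar):
        st = SolverState.initial(tiny_bar, np.tile([3.0, -1.0, 2.0], tiny_bar.n_nodes))
        assert incompressibility_residual(st, tiny_bar) == 0.0

    def test_uniform_expansion_closed_form(self, tiny_bar):
        """v = x gives div v = 3 everywhere, residual 3*sqrt(V_total)."""
        st = SolverState.initial(tiny_bar, tiny_bar.nodes.ravel())
        expected = 3.0 * np.sqrt(tiny_bar.total_volume())
        assert incompressibility_residual(st, tiny_bar) == pytest.approx(expected, rel=1e-12)

    def test_residual_restricted_to_viscoplastic_subdomain(self, tiny_bar):
        mats = {1: si.ViscoelasticMaterial(E_modulus=1e6)}
        st = SolverState.initial(tiny_bar, tiny_bar.nodes.ravel())
        assert incompressibility_residual(st, tiny_bar, mats) == 0.0

    def test_penalty_monotonicity_on_impact_step(self, bar_mesh):
        """Converged impact steps: residual strictly decreases with lambda."""
        scen = si.ImpactScenario.head_on(bar_mesh, duration=4e-4, h=2e-5)
        res = []
        for lam in [1e3, 1e4, 1e5]:
            mat = si.ViscoplasticMaterial(K_viscosity=20.0, m_sensitivity=-0.5,
                                          c_damping=12.0, lambda_penalty=lam)
            out = si.run_impact(bar_mesh, {1: mat}, scen)
            res.append(incompressibility_residual(out.final_state, bar_mesh, {1: mat}))
        assert res[0] > res[1] > res[2]


class TestClassicalComparator:
    def test_spacetime_matches_backward_euler_on_elastic_bar(self, elastic_material):
        """Short sanity check; the converged-order study lives in acceptance."""
        from softimpact.classical import backward_euler_elastic

        mesh = si.generate_bar_mesh(0.1, 0.025, 0.025, (8, 1, 1))
        fixed = (3 * mesh.node_sets["contact_candidates"][:, None] + np.arange(3)).ravel()
        far = np.flatnonzero(np.isclose(mesh.nodes[:, 0], 0.1))
        fvec = np.zeros(3 * mesh.n_nodes)
        fvec[3 * far] = 50.0
        h, n = 5e-6, 200
        T_pulse = 5e-4  # smooth ramp keeps unresolved high modes quiet

        def pulse(t):
            return fvec * (np.sin(np.pi * min(t, T_pulse) / T_pulse) ** 2
                           if t < T_pulse else 0.0)

        t, hist = backward_euler_elastic(mesh, elastic_material, h, n,
                                         f_ext=pulse, fixed_dofs=fixed)
        stp = Stepper(mesh, {1: elastic_material})
        st = SolverState.initial(mesh)
        out = [0.0]
        for i in range(n):
            st = stp.step(st, h, external_force=pulse((i + 1) * h), fixed_dofs=fixed)
            out.append(st.v[3 * mesh.measurement_node()])
        ref = hist[:, 3 * mesh.measurement_node()]
        err = np.linalg.norm(np.array(out) - ref) / np.linalg.norm(ref)
        assert err < 0.10


class TestCheckpoint:
    def test_state_roundtrip(self, tmp_path, tiny_bar):
        from softimpact.spacetime import load_state, save_state

        mats = {1: si.ViscoplasticMaterial(K_viscosity=20.0, m_sensitivity=-0.5)}
        v0 = np.zeros((tiny_bar.n_nodes, 3))
        v0[:, 0] = -1.0 - 5.0 * tiny_bar.nodes[:, 0]
        st = SolverState.initial(tiny_bar, v0.ravel())
        stp = Stepper(tiny_bar, mats)
        st = stp.step(st, 1e-4)
        path = tmp_path / "checkpoint.npz"
        save_state(st, path)
        back = load_state(path)
        assert back.t == st.t
        assert np.array_equal(back.v, st.v)
        assert np.array_equal(back.elastic_strain, st.elastic_strain)
        # resuming from the checkpoint reproduces the trajectory exactly
        a = stp.step(st, 1e-4).v
        b = Stepper(tiny_bar, mats).step(back, 1e-4).v
        assert np.array_equal(a, b)
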