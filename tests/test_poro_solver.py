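"""Consolidation-solver tests: Terzaghi oracle, limits, conservation."""

import numpy as np
import pytest

from brainshift.constitutive import (
    D_from_nu,
    FluidPhase,
    MaterialCard,
    OgdenParams,
    PronySeries,
)
from brainshift.poro_solver import (
    ColumnMesh,
    DrainageBC,
    Phase,
    buoyant_body_force,
    consolidation_coefficient,
    constrained_modulus,
    solve_consolidation,
    terzaghi_pressure,
)

OGDEN = OgdenParams(mu0=794.36, alpha=-2.8, D=D_from_nu(794.36, 0.35))


def fast_card(k=1e-6):
    """Gel skeleton with an artificially permeable fluid phase so that
    consolidation completes within seconds of simulated time."""
    return MaterialCard(name="PHE", ogden=OGDEN, prony=PronySeries(),
                        fluid=FluidPhase(k=k, gamma_w=9779.0))


class TestMeshAndBCs:
    def test_mesh_validation(self):
        with pytest.raises(ValueError):
            ColumnMesh(z=[0.0, 1.0])          # too few nodes
        with pytest.raises(ValueError):
            ColumnMesh(z=[0.0, 2.0, 1.0])     # non-increasing
        with pytest.raises(ValueError):
            ColumnMesh.uniform(5, 1.0, "sideways")

    def test_drained_index_from_fluid_level(self):
        mesh = ColumnMesh.uniform(5, 1.0)
        bc = DrainageBC(top_draining=True, fluid_level=0.6)
        np.testing.assert_array_equal(bc.drained_index(mesh), [3, 4])
        assert len(DrainageBC().drained_index(mesh)) == 0


class TestBuoyantBodyForce:
    def test_neutral_buoyancy(self):
        assert buoyant_body_force(0.5, 1.0, 1000.0, 1000.0) == 0.0

    def test_submerged_value(self):
        w = buoyant_body_force(0.5, 1.0, 1015.0, 1000.0, 9.812)
        assert w == pytest.approx(147.18, abs=0.01)

    def test_emerged_value(self):
        w = buoyant_body_force(1.5, 1.0, 1015.0, 1000.0, 9.812)
        assert w == pytest.approx(9959.18, abs=0.01)


class TestConstrainedModulus:
    def test_linear_limit(self):
        # K + 4 mu0 / 3 with K = 2/D
        expected = 2.0 / OGDEN.D + 4.0 * OGDEN.mu0 / 3.0
        assert constrained_modulus(OGDEN) == pytest.approx(expected, rel=1e-6)


def _fd_consolidation(z, t_end, c_v, p0, n_steps=4000):
    """Implicit finite-difference solve of p_t = c_v p_zz — brute-force
    oracle for the Terzaghi series (drained top, sealed base)."""
    n = len(z)
    h = z[1] - z[0]
    dt = t_end / n_steps
    r = c_v * dt / h**2
    A = np.zeros((n, n))
    for i in range(1, n - 1):
        A[i, i - 1] = -r
        A[i, i] = 1 + 2 * r
        A[i, i + 1] = -r
    A[0, 0] = 1 + 2 * r          # ghost-node reflection at the sealed base
    A[0, 1] = -2 * r
    A[-1, -1] = 1.0              # drained
    p = np.full(n, p0)
    p[-1] = 0.0
    for _ in range(n_steps):
        rhs = p.copy()
        rhs[-1] = 0.0
        p = np.linalg.solve(A, rhs)
    return p


class TestTerzaghiSeries:
    def test_initial_condition(self):
        assert terzaghi_pressure(0.0, 0.0, 1e-6, 1.0, 100.0) == 100.0
        assert terzaghi_pressure(1.0, 0.0, 1e-6, 1.0, 100.0) == 0.0

    def test_long_time_decay(self):
        assert terzaghi_pressure(0.0, 1e9, 1e-4, 1.0, 100.0) == pytest.approx(
            0.0, abs=1e-6)

    def test_matches_finite_difference_oracle(self):
        # dimensionless time 0.2, mid-height: series vs fine-grid FD
        H, cv, p0 = 1.0, 1e-3, 100.0
        t = 0.2 * H**2 / cv
        z = np.linspace(0, H, 201)
        p_fd = _fd_consolidation(z, t, cv, p0)
        p_series = terzaghi_pressure(z, t, cv, H, p0)
        assert np.max(np.abs(p_fd - p_series)) / p0 < 0.005


class TestCoupledSolver:
    def test_oedometer_matches_terzaghi(self):
        # light version of the oracle-equivalence criterion (50 nodes)
        card = fast_card()
        cv = consolidation_coefficient(card)
        H = 0.02
        n = 50
        mesh = ColumnMesh.uniform(n, H)
        q = 0.5
        t_end = 0.3 * H**2 / cv
        ph = Phase(duration=t_end, dt=t_end / 300,
                   bc=DrainageBC(drained_nodes=(n - 1,)),
                   surface_load=-q, gravity=0.0)
        res = solve_consolidation(mesh, card, [ph], p_init=q)
        for T in (0.1, 0.3):
            t = T * H**2 / cv
            st = min(res.states, key=lambda s: abs(s.t - t))
            ana = terzaghi_pressure(mesh.z, st.t, cv, H, q)
            assert np.max(np.abs(st.p - ana)) / q < 0.01

    def test_undrained_limit(self):
        # k scaled to ~zero: the pore fluid carries the applied load and
        # the skeleton does not deform (oedometer, incompressible fluid)
        card = fast_card(k=1e-15)
        n = 51
        mesh = ColumnMesh.uniform(n, 0.02)
        q = 2.0
        ph = Phase(duration=10.0, dt=1.0,
                   bc=DrainageBC(drained_nodes=(n - 1,)),
                   surface_load=-q, gravity=0.0)
        res = solve_consolidation(mesh, card, [ph])
        assert np.max(np.abs(res.final.u)) < 1e-9 * 0.02
        # element-mean pressure carries the load (the nodal field next to
        # the drained face carries the equal-order checkerboard mode)
        p_elem = 0.5 * (res.final.p[:-1] + res.final.p[1:])
        assert np.median(p_elem) == pytest.approx(q, rel=1e-6)

    def test_steady_state_is_drained_elastic(self):
        card = fast_card(k=1e-4)
        n = 31
        mesh = ColumnMesh.uniform(n, 0.02)
        q = 1.0
        ph = Phase(duration=2000.0, dt=20.0,
                   bc=DrainageBC(drained_nodes=(n - 1,)),
                   surface_load=-q, gravity=0.0)
        res = solve_consolidation(mesh, card, [ph], p_init=q)
        M = constrained_modulus(card.ogden)
        assert np.max(np.abs(res.final.p)) < 1e-6 * q
        assert res.final.u[-1] == pytest.approx(-q * 0.02 / M, rel=5e-3)

    def test_fluid_mass_conservation(self):
        # cumulative drained outflow equals the column volume change
        card = fast_card()
        n = 40
        mesh = ColumnMesh.uniform(n, 0.02)
        cv = consolidation_coefficient(card)
        t_end = 0.4 * 0.02**2 / cv
        ph = Phase(duration=t_end, dt=t_end / 200,
                   bc=DrainageBC(drained_nodes=(n - 1,)),
                   surface_load=-1.0, gravity=0.0)
        res = solve_consolidation(mesh, card, [ph], p_init=1.0)
        assert res.cumulative_outflow == pytest.approx(
            -res.volume_change, rel=1e-3)
        assert res.cumulative_outflow > 0

    def test_refinement_convergence(self):
        # halving dt and element size changes the final settlement < 0.5%
        card = fast_card()
        cv = consolidation_coefficient(card)
        H = 0.02
        t_end = 0.5 * H**2 / cv
        out = []
        for n, steps in ((31, 150), (61, 300)):
            mesh = ColumnMesh.uniform(n, H)
            ph = Phase(duration=t_end, dt=t_end / steps,
                       bc=DrainageBC(drained_nodes=(n - 1,)),
                       surface_load=-1.0, gravity=0.0)
            res = solve_consolidation(mesh, card, [ph], p_init=1.0)
            out.append(res.final.u[-1])
        assert abs(out[1] - out[0]) / abs(out[1]) < 0.005

    def test_phe_rate_invariance_after_equilibration(self):
        # without a Prony series, rate effects come only from Darcy flow:
        # ramping the load 10x slower leaves the consolidated state alone
        card = fast_card(k=1e-5)
        n = 31
        mesh = ColumnMesh.uniform(n, 0.02)
        bc = DrainageBC(drained_nodes=(n - 1,))
        finals = []
        for ramp_time in (5.0, 50.0):
            phases = [
                Phase(duration=ramp_time, dt=ramp_time / 20, bc=bc,
                      surface_load=-1.0, gravity=0.0, ramp=True),
                Phase(duration=3000.0, dt=30.0, bc=bc,
                      surface_load=-1.0, gravity=0.0),
            ]
            res = solve_consolidation(mesh, card, phases)
            finals.append(res.final.u[-1])
        assert finals[0] == pytest.approx(finals[1], rel=1e-4)

    def test_gravity_self_weight_small_strain(self):
        # uniform self weight, linear regime: u(top) = -w H^2 / (2 M)
        card = fast_card(k=1e-4)
        n = 41
        H = 0.02
        mesh = ColumnMesh.uniform(n, H)
        ph = Phase(duration=5000.0, dt=50.0,
                   bc=DrainageBC(drained_nodes=(n - 1,)),
                   gravity=1.0, fluid_level=np.inf)
        res = solve_consolidation(mesh, card, [ph])
        w = buoyant_body_force(0.0, np.inf, card.rho_solid,
                               card.fluid.rho_w)   # submerged everywhere
        M = constrained_modulus(card.ogden)
        assert res.final.u[-1] == pytest.approx(-w * H**2 / (2 * M), rel=2e-3)
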