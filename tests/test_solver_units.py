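"""Pointwise solver operations and the closure constants."""

import numpy as np
import pytest

from tracheoflow.geometry import straight_profile
from tracheoflow.meshgen import MeshParams, build_mesh
from tracheoflow.solver import (
    BoundaryConditions,
    ClosureCoefficients,
    FlowState,
    FluidProperties,
    SolverSettings,
    eddy_viscosity,
    residual,
    reynolds_number,
    reynolds_stress,
    solve,
)


def _small_mesh():
    return build_mesh(
        straight_profile(0.02, 0.003),
        MeshParams(n_axial=12, n_radial=8, first_layer_height=2e-4,
                   growth_ratio=1.1, n_bl_layers=1),
    )


def _state(mesh, u=0.0, v=0.0, p=0.0, k=0.0, omega=1.0, mu_t=0.0):
    ni, nj = mesh.ni, mesh.nj
    full = lambda val: np.full((ni, nj), float(val))
    return FlowState(
        mesh=mesh, u=full(u), v=full(v), p=full(p), k=full(k),
        omega=full(omega), mu_t=full(mu_t),
        Few=np.zeros((ni + 1, nj)), Fns=np.zeros((ni, nj + 1)),
    )


class TestEddyViscosity:
    def test_zero_k(self):
        assert eddy_viscosity(1.161, 0.0, 100.0) == 0.0

    def test_hand_value(self):
        assert eddy_viscosity(1.161, 0.01, 100.0) == pytest.approx(1.161e-4)

    def test_linearity_in_k(self):
        assert eddy_viscosity(1.2, 0.02, 50.0) == pytest.approx(
            2 * eddy_viscosity(1.2, 0.01, 50.0)
        )

    def test_nonpositive_omega_rejected(self):
        with pytest.raises(ValueError):
            eddy_viscosity(1.161, 0.01, 0.0)


class TestReynoldsNumber:
    def test_zero_velocity(self):
        assert reynolds_number(FluidProperties(), 0.0, 0.003) == 0.0

    def test_three_lpm_through_3mm(self):
        # U = 4 Q / (pi D^2) with Q = 3 L/min, D = 3 mm
        Q, D = 3 / 60000, 0.003
        U = 4 * Q / (np.pi * D**2)
        assert reynolds_number(FluidProperties(), U, D) == pytest.approx(
            1.32e3, rel=0.005
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            reynolds_number(FluidProperties(), -1.0, 0.003)


class TestClosureCoefficients:
    def test_exact_rationals(self):
        c = ClosureCoefficients()
        assert (c.alpha, c.beta, c.beta_star, c.sigma, c.sigma_star) == (
            5 / 9, 3 / 40, 9 / 100, 1 / 2, 1 / 2
        )


class TestReynoldsStress:
    def test_uniform_flow_isotropic_part_only(self):
        mesh = _small_mesh()
        st = _state(mesh, u=2.0, k=0.01, mu_t=1e-4)
        tau = reynolds_stress(st)
        rho = st.fluid.rho
        interior = (slice(2, -2), slice(1, mesh.nj - 2))  # away from wall BC
        iso = -(2 / 3) * rho * 0.01
        assert np.allclose(tau["xx"][interior], iso, rtol=1e-9)
        assert np.allclose(tau["rr"][interior], iso, rtol=1e-9)
        assert np.allclose(tau["xr"][interior], 0.0, atol=1e-12)

    def test_pure_shear(self):
        mesh = _small_mesh()
        gamma, mu_t = 100.0, 2e-4
        st = _state(mesh, k=0.0, mu_t=mu_t)
        st.u = gamma * mesh.rc.copy()
        tau = reynolds_stress(st)
        interior = (slice(2, -2), slice(1, mesh.nj - 2))
        assert np.allclose(tau["xr"][interior], mu_t * gamma, rtol=1e-6)


class TestResidualMonitor:
    def test_identical_states_zero(self):
        mesh = _small_mesh()
        a = _state(mesh, u=1.0, p=5.0)
        b = _state(mesh, u=1.0, p=5.0)
        assert all(v == 0.0 for v in residual(a, b).values())

    def test_scaled_field(self):
        mesh = _small_mesh()
        a = _state(mesh, u=1.0)
        b = _state(mesh, u=1.0 + 1e-4)
        assert residual(a, b)["u"] == pytest.approx(1e-4 / (1 + 1e-4), rel=1e-6)

    def test_convexity_toward_prev(self):
        mesh = _small_mesh()
        a = _state(mesh, u=1.0)
        b = _state(mesh, u=2.0)
        mid = _state(mesh, u=1.5)
        assert residual(a, mid)["u"] < residual(a, b)["u"]

    def test_mismatched_meshes_rejected(self):
        a = _state(_small_mesh())
        other = build_mesh(
            straight_profile(0.02, 0.003),
            MeshParams(n_axial=6, n_radial=6, first_layer_height=2e-4,
                       growth_ratio=1.1, n_bl_layers=1),
        )
        with pytest.raises(ValueError):
            residual(a, _state(other))


def test_zero_inflow_gives_rest_state():
    mesh = _small_mesh()
    st = solve(mesh, BoundaryConditions(inlet_flow_lpm=0.0), FluidProperties(),
               SolverSettings(laminar_mode=True))
    assert st.converged
    assert np.all(st.u == 0) and np.all(st.v == 0)
    assert np.ptp(st.p) == 0.0


def test_settings_validation():
    with pytest.raises(ValueError):
        SolverSettings(convergence_tol=0.0)
    with pytest.raises(ValueError):
        SolverSettings(relax_u=1.5)
    with pytest.raises(ValueError):
        BoundaryConditions(inlet_flow_lpm=-1.0)
    with pytest.raises(ValueError):
        BoundaryConditions(outlet_pressure=5.0)
    with pytest.raises(ValueError):
        FluidProperties(rho=-1.0)
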