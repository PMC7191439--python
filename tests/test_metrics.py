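"""Aerodynamic read-outs: WSS, pressure drop, energy bookkeeping."""

import numpy as np
import pytest
from scipy.integrate import trapezoid

from tracheoflow.geometry import straight_profile
from tracheoflow.meshgen import MeshParams, build_mesh
from tracheoflow.metrics import (
    MetricsReport,
    energy_flux,
    energy_loss_rate,
    evaluate_case,
    pressure_drop,
    wall_shear_stress,
)
from tracheoflow.solver import (
    BoundaryConditions,
    FluidProperties,
    SolverSettings,
    solve,
)

MU, RHO = 1.864e-5, 1.161


@pytest.fixture(scope="module")
def rest_state():
    mesh = build_mesh(
        straight_profile(0.02, 0.003),
        MeshParams(n_axial=12, n_radial=8, first_layer_height=2e-4,
                   growth_ratio=1.1, n_bl_layers=1),
    )
    return solve(mesh, BoundaryConditions(inlet_flow_lpm=0.0),
                 FluidProperties(), SolverSettings(laminar_mode=True))


class TestEnergyLossRate:
    def test_lossless(self):
        assert energy_loss_rate(1.0, 1.0) == 0.0

    def test_hand_value(self):
        assert energy_loss_rate(1.000, 0.851) == pytest.approx(0.149)

    def test_nonpositive_inlet_rejected(self):
        with pytest.raises(ValueError):
            energy_loss_rate(0.0, 0.0)


class TestZeroFlow:
    def test_wss_zero(self, rest_state):
        assert np.all(wall_shear_stress(rest_state) == 0.0)

    def test_pressure_drop_zero(self, rest_state):
        assert pressure_drop(rest_state, s_up=0.005, s_down=0.015) == 0.0

    def test_energy_flux_zero(self, rest_state):
        assert energy_flux(rest_state, s=0.01) == 0.0


class TestStations:
    def test_outside_anatomy_rejected(self, rest_state):
        with pytest.raises(ValueError, match="anatomical"):
            pressure_drop(rest_state, s_up=-0.01, s_down=0.01)

    def test_reversed_stations_rejected(self, rest_state):
        with pytest.raises(ValueError):
            pressure_drop(rest_state, s_up=0.015, s_down=0.005)


class TestPoiseuilleOracles:
    def test_wall_shear_analytic(self, poiseuille_study):
        """Developed laminar WSS = 8 mu U / D within 3%."""
        res = poiseuille_study["results"][-1]
        wss = wall_shear_stress(res.state)
        U = (1 / 60000) / (np.pi * 0.0015**2)
        exact = 8 * MU * U / 0.003          # 0.117 Pa
        mid = len(wss) // 2
        assert wss[mid] == pytest.approx(exact, rel=0.03)

    def test_laminar_dp_analytic(self, poiseuille_study):
        res = poiseuille_study["results"][-1]
        dp = pressure_drop(res.state, s_up=0.01, s_down=0.09) * (0.1 / 0.08)
        assert dp == pytest.approx(15.63, rel=0.02)

    def test_energy_flux_against_quadrature_oracle(self, poiseuille_study):
        """Face-flux energy integral vs an independent trapezoid rule."""
        res = poiseuille_study["results"][-1]
        mesh, st = res.state.mesh, res.state
        i = mesh.ni // 2
        s = mesh.xn[i]
        E = energy_flux(st, s=s)
        # trapezoid oracle on cell-center profiles at the two adjacent columns
        r = mesh.rc[i, :]
        u = 0.5 * (st.u[i - 1, :] + st.u[i, :])
        p = 0.5 * (st.p[i - 1, :] + st.p[i, :])
        integrand = (p + 0.5 * RHO * u**2) * u * 2 * np.pi * r
        oracle = trapezoid(integrand, r)
        assert E == pytest.approx(oracle, rel=0.02)

    def test_energy_loss_equals_total_pressure_drop_times_flow(
            self, poiseuille_study):
        """Single-outlet duct: EL = dP_total * Q up to discretization."""
        res = poiseuille_study["results"][-1]
        Q = 1 / 60000
        E_in = energy_flux(res.state, s=0.0)
        E_out = energy_flux(res.state, s=0.1)
        dp_tot = pressure_drop(res.state, s_up=0.0, s_down=0.1, total=True)
        assert (E_in - E_out) == pytest.approx(dp_tot * Q, rel=0.02)


def test_plug_flow_energy_flux_identity():
    """Uniform u = U, p = P over area A gives E = (P + rho U^2 / 2) U A."""
    mesh = build_mesh(
        straight_profile(0.02, 0.003),
        MeshParams(n_axial=12, n_radial=8, first_layer_height=2e-4,
                   growth_ratio=1.1, n_bl_layers=1),
    )
    st = solve(mesh, BoundaryConditions(inlet_flow_lpm=0.0),
               FluidProperties(), SolverSettings(laminar_mode=True))
    U, P = 2.0, 10.0
    st.u[:, :] = U
    st.p[:, :] = P
    st.Few[:, :] = RHO * U * mesh.Sx_ew
    A = np.pi * 0.003**2
    assert energy_flux(st, s=0.01) == pytest.approx(
        (P + 0.5 * RHO * U**2) * U * A, rel=1e-9
    )


def test_report_identity_enforced():
    with pytest.raises(ValueError, match="loss_rate"):
        MetricsReport(
            case="X", pressure_drop_Pa={}, pressure_drop_total_Pa={},
            wss_max_Pa={}, wss_max_global_Pa=0.0,
            energy_flux_inlet_W=1.0, energy_flux_outlet_W=0.5,
            energy_loss_W=0.5, loss_rate=0.3, re_throat={},
        )


def test_unconverged_state_flagged(rest_state):
    rest_state.converged = False
    rep = evaluate_case(rest_state, case="warn-check")
    assert "state not converged" in rep.warnings
    rest_state.converged = True
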