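"""Aerodynamic read-outs from a converged flow state.

The quantities the surgical comparison is judged on:

* static pressure drop across each stenotic extent (stations one local
  diameter up-/downstream of the extent),
* maximum wall shear stress over each stenotic wall patch,
* mechanical energy flux E = sum (P + 1/2 rho u^2) Q through a cross
  section, evaluated with the discrete face mass fluxes,
* energy loss EL = E_in - E_out over the anatomical span and the
  normalized loss rate lambda = 1 - E_out/E_in,
* throat Reynolds number per stenosis.

Pressure drops use static pressure (area-averaged at the stations); a
total-pressure variant is reported alongside.  All metrics are evaluated
inside the anatomical span only - the straight inlet/outlet extensions are
numerical scaffolding, not anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import AxisymmetricProfile, cross_section_area
from .meshgen import StructuredMesh
from .solver import FlowState, reynolds_number

__all__ = [
    "MetricsReport",
    "wall_shear_stress",
    "pressure_drop",
    "energy_flux",
    "energy_loss_rate",
    "evaluate_case",
    "REPORT_COLUMNS",
]

REPORT_COLUMNS = [
    "case", "dP_S1_Pa", "dP_S2_Pa", "wss_max_S1_Pa", "wss_max_S2_Pa",
    "EL_W", "lambda", "Re_S1", "Re_S2",
]


@dataclass
class MetricsReport:
    """Per-case aerodynamic summary (one row of the M1-M4 comparison)."""

    case: str
    pressure_drop_Pa: dict          # stenosis id -> static dP
    pressure_drop_total_Pa: dict    # stenosis id -> total-pressure dP
    wss_max_Pa: dict                # stenosis id -> max WSS in extent
    wss_max_global_Pa: float
    energy_flux_inlet_W: float
    energy_flux_outlet_W: float
    energy_loss_W: float
    loss_rate: float
    re_throat: dict                 # stenosis id -> throat Reynolds number
    warnings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.energy_flux_inlet_W > 0:
            expect = 1.0 - self.energy_flux_outlet_W / self.energy_flux_inlet_W
            if abs(self.loss_rate - expect) > 1e-12 * max(1.0, abs(expect)):
                raise ValueError("loss_rate must equal 1 - E_out/E_in")

    def to_row(self) -> dict:
        return {
            "case": self.case,
            "dP_S1_Pa": self.pressure_drop_Pa.get("S1", np.nan),
            "dP_S2_Pa": self.pressure_drop_Pa.get("S2", np.nan),
            "wss_max_S1_Pa": self.wss_max_Pa.get("S1", np.nan),
            "wss_max_S2_Pa": self.wss_max_Pa.get("S2", np.nan),
            "EL_W": self.energy_loss_W,
            "lambda": self.loss_rate,
            "Re_S1": self.re_throat.get("S1", np.nan),
            "Re_S2": self.re_throat.get("S2", np.nan),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.to_row()], columns=REPORT_COLUMNS)


# ---------------------------------------------------------------------------


def wall_shear_stress(state: FlowState, mesh: StructuredMesh | None = None):
    """WSS magnitude per wall face, Pa.

    tau_wall = mu * du_t/dn at the wall, evaluated from the tangential
    velocity of the first (wall-adjacent) cell and its normal distance -
    the quantity the wall-refined mesh exists to resolve.  Molecular
    viscosity applies at the no-slip surface.
    """
    mesh = mesh or state.mesh
    mu = state.fluid.mu
    ut = (
        state.u[:, -1] * mesh.wall_tangent[:, 0]
        + state.v[:, -1] * mesh.wall_tangent[:, 1]
    )
    return np.abs(mu * ut / mesh.wall_dist)


def _column_pressure(state: FlowState, mesh: StructuredMesh, total: bool = False):
    """Area-averaged pressure per cell column (area weights from face annuli)."""
    w = 0.5 * (mesh.Sx_ew[:-1, :] + mesh.Sx_ew[1:, :])
    q = state.p
    if total:
        q = q + 0.5 * state.fluid.rho * (state.u**2 + state.v**2)
    return np.sum(q * w, axis=1) / np.sum(w, axis=1)


def _station_pressure(state, mesh, s: float, total=False) -> float:
    a0, a1 = mesh.profile.anatomical
    if not (a0 - 1e-12 <= s <= a1 + 1e-12):
        raise ValueError(
            f"station s={s:.4g} outside the anatomical region [{a0:.4g}, {a1:.4g}]"
        )
    pbar = _column_pressure(state, mesh, total=total)
    x = mesh.xc[:, 0]
    # linear extrapolation beyond the first/last cell centroid so stations at
    # the domain ends do not lose the half-cell pressure gradient
    if s < x[0]:
        return float(pbar[0] + (pbar[1] - pbar[0]) * (s - x[0]) / (x[1] - x[0]))
    if s > x[-1]:
        return float(
            pbar[-1] + (pbar[-1] - pbar[-2]) * (s - x[-1]) / (x[-1] - x[-2])
        )
    return float(np.interp(s, x, pbar))


def pressure_drop(
    state: FlowState,
    mesh: StructuredMesh | None = None,
    s_up: float = None,
    s_down: float = None,
    total: bool = False,
) -> float:
    """Area-averaged (static by default) pressure at s_up minus at s_down."""
    mesh = mesh or state.mesh
    if s_up >= s_down:
        raise ValueError("require s_up < s_down")
    return _station_pressure(state, mesh, s_up, total) - _station_pressure(
        state, mesh, s_down, total
    )


def energy_flux(state: FlowState, mesh: StructuredMesh | None = None, s: float = None) -> float:
    """Mechanical energy flux (W) through the x-plane nearest to ``s``.

    Discrete form sum_f (p_f + 1/2 rho |u_f|^2) * F_f / rho using the
    stored face mass fluxes, so the same fluxes that satisfy continuity
    carry the energy bookkeeping.
    """
    mesh = mesh or state.mesh
    lo, hi = mesh.xn[0], mesh.xn[-1]
    if not (lo - 1e-12 <= s <= hi + 1e-12):
        raise ValueError(f"s={s} outside domain [{lo}, {hi}]")
    i = int(np.argmin(np.abs(mesh.xn - s)))
    rho = state.fluid.rho
    if i == 0:
        pf, uf, vf = state.p[0, :], state.u[0, :], state.v[0, :]
    elif i == mesh.ni:
        pf = np.zeros(mesh.nj)  # outlet gauge datum
        uf, vf = state.u[-1, :], state.v[-1, :]
    else:
        xl, xr = mesh.xc[i - 1, 0], mesh.xc[i, 0]
        w = (xr - mesh.xn[i]) / (xr - xl)
        pf = w * state.p[i - 1, :] + (1 - w) * state.p[i, :]
        uf = w * state.u[i - 1, :] + (1 - w) * state.u[i, :]
        vf = w * state.v[i - 1, :] + (1 - w) * state.v[i, :]
    F = state.Few[i, :]
    return float(np.sum((pf + 0.5 * rho * (uf**2 + vf**2)) * F / rho))


def energy_loss_rate(E_inlet: float, E_outlet: float) -> float:
    """lambda = 1 - E_outlet/E_inlet (dimensionless loss fraction)."""
    if E_inlet <= 0:
        raise ValueError("E_inlet must be positive")
    return 1.0 - E_outlet / E_inlet


# ---------------------------------------------------------------------------


def evaluate_case(
    state: FlowState,
    profile: AxisymmetricProfile | None = None,
    case: str = "",
    station_offset_diameters: float = 1.0,
) -> MetricsReport:
    """Full MetricsReport for one solved case.

    Measurement stations sit ``station_offset_diameters`` local diameters
    up- and downstream of each stenotic extent (clamped to the anatomy).
    Stenoses marked corrected are still reported - that is the point of the
    before/after comparison.
    """
    mesh = state.mesh
    profile = profile or mesh.profile
    warnings = [] if state.converged else ["state not converged"]
    a0, a1 = profile.anatomical
    rho = state.fluid.rho
    Q = state.bc.inlet_flow_m3s

    wss = wall_shear_stress(state, mesh)
    wx = mesh.wall_center[:, 0]
    anat_wall = (wx >= a0) & (wx <= a1)

    dP, dP_tot, wss_max, re_thr = {}, {}, {}, {}
    for sp in profile.stenoses:
        D_loc = 2.0 * profile.reference_radius
        off = station_offset_diameters * D_loc
        s_up = max(sp.start - off, a0)
        s_dn = min(sp.end + off, a1)
        dP[sp.id] = pressure_drop(state, mesh, s_up, s_dn)
        dP_tot[sp.id] = pressure_drop(state, mesh, s_up, s_dn, total=True)
        in_ext = (wx >= sp.start) & (wx <= sp.end)
        wss_max[sp.id] = float(np.max(wss[in_ext])) if np.any(in_ext) else np.nan
        # throat Reynolds number from the minimal lumen area in the extent
        mask = (profile.s >= sp.start) & (profile.s <= sp.end)
        r_min = float(np.min(profile.R[mask]))
        A_min = np.pi * r_min**2
        U_thr = Q / A_min if Q > 0 else 0.0
        re_thr[sp.id] = reynolds_number(state.fluid, U_thr, 2.0 * r_min)

    E_in = energy_flux(state, mesh, a0)
    E_out = energy_flux(state, mesh, a1)
    if Q > 0:
        lam = energy_loss_rate(E_in, E_out)
    else:
        lam = 0.0
        E_in = E_out = 0.0
    return MetricsReport(
        case=case,
        pressure_drop_Pa=dP,
        pressure_drop_total_Pa=dP_tot,
        wss_max_Pa=wss_max,
        wss_max_global_Pa=float(np.max(wss[anat_wall])) if np.any(anat_wall) else 0.0,
        energy_flux_inlet_W=E_in,
        energy_flux_outlet_W=E_out,
        energy_loss_W=E_in - E_out,
        loss_rate=lam,
        re_throat=re_thr,
        warnings=warnings,
    )
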