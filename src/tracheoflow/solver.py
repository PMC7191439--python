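"""Steady incompressible RANS on axisymmetric structured grids.

Finite-volume discretization with a collocated variable arrangement:

* SIMPLE pressure-velocity coupling; Rhie-Chow momentum-weighted face
  interpolation suppresses pressure checkerboarding.
* Convection: implicit first-order upwind plus deferred second-order-upwind
  correction; diffusion: central with explicit non-orthogonal correction.
* Turbulence: Wilcox k-omega two-equation closure (eddy viscosity
  mu_t = rho k / omega) integrated to the wall; the wall-adjacent omega is
  fixed to the smooth-wall asymptote 6 mu / (rho beta y1^2).

The transient terms of the transport equations are dropped: the steady state
is reached by under-relaxed outer iterations (pseudo-time relaxation), and
convergence is declared on the relative inter-iteration variation of all
fields, mirroring common commercial-solver practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .meshgen import StructuredMesh

__all__ = [
    "FluidProperties",
    "BoundaryConditions",
    "SolverSettings",
    "ClosureCoefficients",
    "FlowState",
    "solve",
    "eddy_viscosity",
    "reynolds_number",
    "reynolds_stress",
    "residual",
    "ConvergenceError",
    "DivergenceError",
]


class ConvergenceError(RuntimeError):
    """Raised when the outer iterations exhaust max_iterations.

    Carries the residual history for diagnosis."""

    def __init__(self, msg, history=None):
        super().__init__(msg)
        self.history = history or []


class DivergenceError(RuntimeError):
    """Raised on the first iteration producing a non-finite field value."""

    def __init__(self, msg, iteration=None):
        super().__init__(msg)
        self.iteration = iteration


@dataclass(frozen=True)
class FluidProperties:
    """Humidified inspired air at body temperature; body forces omitted."""

    rho: float = 1.161        # kg/m^3
    mu: float = 1.864e-5      # kg/(m s)

    def __post_init__(self):
        if self.rho <= 0 or self.mu <= 0:
            raise ValueError("rho and mu must be positive")


@dataclass(frozen=True)
class BoundaryConditions:
    """Ventilator volume-control inflow, zero-gauge outlets, rigid walls."""

    inlet_flow_lpm: float = 3.0           # constant volumetric inflow, L/min
    outlet_pressure: float = 0.0          # gauge Pa, fixed
    inlet_turbulence_intensity: float = 0.05
    inlet_turbulence_length_frac: float = 0.10  # x local diameter
    inlet_profile: str = "plug"           # "plug" | "parabolic"

    def __post_init__(self):
        if self.inlet_flow_lpm < 0:
            raise ValueError("inlet flow must be non-negative")
        if self.outlet_pressure != 0.0:
            raise ValueError("outlet gauge pressure is fixed at zero")
        if self.inlet_profile not in ("plug", "parabolic"):
            raise ValueError(f"unknown inlet profile {self.inlet_profile!r}")

    @property
    def inlet_flow_m3s(self) -> float:
        return self.inlet_flow_lpm / 60000.0


@dataclass(frozen=True)
class SolverSettings:
    convergence_tol: float = 1.0e-5   # relative inter-iteration variation
    max_iterations: int = 3000
    min_iterations: int = 40
    relax_u: float = 0.7
    relax_p: float = 0.3
    relax_turb: float = 0.8
    laminar_mode: bool = False
    production_limit: float = 20.0    # P_k <= limit * beta* rho k omega
    n_consecutive: int = 3            # tol must hold this many checks in a row

    def __post_init__(self):
        if not (0.0 < self.convergence_tol < 1.0):
            raise ValueError("convergence_tol must be in (0, 1)")
        for a in (self.relax_u, self.relax_p, self.relax_turb):
            if not (0.0 < a <= 1.0):
                raise ValueError("relaxation factors must be in (0, 1]")


@dataclass(frozen=True)
class ClosureCoefficients:
    """Wilcox k-omega closure constants (exact rationals)."""

    alpha: float = 5.0 / 9.0
    beta: float = 3.0 / 40.0
    beta_star: float = 9.0 / 100.0
    sigma: float = 1.0 / 2.0
    sigma_star: float = 1.0 / 2.0


@dataclass
class FlowState:
    """Converged (or last-iterate) cell-centered fields on a mesh.

    Face mass fluxes (kg/s, revolved areas) are retained because they satisfy
    discrete continuity to linear-solver precision and feed the metrics.
    """

    mesh: StructuredMesh
    u: np.ndarray             # axial velocity (ni, nj), m/s
    v: np.ndarray             # radial velocity, m/s
    p: np.ndarray             # static gauge pressure, Pa
    k: np.ndarray             # turbulence kinetic energy, m^2/s^2
    omega: np.ndarray         # specific dissipation rate, 1/s
    mu_t: np.ndarray          # eddy viscosity, kg/(m s)
    Few: np.ndarray           # mass flux through x-plane faces (ni+1, nj)
    Fns: np.ndarray           # mass flux through j-line faces (ni, nj+1)
    fluid: FluidProperties = field(default_factory=FluidProperties)
    bc: BoundaryConditions = field(default_factory=BoundaryConditions)
    converged: bool = False
    iterations: int = 0
    history: list = field(default_factory=list)
    clip_events: int = 0

    def mass_imbalance(self) -> np.ndarray:
        """Per-cell net outward mass flux (kg/s)."""
        return (
            self.Few[1:, :] - self.Few[:-1, :] + self.Fns[:, 1:] - self.Fns[:, :-1]
        )

    def inlet_mass_flux(self) -> float:
        return float(np.sum(self.Few[0, :]))

    def outlet_mass_flux(self) -> float:
        return float(np.sum(self.Few[-1, :]))


# ---------------------------------------------------------------------------
# small pure operations


def eddy_viscosity(rho: float, k, omega):
    """Wilcox eddy viscosity mu_t = rho k / omega (element-wise)."""
    k = np.asarray(k, dtype=float)
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0.0):
        raise ValueError("omega must be positive")
    if np.any(k < 0.0):
        raise ValueError("k must be non-negative")
    out = rho * k / omega
    return float(out) if out.ndim == 0 else out


def reynolds_number(fluid: FluidProperties, U: float, D: float) -> float:
    """Re = rho U D / mu."""
    if U < 0 or D <= 0:
        raise ValueError("require U >= 0 and D > 0")
    return fluid.rho * U * D / fluid.mu


def residual(prev: FlowState, curr: FlowState) -> dict:
    """Relative inter-iteration variation per field (convergence monitor)."""
    if prev.mesh is not curr.mesh and (
        prev.u.shape != curr.u.shape or prev.mesh.n_cells != curr.mesh.n_cells
    ):
        raise ValueError("states live on different meshes")
    out = {}
    for name in ("u", "v", "p", "k", "omega"):
        a, b = getattr(prev, name), getattr(curr, name)
        scale = np.max(np.abs(b))
        out[name] = float(np.max(np.abs(b - a)) / (scale + 1e-300))
    return out


# ---------------------------------------------------------------------------
# discretization geometry (precomputed once per mesh)


class _Disc:
    def __init__(self, mesh: StructuredMesh):
        self.mesh = mesh
        ni, nj = mesh.ni, mesh.nj
        self.ni, self.nj = ni, nj
        xc, rc, vol = mesh.xc, mesh.rc, mesh.vol
        self.vol = vol

        # internal x-plane faces: planes i = 1..ni-1, W cell (i-1,j), E cell (i,j)
        Sx = mesh.Sx_ew[1:-1, :]
        fx = mesh.xn[1:-1][:, None] + np.zeros_like(Sx)
        fr = mesh.rf_ew[1:-1, :]
        dW = np.hypot(fx - xc[:-1, :], fr - rc[:-1, :])
        dE = np.hypot(fx - xc[1:, :], fr - rc[1:, :])
        self.w_ew = dE / (dW + dE)
        ddx = xc[1:, :] - xc[:-1, :]
        ddr = rc[1:, :] - rc[:-1, :]
        self.d_ew = (ddx, ddr)
        self.gdiff_ew = Sx / ddx                       # |S|^2 / (S.d), S=(Sx,0)
        self.kr_ew = -ddr * Sx / ddx                   # non-orthogonal remainder
        self.fc_ew = (fx, fr)
        self.Sx_ew_int = Sx

        # internal j-line faces: lines j = 1..nj-1, S cell (i,j-1), N cell (i,j)
        Sxn = mesh.Sx_ns[:, 1:-1]
        Srn = mesh.Sr_ns[:, 1:-1]
        fxn = mesh.xf_ns[:, 1:-1]
        frn = mesh.rf_ns[:, 1:-1]
        dS = np.hypot(fxn - xc[:, :-1], frn - rc[:, :-1])
        dN = np.hypot(fxn - xc[:, 1:], frn - rc[:, 1:])
        self.w_ns = dN / (dS + dN)
        ddxn = xc[:, 1:] - xc[:, :-1]
        ddrn = rc[:, 1:] - rc[:, :-1]
        self.d_ns = (ddxn, ddrn)
        S2 = Sxn**2 + Srn**2
        Sd = Sxn * ddxn + Srn * ddrn
        self.gdiff_ns = S2 / Sd
        self.kx_ns = Sxn - ddxn * S2 / Sd
        self.kr_ns = Srn - ddrn * S2 / Sd
        self.fc_ns = (fxn, frn)
        self.S_ns = (Sxn, Srn)

        # inlet faces (plane 0), outward normal -x
        fx0 = mesh.xn[0]
        self.gdiff_in = mesh.Sx_ew[0, :] / (xc[0, :] - fx0)
        # outlet faces (plane ni), outward +x
        self.gdiff_out = mesh.Sx_ew[-1, :] / (mesh.xn[-1] - xc[-1, :])
        # wall faces
        Sww = np.stack([mesh.Sx_ns[:, -1], mesh.Sr_ns[:, -1]], axis=1)
        dwx = mesh.wall_center[:, 0] - xc[:, -1]
        dwr = mesh.wall_center[:, 1] - rc[:, -1]
        self.gdiff_wall = (Sww[:, 0] ** 2 + Sww[:, 1] ** 2) / (
            Sww[:, 0] * dwx + Sww[:, 1] * dwr
        )

        # sparse structure for the 5-point stencil
        I = np.arange(ni * nj).reshape(ni, nj)
        self._rows = np.concatenate(
            [
                I.ravel(),
                I[:-1, :].ravel(), I[1:, :].ravel(),
                I[:, :-1].ravel(), I[:, 1:].ravel(),
            ]
        )
        self._cols = np.concatenate(
            [
                I.ravel(),
                I[1:, :].ravel(), I[:-1, :].ravel(),
                I[:, 1:].ravel(), I[:, :-1].ravel(),
            ]
        )
        self.shape = (ni * nj, ni * nj)

    def matrix(self, aP, aE, aW, aN, aS):
        data = np.concatenate(
            [
                aP.ravel(),
                -aE[:-1, :].ravel(), -aW[1:, :].ravel(),
                -aN[:, :-1].ravel(), -aS[:, 1:].ravel(),
            ]
        )
        return sp.csr_matrix((data, (self._rows, self._cols)), shape=self.shape)

    # -- face interpolation & gradients ---------------------------------

    def face_values(self, phi, inlet=None, outlet=None, wall=None):
        """Field values on all faces; boundary defaults to zero-gradient."""
        ni, nj = self.ni, self.nj
        few = np.empty((ni + 1, nj))
        few[1:-1, :] = self.w_ew * phi[:-1, :] + (1.0 - self.w_ew) * phi[1:, :]
        few[0, :] = phi[0, :] if inlet is None else inlet
        few[-1, :] = phi[-1, :] if outlet is None else outlet
        fns = np.empty((ni, nj + 1))
        fns[:, 1:-1] = self.w_ns * phi[:, :-1] + (1.0 - self.w_ns) * phi[:, 1:]
        fns[:, 0] = phi[:, 0]          # axis: zero-area, value irrelevant
        fns[:, -1] = phi[:, -1] if wall is None else wall
        return few, fns

    def grad(self, phi, inlet=None, outlet=None, wall=None):
        """Green-Gauss gradient with the axisymmetric radial correction."""
        m = self.mesh
        few, fns = self.face_values(phi, inlet, outlet, wall)
        gx = (
            few[1:, :] * m.Sx_ew[1:, :] - few[:-1, :] * m.Sx_ew[:-1, :]
            + fns[:, 1:] * m.Sx_ns[:, 1:] - fns[:, :-1] * m.Sx_ns[:, :-1]
        ) / self.vol
        gr = (
            fns[:, 1:] * m.Sr_ns[:, 1:] - fns[:, :-1] * m.Sr_ns[:, :-1]
            - phi * self.vol / m.rc
        ) / self.vol
        return gx, gr


def _harmonic(muP, muN, w):
    return 1.0 / (w / muP + (1.0 - w) / muN)


# ---------------------------------------------------------------------------
# generic transport-equation assembly


def _assemble_transport(
    disc, phi, grad_phi, mu_ew, mu_ns, Few, Fns,
    inlet_value=None, wall_value=None, extra_diag=None, source=None,
    inlet_mu=None, wall_mu=None, second_order=True,
):
    """Coefficients for  aP phi_P - sum aNB phi_NB = b.

    Implicit: upwind convection + orthogonal central diffusion.
    Explicit (in b): SOU deferred correction, non-orthogonal cross-diffusion,
    boundary contributions and the supplied volumetric source.
    """
    ni, nj = disc.ni, disc.nj
    aE = np.zeros((ni, nj)); aW = np.zeros((ni, nj))
    aN = np.zeros((ni, nj)); aS = np.zeros((ni, nj))
    aP = np.zeros((ni, nj))
    b = np.zeros((ni, nj)) if source is None else source.copy()
    gx, gr = grad_phi

    # ---- internal x-plane faces
    F = Few[1:-1, :]
    D = mu_ew * disc.gdiff_ew
    Fp = np.maximum(F, 0.0); Fm = np.maximum(-F, 0.0)
    aE[:-1, :] += D + Fm
    aP[:-1, :] += D + Fp
    aW[1:, :] += D + Fp
    aP[1:, :] += D + Fm
    # cross-diffusion (radial component only on these faces)
    grf = disc.w_ew * gr[:-1, :] + (1.0 - disc.w_ew) * gr[1:, :]
    cd = mu_ew * grf * disc.kr_ew
    b[:-1, :] += cd
    b[1:, :] -= cd
    if second_order:
        fx, fr = disc.fc_ew
        up = F >= 0.0
        xc, rc = disc.mesh.xc, disc.mesh.rc
        dxu = fx - np.where(up, xc[:-1, :], xc[1:, :])
        dru = fr - np.where(up, rc[:-1, :], rc[1:, :])
        gxu = np.where(up, gx[:-1, :], gx[1:, :])
        gru = np.where(up, gr[:-1, :], gr[1:, :])
        phiU = np.where(up, phi[:-1, :], phi[1:, :])
        # bound the reconstructed face value by the adjacent cell values:
        # keeps the deferred correction stable on high-aspect tilted cells
        lo = np.minimum(phi[:-1, :], phi[1:, :])
        hi = np.maximum(phi[:-1, :], phi[1:, :])
        phiF = np.clip(phiU + gxu * dxu + gru * dru, lo, hi)
        corr = F * (phiF - phiU)
        b[:-1, :] -= corr
        b[1:, :] += corr

    # ---- internal j-line faces
    F = Fns[:, 1:-1]
    D = mu_ns * disc.gdiff_ns
    Fp = np.maximum(F, 0.0); Fm = np.maximum(-F, 0.0)
    aN[:, :-1] += D + Fm
    aP[:, :-1] += D + Fp
    aS[:, 1:] += D + Fp
    aP[:, 1:] += D + Fm
    gxf = disc.w_ns * gx[:, :-1] + (1.0 - disc.w_ns) * gx[:, 1:]
    grf = disc.w_ns * gr[:, :-1] + (1.0 - disc.w_ns) * gr[:, 1:]
    cd = mu_ns * (gxf * disc.kx_ns + grf * disc.kr_ns)
    b[:, :-1] += cd
    b[:, 1:] -= cd
    if second_order:
        fxn, frn = disc.fc_ns
        up = F >= 0.0
        xc, rc = disc.mesh.xc, disc.mesh.rc
        dxu = fxn - np.where(up, xc[:, :-1], xc[:, 1:])
        dru = frn - np.where(up, rc[:, :-1], rc[:, 1:])
        gxu = np.where(up, gx[:, :-1], gx[:, 1:])
        gru = np.where(up, gr[:, :-1], gr[:, 1:])
        phiU = np.where(up, phi[:, :-1], phi[:, 1:])
        lo = np.minimum(phi[:, :-1], phi[:, 1:])
        hi = np.maximum(phi[:, :-1], phi[:, 1:])
        phiF = np.clip(phiU + gxu * dxu + gru * dru, lo, hi)
        corr = F * (phiF - phiU)
        b[:, :-1] -= corr
        b[:, 1:] += corr

    # ---- boundaries
    if inlet_value is not None:  # Dirichlet inflow
        Din = _as_row(inlet_value, nj)
        Dcoef = inlet_mu * disc.gdiff_in
        aP[0, :] += Dcoef
        b[0, :] += Dcoef * Din
        Fin = Few[0, :]  # positive into the domain
        b[0, :] += np.maximum(Fin, 0.0) * Din
        aP[0, :] += np.maximum(-Fin, 0.0)
    # outlet: zero-gradient, outflow convection only
    Fout = Few[-1, :]
    aP[-1, :] += np.maximum(Fout, 0.0)
    if wall_value is not None:
        Dw = wall_mu * disc.gdiff_wall
        wv = _as_row(wall_value, ni)
        aP[:, -1] += Dw
        b[:, -1] += Dw * wv

    if extra_diag is not None:
        aP += extra_diag
    return aP, aE, aW, aN, aS, b


def _as_row(val, n):
    return np.full(n, float(val)) if np.isscalar(val) else np.asarray(val, float)


def _solve_relaxed(disc, coeffs, phi_old, relax):
    aP, aE, aW, aN, aS, b = coeffs
    aPr = aP / relax
    br = b + (1.0 - relax) * aPr * phi_old
    A = disc.matrix(aPr, aE, aW, aN, aS)
    sol = spla.spsolve(A, br.ravel())
    return sol.reshape(phi_old.shape), aPr


# ---------------------------------------------------------------------------
# main driver


def _inlet_velocity(mesh, bc, fluid):
    """Discrete inlet axial-velocity profile scaled to the exact mass flow."""
    S = mesh.Sx_ew[0, :]
    rf = mesh.rf_ew[0, :]
    Rin = mesh.rn[0, -1]
    if bc.inlet_profile == "parabolic":
        prof = 1.0 - (rf / Rin) ** 2
    else:
        prof = np.ones_like(rf)
    Q = bc.inlet_flow_m3s
    got = np.sum(prof * S)
    return prof * (Q / got) if got > 0 else prof * 0.0


def _inlet_turbulence(mesh, bc, fluid, coeffs):
    Rin = mesh.rn[0, -1]
    Q = bc.inlet_flow_m3s
    U = Q / (np.pi * Rin**2)
    k_in = 1.5 * (bc.inlet_turbulence_intensity * U) ** 2
    ell = bc.inlet_turbulence_length_frac * 2.0 * Rin
    om_in = np.sqrt(max(k_in, 1e-300)) / (coeffs.beta_star**0.25 * ell)
    return max(k_in, 1e-12), max(om_in, 1e-6)


def solve(
    mesh: StructuredMesh,
    bc: BoundaryConditions,
    fluid: FluidProperties,
    settings: SolverSettings | None = None,
    coeffs: ClosureCoefficients | None = None,
) -> FlowState:
    """Run SIMPLE outer iterations to the steady RANS solution.

    Returns a FlowState whose retained face fluxes satisfy per-cell
    continuity to the precision of the (direct) pressure-correction solve.
    """
    settings = settings or SolverSettings()
    coeffs = coeffs or ClosureCoefficients()
    disc = _Disc(mesh)
    ni, nj = mesh.ni, mesh.nj
    rho, mu = fluid.rho, fluid.mu
    Q = bc.inlet_flow_m3s

    u_in = _inlet_velocity(mesh, bc, fluid)
    k_in, om_in = _inlet_turbulence(mesh, bc, fluid, coeffs)
    turbulent = not settings.laminar_mode

    # reference scales for convergence floors
    Amin = float(np.min(np.sum(mesh.Sx_ew, axis=1)))
    U_ref = Q / Amin if Q > 0 else 1.0
    scales = {
        "u": U_ref, "v": 0.2 * U_ref, "p": max(0.5 * rho * U_ref**2, 1e-12),
        "k": k_in, "omega": om_in,
    }

    # initial guess: per-station plug flow from 1-D continuity
    A_col = np.sum(mesh.Sx_ew, axis=1)  # (ni+1,)
    u = np.empty((ni, nj))
    u[:, :] = (0.5 * (Q / A_col[:-1] + Q / A_col[1:]))[:, None]
    v = np.zeros((ni, nj))
    p = np.zeros((ni, nj))
    k = np.full((ni, nj), k_in)
    omega = np.full((ni, nj), om_in)
    mu_t = np.zeros((ni, nj))
    if turbulent and Q > 0:
        omega_wall = 6.0 * mu / (rho * coeffs.beta * mesh.wall_dist**2)
        omega[:, -1] = omega_wall
        mu_t = rho * k / omega

    # initial face fluxes from the plug guess
    Few = np.empty((ni + 1, nj))
    Few[0, :] = rho * u_in * mesh.Sx_ew[0, :]
    uf, _ = disc.face_values(u, inlet=u_in)
    Few[1:, :] = rho * uf[1:, :] * mesh.Sx_ew[1:, :]
    Fns = np.zeros((ni, nj + 1))

    state = FlowState(
        mesh=mesh, u=u, v=v, p=p, k=k, omega=omega, mu_t=mu_t,
        Few=Few, Fns=Fns, fluid=fluid, bc=bc,
    )
    if Q == 0.0:  # rest state: nothing to iterate
        state.converged = True
        return state

    hits = 0
    clip_events = 0
    history = []
    for it in range(1, settings.max_iterations + 1):
        u_old, v_old, p_old = u.copy(), v.copy(), p.copy()
        k_old, om_old = k.copy(), omega.copy()

        mu_eff = mu + mu_t
        w = disc.w_ew
        mu_ew = _harmonic(mu_eff[:-1, :], mu_eff[1:, :], w)
        wn = disc.w_ns
        mu_ns = _harmonic(mu_eff[:, :-1], mu_eff[:, 1:], wn)
        mu_wall = np.full(ni, mu)    # molecular at the no-slip wall

        gp = disc.grad(p, outlet=np.zeros(nj))
        gu = disc.grad(u, inlet=u_in, wall=np.zeros(ni))
        gv = disc.grad(v, inlet=np.zeros(nj), wall=np.zeros(ni))

        # The transpose-gradient part of the viscous stress divergence is
        # omitted: it vanishes identically for constant-viscosity
        # divergence-free fields and is a small correction under the
        # Boussinesq closure, while an explicit treatment destabilizes
        # high-aspect wall cells.
        vol = disc.vol
        src_u = -gp[0] * vol
        src_v = -gp[1] * vol
        if turbulent:
            gk = disc.grad(rho * (2.0 / 3.0) * k, inlet=rho * (2.0 / 3.0) * k_in,
                           wall=np.zeros(ni))
            src_u -= gk[0] * vol
            src_v -= gk[1] * vol

        diag_v = 2.0 * mu_eff * vol / disc.mesh.rc**2

        cu = _assemble_transport(
            disc, u, gu, mu_ew, mu_ns, Few, Fns,
            inlet_value=u_in, wall_value=0.0, source=src_u,
            inlet_mu=mu_eff[0, :], wall_mu=mu_wall,
        )
        u, aPu = _solve_relaxed(disc, cu, u_old, settings.relax_u)
        cv = _assemble_transport(
            disc, v, gv, mu_ew, mu_ns, Few, Fns,
            inlet_value=0.0, wall_value=0.0, extra_diag=diag_v, source=src_v,
            inlet_mu=mu_eff[0, :], wall_mu=mu_wall,
        )
        v, aPv = _solve_relaxed(disc, cv, v_old, settings.relax_u)

        # ---- Rhie-Chow face fluxes and pressure correction
        dP = vol / (0.5 * (aPu + aPv))
        dfe = disc.w_ew * dP[:-1, :] + (1.0 - disc.w_ew) * dP[1:, :]
        Eew = dfe * disc.gdiff_ew
        uf = disc.w_ew * u[:-1, :] + (1.0 - disc.w_ew) * u[1:, :]
        gpf = disc.w_ew * gp[0][:-1, :] + (1.0 - disc.w_ew) * gp[0][1:, :]
        gprf = disc.w_ew * gp[1][:-1, :] + (1.0 - disc.w_ew) * gp[1][1:, :]
        ddx, ddr = disc.d_ew
        Few[1:-1, :] = rho * uf * disc.Sx_ew_int - rho * Eew * (
            (p[1:, :] - p[:-1, :]) - (gpf * ddx + gprf * ddr)
        )
        Few[0, :] = rho * u_in * mesh.Sx_ew[0, :]
        Eout = dP[-1, :] * disc.gdiff_out
        dbx = mesh.xn[-1] - mesh.xc[-1, :]
        Few[-1, :] = rho * u[-1, :] * mesh.Sx_ew[-1, :] - rho * Eout * (
            (0.0 - p[-1, :]) - gp[0][-1, :] * dbx
        )
        Sxn, Srn = disc.S_ns
        dfn = disc.w_ns * dP[:, :-1] + (1.0 - disc.w_ns) * dP[:, 1:]
        Ens = dfn * disc.gdiff_ns
        ufn = disc.w_ns * u[:, :-1] + (1.0 - disc.w_ns) * u[:, 1:]
        vfn = disc.w_ns * v[:, :-1] + (1.0 - disc.w_ns) * v[:, 1:]
        gpfx = disc.w_ns * gp[0][:, :-1] + (1.0 - disc.w_ns) * gp[0][:, 1:]
        gpfr = disc.w_ns * gp[1][:, :-1] + (1.0 - disc.w_ns) * gp[1][:, 1:]
        ddxn, ddrn = disc.d_ns
        Fns[:, 1:-1] = rho * (ufn * Sxn + vfn * Srn) - rho * Ens * (
            (p[:, 1:] - p[:, :-1]) - (gpfx * ddxn + gpfr * ddrn)
        )
        Fns[:, 0] = 0.0
        Fns[:, -1] = 0.0

        imb = Few[1:, :] - Few[:-1, :] + Fns[:, 1:] - Fns[:, :-1]

        aEp = np.zeros((ni, nj)); aWp = np.zeros((ni, nj))
        aNp = np.zeros((ni, nj)); aSp = np.zeros((ni, nj))
        aPp = np.zeros((ni, nj))
        cE = rho * Eew
        aEp[:-1, :] += cE; aPp[:-1, :] += cE
        aWp[1:, :] += cE; aPp[1:, :] += cE
        cN = rho * Ens
        aNp[:, :-1] += cN; aPp[:, :-1] += cN
        aSp[:, 1:] += cN; aPp[:, 1:] += cN
        aPp[-1, :] += rho * Eout           # outlet p' = 0 Dirichlet
        A = disc.matrix(aPp, aEp, aWp, aNp, aSp)
        pc = spla.spsolve(A, (-imb).ravel()).reshape(ni, nj)

        # corrections
        p += settings.relax_p * pc
        gpc = disc.grad(pc, outlet=np.zeros(nj))
        u -= dP * gpc[0]
        v -= dP * gpc[1]
        Few[1:-1, :] -= rho * Eew * (pc[1:, :] - pc[:-1, :])
        Few[-1, :] -= rho * Eout * (0.0 - pc[-1, :])
        Fns[:, 1:-1] -= rho * Ens * (pc[:, 1:] - pc[:, :-1])

        # ---- turbulence transport
        if turbulent:
            gu = disc.grad(u, inlet=u_in, wall=np.zeros(ni))
            gv = disc.grad(v, inlet=np.zeros(nj), wall=np.zeros(ni))
            Sxx, Srr = gu[0], gv[1]
            Stt = v / disc.mesh.rc
            Sxr = 0.5 * (gu[1] + gv[0])
            S2 = 2.0 * (Sxx**2 + Srr**2 + Stt**2 + 2.0 * Sxr**2)
            Pk = mu_t * S2
            Pcap = settings.production_limit * coeffs.beta_star * rho * k * omega
            Pk = np.minimum(Pk, Pcap)

            mu_k_ew = _harmonic(
                mu + coeffs.sigma_star * mu_t[:-1, :],
                mu + coeffs.sigma_star * mu_t[1:, :], w)
            mu_k_ns = _harmonic(
                mu + coeffs.sigma_star * mu_t[:, :-1],
                mu + coeffs.sigma_star * mu_t[:, 1:], wn)
            gk2 = disc.grad(k, inlet=np.full(nj, k_in), wall=np.zeros(ni))
            ck = _assemble_transport(
                disc, k, gk2, mu_k_ew, mu_k_ns, Few, Fns,
                inlet_value=k_in, wall_value=0.0,
                extra_diag=coeffs.beta_star * rho * omega * vol,
                source=Pk * vol,
                inlet_mu=mu + coeffs.sigma_star * mu_t[0, :], wall_mu=mu_wall,
            )
            k, _ = _solve_relaxed(disc, ck, k_old, settings.relax_turb)
            n_neg = int(np.sum(k < 0.0))
            if n_neg:
                clip_events += n_neg
                k = np.maximum(k, 0.0)

            mu_w_ew = _harmonic(
                mu + coeffs.sigma * mu_t[:-1, :],
                mu + coeffs.sigma * mu_t[1:, :], w)
            mu_w_ns = _harmonic(
                mu + coeffs.sigma * mu_t[:, :-1],
                mu + coeffs.sigma * mu_t[:, 1:], wn)
            mu_t_floor = np.maximum(mu_t, 1e-10 * mu)
            Pw = coeffs.alpha * rho * Pk / mu_t_floor
            gom = disc.grad(omega, inlet=np.full(nj, om_in))
            cw = _assemble_transport(
                disc, omega, gom, mu_w_ew, mu_w_ns, Few, Fns,
                inlet_value=om_in,
                extra_diag=2.0 * coeffs.beta * rho * om_old * vol,
                source=(Pw + coeffs.beta * rho * om_old**2) * vol,
                inlet_mu=mu + coeffs.sigma * mu_t[0, :], wall_mu=mu_wall,
            )
            # wall-adjacent omega fixed to the smooth-wall asymptote
            aP_, aE_, aW_, aN_, aS_, b_ = cw
            big = 1.0e30
            aP_[:, -1] += big
            b_[:, -1] += big * omega_wall
            omega, _ = _solve_relaxed(
                disc, (aP_, aE_, aW_, aN_, aS_, b_), om_old, settings.relax_turb
            )
            n_neg = int(np.sum(omega <= 0.0))
            if n_neg:
                clip_events += n_neg
            omega = np.maximum(omega, 1e-4)
            mu_t_new = np.minimum(rho * k / omega, 5.0e4 * mu)
            mu_t = (
                settings.relax_turb * mu_t_new
                + (1.0 - settings.relax_turb) * mu_t
            )

        # ---- convergence bookkeeping
        if not (
            np.all(np.isfinite(u)) and np.all(np.isfinite(v))
            and np.all(np.isfinite(p)) and np.all(np.isfinite(k))
            and np.all(np.isfinite(omega))
        ):
            raise DivergenceError(
                f"non-finite field value at iteration {it}", iteration=it
            )
        changes = {
            "u": np.max(np.abs(u - u_old)) / (np.max(np.abs(u)) + 1e-3 * scales["u"]),
            "v": np.max(np.abs(v - v_old)) / (np.max(np.abs(v)) + 1e-3 * scales["u"]),
            "p": np.max(np.abs(p - p_old)) / (np.max(np.abs(p)) + 1e-3 * scales["p"]),
        }
        if turbulent:
            changes["k"] = np.max(np.abs(k - k_old)) / (np.max(np.abs(k)) + 1e-3 * scales["k"])
            changes["omega"] = np.max(np.abs(omega - om_old)) / (
                np.max(np.abs(omega)) + 1e-3 * scales["omega"]
            )
        rec = {"iteration": it, **{f"d_{n}": float(c) for n, c in changes.items()}}
        rec["mass_imbalance"] = float(np.sum(np.abs(imb)) / (rho * Q))
        history.append(rec)

        if max(changes.values()) < settings.convergence_tol:
            hits += 1
        else:
            hits = 0
        if hits >= settings.n_consecutive and it >= settings.min_iterations:
            state.converged = True
            state.iterations = it
            break
    else:
        state.iterations = settings.max_iterations
        state.u, state.v, state.p = u, v, p
        state.k, state.omega, state.mu_t = k, omega, mu_t
        state.history = history
        raise ConvergenceError(
            f"no convergence in {settings.max_iterations} iterations "
            f"(last changes: {history[-1]})",
            history=history,
        )

    state.u, state.v, state.p = u, v, p
    state.k, state.omega, state.mu_t = k, omega, mu_t
    state.Few, state.Fns = Few, Fns
    state.history = history
    state.clip_events = clip_events
    return state


def reynolds_stress(state: FlowState, mesh: StructuredMesh | None = None):
    """Boussinesq Reynolds-stress tensor components.

    tau_ij = 2 mu_t S_ij - (2/3) rho k delta_ij with S_ij the mean
    strain-rate tensor; returns a dict of the axisymmetric components
    (xx, rr, tt, xr) as cell arrays.
    """
    mesh = mesh or state.mesh
    disc = _Disc(mesh)
    gu = disc.grad(state.u, wall=np.zeros(mesh.ni))
    gv = disc.grad(state.v, wall=np.zeros(mesh.ni))
    rho = state.fluid.rho
    iso = (2.0 / 3.0) * rho * state.k
    Sxx, Srr = gu[0], gv[1]
    Stt = state.v / mesh.rc
    Sxr = 0.5 * (gu[1] + gv[0])
    return {
        "xx": 2.0 * state.mu_t * Sxx - iso,
        "rr": 2.0 * state.mu_t * Srr - iso,
        "tt": 2.0 * state.mu_t * Stt - iso,
        "xr": 2.0 * state.mu_t * Sxr,
    }
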