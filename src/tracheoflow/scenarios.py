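"""Programmatic construction of every study case - no downloads, no files.

The reference patient scenario is an infant trachea carrying two stenoses of
severity 68.7% (S1, proximal) and 86.5% (S2, distal), ventilated with a
constant 3 L/min volume-controlled inflow of humidified air
(rho = 1.161 kg/m^3, mu = 1.864e-5 kg/(m s)).  The four surgical variants are

    M1 = untouched, M2 = S1 corrected, M3 = S2 corrected, M4 = both.

Geometric quantities the clinical description does not pin down (healthy
caliber, stenosis placement and length) carry explicit synthetic-default
provenance so they cannot be mistaken for patient measurements: reference
diameter 6 mm (typical 5-month infant), S1 centred at one third of the
tracheal length, S2 in the distal third, each extent 20% of the length (the
stenotic region jointly covering 40% > 30% of the trachea).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import (
    AxisymmetricProfile,
    StenosisSpec,
    SurgicalScheme,
    apply_scheme,
    apply_stenosis,
    extend_domain,
    scheme_label,
    straight_profile,
)
from .meshgen import MeshParams
from .solver import BoundaryConditions, FluidProperties, SolverSettings

__all__ = ["CaseSpec", "make_patient_like_suite", "make_validation_suite",
           "PATIENT_DEFAULTS"]

#: Study-condition defaults with provenance: "reference-case" values come from
#: the clinical description, "synthetic-default" values are this package's
#: documented stand-ins for unreported geometry.
PATIENT_DEFAULTS = {
    "severity_S1": (0.687, "reference-case"),
    "severity_S2": (0.865, "reference-case"),
    "flow_lpm": (3.0, "reference-case"),
    "rho": (1.161, "reference-case"),
    "mu": (1.864e-5, "reference-case"),
    "inlet_extension_diameters": (20.0, "reference-case"),
    "outlet_extension_diameters": (40.0, "reference-case"),
    "tracheal_length_m": (0.045, "synthetic-default"),
    "reference_radius_m": (0.003, "synthetic-default"),
    "s1_center_frac": (1.0 / 3.0, "synthetic-default"),
    "s2_center_frac": (0.7333333333333333, "synthetic-default"),
    "stenosis_length_frac": (0.20, "synthetic-default"),
}


@dataclass(frozen=True)
class CaseSpec:
    """Complete, reproducible description of one simulation case."""

    label: str
    tracheal_length: float
    reference_radius: float
    stenoses: tuple = ()
    scheme: SurgicalScheme = field(default_factory=SurgicalScheme)
    inlet_extension: float = 20.0     # x diameter
    outlet_extension: float = 40.0
    bc: BoundaryConditions = field(default_factory=BoundaryConditions)
    fluid: FluidProperties = field(default_factory=FluidProperties)
    mesh: MeshParams = field(default_factory=MeshParams)
    settings: SolverSettings = field(default_factory=SolverSettings)
    seed: int = 0

    def build_profile(self) -> AxisymmetricProfile:
        """Anatomy -> stenoses -> surgical corrections -> extensions."""
        prof = straight_profile(self.tracheal_length, self.reference_radius)
        for sp in self.stenoses:
            prof = apply_stenosis(prof, sp)
        prof = apply_scheme(prof, self.scheme)
        return extend_domain(prof, self.inlet_extension, self.outlet_extension)

    def to_config(self) -> dict:
        """Plain-data dump (YAML-ready) with provenance flags."""
        prov = {k: v[1] for k, v in PATIENT_DEFAULTS.items()}
        return {
            "label": self.label,
            "geometry": {
                "tracheal_length_m": self.tracheal_length,
                "reference_radius_m": self.reference_radius,
                "stenoses": [
                    {
                        "id": sp.id, "center_m": sp.center, "length_m": sp.length,
                        "severity": sp.severity, "shape": sp.shape,
                    }
                    for sp in self.stenoses
                ],
                "corrected": sorted(self.scheme.corrected),
                "inlet_extension_diameters": self.inlet_extension,
                "outlet_extension_diameters": self.outlet_extension,
            },
            "fluid": {"rho_kg_m3": self.fluid.rho, "mu_kg_ms": self.fluid.mu},
            "boundary_conditions": {
                "inlet_flow_L_min": self.bc.inlet_flow_lpm,
                "outlet_gauge_Pa": self.bc.outlet_pressure,
                "inlet_turbulence_intensity": self.bc.inlet_turbulence_intensity,
                "inlet_turbulence_length_frac": self.bc.inlet_turbulence_length_frac,
                "inlet_profile": self.bc.inlet_profile,
            },
            "mesh": {
                "n_axial": self.mesh.n_axial, "n_radial": self.mesh.n_radial,
                "first_layer_height_m": self.mesh.first_layer_height,
                "growth_ratio": self.mesh.growth_ratio,
                "n_bl_layers": self.mesh.n_bl_layers,
            },
            "solver": {
                "convergence_tol": self.settings.convergence_tol,
                "max_iterations": self.settings.max_iterations,
                "laminar_mode": self.settings.laminar_mode,
            },
            "seed": self.seed,
            "provenance": prov,
        }


def _patient_stenoses(L: float) -> tuple:
    lfrac = PATIENT_DEFAULTS["stenosis_length_frac"][0]
    return (
        StenosisSpec(
            "S1",
            center=PATIENT_DEFAULTS["s1_center_frac"][0] * L,
            length=lfrac * L,
            severity=PATIENT_DEFAULTS["severity_S1"][0],
        ),
        StenosisSpec(
            "S2",
            center=PATIENT_DEFAULTS["s2_center_frac"][0] * L,
            length=lfrac * L,
            severity=PATIENT_DEFAULTS["severity_S2"][0],
        ),
    )


def make_patient_like_suite(overrides: dict | None = None, seed: int = 0):
    """The four surgical-scheme cases M1-M4 on the patient-like anatomy.

    ``overrides`` may replace any of: tracheal_length, reference_radius,
    mesh (MeshParams), bc, fluid, settings.  Severities, flow and fluid
    default to the reference-case values.
    """
    ov = dict(overrides or {})
    L = ov.pop("tracheal_length", PATIENT_DEFAULTS["tracheal_length_m"][0])
    R0 = ov.pop("reference_radius", PATIENT_DEFAULTS["reference_radius_m"][0])
    mesh = ov.pop("mesh", MeshParams())
    bc = ov.pop("bc", BoundaryConditions(
        inlet_flow_lpm=PATIENT_DEFAULTS["flow_lpm"][0]))
    fluid = ov.pop("fluid", FluidProperties(
        rho=PATIENT_DEFAULTS["rho"][0], mu=PATIENT_DEFAULTS["mu"][0]))
    settings = ov.pop("settings", SolverSettings())
    if ov:
        raise ValueError(f"unknown overrides: {sorted(ov)}")
    stenoses = _patient_stenoses(L)
    if stenoses[0].end >= stenoses[1].start:
        raise ValueError("stenoses overlap under these geometric parameters")
    suite = []
    for corrected in ((), ("S1",), ("S2",), ("S1", "S2")):
        scheme = SurgicalScheme(corrected)
        suite.append(
            CaseSpec(
                label=scheme_label(scheme),
                tracheal_length=L,
                reference_radius=R0,
                stenoses=stenoses,
                scheme=scheme,
                inlet_extension=PATIENT_DEFAULTS["inlet_extension_diameters"][0],
                outlet_extension=PATIENT_DEFAULTS["outlet_extension_diameters"][0],
                bc=bc, fluid=fluid, mesh=mesh, settings=settings, seed=seed,
            )
        )
    return suite


def make_validation_suite(seed: int = 0):
    """Analytic and benchmark fixtures exercised by the test-suite.

    Returns a dict of named CaseSpec records:

    * ``poiseuille``    - laminar straight pipe, D = 3 mm, L = 0.1 m,
      Q = 1 L/min, parabolic (developed) inflow; oracle: Hagen-Poiseuille.
    * ``stokes_scaling``- low-flow laminar pipe for the dP-linearity check.
    * ``severity_sweep``- single stenosis, r in {0.3, 0.5, 0.7, 0.865}.
    * ``turbulent_pipe``- straight pipe at Re = 1e4; oracle: Blasius.
    """
    fluid = FluidProperties()
    lam = SolverSettings(laminar_mode=True)

    poiseuille = CaseSpec(
        label="poiseuille",
        tracheal_length=0.1, reference_radius=0.0015,
        inlet_extension=0.0, outlet_extension=0.0,
        bc=BoundaryConditions(inlet_flow_lpm=1.0, inlet_profile="parabolic"),
        fluid=fluid,
        mesh=MeshParams(n_axial=24, n_radial=8, first_layer_height=0.0015 / 9,
                        growth_ratio=1.1, n_bl_layers=1),
        settings=replace(lam, convergence_tol=1e-7),
        seed=seed,
    )
    stokes = replace(
        poiseuille, label="stokes_scaling",
        bc=BoundaryConditions(inlet_flow_lpm=0.05, inlet_profile="parabolic"),
    )

    L = PATIENT_DEFAULTS["tracheal_length_m"][0]
    R0 = PATIENT_DEFAULTS["reference_radius_m"][0]
    sweep = []
    for r in (0.3, 0.5, 0.7, 0.865):
        sweep.append(
            CaseSpec(
                label=f"sweep_r{r:g}",
                tracheal_length=L, reference_radius=R0,
                stenoses=(StenosisSpec("S1", center=L / 2, length=0.2 * L,
                                       severity=r),),
                inlet_extension=20.0, outlet_extension=40.0,
                bc=BoundaryConditions(inlet_flow_lpm=3.0),
                fluid=fluid,
                mesh=MeshParams(n_axial=160, n_radial=28,
                                first_layer_height=1e-5,
                                growth_ratio=1.2, n_bl_layers=6),
                seed=seed,
            )
        )

    Re = 1.0e4
    D = 0.006
    U = Re * fluid.mu / (fluid.rho * D)
    turb = CaseSpec(
        label="turbulent_pipe",
        tracheal_length=60.0 * D, reference_radius=D / 2,
        inlet_extension=0.0, outlet_extension=0.0,
        bc=BoundaryConditions(inlet_flow_lpm=U * np.pi * (D / 2) ** 2 * 60000.0),
        fluid=fluid,
        mesh=MeshParams(n_axial=120, n_radial=36, first_layer_height=4e-6,
                        growth_ratio=1.2, n_bl_layers=10),
        seed=seed,
    )
    return {
        "poiseuille": poiseuille,
        "stokes_scaling": stokes,
        "severity_sweep": sweep,
        "turbulent_pipe": turb,
    }
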