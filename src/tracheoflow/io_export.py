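"""Plain-text exchange formats: legacy VTK, STL, YAML case configs.

The structured-grid writer targets the legacy ASCII VTK dialect readable by
ParaView/VisIt; the revolved lumen surface can be exported as ASCII or
binary STL for CAD round-trips.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import yaml

from .geometry import AxisymmetricProfile
from .meshgen import StructuredMesh
from .solver import FlowState

__all__ = ["write_vtk", "write_stl", "write_config", "read_config"]


def write_vtk(path, mesh: StructuredMesh, state: FlowState | None = None) -> None:
    """Legacy ASCII VTK structured grid, optionally with the flow fields.

    The axisymmetric (x, r) lattice is written as a flat z = 0 sheet; cell
    fields are attached as point data on cell centroids is not possible in
    this dialect, so fields are emitted as CELL_DATA.
    """
    ni, nj = mesh.ni, mesh.nj
    lines = [
        "# vtk DataFile Version 3.0",
        "axisymmetric airway grid",
        "ASCII",
        "DATASET STRUCTURED_GRID",
        f"DIMENSIONS {ni + 1} {nj + 1} 1",
        f"POINTS {(ni + 1) * (nj + 1)} float",
    ]
    for j in range(nj + 1):
        for i in range(ni + 1):
            lines.append(f"{mesh.xn[i]:.9g} {mesh.rn[i, j]:.9g} 0")
    if state is not None:
        fields = {
            "u": state.u, "v": state.v, "p": state.p,
            "k": state.k, "omega": state.omega, "mu_t": state.mu_t,
        }
        lines.append(f"CELL_DATA {ni * nj}")
        for name, arr in fields.items():
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            # VTK cell ordering: i fastest, then j
            lines.extend(f"{arr[i, j]:.9g}" for j in range(nj) for i in range(ni))
    Path(path).write_text("\n".join(lines) + "\n")


def _revolve(profile: AxisymmetricProfile, n_theta: int):
    s, R = profile.s, profile.R
    th = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    tris = []
    for i in range(len(s) - 1):
        for t in range(n_theta):
            t2 = (t + 1) % n_theta
            a = (s[i], R[i] * np.cos(th[t]), R[i] * np.sin(th[t]))
            b = (s[i + 1], R[i + 1] * np.cos(th[t]), R[i + 1] * np.sin(th[t]))
            c = (s[i + 1], R[i + 1] * np.cos(th[t2]), R[i + 1] * np.sin(th[t2]))
            d = (s[i], R[i] * np.cos(th[t2]), R[i] * np.sin(th[t2]))
            tris.append((a, b, c))
            tris.append((a, c, d))
    return tris


def write_stl(path, profile: AxisymmetricProfile, n_theta: int = 48,
              ascii_dialect: bool = True, decimate: int = 8) -> None:
    """Revolved lumen surface as STL (ascii by default, binary on request).

    ``decimate`` keeps every n-th axial sample to bound the triangle count.
    """
    prof = profile
    if decimate > 1 and profile.s.size > 2 * decimate:
        idx = np.unique(np.r_[np.arange(0, profile.s.size, decimate),
                              profile.s.size - 1])
        from dataclasses import replace
        prof = replace(profile, s=profile.s[idx], R=profile.R[idx])
    tris = _revolve(prof, n_theta)
    path = Path(path)
    if ascii_dialect:
        out = ["solid lumen"]
        for a, b, c in tris:
            n = np.cross(np.subtract(b, a), np.subtract(c, a))
            nn = np.linalg.norm(n)
            n = n / nn if nn > 0 else n
            out.append(f" facet normal {n[0]:.6e} {n[1]:.6e} {n[2]:.6e}")
            out.append("  outer loop")
            for v in (a, b, c):
                out.append(f"   vertex {v[0]:.6e} {v[1]:.6e} {v[2]:.6e}")
            out.append("  endloop")
            out.append(" endfacet")
        out.append("endsolid lumen")
        path.write_text("\n".join(out) + "\n")
    else:
        with open(path, "wb") as fh:
            fh.write(b"\0" * 80)
            fh.write(struct.pack("<I", len(tris)))
            for a, b, c in tris:
                n = np.cross(np.subtract(b, a), np.subtract(c, a))
                nn = np.linalg.norm(n)
                n = n / nn if nn > 0 else n
                fh.write(struct.pack("<3f", *n))
                for v in (a, b, c):
                    fh.write(struct.pack("<3f", *v))
                fh.write(struct.pack("<H", 0))


def write_config(path, case_or_cases) -> None:
    """Case configuration(s) as YAML (SI units, provenance flags included)."""
    if isinstance(case_or_cases, (list, tuple)):
        doc = {"cases": [c.to_config() for c in case_or_cases]}
    else:
        doc = {"cases": [case_or_cases.to_config()]}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_config(path) -> list:
    """Parse a YAML config back into CaseSpec records."""
    from .geometry import StenosisSpec, SurgicalScheme
    from .meshgen import MeshParams
    from .scenarios import CaseSpec
    from .solver import BoundaryConditions, FluidProperties, SolverSettings

    doc = yaml.safe_load(Path(path).read_text())
    cases = []
    for c in doc["cases"]:
        g, f, b, m, s = (c["geometry"], c["fluid"], c["boundary_conditions"],
                         c["mesh"], c["solver"])
        cases.append(
            CaseSpec(
                label=c["label"],
                tracheal_length=g["tracheal_length_m"],
                reference_radius=g["reference_radius_m"],
                stenoses=tuple(
                    StenosisSpec(sp["id"], sp["center_m"], sp["length_m"],
                                 sp["severity"], sp.get("shape", "cosine"))
                    for sp in g["stenoses"]
                ),
                scheme=SurgicalScheme(g.get("corrected", [])),
                inlet_extension=g["inlet_extension_diameters"],
                outlet_extension=g["outlet_extension_diameters"],
                bc=BoundaryConditions(
                    inlet_flow_lpm=b["inlet_flow_L_min"],
                    inlet_turbulence_intensity=b["inlet_turbulence_intensity"],
                    inlet_turbulence_length_frac=b["inlet_turbulence_length_frac"],
                    inlet_profile=b.get("inlet_profile", "plug"),
                ),
                fluid=FluidProperties(rho=f["rho_kg_m3"], mu=f["mu_kg_ms"]),
                mesh=MeshParams(
                    n_axial=m["n_axial"], n_radial=m["n_radial"],
                    first_layer_height=m["first_layer_height_m"],
                    growth_ratio=m["growth_ratio"],
                    n_bl_layers=m["n_bl_layers"],
                ),
                settings=SolverSettings(
                    convergence_tol=s["convergence_tol"],
                    max_iterations=s["max_iterations"],
                    laminar_mode=s["laminar_mode"],
                ),
                seed=c.get("seed", 0),
            )
        )
    return cases
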