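"""Structured axisymmetric finite-volume grids with wall boundary layers.

A grid is an (n_axial) x (n_radial) lattice of quadrilateral cells in the
(x, r) half-plane; revolving each quad about the axis gives the actual
finite volume (Pappus).  Radial lines are vertical, the outermost grid line
follows the lumen wall R(x), and the wall-adjacent spacing follows the
first-layer-height / growth-ratio prescription used for boundary-layer
(prism) meshing, so near-wall gradients (hence WSS) are resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import AxisymmetricProfile

__all__ = ["MeshParams", "StructuredMesh", "build_mesh", "refine", "MeshError"]


class MeshError(ValueError):
    pass


@dataclass(frozen=True)
class MeshParams:
    """Grid-resolution controls.

    first_layer_height is the wall-adjacent radial cell thickness (m);
    successive boundary-layer cells grow by growth_ratio for n_bl_layers
    layers, then the interior is graded smoothly to the axis.
    """

    n_axial: int = 160
    n_radial: int = 28
    first_layer_height: float = 1.0e-5
    growth_ratio: float = 1.2
    n_bl_layers: int = 3

    def __post_init__(self) -> None:
        if self.n_axial < 4 or self.n_radial < 4:
            raise MeshError("cell counts must be >= 4")
        if self.first_layer_height <= 0:
            raise MeshError("first_layer_height must be positive")
        if self.growth_ratio < 1.0:
            raise MeshError("growth_ratio must be >= 1")
        if self.n_bl_layers < 1:
            raise MeshError("n_bl_layers must be >= 1")
        if self.n_radial < self.n_bl_layers + 3:
            raise MeshError("n_radial must exceed n_bl_layers + 2")


def refine(params: MeshParams, factor: int) -> MeshParams:
    """Uniform refinement: counts x factor, first layer / factor."""
    if int(factor) != factor or factor < 2:
        raise MeshError(f"refinement factor must be an integer >= 2, got {factor}")
    factor = int(factor)
    return replace(
        params,
        n_axial=params.n_axial * factor,
        n_radial=params.n_radial * factor,
        first_layer_height=params.first_layer_height / factor,
    )


@dataclass
class StructuredMesh:
    """Axisymmetric structured grid plus precomputed FV geometry.

    Nodes: xn (ni+1,), rn (ni+1, nj+1); j=0 is the axis (r=0), j=nj the wall.
    Faces: "ew" faces are the vertical annuli at the xn planes (normal +x),
    "ns" faces connect consecutive stations along a j grid line (normal +j).
    All areas/volumes include the full 2*pi revolution.
    """

    xn: np.ndarray
    rn: np.ndarray
    profile: AxisymmetricProfile
    params: MeshParams

    def __post_init__(self) -> None:
        xn, rn = self.xn, self.rn
        self.ni = xn.size - 1
        self.nj = rn.shape[1] - 1
        ni, nj = self.ni, self.nj

        # cell centroids and volumes via Pappus on each quad
        x4 = np.stack(
            [
                np.repeat(xn[:-1, None], nj, axis=1),
                np.repeat(xn[1:, None], nj, axis=1),
                np.repeat(xn[1:, None], nj, axis=1),
                np.repeat(xn[:-1, None], nj, axis=1),
            ]
        )  # (4, ni, nj): i,j -> i+1,j -> i+1,j+1 -> i,j+1
        r4 = np.stack([rn[:-1, :-1], rn[1:, :-1], rn[1:, 1:], rn[:-1, 1:]])
        x_n = np.roll(x4, -1, axis=0)
        r_n = np.roll(r4, -1, axis=0)
        cross = x4 * r_n - x_n * r4
        area2 = np.sum(cross, axis=0)  # 2*A, positive for CCW
        A = 0.5 * area2
        if np.any(A <= 0):
            raise MeshError("degenerate quad with non-positive planar area")
        cx = np.sum((x4 + x_n) * cross, axis=0) / (3.0 * area2)
        cr = np.sum((r4 + r_n) * cross, axis=0) / (3.0 * area2)
        self.xc, self.rc = cx, cr
        self.vol = 2.0 * np.pi * cr * A
        if np.any(self.vol <= 0):
            raise MeshError("non-positive cell volume")

        # east-west faces (vertical annuli at each xn plane): (ni+1, nj)
        self.Sx_ew = np.pi * (rn[:, 1:] ** 2 - rn[:, :-1] ** 2)
        self.rf_ew = 0.5 * (rn[:, 1:] + rn[:, :-1])

        # north-south faces along j grid lines: (ni, nj+1)
        dx = np.diff(xn)[:, None]
        dr = rn[1:, :] - rn[:-1, :]
        rbar = 0.5 * (rn[1:, :] + rn[:-1, :])
        self.Sx_ns = 2.0 * np.pi * rbar * (-dr)
        self.Sr_ns = 2.0 * np.pi * rbar * dx
        self.xf_ns = 0.5 * (xn[1:] + xn[:-1])[:, None] + np.zeros_like(rbar)
        self.rf_ns = rbar

        # wall patch geometry (j = nj line)
        wx = self.xf_ns[:, nj]
        wr = rbar[:, nj]
        tx, tr = dx[:, 0], dr[:, nj]
        tl = np.hypot(tx, tr)
        self.wall_tangent = np.stack([tx / tl, tr / tl], axis=1)  # (ni, 2)
        self.wall_center = np.stack([wx, wr], axis=1)
        Sw = np.stack([self.Sx_ns[:, nj], self.Sr_ns[:, nj]], axis=1)
        self.wall_area = np.linalg.norm(Sw, axis=1)
        nhat = Sw / self.wall_area[:, None]
        self.wall_normal = nhat  # outward
        # perpendicular distance from first-cell centroid to the wall face
        dvec = np.stack([self.xc[:, nj - 1] - wx, self.rc[:, nj - 1] - wr], axis=1)
        self.wall_dist = np.abs(np.sum(dvec * nhat, axis=1))

        self._quality = None

    # -- convenience -----------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.ni * self.nj

    def total_volume(self) -> float:
        return float(np.sum(self.vol))

    def anatomical_column_mask(self) -> np.ndarray:
        a0, a1 = self.profile.anatomical
        return (self.xc[:, 0] >= a0 - 1e-12) & (self.xc[:, 0] <= a1 + 1e-12)

    def quality_report(self) -> dict:
        """Aspect ratios, size jumps, wall spacing; flags rather than errors."""
        if self._quality is None:
            dxc = np.diff(self.xn)
            drc = self.rn[:, 1:] - self.rn[:, :-1]
            dr_cell = 0.5 * (drc[1:, :] + drc[:-1, :])
            aspect = np.maximum(dxc[:, None] / dr_cell, dr_cell / dxc[:, None])
            jump_ax = dxc[1:] / dxc[:-1]
            jump_ax = np.maximum(jump_ax, 1.0 / jump_ax)
            jump_rad = dr_cell[:, 1:] / dr_cell[:, :-1]
            jump_rad = np.maximum(jump_rad, 1.0 / jump_rad)
            self._quality = {
                "n_cells": self.n_cells,
                "min_volume_m3": float(np.min(self.vol)),
                "max_aspect_ratio": float(np.max(aspect)),
                "max_axial_size_jump": float(np.max(jump_ax)) if jump_ax.size else 1.0,
                "max_radial_size_jump": float(np.max(jump_rad)),
                "wall_first_layer_m": float(np.mean(self.rn[:, -1] - self.rn[:, -2])),
                "flag_high_aspect": bool(np.max(aspect) > 2000.0),
                "flag_large_jump": bool(np.max(jump_rad) > 3.0),
            }
        return self._quality


# ---------------------------------------------------------------------------
# axial / radial point distributions


def _geometric_ratio(d0: float, L: float, n: int) -> float:
    """Ratio q with sum_{k=0}^{n-1} d0 q^k = L (q in (0.2, 5)); 1 if degenerate."""
    if n <= 0:
        raise MeshError("need at least one cell in a graded run")
    if abs(n * d0 - L) < 1e-14 * L:
        return 1.0

    from scipy.optimize import brentq

    def f(q):
        return d0 * (q**n - 1.0) / (q - 1.0) - L

    lo, hi = 0.2, 5.0
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:  # cannot fit with a sane ratio; fall back to uniform
        return 1.0
    return brentq(f, lo, hi, xtol=1e-14)


def _graded_spacings(d0: float, L: float, n: int) -> np.ndarray:
    q = _geometric_ratio(d0, L, n)
    if q == 1.0:
        return np.full(n, L / n)
    d = d0 * q ** np.arange(n)
    return d * (L / d.sum())  # exact closure


def _axial_nodes(profile: AxisymmetricProfile, n_axial: int) -> np.ndarray:
    """Distribute axial stations: uniform over the anatomy, graded extensions."""
    lo, hi = profile.extent
    a0, a1 = profile.anatomical
    L_in, L_an, L_out = a0 - lo, a1 - a0, hi - a1
    if L_in <= 1e-12 and L_out <= 1e-12:
        return np.linspace(lo, hi, n_axial + 1)
    # cell budget: anatomy gets the bulk; extensions share by sqrt(length)
    w_in = 0.9 * np.sqrt(L_in / L_an) if L_in > 0 else 0.0
    w_out = 0.9 * np.sqrt(L_out / L_an) if L_out > 0 else 0.0
    n_in = int(round(n_axial * w_in / (1.0 + w_in + w_out)))
    n_out = int(round(n_axial * w_out / (1.0 + w_in + w_out)))
    n_in = max(n_in, 4) if L_in > 0 else 0
    n_out = max(n_out, 4) if L_out > 0 else 0
    n_an = n_axial - n_in - n_out
    if n_an < 8:
        raise MeshError("n_axial too small for the requested extensions")
    dx_an = L_an / n_an
    nodes = [np.linspace(a0, a1, n_an + 1)]
    if n_in:
        d = _graded_spacings(dx_an, L_in, n_in)[::-1]  # grow away from anatomy
        nodes.insert(0, a0 - np.concatenate([[L_in], L_in - np.cumsum(d)[:-1]]))
    if n_out:
        d = _graded_spacings(dx_an, L_out, n_out)
        nodes.append(a1 + np.cumsum(d))
    return np.concatenate(nodes)


def _radial_nodes(R_local: float, params: MeshParams, x_station: float) -> np.ndarray:
    """Node radii 0..R at one station: BL stack at the wall, graded interior."""
    h, g, nbl = params.first_layer_height, params.growth_ratio, params.n_bl_layers
    bl = h * g ** np.arange(nbl)  # thickness of layer 1..nbl from the wall
    t_bl = bl.sum()
    if t_bl > 0.6 * R_local:
        raise MeshError(
            f"boundary-layer stack ({t_bl:.3e} m) exceeds 60% of the local "
            f"radius ({R_local:.3e} m) at axial station x={x_station:.5f} m"
        )
    n_in = params.n_radial - nbl
    L_in = R_local - t_bl
    d_edge = bl[-1] * g  # continue the growth into the interior
    d_in = _graded_spacings(d_edge, L_in, n_in)
    # offsets from the wall inward: BL first, then interior down to the axis
    off = np.concatenate([[0.0], np.cumsum(np.concatenate([bl, d_in]))])
    r = R_local - off
    r[-1] = 0.0
    return r[::-1].copy()  # ascending from the axis to the wall


def build_mesh(profile: AxisymmetricProfile, params: MeshParams) -> StructuredMesh:
    """Body-fitted structured grid conforming to R(s) with wall clustering."""
    xn = _axial_nodes(profile, params.n_axial)
    Rw = profile.radius_at(xn)
    rn = np.empty((xn.size, params.n_radial + 1))
    for i, (x, R_loc) in enumerate(zip(xn, Rw)):
        rn[i] = _radial_nodes(float(R_loc), params, float(x))
    return StructuredMesh(xn=xn, rn=rn, profile=profile, params=params)
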