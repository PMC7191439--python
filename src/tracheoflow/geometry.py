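"""Parametric axisymmetric airway lumen geometry.

The patient trachea is represented as a body of revolution: a lumen radius
``R(s)`` sampled along the axial (arc-length) coordinate ``s``.  Stenoses are
smooth raised-cosine constrictions whose depth is set from the target
cross-sectional severity

    r = (S_TE - S_SP) / S_TE * 100%

with ``S_TE`` the tracheal-entrance area and ``S_SP`` the minimal area inside
the stenotic extent.  Virtual surgical correction restores the affected extent
to the reference caliber while leaving other stenoses untouched, which is how
the four surgical-scheme variants M1-M4 are produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "StenosisSpec",
    "SurgicalScheme",
    "AxisymmetricProfile",
    "straight_profile",
    "apply_stenosis",
    "correct_stenosis",
    "extend_domain",
    "cross_section_area",
    "stenosis_ratio",
    "scheme_label",
    "SCHEME_LABELS",
]


class GeometryError(ValueError):
    """Invalid geometric request (overlap, out-of-range, unknown id)."""


@dataclass(frozen=True)
class StenosisSpec:
    """A single smooth axisymmetric constriction.

    severity is the target fractional area reduction relative to the
    entrance section (0 <= severity < 1); shape currently supports the
    C1-smooth "cosine" bump family.
    """

    id: str
    center: float          # axial position of the throat (m)
    length: float          # axial extent of the constriction (m)
    severity: float        # fractional area reduction, 0 <= r < 1
    shape: str = "cosine"

    def __post_init__(self) -> None:
        if not (0.0 <= self.severity < 1.0):
            raise GeometryError(f"severity must be in [0, 1), got {self.severity}")
        if self.length <= 0:
            raise GeometryError(f"length must be positive, got {self.length}")
        if self.shape != "cosine":
            raise GeometryError(f"unknown stenosis shape {self.shape!r}")

    @property
    def start(self) -> float:
        return self.center - 0.5 * self.length

    @property
    def end(self) -> float:
        return self.center + 0.5 * self.length


@dataclass(frozen=True)
class SurgicalScheme:
    """Subset of stenosis ids virtually corrected (restored to caliber)."""

    corrected: frozenset[str] = frozenset()

    def __init__(self, corrected=()) -> None:
        object.__setattr__(self, "corrected", frozenset(corrected))


#: Bijection between the four subsets of {S1, S2} and the model labels.
SCHEME_LABELS: dict[frozenset, str] = {
    frozenset(): "M1",
    frozenset({"S1"}): "M2",
    frozenset({"S2"}): "M3",
    frozenset({"S1", "S2"}): "M4",
}


def scheme_label(scheme: SurgicalScheme) -> str:
    try:
        return SCHEME_LABELS[scheme.corrected]
    except KeyError:
        raise GeometryError(
            f"scheme {set(scheme.corrected)} has no M1-M4 label"
        ) from None


@dataclass(frozen=True)
class AxisymmetricProfile:
    """Arc-length-sampled lumen radius; the stand-in for a reconstructed airway.

    ``s`` is strictly increasing (m); ``R`` the lumen radius at each sample
    (m, positive).  ``stenoses`` are all specs ever applied; ids listed in
    ``corrected`` are surgically restored and no longer shape the lumen but
    remain queryable (their ratio evaluates to ~0).  ``anatomical`` marks the
    axial span of the real anatomy; straight inlet/outlet extensions added for
    flow development lie outside it and are excluded from metric evaluation.
    """

    s: np.ndarray
    R: np.ndarray
    reference_radius: float
    stenoses: tuple[StenosisSpec, ...] = ()
    corrected: frozenset[str] = frozenset()
    anatomical: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        s = np.asarray(self.s, dtype=float)
        R = np.asarray(self.R, dtype=float)
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "R", R)
        if s.ndim != 1 or s.shape != R.shape or s.size < 2:
            raise GeometryError("s and R must be matching 1-D arrays (>= 2 samples)")
        if not np.all(np.diff(s) > 0):
            raise GeometryError("arc-length samples must be strictly increasing")
        if not np.all(R > 0):
            raise GeometryError("lumen radius must be positive everywhere")
        if self.reference_radius <= 0:
            raise GeometryError("reference radius must be positive")

    # -- queries ---------------------------------------------------------

    @property
    def extent(self) -> tuple[float, float]:
        return float(self.s[0]), float(self.s[-1])

    def radius_at(self, s):
        """Linear interpolation of the lumen radius; scalar or array ``s``."""
        lo, hi = self.extent
        s_arr = np.asarray(s, dtype=float)
        if np.any(s_arr < lo - 1e-12) or np.any(s_arr > hi + 1e-12):
            raise GeometryError(f"position {s} outside profile extent [{lo}, {hi}]")
        out = np.interp(s_arr, self.s, self.R)
        return float(out) if np.isscalar(s) or s_arr.ndim == 0 else out

    def active_stenoses(self) -> tuple[StenosisSpec, ...]:
        return tuple(sp for sp in self.stenoses if sp.id not in self.corrected)

    def stenosis(self, stenosis_id: str) -> StenosisSpec:
        for sp in self.stenoses:
            if sp.id == stenosis_id:
                return sp
        raise GeometryError(f"unknown stenosis id {stenosis_id!r}")

    def entrance_area(self) -> float:
        """Cross-sectional area at the anatomical (tracheal) entrance."""
        return cross_section_area(self, self.anatomical[0])


# ---------------------------------------------------------------------------
# construction


def straight_profile(
    length: float,
    radius: float,
    n_samples: int = 1201,
) -> AxisymmetricProfile:
    """Uniform-caliber anatomical segment on s in [0, length]."""
    if length <= 0 or radius <= 0:
        raise GeometryError("length and radius must be positive")
    s = np.linspace(0.0, length, n_samples)
    R = np.full_like(s, float(radius))
    return AxisymmetricProfile(
        s=s, R=R, reference_radius=float(radius), anatomical=(0.0, length)
    )


def _cosine_bump(s: np.ndarray, spec: StenosisSpec) -> np.ndarray:
    """Unit-amplitude C1 bump: 1 at the throat, 0 outside the extent."""
    xi = (s - spec.center) / spec.length  # -0.5 .. 0.5 inside
    bump = np.where(np.abs(xi) < 0.5, 0.5 * (1.0 + np.cos(2.0 * np.pi * xi)), 0.0)
    return bump


def _rebuild_radius(profile: AxisymmetricProfile) -> np.ndarray:
    """Radius from the reference caliber minus all active constriction bumps.

    Stenoses never overlap, so superposition is exact; extensions (outside the
    anatomical span) keep their stored radius.
    """
    R0 = profile.reference_radius
    s = profile.s
    a0, a1 = profile.anatomical
    in_anat = (s >= a0 - 1e-12) & (s <= a1 + 1e-12)
    R = np.where(in_anat, R0, profile.R)
    for sp in profile.active_stenoses():
        depth = R0 * (1.0 - np.sqrt(1.0 - sp.severity))
        R = R - depth * _cosine_bump(s, sp)
    return R


def _with_critical_samples(profile: AxisymmetricProfile, spec: StenosisSpec) -> np.ndarray:
    """Axial sample set including the throat and extent edges of ``spec``."""
    extra = np.array([spec.start, spec.center, spec.end])
    lo, hi = profile.extent
    extra = extra[(extra >= lo) & (extra <= hi)]
    s = np.union1d(profile.s, extra)
    return s


def apply_stenosis(profile: AxisymmetricProfile, spec: StenosisSpec) -> AxisymmetricProfile:
    """Superpose a new constriction; returns a new profile.

    The bump depth is chosen so the minimal area in the extent meets the
    requested severity relative to the entrance area exactly (the entrance is
    at reference caliber).
    """
    a0, a1 = profile.anatomical
    if spec.start < a0 - 1e-12 or spec.end > a1 + 1e-12:
        raise GeometryError(
            f"stenosis {spec.id!r} extent [{spec.start:.4g}, {spec.end:.4g}] "
            f"outside anatomical segment [{a0:.4g}, {a1:.4g}]"
        )
    for other in profile.stenoses:
        if other.id == spec.id:
            raise GeometryError(f"stenosis id {spec.id!r} already present")
        if spec.start < other.end and other.start < spec.end:
            raise GeometryError(
                f"stenosis {spec.id!r} overlaps {other.id!r}"
            )
    s = _with_critical_samples(profile, spec)
    base = replace(
        profile,
        s=s,
        R=np.interp(s, profile.s, profile.R),
        stenoses=profile.stenoses + (spec,),
    )
    return replace(base, R=_rebuild_radius(base))


def correct_stenosis(profile: AxisymmetricProfile, stenosis_id: str) -> AxisymmetricProfile:
    """Virtually restore one stenotic extent to the reference caliber.

    The spec stays on the profile (marked corrected) so its region can still
    be interrogated; all other stenoses are untouched.
    """
    profile.stenosis(stenosis_id)  # raises on unknown id
    out = replace(profile, corrected=profile.corrected | {stenosis_id})
    return replace(out, R=_rebuild_radius(out))


def reapply_stenosis(profile: AxisymmetricProfile, stenosis_id: str) -> AxisymmetricProfile:
    """Undo a virtual correction (round-trip helper)."""
    profile.stenosis(stenosis_id)
    out = replace(profile, corrected=profile.corrected - {stenosis_id})
    return replace(out, R=_rebuild_radius(out))


def apply_scheme(profile: AxisymmetricProfile, scheme: SurgicalScheme) -> AxisymmetricProfile:
    """Apply a surgical scheme: correct every stenosis listed in it."""
    ids = {sp.id for sp in profile.stenoses}
    unknown = set(scheme.corrected) - ids
    if unknown:
        raise GeometryError(f"scheme references unknown stenoses {sorted(unknown)}")
    out = profile
    for sid in sorted(scheme.corrected):
        out = correct_stenosis(out, sid)
    return out


def extend_domain(
    profile: AxisymmetricProfile,
    inlet_factor: float,
    outlet_factor: float,
    n_per_diameter: float = 4.0,
) -> AxisymmetricProfile:
    """Prepend/append straight constant-radius runs of ``factor x local D``.

    The anatomical span keeps its coordinates; the inlet extension occupies
    negative ``s``.  Extensions let the boundary layer develop upstream and
    the pressure recover downstream, mirroring standard CFD practice.
    """
    if inlet_factor < 0 or outlet_factor < 0:
        raise GeometryError("extension factors must be non-negative")
    if inlet_factor == 0 and outlet_factor == 0:
        return profile
    s, R = profile.s, profile.R
    if inlet_factor > 0:
        D_in = 2.0 * R[0]
        L = inlet_factor * D_in
        n = max(int(np.ceil(n_per_diameter * inlet_factor)), 2)
        s_ext = s[0] - np.linspace(L, 0.0, n + 1)[:-1]
        s = np.concatenate([s_ext, s])
        R = np.concatenate([np.full(n, R[0]), R])
    if outlet_factor > 0:
        D_out = 2.0 * R[-1]
        L = outlet_factor * D_out
        n = max(int(np.ceil(n_per_diameter * outlet_factor)), 2)
        s_ext = s[-1] + np.linspace(0.0, L, n + 1)[1:]
        s = np.concatenate([s, s_ext])
        R = np.concatenate([R, np.full(n, R[-1])])
    return replace(profile, s=s, R=R)


# ---------------------------------------------------------------------------
# measurements


def cross_section_area(profile: AxisymmetricProfile, s: float) -> float:
    """Lumen cross-sectional area pi R(s)^2 at axial position ``s`` (m^2)."""
    r = profile.radius_at(s)
    return float(np.pi * r * r)


def stenosis_ratio(profile: AxisymmetricProfile, stenosis_id: str) -> float:
    """Severity of one stenosis in percent.

    (S_TE - S_SP)/S_TE x 100 with S_TE the entrance area and S_SP the minimal
    cross-sectional area inside the stenotic extent.
    """
    sp = profile.stenosis(stenosis_id)
    s_te = profile.entrance_area()
    mask = (profile.s >= sp.start - 1e-12) & (profile.s <= sp.end + 1e-12)
    if not np.any(mask):
        raise GeometryError(f"no samples inside stenosis {stenosis_id!r}")
    r_min = float(np.min(profile.R[mask]))
    s_sp = np.pi * r_min * r_min
    return (s_te - s_sp) / s_te * 100.0
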