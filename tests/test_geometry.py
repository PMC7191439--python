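"""Parametric lumen profiles: areas, severities, virtual surgery."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tracheoflow.geometry import (
    AxisymmetricProfile,
    GeometryError,
    StenosisSpec,
    SurgicalScheme,
    apply_scheme,
    apply_stenosis,
    correct_stenosis,
    cross_section_area,
    extend_domain,
    reapply_stenosis,
    scheme_label,
    stenosis_ratio,
    straight_profile,
)


@pytest.fixture
def tube():
    return straight_profile(0.045, 0.003)


class TestCrossSectionArea:
    def test_unit_radius(self):
        prof = straight_profile(1.0, 1.0)
        assert cross_section_area(prof, 0.5) == pytest.approx(np.pi)

    def test_three_mm_radius(self, tube):
        assert cross_section_area(tube, 0.01) == pytest.approx(2.827e-5, rel=1e-3)

    def test_constant_along_straight_tube(self, tube):
        areas = [cross_section_area(tube, s) for s in np.linspace(0, 0.045, 7)]
        assert np.ptp(areas) == 0.0

    def test_outside_extent_raises(self, tube):
        with pytest.raises(GeometryError):
            cross_section_area(tube, 0.05)


class TestStenosisRatio:
    def test_no_constriction_is_zero(self, tube):
        prof = apply_stenosis(tube, StenosisSpec("S1", 0.02, 0.009, 0.0))
        assert stenosis_ratio(prof, "S1") == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_area_pair(self):
        # entrance 28.27 mm^2 (R = 3 mm), throat 8.85 mm^2 -> 68.7%
        r_min = np.sqrt(8.85e-6 / np.pi)
        s = np.linspace(0.0, 0.045, 901)
        R = np.full_like(s, 0.003)
        mid = (s > 0.02) & (s < 0.025)
        R[mid] = r_min
        prof = AxisymmetricProfile(
            s=s, R=R, reference_radius=0.003,
            stenoses=(StenosisSpec("S1", 0.0225, 0.009, 0.687),),
            anatomical=(0.0, 0.045),
        )
        assert stenosis_ratio(prof, "S1") == pytest.approx(68.7, abs=0.05)

    def test_constructor_round_trip(self, tube):
        prof = apply_stenosis(tube, StenosisSpec("S2", 0.033, 0.009, 0.865))
        assert stenosis_ratio(prof, "S2") == pytest.approx(86.5, abs=0.01)

    def test_unknown_id_raises(self, tube):
        with pytest.raises(GeometryError):
            stenosis_ratio(tube, "S9")


class TestApplyStenosis:
    def test_zero_severity_keeps_radius(self, tube):
        prof = apply_stenosis(tube, StenosisSpec("S1", 0.02, 0.009, 0.0))
        assert np.allclose(prof.R, tube.reference_radius)

    def test_half_severity_min_radius(self, tube):
        prof = apply_stenosis(tube, StenosisSpec("S1", 0.02, 0.009, 0.5))
        assert prof.R.min() == pytest.approx(0.003 * np.sqrt(0.5), rel=1e-9)

    def test_two_stenoses_independent(self, tube):
        prof = apply_stenosis(tube, StenosisSpec("S1", 0.015, 0.009, 0.687))
        prof = apply_stenosis(prof, StenosisSpec("S2", 0.033, 0.009, 0.865))
        assert stenosis_ratio(prof, "S1") == pytest.approx(68.7, abs=0.01)
        assert stenosis_ratio(prof, "S2") == pytest.approx(86.5, abs=0.01)

    def test_overlap_rejected(self, tube):
        prof = apply_stenosis(tube, StenosisSpec("S1", 0.02, 0.01, 0.5))
        with pytest.raises(GeometryError, match="overlap"):
            apply_stenosis(prof, StenosisSpec("S2", 0.025, 0.01, 0.5))

    def test_extent_outside_anatomy_rejected(self, tube):
        with pytest.raises(GeometryError, match="outside"):
            apply_stenosis(tube, StenosisSpec("S1", 0.002, 0.01, 0.5))


class TestCorrection:
    def test_full_restoration_matches_clean_profile(self, tube):
        prof = apply_stenosis(tube, StenosisSpec("S1", 0.015, 0.009, 0.687))
        prof = apply_stenosis(prof, StenosisSpec("S2", 0.033, 0.009, 0.865))
        m4 = correct_stenosis(correct_stenosis(prof, "S1"), "S2")
        assert np.allclose(m4.R, tube.reference_radius, atol=1e-12)
        assert stenosis_ratio(m4, "S1") == pytest.approx(0.0, abs=1e-9)

    def test_correction_is_local(self, tube):
        prof = apply_stenosis(tube, StenosisSpec("S1", 0.015, 0.009, 0.687))
        prof = apply_stenosis(prof, StenosisSpec("S2", 0.033, 0.009, 0.865))
        m2 = correct_stenosis(prof, "S1")
        assert stenosis_ratio(m2, "S2") == pytest.approx(86.5, abs=0.01)

    def test_correct_then_reapply_round_trip(self, tube):
        prof = apply_stenosis(tube, StenosisSpec("S1", 0.02, 0.009, 0.7))
        back = reapply_stenosis(correct_stenosis(prof, "S1"), "S1")
        assert np.allclose(back.R, prof.R, atol=1e-15)

    def test_corrections_commute(self, tube):
        prof = apply_stenosis(tube, StenosisSpec("S1", 0.015, 0.009, 0.687))
        prof = apply_stenosis(prof, StenosisSpec("S2", 0.033, 0.009, 0.865))
        a = correct_stenosis(correct_stenosis(prof, "S1"), "S2")
        b = correct_stenosis(correct_stenosis(prof, "S2"), "S1")
        assert np.array_equal(a.R, b.R)

    def test_unknown_id_raises(self, tube):
        with pytest.raises(GeometryError):
            correct_stenosis(tube, "S1")


class TestSchemes:
    def test_label_bijection(self):
        labels = {scheme_label(SurgicalScheme(c))
                  for c in [(), ("S1",), ("S2",), ("S1", "S2")]}
        assert labels == {"M1", "M2", "M3", "M4"}

    def test_scheme_application(self, tube):
        prof = apply_stenosis(tube, StenosisSpec("S1", 0.015, 0.009, 0.687))
        prof = apply_stenosis(prof, StenosisSpec("S2", 0.033, 0.009, 0.865))
        m3 = apply_scheme(prof, SurgicalScheme(("S2",)))
        assert stenosis_ratio(m3, "S2") == pytest.approx(0.0, abs=1e-9)
        assert stenosis_ratio(m3, "S1") == pytest.approx(68.7, abs=0.01)

    def test_unknown_scheme_id(self, tube):
        with pytest.raises(GeometryError):
            apply_scheme(tube, SurgicalScheme(("S1",)))


class TestExtendDomain:
    def test_zero_factors_unchanged(self, tube):
        assert extend_domain(tube, 0, 0) is tube

    def test_inlet_extension_length(self, tube):
        ext = extend_domain(tube, 20, 0)
        assert ext.extent[0] == pytest.approx(-20 * 0.006)
        assert ext.anatomical == (0.0, 0.045)

    def test_extended_profile_valid(self, tube):
        ext = extend_domain(tube, 20, 40)
        assert np.all(np.diff(ext.s) > 0)
        assert np.all(ext.R > 0)
        assert ext.radius_at(-0.1) == pytest.approx(0.003)
        assert ext.radius_at(0.2) == pytest.approx(0.003)

    def test_negative_factor_rejected(self, tube):
        with pytest.raises(GeometryError):
            extend_domain(tube, -1, 0)


@given(
    severity=st.floats(0.1, 0.9),
    center_frac=st.floats(0.25, 0.75),
    length_frac=st.floats(0.1, 0.3),
)
def test_severity_round_trip_property(severity, center_frac, length_frac):
    """stenosis_ratio recovers the constructor severity for any placement."""
    L = 0.045
    tube = straight_profile(L, 0.003)
    spec = StenosisSpec("S", center_frac * L, length_frac * L, severity)
    prof = apply_stenosis(tube, spec)
    assert stenosis_ratio(prof, "S") == pytest.approx(100 * severity, abs=0.05)
    restored = correct_stenosis(prof, "S")
    assert np.allclose(restored.R, 0.003, atol=1e-12)


def test_invalid_specs_rejected():
    with pytest.raises(GeometryError):
        StenosisSpec("S", 0.01, 0.01, 1.0)
    with pytest.raises(GeometryError):
        StenosisSpec("S", 0.01, -0.01, 0.5)
    with pytest.raises(GeometryError):
        straight_profile(-1.0, 0.003)
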