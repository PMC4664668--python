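"""Array profiles, PVDR, merge depth and dose bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from minibeams import (
    PROTON,
    BeamShape,
    BeamSpec,
    EnergySpec,
    MergeRule,
    array_profile,
    biological_entrance_ratio,
    collimator_yield,
    dose_bookkeeping,
    incident_dose_factor,
    merge_depth,
    pvdr,
)
from minibeams.errors import DomainError
from minibeams.minibeam_array import LateralProfile


def _planar(energy=109.0, spacing=1.0, width=0.3):
    return BeamSpec(
        species=PROTON,
        energy=EnergySpec(energy),
        shape=BeamShape.PLANAR,
        incident_width_fwhm=width,
        spacing_on_center=spacing,
    )


class TestArrayProfile:
    def test_surface_profile_has_disjoint_peaks(self):
        # spacing >> width: neighbours contribute nothing at the valley
        wide = array_profile(_planar(spacing=1.5), depth=0.0, n_beams=5)
        assert wide.interp(0.75) < 1e-4 * wide.interp(0.0)
        # 0.3-mm beams spaced 1.0-mm on-center: PVDR still above 1e3 at the surface
        res = pvdr(array_profile(_planar(), depth=0.0, n_beams=5))
        assert res.value > 1e3 and not res.merged

    def test_single_beam_profile_is_the_kernel(self):
        beam = BeamSpec(species=PROTON, energy=EnergySpec(109.0), incident_width_fwhm=0.3)
        p = array_profile(beam, depth=0.0, n_beams=1)
        assert p.interp(0.0) == pytest.approx(1.0, rel=1e-6)  # unit entrance dose
        # Gaussian of FWHM 0.3: half maximum at +-0.15
        assert p.interp(0.15) == pytest.approx(0.5, rel=0.01)

    def test_lateral_dose_conservation_with_depth(self):
        """Scattering redistributes dose laterally but does not absorb it."""
        beam = _planar()
        totals = []
        for depth in (0.0, 15.0, 30.0, 45.0):
            p = array_profile(beam, depth=depth, n_beams=7)
            totals.append(np.trapezoid(p.dose, p.positions))
        totals = np.asarray(totals)
        assert np.max(np.abs(totals / totals[0] - 1.0)) < 0.005

    def test_even_n_beams_rejected(self):
        with pytest.raises(DomainError):
            array_profile(_planar(), depth=0.0, n_beams=4)


class TestPvdr:
    def test_flat_profile_is_merged(self):
        x = np.linspace(-3, 3, 601)
        p = LateralProfile(positions=x, dose=np.ones_like(x), depth=0.0, spacing=1.0)
        res = pvdr(p)
        assert res.value == 1.0 and res.merged

    def test_nonincreasing_with_depth(self):
        beam = _planar()
        depths = [0.0, 10.0, 20.0, 30.0, 40.0]
        values = [pvdr(array_profile(beam, d, n_beams=7)).value for d in depths]
        assert all(a >= b * (1 - 1e-9) for a, b in zip(values, values[1:]))

    def test_needs_enough_peaks(self):
        x = np.linspace(-0.4, 0.4, 81)
        p = LateralProfile(positions=x, dose=np.ones_like(x), depth=0.0, spacing=1.0)
        with pytest.raises(DomainError):
            pvdr(p)


class TestMergeDepth:
    def test_both_rules_agree_within_15pct(self, proton_planar_10cm, li7_planar_10cm):
        for beam in (proton_planar_10cm, li7_planar_10cm):
            rep = merge_depth(beam)
            gap = abs(rep.merge_depth_valley_rule - rep.merge_depth_fwhm_rule)
            assert gap / rep.merge_depth_valley_rule < 0.15

    def test_spacing_equal_width_merges_at_surface(self):
        beam = _planar(spacing=0.3)
        rep = merge_depth(beam)
        assert rep.merge_depth_fwhm_rule == 0.0

    def test_pencil_merges_no_earlier_than_planar(self):
        planar = _planar(energy=115.8, spacing=1.0)
        pencil = BeamSpec(
            species=PROTON,
            energy=EnergySpec(115.8),
            shape=BeamShape.PENCIL,
            incident_width_fwhm=0.3,
            spacing_on_center=1.0,
        )
        zp = merge_depth(planar).merge_depth_valley_rule
        zq = merge_depth(pencil).merge_depth_valley_rule
        assert zq >= zp - 0.01

    def test_rule_selection_in_report(self, proton_planar_10cm):
        rep = merge_depth(proton_planar_10cm, rule=MergeRule.FWHM_EQUALS_SPACING)
        assert rep.merge_depth == rep.merge_depth_fwhm_rule


class TestBookkeeping:
    def test_collimator_yields_printed_values(self):
        assert collimator_yield(BeamShape.PENCIL, 0.3, 0.5) * 100 == pytest.approx(28.3, abs=0.05)
        assert collimator_yield(BeamShape.PENCIL, 0.3, 0.7) * 100 == pytest.approx(14.4, abs=0.05)
        assert collimator_yield(BeamShape.PLANAR, 0.5, 0.5) == pytest.approx(1.0)

    def test_incident_dose_factors_printed_values(self):
        assert round(incident_dose_factor(BeamShape.PLANAR, 0.3, 0.7), 1) == 2.3
        assert round(incident_dose_factor(BeamShape.PENCIL, 0.3, 0.7), 1) == 6.9
        assert round(incident_dose_factor(BeamShape.PENCIL, 0.3, 0.5), 1) == 3.5

    def test_factor_is_exact_inverse_of_yield(self):
        for shape, w, s in [
            (BeamShape.PLANAR, 0.3, 0.7),
            (BeamShape.PENCIL, 0.3, 0.5),
            (BeamShape.PENCIL, 0.68, 1.36),
        ]:
            assert incident_dose_factor(shape, w, s) * collimator_yield(shape, w, s) == pytest.approx(1.0, rel=1e-12)

    def test_biological_entrance_ratio(self):
        assert biological_entrance_ratio(2.3, 7.0) == pytest.approx(0.33, abs=0.005)
        assert biological_entrance_ratio(4.2, 1.0) == 4.2
        with pytest.raises(DomainError):
            biological_entrance_ratio(2.3, 0.5)

    def test_minibeam_tolerance_advantage_over_solid(self):
        # 170 Gy tolerated in-beam vs 22.5 Gy solid-beam tolerance
        assert 170.0 / 22.5 > 7.5

    def test_bookkeeping_assembly(self):
        bk = dose_bookkeeping(BeamShape.PLANAR, 0.3, 0.7, sparing_factor=7.0)
        assert bk.incident_dose_factor == pytest.approx(7.0 / 3.0)
        assert bk.dilution_factor == pytest.approx(7.0 / 3.0)
        assert bk.biological_entrance_ratio == pytest.approx(0.33, abs=0.005)

    def test_spacing_below_width_rejected(self):
        with pytest.raises(DomainError):
            collimator_yield(BeamShape.PLANAR, 0.5, 0.3)


@settings(derandomize=True, max_examples=40)
@given(
    width=st.floats(min_value=0.05, max_value=1.0),
    ratio=st.floats(min_value=1.0, max_value=10.0),
    pencil=st.booleans(),
)
def test_yield_factor_product_is_unity(width, ratio, pencil):
    shape = BeamShape.PENCIL if pencil else BeamShape.PLANAR
    spacing = width * ratio
    y = collimator_yield(shape, width, spacing)
    assert 0.0 < y <= 1.0
    assert incident_dose_factor(shape, width, spacing) * y == pytest.approx(1.0, rel=1e-9)
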