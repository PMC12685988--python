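"""Stress-strain reconstruction and CS/CE metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nodulemech import (
    GeometryError,
    InsufficientStrainError,
    MachineSpec,
    NoContactError,
    NoduleRecord,
    StressStrainCurve,
    compression_energy,
    compression_strength,
    contact_ratio,
    find_origin,
    loading_area,
    mpa_to_gf_mm2,
    resample_to_grid,
    stiffness_profile,
    to_stress_strain,
)


def make_recording(loads, disps=None, times=None):
    from nodulemech import TestRecording as Recording

    n = len(loads)
    return Recording(
        time_ms=np.arange(n) * 20.0 if times is None else np.asarray(times),
        load_n=np.asarray(loads, dtype=float),
        displacement_mm=np.arange(n) * 0.01 if disps is None else np.asarray(disps),
    )


class TestFindOrigin:
    def test_direct_threshold_crossing(self):
        rec = make_recording([0.0, 0.1, 0.25, 1.0])
        idx, disp = find_origin(rec, a0_mm2=10.0)
        assert idx == 2  # 0.25 / 10 > 0.02
        assert disp[idx] == 0.0
        np.testing.assert_allclose(disp, rec.displacement_mm - rec.displacement_mm[2])

    def test_no_contact_error(self):
        rec = make_recording([0.0, 0.1, 0.15, 0.19])
        with pytest.raises(NoContactError, match="no contact"):
            find_origin(rec, a0_mm2=10.0)

    def test_simulator_contact_ground_truth(self, plateau_recording, geometry):
        idx, _ = find_origin(plateau_recording, geometry.a0_mm2)
        assert idx == plateau_recording.meta["contact_index"]

    def test_noisy_origin_near_truth(self):
        from nodulemech import CrushCurveParams, simulate_crush_curve

        # Typical-size nodule: contact threshold well above the noise floor.
        geom = NoduleRecord("n", a0_mm2=25.0, h0_mm=3.0)
        params = CrushCurveParams()  # default noise at machine accuracy
        for seed in range(20):
            rec = simulate_crush_curve(params, geom, seed=seed)
            idx, _ = find_origin(rec, geom.a0_mm2)
            assert abs(idx - rec.meta["contact_index"]) <= 2


class TestStressStrainTransform:
    @pytest.mark.parametrize(
        "eps, expected_rc, expected_area, expected_sigma",
        [
            (0.0, 0.5, 5.0, 0.2),  # start of compression
            (0.5, 1.0, 20.0, 0.05),  # half height: Rc saturated
        ],
    )
    def test_area_formula_at_landmarks(self, eps, expected_rc, expected_area, expected_sigma):
        assert contact_ratio(eps) == expected_rc
        assert loading_area(eps, a0_mm2=10.0) == pytest.approx(expected_area)
        assert 1.0 / loading_area(eps, 10.0) == pytest.approx(expected_sigma)

    def test_both_area_formulas_agree(self):
        # A = Rc*A0/(1-eps) must equal Rc*V0/H evaluated independently.
        a0, h0, eps = 10.0, 4.0, 0.25
        v0 = a0 * h0
        h = h0 * (1 - eps)
        rc = min(0.5 + eps, 1.0)
        area_via_volume = rc * v0 / h
        assert loading_area(eps, a0) == pytest.approx(area_via_volume)
        assert area_via_volume == pytest.approx(10.0)
        assert 1.0 / area_via_volume == pytest.approx(0.1)  # F=1 N -> 0.1 MPa

    def test_strain_reaching_one_is_geometry_error(self):
        rec = make_recording([0.0, 1.0, 2.0, 3.0], disps=[0.0, 0.5, 2.0, 3.6])
        nodule = NoduleRecord("bad", a0_mm2=10.0, h0_mm=3.0)
        with pytest.raises(GeometryError, match="strain"):
            to_stress_strain(rec, nodule)

    def test_constant_load_stress_decreases_below_half_strain(self):
        # sigma ∝ (1-eps)/(0.5+eps) is strictly decreasing on [0, 0.5].
        h0 = 2.0
        disps = np.linspace(0.0, 0.5 * h0, 50)
        rec = make_recording(np.full(50, 5.0), disps=disps, times=np.arange(50) * 20.0)
        curve = to_stress_strain(rec, NoduleRecord("c", a0_mm2=10.0, h0_mm=h0))
        assert np.all(np.diff(curve.stress_mpa) < 0)

    def test_roundtrip_recovers_true_stress(self, plateau_recording, geometry):
        curve = to_stress_strain(plateau_recording, geometry)
        truth = plateau_recording.meta["true_stress_mpa"]
        assert len(curve) == len(truth)
        # Sample 0 is the synthetic seating snap; all later samples exact.
        np.testing.assert_allclose(
            curve.stress_mpa[1:], truth[1:], atol=1e-6, rtol=0
        )
        plateau = curve.stress_mpa[(curve.strain > 0.15) & (curve.strain < 0.4)]
        np.testing.assert_allclose(plateau, 1.0, rtol=1e-12)

    def test_roundtrip_gradual_closed_form(self, gradual_recording, geometry):
        curve = to_stress_strain(gradual_recording, geometry)
        expected = 4.0 * curve.strain**2
        assert np.abs(curve.stress_mpa[1:] - expected[1:]).max() < 1e-6


class TestResampleToGrid:
    def test_midpoint_interpolation(self):
        curve = StressStrainCurve([0.0, 0.04, 0.06], [0.0, 0.4, 0.6])
        grid = resample_to_grid(curve, 0.05)
        assert grid.strain[-1] == pytest.approx(0.05)
        assert grid.stress_mpa[-1] == pytest.approx(0.5)

    def test_grid_truncates_to_last_full_multiple(self):
        curve = StressStrainCurve(np.linspace(0, 0.43, 100), np.linspace(0, 1, 100))
        grid = resample_to_grid(curve, 0.05)
        assert grid.strain[-1] == pytest.approx(0.40)

    def test_single_sample_rejected(self):
        with pytest.raises(InsufficientStrainError):
            resample_to_grid(StressStrainCurve([0.1], [0.5]))

    def test_matches_independent_fine_interpolator(self):
        rng = np.random.default_rng(5)
        eps = np.sort(rng.uniform(0, 0.8, 300))
        eps[0] = 0.0
        sigma = np.cumsum(rng.uniform(0, 0.05, 300))
        curve = StressStrainCurve(eps, sigma)
        grid = resample_to_grid(curve, 0.05)
        # Oracle: manual bracketing + linear interpolation, point by point.
        for g, s in zip(grid.strain, grid.stress_mpa):
            j = np.searchsorted(eps, g)
            if eps[min(j, len(eps) - 1)] == g:
                expected = sigma[j]
            else:
                x0, x1, y0, y1 = eps[j - 1], eps[j], sigma[j - 1], sigma[j]
                expected = y0 + (y1 - y0) * (g - x0) / (x1 - x0)
            assert s == pytest.approx(expected, abs=1e-12)


class TestCompressionStrength:
    def test_monotone_curve_peak_at_endpoint(self):
        eps = np.linspace(0, 0.6, 200)
        curve = StressStrainCurve(eps, 2 * eps)
        assert compression_strength(curve, 0.5) == pytest.approx(1.0)

    def test_interior_peak(self):
        eps = np.array([0.0, 0.12, 0.2])
        curve = StressStrainCurve(eps, np.array([0.0, 0.9, 0.5]))
        assert compression_strength(curve, 0.2) == pytest.approx(0.9)

    def test_level_beyond_data_is_missing_not_extrapolated(self):
        curve = StressStrainCurve([0.0, 0.3], [0.0, 1.0])
        with pytest.raises(InsufficientStrainError):
            compression_strength(curve, 0.5)
        profile = stiffness_profile(curve, levels=(0.2, 0.5))
        assert np.isfinite(profile.cs(0.2))
        assert np.isnan(profile.cs(0.5)) and np.isnan(profile.ce(0.5))

    def test_serrated_curve_equals_exhaustive_scan(self, small_cohort):
        records, recordings = small_cohort
        for record, rec in list(zip(records, recordings))[:10]:
            curve = to_stress_strain(rec, record)
            for level in (0.1, 0.3, 0.5):
                if curve.max_strain < level:
                    continue
                oracle = max(
                    s for e, s in zip(curve.strain, curve.stress_mpa) if e <= level
                )
                assert compression_strength(curve, level) >= oracle - 1e-12
                assert compression_strength(curve, level) == pytest.approx(
                    max(oracle, np.interp(level, curve.strain, curve.stress_mpa))
                )


class TestCompressionEnergy:
    def test_triangle_area(self):
        eps = np.linspace(0, 0.6, 601)
        curve = StressStrainCurve(eps, 2 * eps)
        assert compression_energy(curve, 0.5) == pytest.approx(0.25, abs=1e-9)

    def test_rectangle_area(self):
        eps = np.linspace(0, 0.5, 501)
        curve = StressStrainCurve(eps, np.ones_like(eps))
        assert compression_energy(curve, 0.3) == pytest.approx(0.3, abs=1e-12)

    def test_refinement_oracle_on_serrated_curve(self, geometry):
        from nodulemech import CrushCurveParams, noise_free, simulate_crush_curve

        params = noise_free(CrushCurveParams(drop_rate=30.0, drop_depth_fraction=0.2))
        rec = simulate_crush_curve(params, geometry, seed=6)
        curve = to_stress_strain(rec, geometry)
        level = min(0.5, curve.max_strain)
        # Oracle: trapezoid on a 1e5-point refinement of the sampling
        # partition (kinks of the piecewise-linear curve included).
        fine = np.union1d(
            np.linspace(0, level, 100_000),
            curve.strain[curve.strain <= level],
        )
        oracle = np.trapezoid(np.interp(fine, curve.strain, curve.stress_mpa), fine)
        assert compression_energy(curve, level) == pytest.approx(oracle, rel=1e-6)

    def test_energy_invariant_to_resampling_density(self, plateau_recording, geometry):
        curve = to_stress_strain(plateau_recording, geometry)
        coarse = resample_to_grid(curve, 0.05)
        # Gridding coarsens the partition; agreement to ~2% on a smooth curve.
        assert compression_energy(coarse, 0.4) == pytest.approx(
            compression_energy(curve, 0.4), rel=2e-2
        )


class TestProfileInvariants:
    def test_cs_ce_monotone_and_bounded(self, property_cohort):
        """CS, CE non-decreasing in level; CE(s) <= s*CS(s); over 1000 curves."""
        records, recordings = property_cohort
        levels = (0.1, 0.2, 0.3, 0.4, 0.5)
        for record, rec in zip(records, recordings):
            curve = to_stress_strain(rec, record)
            profile = stiffness_profile(curve, levels)
            cs = [profile.cs(s) for s in levels if not np.isnan(profile.cs(s))]
            ce = [profile.ce(s) for s in levels if not np.isnan(profile.ce(s))]
            assert np.all(np.diff(cs) >= -1e-12)
            assert np.all(np.diff(ce) >= -1e-12)
            for s in levels:
                if not np.isnan(profile.cs(s)):
                    assert profile.ce(s) <= s * profile.cs(s) + 1e-12


@given(
    k=st.floats(min_value=0.1, max_value=50.0),
    level=st.floats(min_value=0.05, max_value=0.6),
)
@settings(max_examples=50, deadline=None)
def test_linear_curve_closed_forms(k, level):
    """For sigma = k*eps: CS(s) = k*s and CE(s) = k*s^2/2 at any level."""
    eps = np.linspace(0, 0.7, 1401)
    curve = StressStrainCurve(eps, k * eps)
    assert compression_strength(curve, level) == pytest.approx(k * level, rel=1e-6)
    assert compression_energy(curve, level) == pytest.approx(
        k * level**2 / 2, rel=1e-4
    )


def test_unit_conversion_to_gram_force():
    assert mpa_to_gf_mm2(0.378) == pytest.approx(38.5, abs=0.05)
    assert mpa_to_gf_mm2(1.0) == pytest.approx(101.97, abs=0.01)
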