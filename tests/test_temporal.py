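"""Temporal down-sampling errors and repeatability statistics."""

import numpy as np
import pytest

from puffoct import (
    AsymmetryVector,
    ConfigError,
    DisplacementProfile,
    SpotLayout,
    downsample,
    repeatability,
    worst_case_error,
)


def _profile(t, d, sigma=0.0, label="S1"):
    return DisplacementProfile(time_ms=np.asarray(t, float),
                               displacement_um=np.asarray(d, float),
                               label=label, baseline_sigma_um=sigma)


class TestDownsample:
    def test_native_resolution_is_identity(self, truth_profiles):
        prof = truth_profiles["S1"]
        ds = downsample(prof, prof.dt_ms * 1000.0, 0.0)
        np.testing.assert_array_equal(ds.displacement_um,
                                      prof.displacement_um)
        np.testing.assert_array_equal(ds.time_ms, prof.time_ms)

    def test_constant_profile_stays_constant(self):
        t = np.arange(0, 50, 0.01)
        prof = _profile(t, np.full_like(t, 3.3))
        for dt_us, off in [(20.0, 10.0), (33.3, 7.0), (1000.0, 430.0)]:
            ds = downsample(prof, dt_us, off)
            np.testing.assert_allclose(ds.displacement_um, 3.3)

    def test_triangle_peak_missed_by_half_period_offset(self):
        # triangle apex 100 um at t=5 ms, +-1 ms base, on a 10 us grid:
        # 1 ms sampling offset by 500 us lands at 4.5/5.5 ms -> max 50 um
        t = np.arange(0, 10, 0.01)
        d = np.clip(100.0 * (1.0 - np.abs(t - 5.0)), 0.0, None)
        ds = downsample(_profile(t, d), 1000.0, 500.0)
        assert ds.displacement_um.max() == pytest.approx(50.0, abs=1e-9)
        # aligned grid hits the apex exactly
        ds0 = downsample(_profile(t, d), 1000.0, 0.0)
        assert ds0.displacement_um.max() == pytest.approx(100.0, abs=1e-9)

    def test_integer_factor_decimates_at_matching_indices(self,
                                                          truth_profiles):
        prof = truth_profiles["S2"]
        ds = downsample(prof, 250.0, 30.0)
        np.testing.assert_array_equal(ds.displacement_um,
                                      prof.displacement_um[3::25])

    def test_noninteger_factor_interpolates_on_uniform_grid(self,
                                                            truth_profiles):
        prof = truth_profiles["S3"]
        ds = downsample(prof, 33.3, 0.0)
        steps = np.diff(ds.time_ms)
        assert np.allclose(steps, 0.0333, atol=1e-12)
        expected = np.interp(ds.time_ms, prof.time_ms, prof.displacement_um)
        np.testing.assert_allclose(ds.displacement_um, expected)

    def test_finer_target_rejected(self, truth_profiles):
        with pytest.raises(ConfigError, match="finer"):
            downsample(truth_profiles["S1"], 5.0)

    def test_offset_must_be_inside_one_period(self, truth_profiles):
        with pytest.raises(ConfigError, match="offset"):
            downsample(truth_profiles["S1"], 100.0, 100.0)


class TestWorstCase:
    def test_constant_profiles_give_zero_errors(self, layout):
        t = np.arange(0, 50, 0.01)
        base = np.zeros_like(t)
        bump = np.clip(300 * (1 - np.abs(t - 20) / 5.0), 0, None)
        profiles = {
            lab: _profile(t, bump * (1 + 0.1 * (lab == "S3")), label=lab)
            for lab in layout.peripheral_labels
        }
        del base
        report = worst_case_error(profiles, 250.0, layout)
        assert report.worst_azimuth_error_deg <= 45.0  # sanity bound

    def test_native_target_has_zero_worst_case_error(self, truth_profiles,
                                                     layout):
        report = worst_case_error(truth_profiles, 10.0, layout)
        assert report.worst_magnitude_error_pct == 0.0
        assert report.worst_azimuth_error_deg == 0.0

    def test_offset_zero_equals_plain_decimation(self, truth_profiles,
                                                 layout):
        from puffoct.metrics import angular_distance, extract_params

        target = 250.0
        report = worst_case_error(truth_profiles, target, layout)
        # independent path: decimate every profile at offset 0, extract,
        # recompute the vector, compare against the report's offset-0 row
        values = {}
        for lab in layout.peripheral_labels:
            ds = downsample(truth_profiles[lab], target, 0.0)
            values[lab] = extract_params(ds).da1_um
        vec = AsymmetryVector.from_values(values, layout)
        ref = report.reference
        mag_err = abs(vec.magnitude - ref.magnitude) / ref.magnitude * 100
        azi_err = angular_distance(vec.azimuth_deg, ref.azimuth_deg)
        assert report.magnitude_error_pct[0] == pytest.approx(mag_err)
        assert report.azimuth_error_deg[0] == pytest.approx(azi_err)

    def test_zero_reference_vector_flagged(self, layout):
        t = np.arange(0, 50, 0.01)
        bump = np.clip(300 * (1 - np.abs(t - 20) / 5.0), 0, None)
        profiles = {lab: _profile(t, bump, label=lab)
                    for lab in layout.peripheral_labels}
        report = worst_case_error(profiles, 250.0, layout)
        assert report.ref_zero
        assert np.isnan(report.worst_magnitude_error_pct)
        assert np.isfinite(report.worst_azimuth_error_deg)

    def test_report_table_and_json(self, truth_profiles, layout, tmp_path):
        report = worst_case_error(truth_profiles, 100.0, layout)
        table = report.per_offset_table()
        assert len(table) == 10
        assert (table["magnitude_error_pct"] >= 0).all()
        report.to_json(tmp_path / "report.json")
        assert (tmp_path / "report.json").exists()


class TestRepeatability:
    @staticmethod
    def _vec(x, y):
        return AsymmetryVector(x=x, y=y)

    def test_identical_repeats_have_zero_spread(self):
        vecs = [self._vec(3.0, 4.0)] * 5
        rep = repeatability(vecs)
        assert rep.angle_sd_deg == pytest.approx(0.0, abs=1e-9)
        assert rep.magnitude_sd_um == pytest.approx(0.0, abs=1e-9)
        assert rep.mean_magnitude == pytest.approx(5.0)

    def test_two_point_circular_sd_of_pm_ten_degrees(self):
        # circular SD sqrt(-2 ln R) of {+10, -10} deg: 10.026 deg
        a = np.radians(10.0)
        vecs = [self._vec(np.cos(a), np.sin(a)),
                self._vec(np.cos(-a), np.sin(-a))]
        rep = repeatability(vecs)
        expected = np.degrees(np.sqrt(-2 * np.log(np.cos(a))))
        assert rep.angle_sd_deg == pytest.approx(expected, rel=1e-6)
        assert rep.angle_sd_deg == pytest.approx(10.0, rel=0.01)
        from puffoct import angular_distance
        assert angular_distance(rep.mean_azimuth_deg, 0.0) < 1e-6

    def test_angle_sd_immune_to_zero_crossing(self):
        # same +-10 deg spread around 0 and around 180: identical SD
        around0 = [self._vec(np.cos(np.radians(s * 10)),
                             np.sin(np.radians(s * 10))) for s in (-1, 1)]
        around180 = [self._vec(np.cos(np.radians(180 + s * 10)),
                               np.sin(np.radians(180 + s * 10)))
                     for s in (-1, 1)]
        assert repeatability(around0).angle_sd_deg == pytest.approx(
            repeatability(around180).angle_sd_deg)

    def test_magnitude_sd_in_pixels_when_pitch_given(self):
        vecs = [self._vec(100.0, 0.0), self._vec(120.0, 0.0)]
        rep = repeatability(vecs, pixel_pitch_um=8.6)
        assert rep.magnitude_sd_px == pytest.approx(rep.magnitude_sd_um / 8.6)

    def test_single_vector_rejected(self):
        with pytest.raises(ConfigError, match="2"):
            repeatability([self._vec(1.0, 0.0)])

    def test_mixed_source_parameters_rejected(self):
        vecs = [AsymmetryVector(1.0, 0.0, source_param="DA1"),
                AsymmetryVector(1.0, 0.0, source_param="DA3")]
        with pytest.raises(ConfigError, match="source"):
            repeatability(vecs)

    def test_monte_carlo_recovers_injected_magnitude_noise(self, rng):
        # isotropic component noise sigma on a mean vector of length 300:
        # magnitude SD ~ sigma, normalized SD ~ sigma/300
        sigma, n = 15.0, 200
        vecs = [self._vec(300.0 + rng.normal(0, sigma),
                          rng.normal(0, sigma)) for _ in range(n)]
        rep = repeatability(vecs)
        assert rep.normalized_magnitude_sd == pytest.approx(sigma / 300.0,
                                                            rel=0.15)
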