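"""Deformation parameters and asymmetry vectors."""

import numpy as np
import pytest
from scipy.interpolate import PchipInterpolator

from puffoct import (
    AsymmetryVector,
    ConfigError,
    DisplacementProfile,
    OnsetError,
    ParameterError,
    SpotLayout,
    angular_distance,
    detect_onset,
    difference_vector,
    extract_params,
    main_vector,
    pair_vectors,
    signed_angle,
)
from puffoct.metrics import MeridionalVector


def _profile(t, d, sigma=0.0, label="S1"):
    return DisplacementProfile(time_ms=np.asarray(t),
                               displacement_um=np.asarray(d),
                               label=label, baseline_sigma_um=sigma)


def _two_lobe_profile(dt_ms=0.01):
    """Smooth two-peak profile with exactly known descriptors.

    Monotone cubic through knots: onset 5 ms, DA1 = 300 µm at onset+6 ms,
    DA2 = 120 µm at onset+11 ms, DA3 = 250 µm at onset+16 ms, back to zero
    at 30 ms.  Monotone interpolation puts each local extremum exactly at
    its knot with zero derivative, so the frozen values are exact.
    """
    knots_t = [0.0, 5.0, 11.0, 16.0, 21.0, 30.0, 40.0]
    knots_v = [0.0, 0.0, 300.0, 120.0, 250.0, 0.0, 0.0]
    t = np.arange(0.0, 40.0, dt_ms)
    d = PchipInterpolator(knots_t, knots_v)(t)
    return _profile(t, d)


class TestOnset:
    def test_zero_profile_has_no_onset(self):
        t = np.arange(0, 10, 0.01)
        with pytest.raises(OnsetError, match="no onset"):
            detect_onset(_profile(t, np.zeros_like(t)))

    def test_noise_free_lobe_onset_at_first_rise(self):
        prof = _two_lobe_profile()
        onset = detect_onset(prof)
        assert onset == pytest.approx(5.0, abs=2 * prof.dt_ms)

    def test_short_excursion_is_not_an_onset(self):
        t = np.arange(0, 10, 0.01)
        d = np.zeros_like(t)
        d[200:209] = 100.0  # 9 samples above threshold, sustain needs 10
        with pytest.raises(OnsetError):
            detect_onset(_profile(t, d, sigma=1.0), k_sigma=5, m_sustain=10)
        d[200:210] = 100.0  # now sustained
        onset = detect_onset(_profile(t, d, sigma=1.0), k_sigma=5,
                             m_sustain=10)
        assert onset == pytest.approx(t[200])

    def test_sustain_window_scales_with_grid(self):
        # 0.1 ms sustain = 10 samples at 10 us but a single sample at 1 ms
        t = np.arange(0, 50, 1.0)
        d = np.zeros_like(t)
        d[20:45] = 50.0
        onset = detect_onset(_profile(t, d, sigma=1.0))
        assert onset == pytest.approx(20.0)


class TestExtractParams:
    def test_two_lobe_profile_recovers_frozen_descriptors(self):
        par = extract_params(_two_lobe_profile())
        dt = 0.01
        assert par.da1_um == pytest.approx(300.0, abs=0.1)
        assert par.da2_um == pytest.approx(120.0, abs=0.1)
        assert par.da3_um == pytest.approx(250.0, abs=0.1)
        assert par.t_da1_ms == pytest.approx(6.0, abs=5 * dt)
        assert par.t_da2_ms == pytest.approx(11.0, abs=5 * dt)
        assert par.t_da3_ms == pytest.approx(16.0, abs=5 * dt)
        assert par.mean_da_um == pytest.approx(275.0, abs=0.2)
        assert par.ratio == pytest.approx(1.2, abs=0.01)
        assert par.has_da2 and par.has_da3

    def test_rectangle_area_is_height_times_width(self):
        t = np.arange(0.0, 30.0, 0.01)
        d = np.where((t >= 5.0) & (t < 15.0), 100.0, 0.0)
        par = extract_params(_profile(t, d))
        assert par.area_um_ms == pytest.approx(1000.0, rel=1e-3)

    def test_monotone_single_lobe_flags_da2_da3_absent(self):
        t = np.arange(0.0, 20.0, 0.01)
        d = np.clip(t - 5.0, 0.0, None) * 10.0  # rises to the record end
        par = extract_params(_profile(t, d))
        assert par.da1_um == pytest.approx(d.max())
        assert not par.has_da2 and not par.has_da3
        assert par.mean_da_um is None and par.ratio is None

    def test_single_peak_profile_flags_absent(self):
        t = np.arange(0.0, 40.0, 0.01)
        knots = PchipInterpolator([0, 5, 15, 25, 40], [0, 0, 400, 0, 0])
        par = extract_params(_profile(t, knots(t)))
        assert par.da1_um == pytest.approx(400.0, abs=0.1)
        assert not par.has_da3

    def test_extraction_on_truth_profiles_matches_generator(self,
                                                            cone_truth,
                                                            truth_profiles):
        for lab, prof in truth_profiles.items():
            par = extract_params(prof)
            tp = cone_truth.params[lab]
            assert par.da1_um == pytest.approx(tp.da1_um, abs=1e-6)
            assert par.da3_um == pytest.approx(tp.da3_um, abs=1e-6)
            assert par.da2_um == pytest.approx(tp.da2_um, abs=1e-6)
            assert par.onset_ms == pytest.approx(tp.onset_ms,
                                                 abs=2 * prof.dt_ms)

    def test_area_matches_fine_riemann_oracle(self, truth_profiles):
        prof = truth_profiles["S1"]
        par = extract_params(prof)
        # independent oracle: midpoint Riemann sum on a 10x finer grid
        t_fine = np.arange(prof.time_ms[0], prof.time_ms[-1], prof.dt_ms / 10)
        d_fine = np.interp(t_fine, prof.time_ms, prof.displacement_um)
        sel = t_fine >= par.onset_ms
        oracle = float(np.sum(d_fine[sel]) * prof.dt_ms / 10)
        assert par.area_um_ms == pytest.approx(oracle, rel=1e-3)


class TestVectors:
    def test_all_equal_values_give_four_zero_vectors(self, layout):
        vecs = pair_vectors({lab: 5.0 for lab in layout.peripheral_labels},
                            layout)
        assert len(vecs) == 4
        for v in vecs:
            assert v.magnitude == 0.0

    def test_single_excess_spot_drives_its_pair_only(self, layout):
        values = {lab: 1.0 for lab in layout.peripheral_labels}
        values["S7"] = 2.0
        vecs = {v.pair: v for v in pair_vectors(values, layout)}
        v37 = vecs[("S3", "S7")]
        assert v37.magnitude == pytest.approx(1.0)
        assert v37.azimuth_deg == pytest.approx(layout.azimuth("S7"))
        for pair, v in vecs.items():
            if pair != ("S3", "S7"):
                assert v.magnitude == 0.0

    def test_pair_magnitude_and_direction(self, layout):
        values = {lab: 1.0 for lab in layout.peripheral_labels}
        values["S1"], values["S5"] = 3.0, 1.0
        vecs = {v.pair: v for v in pair_vectors(values, layout)}
        v15 = vecs[("S1", "S5")]
        assert v15.magnitude == pytest.approx(2.0)
        assert v15.azimuth_deg == pytest.approx(layout.azimuth("S1"))

    def test_missing_spot_rejected_by_name(self, layout):
        values = {lab: 1.0 for lab in layout.peripheral_labels}
        del values["S4"]
        with pytest.raises(ConfigError, match="S4"):
            pair_vectors(values, layout)

    def test_tie_break_zero_vector_uses_first_label_azimuth(self, layout):
        values = {lab: 2.0 for lab in layout.peripheral_labels}
        vecs = pair_vectors(values, layout)
        assert vecs[0].azimuth_deg == layout.azimuth("S1")

    def test_zero_meridionals_sum_to_flagged_zero_vector(self, layout):
        values = {lab: 1.0 for lab in layout.peripheral_labels}
        vec = AsymmetryVector.from_values(values, layout)
        assert vec.is_zero
        assert vec.azimuth_deg == 0.0
        assert vec.magnitude == 0.0

    def test_single_meridional_vector_passes_through(self):
        m = MeridionalVector(pair=("S8", "S4"), magnitude=1.0,
                             azimuth_deg=315.0)
        zeros = [MeridionalVector(pair=(f"S{k}", f"S{k+4}"), magnitude=0.0,
                                  azimuth_deg=(k - 1) * 45.0)
                 for k in range(1, 4)]
        vec = main_vector([*zeros, m])
        assert vec.magnitude == pytest.approx(1.0)
        assert vec.azimuth_deg == pytest.approx(315.0)

    def test_two_adjacent_excess_spots_sum_by_brute_force(self, layout):
        # excess 1 at S1 (0 deg) and S2 (45 deg): |sum| = sqrt(2+sqrt(2))
        values = {lab: 1.0 for lab in layout.peripheral_labels}
        values["S1"] = values["S2"] = 2.0
        vec = AsymmetryVector.from_values(values, layout)
        expected = np.hypot(1.0 + np.cos(np.pi / 4), np.sin(np.pi / 4))
        assert expected == pytest.approx(np.sqrt(2 + np.sqrt(2)))
        assert vec.magnitude == pytest.approx(expected)
        assert vec.azimuth_deg == pytest.approx(22.5)

    def test_signed_azimuth_convention(self):
        assert signed_angle(0.0) == 0.0
        assert signed_angle(180.0) == 180.0
        assert signed_angle(270.0) == -90.0
        assert signed_angle(341.7) == pytest.approx(-18.3)


class TestDifferenceVector:
    def test_identical_pre_post_gives_zero(self, layout):
        values = {lab: float(i) for i, lab in
                  enumerate(layout.peripheral_labels)}
        vec = difference_vector(values, values, layout)
        assert vec.is_zero

    def test_added_focal_excess_sets_difference_azimuth(self, layout):
        pre = {lab: 10.0 for lab in layout.peripheral_labels}
        post = dict(pre)
        post["S7"] += 4.0  # focal softening at 270 deg
        vec = difference_vector(post, pre, layout)
        assert vec.azimuth_deg == pytest.approx(layout.azimuth("S7"))
        assert vec.magnitude == pytest.approx(4.0)

    def test_both_linearity_paths_agree(self, layout, rng):
        pre = {lab: float(v) for lab, v in
               zip(layout.peripheral_labels, rng.uniform(100, 400, 8))}
        post = {lab: float(v) for lab, v in
                zip(layout.peripheral_labels, rng.uniform(100, 400, 8))}
        diff = difference_vector(post, pre, layout)
        v_post = AsymmetryVector.from_values(post, layout)
        v_pre = AsymmetryVector.from_values(pre, layout)
        assert diff.x == pytest.approx(v_post.x - v_pre.x)
        assert diff.y == pytest.approx(v_post.y - v_pre.y)

    def test_label_mismatch_rejected(self, layout):
        pre = {lab: 1.0 for lab in layout.peripheral_labels}
        post = dict(pre)
        post["S9"] = post.pop("S8")
        with pytest.raises(ConfigError, match="S8|S9"):
            difference_vector(post, pre, layout)


class TestAngularDistance:
    @pytest.mark.parametrize(
        "a, b, expected",
        [(318.0, 321.0, 3.0), (350.0, 10.0, 20.0), (123.4, 123.4, 0.0),
         (0.0, 180.0, 180.0), (-18.3, 341.7, 0.0)],
    )
    def test_examples(self, a, b, expected):
        assert angular_distance(a, b) == pytest.approx(expected)

    def test_nonfinite_rejected(self):
        with pytest.raises(ConfigError):
            angular_distance(float("nan"), 0.0)
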