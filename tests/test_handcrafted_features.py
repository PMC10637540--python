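import numpy as np
import pytest

from dvpclust.handcrafted_features import (
    DDR_SENTINEL,
    FEATURE_NAMES,
    detect_fiducials,
    extract_feature_matrix,
    extract_features,
    fit_transform_features,
)
from dvpclust.preprocess import normalize_pulse
from dvpclust.synth_data import make_class_templates, render_template


@pytest.fixture(scope="module")
def class_pulses():
    """Noise-free normalized pulses of the four classes at a neutral age."""
    return {
        p.class_id: normalize_pulse(render_template(p, 100)) for p in make_class_templates()
    }


class TestFiducials:
    def test_class1_landmarks_present_and_ordered(self, class_pulses):
        fid = detect_fiducials(class_pulses[1])
        assert fid.dicrotic_notch_idx is not None
        assert fid.diastolic_peak_idx is not None
        assert (
            fid.onset_idx
            < fid.systolic_peak_idx
            < fid.dicrotic_notch_idx
            <= fid.diastolic_peak_idx
        )
        # the generator places the diastolic wave at t = 0.60 for class 1
        assert abs(fid.diastolic_peak_idx - 59) <= 3

    def test_class4_notch_and_diastolic_absent(self, class_pulses):
        fid = detect_fiducials(class_pulses[4])
        assert fid.diastolic_peak_idx is None

    def test_systolic_peak_is_global_argmax(self, class_pulses):
        for pulse in class_pulses.values():
            assert detect_fiducials(pulse).systolic_peak_idx == int(np.argmax(pulse))

    def test_max_downslope_is_most_negative_post_systolic_derivative(self, class_pulses):
        pulse = class_pulses[2]
        fid = detect_fiducials(pulse)
        d1 = np.gradient(pulse)
        assert fid.max_downslope_idx == fid.systolic_peak_idx + int(
            np.argmin(d1[fid.systolic_peak_idx :])
        )


class TestExtractFeatures:
    def test_vector_has_fourteen_named_entries_in_order(self, class_pulses):
        v = extract_features(class_pulses[1])
        assert v.shape == (14,)
        assert len(FEATURE_NAMES) == 14

    def test_class4_gets_ddr_sentinel(self, class_pulses):
        v = extract_features(class_pulses[4])
        assert v[FEATURE_NAMES.index("DDR")] == DDR_SENTINEL

    def test_class1_ddr_is_a_genuine_ratio_below_one(self, class_pulses):
        # notch amplitude below diastolic-peak amplitude (the class-1 notch
        # is the global minimum of the normalized pulse, so DDR may be 0)
        ddr = extract_features(class_pulses[1])[FEATURE_NAMES.index("DDR")]
        assert 0.0 <= ddr < 1.0
        assert ddr != DDR_SENTINEL

    def test_symmetric_triangle_has_zero_skew_single_peak(self):
        tri = np.concatenate([np.linspace(0, 1, 50), np.linspace(1, 0, 50)])
        v = extract_features(tri)
        assert v[FEATURE_NAMES.index("Skew")] == pytest.approx(0.0, abs=1e-9)
        assert v[FEATURE_NAMES.index("nbr_peaks")] == 1

    def test_class1_two_peaks_and_reflected_wave_flag(self, class_pulses):
        v = extract_features(class_pulses[1])
        assert v[FEATURE_NAMES.index("nbr_peaks")] == 2
        assert v[FEATURE_NAMES.index("AI_bin")] == 1.0

    def test_class4_no_reflected_wave_flag(self, class_pulses):
        v = extract_features(class_pulses[4])
        assert v[FEATURE_NAMES.index("AI_bin")] == 0.0

    def test_total_area_grows_with_systolic_width(self, class_pulses):
        # class 4 has a much wider systolic wave than class 1
        a1 = extract_features(class_pulses[1])[FEATURE_NAMES.index("S_P_Onde")]
        a4 = extract_features(class_pulses[4])[FEATURE_NAMES.index("S_P_Onde")]
        assert a4 > a1

    def test_extraction_total_on_noisy_pulses(self, rng, smooth_pulses):
        # never raises, always 14 finite entries
        for p in smooth_pulses(20, rng):
            noisy = normalize_pulse(p + rng.normal(0, 0.05, size=p.size))
            v = extract_features(noisy)
            assert v.shape == (14,) and np.isfinite(v).all()

    def test_ddr_ordering_class1_below_class3(self, class_pulses):
        ddr1 = extract_features(class_pulses[1])[FEATURE_NAMES.index("DDR")]
        ddr3 = extract_features(class_pulses[3])[FEATURE_NAMES.index("DDR")]
        assert ddr1 < ddr3  # deeper notch relative to the diastolic wave


class TestMatrixAndScaling:
    def test_matrix_columns_named_after_features(self, class_pulses):
        df = extract_feature_matrix(np.vstack(list(class_pulses.values())))
        assert list(df.columns) == FEATURE_NAMES

    def test_train_columns_standardized(self, rng):
        train = rng.normal(5, 2, size=(200, 14))
        scaled, _, _ = fit_transform_features(train)
        np.testing.assert_allclose(scaled.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(scaled.std(axis=0), 1.0, atol=1e-10)

    def test_test_matrix_uses_train_statistics(self, rng):
        train = rng.normal(0, 1, size=(100, 14))
        shifted = train + 10.0
        _, (scaled_shifted,), _ = fit_transform_features(train, shifted)
        # shifted data transformed with train statistics keeps the offset
        assert scaled_shifted.mean() == pytest.approx(10.0, abs=0.5)

    def test_constant_column_error_names_the_feature(self, rng):
        train = rng.normal(0, 1, size=(50, 14))
        train[:, FEATURE_NAMES.index("AI_bin")] = 1.0
        with pytest.raises(ValueError, match="AI_bin"):
            fit_transform_features(train)
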