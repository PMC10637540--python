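import numpy as np
import pandas as pd
import pytest
from scipy.signal import find_peaks

from dvpclust import ddtw
from dvpclust.preprocess import normalize_pulse
from dvpclust.synth_data import (
    COVARIATE_TARGETS,
    CLINICAL_COLUMNS,
    SyntheticConfig,
    generate_dataset,
    generate_pulse,
    make_class_templates,
    render_template,
)


class TestClassTemplates:
    def test_four_classes_with_required_morphology_gradient(self):
        params = make_class_templates()
        assert [p.class_id for p in params] == [1, 2, 3, 4]
        dia = [p.diastolic_amp for p in params]
        notch = [p.notch_depth for p in params]
        assert all(a > b for a, b in zip(dia, dia[1:]))
        assert all(a > b for a, b in zip(notch, notch[1:]))
        assert params[3].diastolic_amp == 0

    def test_class1_has_notch_and_diastolic_peak(self, templates):
        peaks, _ = find_peaks(templates[0], prominence=0.01)
        assert len(peaks) >= 2  # systolic + diastolic wave

    def test_class4_is_a_single_broad_wave(self, templates):
        peaks, _ = find_peaks(templates[3], prominence=0.01)
        assert len(peaks) == 1

    def test_templates_are_amplitude_normalized(self, templates):
        assert np.allclose(templates.max(axis=1), 1.0)
        assert np.allclose(templates.min(axis=1), 0.0)


class TestGeneratePulse:
    def test_diastolic_wave_attenuates_with_age(self):
        p1 = make_class_templates()[0]
        young = render_template(p1, 100, vascular_age=20.0)
        old = render_template(p1, 100, vascular_age=80.0)
        # diastolic-wave amplitude read off at the diastolic center
        idx = int(round(p1.diastolic_center * 99))
        assert young[idx] > old[idx]

    def test_noise_free_class4_has_one_local_maximum(self):
        p4 = make_class_templates()[3]
        pulse = generate_pulse(p4, 50.0, np.random.default_rng(0), noise_sd=0.0, length=100)
        peaks, _ = find_peaks(pulse, prominence=0.01)
        assert len(peaks) == 1

    def test_seeded_determinism_is_bitwise(self):
        p = make_class_templates()[1]
        a = generate_pulse(p, 40.0, np.random.default_rng(7))
        b = generate_pulse(p, 40.0, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_invalid_age_rejected(self):
        with pytest.raises(ValueError):
            generate_pulse(make_class_templates()[0], 17.0, np.random.default_rng(0))

    def test_lengths_span_configured_range(self):
        p = make_class_templates()[0]
        rng = np.random.default_rng(3)
        lengths = {len(generate_pulse(p, 30.0, rng)) for _ in range(200)}
        assert min(lengths) >= 60 and max(lengths) <= 140
        assert len(lengths) > 20


class TestGenerateDataset:
    def test_covariate_moment_recovery_at_10k(self):
        cfg = SyntheticConfig(n_subjects=10_000, pulses_per_subject=1,
                              waveform_noise_sd=0.0, seed=11)
        _, clinical, _ = generate_dataset(cfg)
        for var, (mean, sd, lo, hi) in COVARIATE_TARGETS.items():
            x = clinical[var].to_numpy()
            se = sd / np.sqrt(len(x))
            assert abs(x.mean() - mean) < 3 * se, var
            assert x.min() >= lo - 1e-9 and x.max() <= hi + 1e-9, var

    def test_identical_tables_for_identical_config(self):
        cfg = SyntheticConfig(n_subjects=30, pulses_per_subject=2, seed=5)
        _, t1, _ = generate_dataset(cfg)
        _, t2, _ = generate_dataset(cfg)
        pd.testing.assert_frame_equal(t1, t2)

    def test_degenerate_mixture_plants_one_class(self):
        cfg = SyntheticConfig(n_subjects=50, pulses_per_subject=1,
                              class_mixture=(1, 0, 0, 0), seed=2)
        _, _, labels = generate_dataset(cfg)
        assert set(labels.tolist()) == {1}

    def test_invalid_mixture_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(class_mixture=(0.5, 0.5, 0.5, 0.5))

    def test_table_layout_and_alignment(self):
        cfg = SyntheticConfig(n_subjects=10, pulses_per_subject=3, seed=0)
        pulses, clinical, labels = generate_dataset(cfg)
        assert list(clinical.columns) == CLINICAL_COLUMNS
        assert len(pulses) == len(clinical) == len(labels) == 30

    def test_transit_time_decreases_with_pwv(self):
        cfg = SyntheticConfig(n_subjects=2000, pulses_per_subject=1, seed=4,
                              covariate_noise_sd={"PWV": 1.96, "PAS": 14.31,
                                                  "PAD": 8.70, "TT_frac": 0.0})
        _, clinical, _ = generate_dataset(cfg)
        by_pwv = clinical.sort_values("PWV")
        tt = by_pwv["TT"].to_numpy()
        pwv = by_pwv["PWV"].to_numpy()
        # strictly decreasing wherever PWV strictly increases (clipping at
        # the PWV bounds produces ties with identical TT)
        strict = np.diff(pwv) > 0
        assert (np.diff(tt)[strict] < 0).all()
        assert (np.diff(tt)[~strict] == 0).all()

    def test_older_subjects_favor_higher_classes(self):
        cfg = SyntheticConfig(n_subjects=3000, pulses_per_subject=1, seed=6)
        _, clinical, _ = generate_dataset(cfg)
        mean_age = clinical.groupby("true_class")["age"].mean()
        assert mean_age.is_monotonic_increasing


class TestSeparability:
    def test_noise_free_pulse_is_nearest_its_own_template(self, templates):
        for ci, params in enumerate(make_class_templates()):
            for age in (20.0, 50.0, 80.0):
                pulse = normalize_pulse(render_template(params, 100, vascular_age=age))
                d = [ddtw.ddtw_distance(pulse, templates[j]) for j in range(4)]
                assert int(np.argmin(d)) == ci

    def test_templates_pairwise_ddtw_strictly_positive(self, templates):
        D = ddtw.pairwise_ddtw(templates)
        off = D[~np.eye(4, dtype=bool)]
        assert (off > 0).all()
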