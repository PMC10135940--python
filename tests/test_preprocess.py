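"""Conditioning chain: filter, segmentation, references, screening, channels."""

import numpy as np
import pytest
from scipy import signal as sps
from scipy import stats as sstats

from ppgbp.fixtures import make_quality_batch
from ppgbp.preprocess import (
    DegenerateSegmentError, FilterSpec, bandpass_filter, segment,
    extract_bp_reference, skewness, autocorrelation_sqi, quality_filter,
    minmax_normalize, make_model_input, preprocess_record, screening_summary,
)
from ppgbp.synth import SimConfig, generate_record

FS = 125.0


def analytic_gain(freq_hz, spec=None, fs=FS):
    """Single-pass magnitude response of the designed Butterworth band-pass."""
    spec = spec or FilterSpec()
    w, h = sps.sosfreqz(spec.sos(fs), worN=[freq_hz], fs=fs)
    return float(np.abs(h[0]))


class TestBandpassFilter:
    def test_constant_annihilated(self):
        y = bandpass_filter(np.full(2000, 5.0), FS)
        assert np.max(np.abs(y[200:-200])) < 1e-6

    @pytest.mark.parametrize("mode,power", [("zero-phase", 2), ("causal", 1)])
    def test_passband_tone_matches_analytic_response(self, mode, power):
        t = np.arange(int(30 * FS)) / FS
        x = np.sin(2 * np.pi * 2.0 * t)
        y = bandpass_filter(x, FS, FilterSpec(mode=mode))
        core = slice(int(5 * FS), int(25 * FS))
        ratio = np.sqrt(np.mean(y[core] ** 2)) / np.sqrt(np.mean(x[core] ** 2))
        expected = analytic_gain(2.0) ** power  # zero-phase applies |H| twice
        assert ratio == pytest.approx(expected, rel=0.02)
        assert abs(ratio - 1.0) < 0.12

    def test_stopband_tone_attenuated(self):
        t = np.arange(int(10 * FS)) / FS
        x = np.sin(2 * np.pi * 50.0 * t)
        y = bandpass_filter(x, FS, FilterSpec(mode="causal"))
        core = slice(int(2 * FS), int(8 * FS))
        # quadrature projection isolates the tone from the startup transient
        amp = np.hypot(2 * np.mean(y[core] * np.sin(2 * np.pi * 50 * t[core])),
                       2 * np.mean(y[core] * np.cos(2 * np.pi * 50 * t[core])))
        assert amp < 0.1
        assert amp == pytest.approx(analytic_gain(50.0), rel=0.05)

    def test_length_preserved(self):
        y = bandpass_filter(np.random.default_rng(0).standard_normal(500), FS)
        assert len(y) == 500

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="short"):
            bandpass_filter(np.ones(10), FS)

    def test_high_cut_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(np.ones(500), FS, FilterSpec(high_hz=70.0))


class TestSegmentation:
    def _record(self, duration):
        return generate_record(SimConfig(duration_s=duration, seed=1).clean())

    @pytest.mark.parametrize("duration,stride,expected", [
        (30.0, 3.0, 10),
        (30.0, 1.5, 19),
        (2.0, 3.0, 0),
    ])
    def test_window_count(self, duration, stride, expected):
        segs = segment(self._record(duration), window_s=3.0, stride_s=stride)
        assert len(segs) == expected
        assert all(len(s.ppg_window) == 375 for s in segs)

    def test_abp_cut_at_identical_offsets(self):
        rec = self._record(12.0)
        segs = segment(rec)
        for s in segs:
            np.testing.assert_array_equal(
                s.abp_window, rec.abp[s.start_index : s.start_index + 375]
            )

    def test_abp_stays_raw_mmHg(self):
        """The label pathway must never be filtered or normalized."""
        rec = self._record(12.0)
        inputs, _ = preprocess_record(rec)
        for m in inputs:
            assert 50.0 < m.labels[1] < m.labels[0] < 200.0

    def test_fractional_window_rounds_to_nearest_sample(self):
        rec = self._record(10.0)
        segs = segment(rec, window_s=3.001)  # 375.125 samples -> 375
        assert all(len(s.ppg_window) == 375 for s in segs)

    def test_non_positive_stride_rejected(self):
        rec = self._record(10.0)
        with pytest.raises(ValueError, match="stride"):
            segment(rec, stride_s=0.0)


class TestReferenceExtraction:
    def test_clean_beats_recovered(self):
        rec = generate_record(SimConfig(duration_s=6.0, seed=2).clean())
        sbp, dbp = extract_bp_reference(rec.abp, rec.fs)
        assert sbp == pytest.approx(120.0, abs=0.5)
        assert dbp == pytest.approx(80.0, abs=0.5)

    def test_single_beat_falls_back_to_global_extrema(self):
        rec = generate_record(SimConfig(duration_s=10.0, hr_bpm=60.0, seed=3).clean())
        window = rec.abp[:100]  # less than one full cycle
        sbp, dbp = extract_bp_reference(window, rec.fs)
        assert sbp == pytest.approx(window.max())
        assert dbp == pytest.approx(window.min())

    def test_drifting_sbp_matches_ground_truth_beat_mean(self):
        cfg = SimConfig(duration_s=10.0, hr_bpm=60.0, sbp=115.0, sbp_end=125.0,
                        jitter_frac=0.0, seed=4).clean()
        rec = generate_record(cfg)
        sbp, _ = extract_bp_reference(rec.abp, rec.fs)
        assert sbp == pytest.approx(rec.meta["beat_sbp"].mean(), abs=0.5)

    def test_flat_window_flags_quality_failure(self):
        sbp, dbp = extract_bp_reference(np.full(375, 90.0), FS)
        assert np.isnan(sbp) and np.isnan(dbp)


class TestSkewness:
    def test_symmetric_sequence_is_zero(self):
        assert skewness([1, 2, 3, 4, 5]) == pytest.approx(0.0, abs=1e-12)

    def test_three_zeros_one_one(self):
        assert skewness([0, 0, 0, 1]) == pytest.approx(2 / np.sqrt(3), abs=1e-12)

    def test_matches_population_moment_oracle(self, rng):
        for _ in range(20):
            x = rng.standard_normal(rng.integers(10, 200))
            brute = np.mean(((x - x.mean()) / x.std()) ** 3)
            assert skewness(x) == pytest.approx(brute, abs=1e-10)
            assert skewness(x) == pytest.approx(sstats.skew(x, bias=True), abs=1e-10)

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(100)
        assert skewness(3.7 * x + 11.0) == pytest.approx(skewness(x), abs=1e-10)

    def test_constant_is_degenerate(self):
        assert np.isnan(skewness(np.ones(50)))


class TestAutocorrelationSQI:
    def test_pure_sinusoid_near_one(self):
        t = np.arange(375) / FS
        assert autocorrelation_sqi(np.sin(2 * np.pi * 1.2 * t), FS) >= 0.99

    def test_white_noise_low(self, rng):
        vals = [autocorrelation_sqi(rng.standard_normal(375), FS) for _ in range(5)]
        assert max(vals) < 0.3

    def test_corrupted_segment_below_threshold(self):
        damaged = make_quality_batch()[3].ppg_window
        assert autocorrelation_sqi(damaged, FS) < 0.6

    def test_damage_reduces_periodicity(self):
        clean = make_quality_batch()[4].ppg_window
        half = clean.copy()
        half[len(half) // 2 :] = 0.0
        assert autocorrelation_sqi(half, FS) < autocorrelation_sqi(clean, FS)

    def test_matches_brute_force_pearson(self, rng):
        x = rng.standard_normal(375)
        lag_min, lag_max = 50, 250  # fs*60/150 .. fs*60/30
        brute = max(
            np.corrcoef(x[:-lag], x[lag:])[0, 1] for lag in range(lag_min, lag_max + 1)
        )
        assert autocorrelation_sqi(x, FS) == pytest.approx(brute, abs=1e-10)

    def test_zero_variance_degenerate(self):
        assert np.isnan(autocorrelation_sqi(np.zeros(375), FS))


class TestQualityFilter:
    def test_constructed_batch_keeps_exactly_one(self):
        kept, reports = quality_filter(make_quality_batch())
        assert len(kept) == 1
        assert reports[4].passed
        assert reports[0].fail_reasons == ["bp_range"]
        assert reports[1].fail_reasons == ["bp_range"]
        assert reports[2].fail_reasons == ["skewness"]
        assert reports[3].fail_reasons == ["autocorrelation"]

    def test_counts_reconcile(self):
        kept, reports = quality_filter(make_quality_batch())
        s = screening_summary(reports)
        failed_segments = sum(1 for r in reports if not r.passed)
        assert s["total"] == s["kept"] + s["failed"]
        assert s["failed"] == failed_segments
        assert sum(s["failures_per_rule"].values()) >= s["failed"]

    def test_empty_input(self):
        kept, reports = quality_filter([])
        assert kept == [] and reports == []

    def test_clean_batch_fully_kept(self, small_dataset):
        # small_dataset is built by preprocess_records on clean records:
        # every generated segment must have survived screening
        X, y, _ = small_dataset
        assert len(X) == 40 * 3  # 40 records x 3 windows of 10 s


class TestNormalizationAndChannels:
    @pytest.mark.parametrize("x,expected", [
        ([2, 4, 6], [0.0, 0.5, 1.0]),
        ([-1, 0, 3], [0.0, 0.25, 1.0]),
    ])
    def test_minmax_examples(self, x, expected):
        np.testing.assert_allclose(minmax_normalize(x), expected, atol=1e-12)

    def test_minmax_idempotent(self, rng):
        x = minmax_normalize(rng.standard_normal(100))
        np.testing.assert_allclose(minmax_normalize(x), x, atol=1e-12)

    def test_minmax_constant_rejected(self):
        with pytest.raises(DegenerateSegmentError):
            minmax_normalize(np.full(10, 3.3))

    def test_model_input_contract(self, clean_record):
        inputs, _ = preprocess_record(clean_record)
        m = inputs[0]
        assert m.channels.shape == (3, 375)
        assert m.channels.min() >= 0.0 and m.channels.max() <= 1.0
        assert m.channels[0].min() == 0.0 and m.channels[0].max() == 1.0
        assert m.labels[0] > m.labels[1]

    def test_apg_is_double_difference(self, clean_record):
        from ppgbp.preprocess import bandpass_filter, segment as seg_fn, extract_bp_reference

        filtered = bandpass_filter(clean_record.ppg, clean_record.fs)
        seg = seg_fn(clean_record, ppg=filtered)[2]
        seg.sbp_ref, seg.dbp_ref = extract_bp_reference(seg.abp_window, clean_record.fs)
        m = make_model_input(seg)
        ch0 = minmax_normalize(seg.ppg_window)
        vpg = np.append(np.diff(ch0), np.diff(ch0)[-1])
        apg = np.append(np.diff(vpg), np.diff(vpg)[-1])
        np.testing.assert_allclose(m.channels[2], minmax_normalize(apg), atol=1e-12)

    def test_linear_ramp_degenerate_vpg(self):
        from ppgbp.preprocess import SegmentPair

        seg = SegmentPair(
            ppg_window=np.linspace(0, 1, 375), abp_window=np.zeros(375),
            start_index=0, sbp_ref=120.0, dbp_ref=80.0,
        )
        with pytest.raises(DegenerateSegmentError, match="derivative"):
            make_model_input(seg)

    def test_stage_order_recorded(self, clean_record):
        inputs, _ = preprocess_record(clean_record)
        assert inputs, "clean record should yield kept segments"
        for m in inputs:
            assert m.provenance == [
                "filtered", "segmented", "referenced", "screened", "normalized",
            ]
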