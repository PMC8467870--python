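"""Filter response, label-preserving filtering, segmentation, window labels."""

import numpy as np
import pytest

from arousalstack.config import FilterSpec, SegmentationConfig
from arousalstack.preprocess import (
    apply_filter,
    design_filter,
    frequency_response,
    label_segment,
    segment_record,
)
from arousalstack.synthetic import EEGRecord

FS = 200.0


@pytest.fixture(scope="module")
def fir():
    return design_filter(FilterSpec(), FS)


class TestDesign:
    def test_tap_count_matches_order_127(self, fir):
        kind, taps = fir
        assert kind == "fir"
        assert len(taps) == 128

    def test_dc_gain_unity(self, fir):
        w, h = frequency_response(fir)
        assert abs(abs(h[0]) - 1.0) <= 0.01

    def test_60hz_attenuation_exceeds_30db(self, fir):
        w, h = frequency_response(fir, n=4096)
        mag_db = 20 * np.log10(np.abs(h) + 1e-300)
        assert mag_db[np.argmin(np.abs(w - 60.0))] <= -30.0

    def test_passband_near_unity_below_39hz(self, fir):
        w, h = frequency_response(fir)
        band = (w >= 0.5) & (w <= 39.0)
        assert np.abs(np.abs(h[band]) - 1.0).max() <= 0.06

    def test_iir_mode_also_rejects_mains(self):
        coefs = design_filter(FilterSpec(realization="iir"), FS)
        w, h = frequency_response(coefs)
        assert 20 * np.log10(abs(h[np.argmin(np.abs(w - 60.0))])) <= -30.0

    def test_edges_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError):
            design_filter(FilterSpec(passband_edge=98.0, stopband_edge=100.0), FS)
        with pytest.raises(ValueError):
            design_filter(FilterSpec(passband_edge=90.0, stopband_edge=110.0), FS)


def _sine_record(freq: float, seconds: float = 30.0) -> EEGRecord:
    t = np.arange(int(seconds * FS)) / FS
    x = np.sin(2 * np.pi * freq * t)
    return EEGRecord(x, np.zeros_like(x, dtype=np.int8), FS)


class TestApply:
    def test_60hz_sinusoid_suppressed(self, fir):
        rec = _sine_record(60.0)
        out = apply_filter(rec, fir)
        core = slice(400, -400)  # avoid edge transients
        ratio = np.std(out.samples[core]) / np.std(rec.samples[core])
        assert ratio <= 0.05

    def test_10hz_sinusoid_passes(self, fir):
        rec = _sine_record(10.0)
        out = apply_filter(rec, fir)
        core = slice(400, -400)
        ratio = np.std(out.samples[core]) / np.std(rec.samples[core])
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_zero_in_zero_out(self, fir):
        rec = EEGRecord(np.zeros(2000), np.zeros(2000, dtype=np.int8), FS)
        out = apply_filter(rec, fir)
        np.testing.assert_allclose(out.samples, 0.0)

    def test_linearity(self, fir, rng):
        x = rng.standard_normal(4000)
        y = rng.standard_normal(4000)
        zeros = np.zeros(4000, dtype=np.int8)
        fx = apply_filter(EEGRecord(x, zeros, FS), fir).samples
        fy = apply_filter(EEGRecord(y, zeros, FS), fir).samples
        fxy = apply_filter(EEGRecord(2.0 * x - 3.0 * y, zeros, FS), fir).samples
        np.testing.assert_allclose(fxy, 2.0 * fx - 3.0 * fy, atol=1e-9)

    def test_labels_pass_through_unchanged(self, fir, rng):
        labels = (rng.random(3000) < 0.3).astype(np.int8)
        rec = EEGRecord(rng.standard_normal(3000), labels, FS)
        out = apply_filter(rec, fir)
        np.testing.assert_array_equal(out.labels, labels)

    def test_empty_record_rejected(self, fir):
        with pytest.raises(ValueError):
            apply_filter(EEGRecord(np.array([]), np.array([], dtype=np.int8), FS), fir)


def _record_of_hours(hours: float, extra_seconds: float = 0.0) -> EEGRecord:
    n = int((hours * 3600 + extra_seconds) * FS)
    return EEGRecord(np.zeros(n), np.zeros(n, dtype=np.int8), FS)


class TestSegmentation:
    def test_six_hour_record_gives_480_segments(self):
        segs = segment_record(_record_of_hours(6))
        assert len(segs) == 480  # (6h - 2h edges) / 30 s

    def test_two_hour_record_gives_none(self):
        assert segment_record(_record_of_hours(2)) == []

    def test_partial_trailing_window_dropped(self):
        segs = segment_record(_record_of_hours(4, extra_seconds=10.0))
        assert len(segs) == 240

    def test_segments_partition_usable_span(self):
        segs = segment_record(_record_of_hours(3))
        offsets = [s.start_offset for s in segs]
        assert offsets[0] == 3600.0
        assert np.all(np.diff(offsets) == 30.0)
        assert all(len(s.x) == 6000 for s in segs)


class TestWindowLabel:
    def test_all_zero_and_all_one(self):
        assert label_segment(np.zeros(6000, dtype=np.int8)) == 0
        assert label_segment(np.ones(6000, dtype=np.int8)) == 1

    def test_3s_run_threshold(self):
        lab = np.zeros(6000, dtype=np.int8)
        lab[100:600] = 1  # 2.5 s
        assert label_segment(lab) == 0
        lab[100:700] = 1  # 3.0 s
        assert label_segment(lab) == 1

    def test_fragmented_runs_do_not_sum(self):
        lab = np.zeros(6000, dtype=np.int8)
        lab[0:400] = 1
        lab[1000:1400] = 1
        lab[2000:2400] = 1  # 3 x 2 s, no single 3-s run
        assert label_segment(lab) == 0

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            label_segment(np.zeros(5999, dtype=np.int8))

    def test_agrees_with_brute_force_run_scan(self, rng):
        for _ in range(50):
            lab = (rng.random(6000) < 0.995).astype(np.int8)  # long runs likely
            best = run = 0
            for v in lab:
                run = run + 1 if v else 0
                best = max(best, run)
            assert label_segment(lab) == int(best >= 600)


class TestWindowLabelProperties:
    """Property: the window rule equals a brute-force longest-run scan."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.lists(st.booleans(), min_size=200, max_size=200))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_longest_run_scan(self, bits):
        lab = np.asarray(bits, dtype=np.int8)
        best = run = 0
        for v in lab:
            run = run + 1 if v else 0
            best = max(best, run)
        got = label_segment(lab, min_run_seconds=0.1, sampling_rate=200.0,
                            n_samples=200)
        assert got == int(best >= 20)

    @given(st.integers(min_value=0, max_value=180), st.integers(min_value=1, max_value=40))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_single_run_threshold_is_sharp(self, start, length):
        lab = np.zeros(200, dtype=np.int8)
        lab[start : start + length] = 1
        length = int(lab.sum())  # clipped at the window edge
        got = label_segment(lab, min_run_seconds=0.1, sampling_rate=200.0,
                            n_samples=200)
        assert got == int(length >= 20)


def test_end_to_end_segment_labels_match_recount():
    """Segment labels recomputed per window from raw sample labels."""
    from conftest import make_synth
    from arousalstack.synthetic import generate_record

    rec = generate_record(make_synth(seconds=1800.0, seed=31))
    seg_cfg = SegmentationConfig(discard_edges_seconds=0.0)
    for seg in segment_record(rec, seg_cfg):
        i0 = int(seg.start_offset * FS)
        window = rec.labels[i0 : i0 + 6000]
        assert seg.label == label_segment(window)
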