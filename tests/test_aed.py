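import numpy as np
import pytest

from rriguard.aed import (
    DetectionThresholds,
    calibrate_re_threshold,
    calibrate_rri_limits,
    classify_beat,
    detect_stream,
)
from rriguard.rri_data import RRISeries, build_hankel
from rriguard.neuralnet import reconstruction_error
from rriguard.synthgen import (
    InjectionConfig,
    contaminate,
    inject_af_segment,
    inject_pac,
    inject_pvc,
    simulate_normal_rri,
)

# roomy manual thresholds for the zero-weight model, whose RE is just the
# centered-window norm: clean constant windows score 0, spikes score large
TH = DetectionThresholds(re_max=50.0, r1=700.0, r2=950.0)


class TestCalibration:
    def test_re_ceiling_is_validation_maximum(self, ae_model, validation_series):
        re_max = calibrate_re_threshold(ae_model, validation_series)
        rows = build_hankel(validation_series).rows
        res = reconstruction_error(
            ae_model, rows - rows.mean(axis=1, keepdims=True)
        )
        assert re_max == pytest.approx(np.max(res))

    def test_zero_positives_on_calibration_series(
        self, ae_model, thresholds, validation_series
    ):
        labels = detect_stream(ae_model, thresholds, validation_series)
        assert all(l.label == "NORMAL" for l in labels)

    def test_too_few_windows_rejected(self, ae_model):
        with pytest.raises(ValueError, match="50"):
            calibrate_re_threshold(ae_model, simulate_normal_rri(20, seed=1))

    def test_uniform_limits_match_analytic_percentiles(self):
        rng = np.random.default_rng(8)
        s = RRISeries(rri=rng.uniform(700.0, 900.0, size=100_000))
        r1, r2 = calibrate_rri_limits(s, alpha=99.0)
        assert r1 == pytest.approx(701.0, abs=1.0)
        assert r2 == pytest.approx(899.0, abs=1.0)

    def test_alpha_100_gives_min_and_max(self):
        rng = np.random.default_rng(9)
        s = RRISeries(rri=rng.uniform(700.0, 900.0, size=1000))
        r1, r2 = calibrate_rri_limits(s, alpha=100.0)
        assert r1 == s.rri.min() and r2 == s.rri.max()

    def test_limits_ordered(self, validation_series):
        r1, r2 = calibrate_rri_limits(validation_series)
        assert r1 < r2


class TestClassifyBeat:
    """Branch predicates via a zero-weight model (RE = centered norm)."""

    def test_short_then_long_is_pvc(self, zero_model):
        lab = classify_beat(zero_model, TH, [800.0, 800.0, 800.0, 600.0], 1000.0)
        assert lab.label == "PVC"

    def test_short_then_normal_is_pac(self, zero_model):
        lab = classify_beat(zero_model, TH, [800.0, 800.0, 800.0, 600.0], 800.0)
        assert lab.label == "PAC"

    def test_short_then_short_is_other(self, zero_model):
        lab = classify_beat(zero_model, TH, [800.0, 800.0, 800.0, 600.0], 600.0)
        assert lab.label == "OTHER"

    def test_doubled_interval_is_rde(self, zero_model):
        lab = classify_beat(zero_model, TH, [800.0, 800.0, 800.0, 1600.0], 800.0)
        assert lab.label == "RDE"

    def test_long_after_short_is_pvc_not_rde(self, zero_model):
        # compensatory pause following a short interval must not be read as
        # a detection error
        lab = classify_beat(zero_model, TH, [800.0, 800.0, 600.0, 1000.0], 800.0)
        assert lab.label == "PVC"

    def test_small_re_is_normal_regardless_of_intervals(self, zero_model):
        lab = classify_beat(zero_model, TH, [810.0, 800.0, 790.0, 800.0], 2000.0)
        assert lab.label == "NORMAL"


class TestDetectStream:
    def test_constant_series_all_normal(self, zero_model):
        s = RRISeries(rri=[800.0] * 50)
        assert all(l.label == "NORMAL" for l in detect_stream(zero_model, TH, s))

    def test_single_pvc_yields_one_label_at_event(self, ae_model, thresholds):
        clean = simulate_normal_rri(400, seed=60)
        dirty, _ = inject_pvc(clean, 200, 300.0)
        labels = detect_stream(ae_model, thresholds, dirty)
        ectopic = [l for l in labels if l.label != "NORMAL"]
        assert len(ectopic) == 1
        assert ectopic[0].beat_index == 200
        assert ectopic[0].label == "PVC"

    def test_single_pac_yields_one_label_at_event(self, ae_model, thresholds):
        clean = simulate_normal_rri(400, seed=61)
        dirty, _ = inject_pac(clean, 200, 300.0)
        labels = detect_stream(ae_model, thresholds, dirty)
        ectopic = [l for l in labels if l.label != "NORMAL"]
        assert len(ectopic) == 1
        assert ectopic[0].beat_index == 200
        assert ectopic[0].label == "PAC"

    def test_deterministic(self, ae_model, thresholds):
        s, _ = contaminate(
            simulate_normal_rri(2000, seed=62), InjectionConfig(seed=63)
        )
        a = detect_stream(ae_model, thresholds, s)
        b = detect_stream(ae_model, thresholds, s)
        assert [(l.beat_index, l.label) for l in a] == [
            (l.beat_index, l.label) for l in b
        ]

    def test_one_label_per_beat(self, ae_model, thresholds):
        s = simulate_normal_rri(500, seed=64)
        labels = detect_stream(ae_model, thresholds, s)
        assert [l.beat_index for l in labels] == list(range(len(s)))

    def test_af_segment_barely_detected(self, ae_model, thresholds):
        """The small-amplitude AF surrogate should pass almost unnoticed."""
        clean = simulate_normal_rri(2000, seed=65)
        dirty, log = inject_af_segment(clean, 800, 80, seed=66)
        labels = detect_stream(ae_model, thresholds, dirty)
        af_beats = {e.beat_index for e in log}
        flagged = [l for l in labels if l.label != "NORMAL" and l.beat_index in af_beats]
        assert len(flagged) < 0.05 * len(af_beats)

    def test_sensitivity_monotone_in_pulse_height(self, ae_model, thresholds):
        """Bigger compensatory pulses are never harder to detect."""
        rng = np.random.default_rng(67)
        sens = []
        for H in (120.0, 200.0, 300.0):
            hits = 0
            n_events = 170
            clean = simulate_normal_rri(20000, seed=68)
            dirty = clean.replace(clean.rri.copy())
            positions = np.arange(100, 100 + 110 * n_events, 110)
            for p in positions:
                dirty, _ = inject_pvc(dirty, int(p), H)
            labels = detect_stream(ae_model, thresholds, dirty)
            flagged = {l.beat_index for l in labels if l.label != "NORMAL"}
            hits = sum(
                1 for p in positions if any(abs(b - p) <= 1 for b in flagged)
            )
            sens.append(hits / n_events)
        assert sens[0] <= sens[1] <= sens[2]

    def test_high_pulse_sensitivity(self, ae_model, thresholds):
        """Events with H >= 250 ms on a low-noise surrogate are nearly all caught."""
        clean = simulate_normal_rri(20000, seed=69)
        dirty = clean.replace(clean.rri.copy())
        rng = np.random.default_rng(70)
        positions = np.arange(100, 100 + 110 * 170, 110)
        for p in positions:
            dirty, _ = inject_pvc(dirty, int(p), float(rng.uniform(250, 369)))
        labels = detect_stream(ae_model, thresholds, dirty)
        flagged = {l.beat_index for l in labels if l.label != "NORMAL"}
        hits = sum(1 for p in positions if any(abs(b - p) <= 1 for b in flagged))
        assert hits / len(positions) >= 0.95
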