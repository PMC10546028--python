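"""Timelines, segmentation, response summaries and phenotype rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neurohemo.protocol import (
    ProtocolTimeline,
    Segment,
    Thresholds,
    build_timeline,
    classify_flow,
    classify_oxygenation,
    segment_indices,
    summarize_response,
)

FS = 10.0


class TestTimeline:
    def test_vft_defaults_total_160_s(self):
        tl = build_timeline("VFT")
        assert tl.total_duration_s == pytest.approx(160.0)
        assert [s.duration_s for s in tl.segments] == [30.0, 60.0, 70.0]

    def test_zero_length_recovery_rejected(self):
        with pytest.raises(ValueError):
            build_timeline("HCT", recovery_s=0.0)

    def test_vbh_task_is_breath_hold_span(self):
        tl = build_timeline("VBH", events={"breath_start": 30.0, "breath_end": 55.0})
        assert tl.segment("task").duration_s == pytest.approx(25.0)
        assert tl.segment("baseline").duration_s == pytest.approx(30.0)

    def test_vbh_requires_events(self):
        with pytest.raises(ValueError, match="breath"):
            build_timeline("VBH")

    def test_event_outside_recording_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            ProtocolTimeline(
                "VFT",
                (Segment("baseline", 0, 30), Segment("task", 30, 60),
                 Segment("recovery", 90, 70)),
                {"marker": 500.0},
            )

    def test_json_round_trip(self, tmp_path):
        tl = build_timeline("VBH", events={"breath_start": 30.0, "breath_end": 70.0})
        path = tmp_path / "t.json"
        tl.to_json(path)
        assert ProtocolTimeline.from_json(path) == tl


class TestSegmentation:
    def test_sample_counts_on_default_grid(self):
        tl = build_timeline("VFT")
        time = np.arange(0, 160, 1 / FS)
        idx = segment_indices(time, tl)
        assert idx["baseline"].size == 300
        assert idx["task"].size == 600
        assert idx["recovery"].size == 700

    def test_boundary_sample_goes_to_later_segment(self):
        tl = build_timeline("VFT")
        time = np.arange(0, 160, 1 / FS)
        idx = segment_indices(time, tl)
        i30 = np.flatnonzero(time == 30.0)[0]
        assert i30 in idx["task"] and i30 not in idx["baseline"]

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="timeline"):
            segment_indices(np.arange(0, 100, 0.1), build_timeline("VFT"))

    @settings(max_examples=30, derandomize=True)
    @given(
        b=st.floats(5, 50), t=st.floats(5, 80), r=st.floats(5, 80),
        fs=st.sampled_from([2.0, 5.0, 10.0]),
    )
    def test_partition_property(self, b, t, r, fs):
        """Every in-range sample lands in exactly one segment."""
        tl = build_timeline("VFT", b, t, r)
        time = np.arange(0, tl.total_duration_s + 5, 1 / fs)
        idx = segment_indices(time, tl)
        all_idx = np.concatenate(list(idx.values()))
        in_range = np.flatnonzero((time >= 0) & (time < tl.total_duration_s))
        assert np.array_equal(np.sort(all_idx), in_range)
        assert len(np.unique(all_idx)) == all_idx.size


class TestSummaries:
    def _series(self, values):
        tl = build_timeline("VFT")
        time = np.arange(0, 160, 1 / FS)
        return summarize_response({"x": values(time)}, time, tl)

    def test_flat_zero_series_all_zero(self):
        s = self._series(lambda t: np.zeros_like(t))["x"]
        assert s.task_delta == 0 and s.recovery_delta == 0 and s.task_slope == 0
        assert s.fluctuation_index == 0.0  # 0/0 guarded

    def test_task_ramp_matches_closed_form(self):
        """Linear ramp of height A over the task: mean = A/2, slope = A/60."""
        A = 2.0

        def ramp(t):
            x = np.zeros_like(t)
            in_task = (t >= 30) & (t < 90)
            x[in_task] = A * (t[in_task] - 30) / 60.0
            x[t >= 90] = 0.0
            return x

        s = self._series(ramp)["x"]
        assert s.task_delta == pytest.approx(A / 2, rel=0.01)
        assert s.task_slope == pytest.approx(A / 60, rel=0.01)

    def test_small_segment_rejected(self):
        tl = build_timeline("VFT")
        time = np.arange(0, 160, 25.0)  # ~1 sample per segment
        with pytest.raises(ValueError, match="samples"):
            summarize_response({"x": np.zeros(time.size)}, time, tl)

    def test_statistics_respect_segment_membership(self, rng):
        """Moving the recovery values never changes task statistics."""
        tl = build_timeline("VFT")
        time = np.arange(0, 160, 1 / FS)
        x = rng.normal(size=time.size)
        y = x.copy()
        y[time >= 90] += 100.0
        sx = summarize_response({"x": x}, time, tl)["x"]
        sy = summarize_response({"x": y}, time, tl)["x"]
        assert sx.task_delta == sy.task_delta
        assert sx.task_slope == sy.task_slope


def _mock_summary(d_o, d_h, protocol="VFT"):
    time = np.arange(0, 160, 1 / FS)
    tl = build_timeline(protocol, events=(
        {"breath_start": 30.0, "breath_end": 90.0} if protocol == "VBH" else None
    ))
    block = ((time >= 30) & (time < 90)).astype(float)
    return summarize_response(
        {"dHbO2": d_o * block, "dHb": d_h * block}, time, tl
    )


class TestOxygenationRules:
    def test_healthy_like_activation(self):
        label, margins = classify_oxygenation(_mock_summary(+0.8, -0.3))
        assert label == "typical_activation"
        assert margins["typical_activation"] > 0

    def test_ischemia_when_both_decline(self):
        assert classify_oxygenation(_mock_summary(-0.6, -0.3))[0] == "task_ischemia"

    def test_blunted_when_amplitudes_small(self):
        assert classify_oxygenation(_mock_summary(+0.05, -0.03))[0] == "blunted"

    def test_vbh_typical_hypoxia(self):
        label, _ = classify_oxygenation(_mock_summary(-0.5, +0.3, "VBH"))
        assert label == "hypoxia_typical"

    def test_vbh_paradoxical_rise_is_atypical(self):
        label, _ = classify_oxygenation(_mock_summary(+0.4, +0.3, "VBH"))
        assert label == "hypoxia_atypical"

    def test_threshold_monotone_toward_blunted(self):
        """Raising the blunted ceiling can only move labels toward blunted."""
        summary = _mock_summary(+0.15, -0.12)
        labels = [
            classify_oxygenation(summary, thresholds=Thresholds(theta_blunted_um=tb))[0]
            for tb in (0.05, 0.1, 0.2, 0.5)
        ]
        seen_blunted = False
        for lab in labels:
            if seen_blunted:
                assert lab == "blunted"
            seen_blunted = seen_blunted or lab == "blunted"


def _flow_summary(shape, protocol="VFT", noise_sd=2.0):
    """Summary of a mock rCBF shape plus a measurement-noise floor (without
    noise the baseline band SD is numerically degenerate and the
    fluctuation-index ratio is meaningless)."""
    time = np.arange(0, 160, 0.5)
    tl = build_timeline(protocol, events=(
        {"breath_start": 30.0, "breath_end": 90.0} if protocol == "VBH" else None
    ))
    noise = np.random.default_rng(0).normal(0, noise_sd, time.size)
    return summarize_response({"rCBF": shape(time) + noise}, time, tl)


class TestFlowRules:
    def test_constant_flow_is_stable(self):
        label, _ = classify_flow(_flow_summary(lambda t: np.full_like(t, 100.0)))
        assert label == "stable"

    def test_oscillation_during_task_is_instability(self):
        def shape(t):
            gate = (t >= 30) & (t < 90)
            return 100 + 15 * np.sin(2 * np.pi * 0.1 * t) * gate

        assert classify_flow(_flow_summary(shape))[0] == "flow_instability"

    @staticmethod
    def _smooth_block(t, amplitude, sustain=False, tau=10.0):
        """Saturating rise during the 30–90 s task; optional plateau hold."""
        x = np.full_like(t, 100.0)
        in_task = (t >= 30) & (t < 90)
        x[in_task] += amplitude * (1 - np.exp(-(t[in_task] - 30) / tau))
        end_val = amplitude * (1 - np.exp(-60 / tau))
        post = t >= 90
        x[post] += end_val if sustain else end_val * np.exp(-(t[post] - 90) / tau)
        return x

    def test_sustained_rise_is_task_increase(self):
        shape = lambda t: self._smooth_block(t, +10.0, sustain=True)
        assert classify_flow(_flow_summary(shape))[0] == "task_increase"

    def test_drop_with_recovery_is_task_decrease_recover(self):
        shape = lambda t: self._smooth_block(t, -12.0)
        assert classify_flow(_flow_summary(shape))[0] == "task_decrease_recover"

    def test_vbh_dip_then_hyperemia(self):
        def shape(t):
            x = np.full_like(t, 100.0)
            hold = (t >= 30) & (t < 90)
            x[hold] -= 10 * (1 - np.exp(-(t[hold] - 30) / 20.0))
            post = t >= 90
            s = t[post] - 90
            end = -10 * (1 - np.exp(-3.0))
            x[post] += end * np.exp(-s / 10) + 20 * (s / 6) * np.exp(1 - s / 6)
            return x

        assert classify_flow(_flow_summary(shape, "VBH"))[0] == "vbh_dip_hyperemia"

    def test_rules_always_return_margins(self):
        label, margins = classify_flow(_flow_summary(lambda t: np.full_like(t, 100.0)))
        assert {"task_delta_pct", "fluctuation_index", "stable"} <= margins.keys()
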