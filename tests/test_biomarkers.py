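"""Biomarker extraction against closed-form synthetic ground truth."""

import math
from dataclasses import replace

import numpy as np
import pytest

from popneuron.biomarkers import (BiomarkerSet, ahp_tau, compute_biomarkers,
                                  detect_aps, firing_rate, full_width,
                                  half_width, peak_and_slopes,
                                  resting_membrane_potential,
                                  threshold_voltage)
from popneuron.protocols import step_protocol
from popneuron.synthetic import SyntheticSpikeSpec, generate_trace
from popneuron.trace import Trace


def flat_trace(v=-65.0, t_stop=100.0, dt=0.05):
    t = np.arange(0.0, t_stop, dt)
    return Trace(t=t, v=np.full_like(t, v))


class TestDetectAps:
    def test_flat_trace_no_events(self):
        assert detect_aps(flat_trace()) == []

    def test_three_spikes_at_known_times(self):
        spec = SyntheticSpikeSpec(spike_times=(100.0, 300.0, 500.0),
                                  t_stop=800.0)
        trace, _ = generate_trace(spec)
        events = detect_aps(trace)
        assert len(events) == 3
        expected_peaks = [t0 + spec.foot_duration + spec.rise_duration
                          for t0 in spec.spike_times]
        for ev, tp in zip(events, expected_peaks):
            assert trace.t[ev.peak_index] == pytest.approx(tp, abs=0.1)
            assert ev.peak_voltage == pytest.approx(spec.peak, abs=0.5)

    def test_subthreshold_oscillation_ignored(self):
        t = np.arange(0.0, 500.0, 0.05)
        v = -45.0 + 25.0 * np.sin(2 * np.pi * t / 50.0)  # -70..-20 mV
        assert detect_aps(Trace(t=t, v=v)) == []


class TestThresholdVoltage:
    def test_slope_break_recovered(self):
        spec = SyntheticSpikeSpec(spike_times=(200.0,), threshold=-40.0,
                                  foot_slope=2.0, rise_slope=20.0, t_stop=600.0)
        trace, truth = generate_trace(spec)
        assert threshold_voltage(trace) == pytest.approx(-40.0, abs=1.0)

    def test_never_surpassing_gradient_is_flagged(self):
        t = np.arange(0.0, 200.0, 0.05)
        v = -65.0 + 0.4 * t  # 0.4 mV/ms everywhere, crosses 0 at 162.5 ms
        assert math.isnan(threshold_voltage(Trace(t=t, v=v)))

    def test_no_ap_is_flagged(self):
        assert math.isnan(threshold_voltage(flat_trace()))


class TestPeakAndSlopes:
    def test_triangle_spike_slopes(self):
        spec = SyntheticSpikeSpec(spike_times=(100.0,), rise_slope=100.0,
                                  fall_slope=50.0, foot_slope=4.0, t_stop=400.0)
        trace, truth = generate_trace(spec)
        ev = detect_aps(trace)[0]
        peak, smax, smin = peak_and_slopes(ev, trace)
        assert peak == pytest.approx(spec.peak, abs=0.5)
        assert smax == pytest.approx(100.0, rel=0.02)
        assert smin == pytest.approx(-50.0, rel=0.02)

    def test_symmetric_spike(self):
        spec = SyntheticSpikeSpec(spike_times=(100.0,), rise_slope=80.0,
                                  fall_slope=80.0, t_stop=400.0)
        trace, _ = generate_trace(spec)
        ev = detect_aps(trace)[0]
        _, smax, smin = peak_and_slopes(ev, trace)
        assert smax == pytest.approx(-smin, rel=0.02)


class TestWidths:
    def test_triangle_widths_match_arithmetic(self):
        spec = SyntheticSpikeSpec(spike_times=(100.0,), threshold=-40.0,
                                  peak=40.0, rise_slope=100.0, fall_slope=50.0,
                                  t_stop=400.0)
        trace, truth = generate_trace(spec)
        ev = detect_aps(trace)[0]
        # full width: 80 mV climb at 100 + 80 mV drop at 50 = 0.8 + 1.6 ms
        assert truth["full_width"] == pytest.approx(2.4)
        assert full_width(ev, trace, -40.0) == pytest.approx(2.4, abs=0.02)
        # half width at 0 mV: half the excursion at both slopes
        assert half_width(ev, trace, -40.0) == pytest.approx(1.2, abs=0.02)

    def test_half_not_exceeding_full(self):
        for rise, fall in [(60.0, 30.0), (120.0, 90.0), (200.0, 40.0)]:
            spec = SyntheticSpikeSpec(spike_times=(100.0,), rise_slope=rise,
                                      fall_slope=fall, t_stop=400.0)
            trace, _ = generate_trace(spec)
            ev = detect_aps(trace)[0]
            assert (half_width(ev, trace, spec.threshold)
                    <= full_width(ev, trace, spec.threshold))

    def test_threshold_above_peak_flagged(self):
        spec = SyntheticSpikeSpec(spike_times=(100.0,), t_stop=400.0)
        trace, _ = generate_trace(spec)
        ev = detect_aps(trace)[0]
        assert math.isnan(full_width(ev, trace, 60.0))
        assert math.isnan(half_width(ev, trace, 60.0))

    def test_interpolation_beats_sampling_quantisation(self):
        spec = SyntheticSpikeSpec(spike_times=(100.0,), t_stop=400.0)
        fine, _ = generate_trace(spec)
        coarse, _ = generate_trace(replace(spec, sampling_hz=10000.0))
        w_fine = full_width(detect_aps(fine)[0], fine, spec.threshold)
        w_coarse = full_width(detect_aps(coarse)[0], coarse, spec.threshold)
        assert abs(w_fine - w_coarse) < 0.1  # one coarse sample interval

    def test_time_dilation_scales_widths_linearly(self):
        """Halving both slopes doubles the excursion times, hence widths."""
        spec = SyntheticSpikeSpec(spike_times=(100.0,), rise_slope=100.0,
                                  fall_slope=50.0, t_stop=400.0)
        slow = replace(spec, rise_slope=50.0, fall_slope=25.0)
        tr1, _ = generate_trace(spec)
        tr2, _ = generate_trace(slow)
        w1 = full_width(detect_aps(tr1)[0], tr1, spec.threshold)
        w2 = full_width(detect_aps(tr2)[0], tr2, spec.threshold)
        assert w2 == pytest.approx(2.0 * w1, rel=0.02)


class TestAhpTau:
    @pytest.mark.parametrize("tau", [5.0, 12.0, 30.0])
    def test_recovers_generator_tau_under_noise(self, tau):
        spec = SyntheticSpikeSpec(spike_times=(100.0,), ahp_tau=tau,
                                  ahp_depth=10.0, noise_sd=0.1, seed=7,
                                  t_stop=500.0)
        trace, _ = generate_trace(spec)
        ev = detect_aps(trace)[0]
        assert ahp_tau(trace, ev) == pytest.approx(tau, rel=0.02)

    def test_constant_after_minimum_is_flagged(self):
        t = np.arange(0.0, 100.0, 0.05)
        v = np.full_like(t, -65.0)
        spike = (t >= 10.0) & (t < 11.0)
        v[spike] = 30.0
        trace = Trace(t=t, v=v)
        ev = detect_aps(trace)[0]
        assert math.isnan(ahp_tau(trace, ev))

    def test_window_truncates_at_50ms_on_slow_recovery(self):
        """tau of a very slow recovery is still recovered from <=50 ms of data."""
        spec = SyntheticSpikeSpec(spike_times=(50.0,), ahp_tau=80.0,
                                  ahp_depth=12.0, t_stop=600.0)
        trace, _ = generate_trace(spec)
        ev = detect_aps(trace)[0]
        fit = ahp_tau(trace, ev)
        assert fit == pytest.approx(80.0, rel=0.05)
        # the recovery gradient never reaches 5 mV/ms, so only the 50 ms cap
        # can have ended the window; a fit this good from a window shorter
        # than tau confirms the cap was applied to well-conditioned data
        assert spec.ahp_depth / spec.ahp_tau < 5.0


class TestRmpAndRate:
    def test_flat_trace(self):
        assert resting_membrane_potential(flat_trace(v=-65.0)) == -65.0

    def test_ripple_minimum_in_tail(self):
        t = np.arange(0.0, 1000.0, 0.05)
        v = -70.0 - 0.2 * np.exp(-t / 100.0)
        v[int(0.95 * t.size)] = -70.3  # dip inside the last 10%
        assert resting_membrane_potential(Trace(t=t, v=v)) == pytest.approx(-70.3)

    def test_ten_sample_trace_uses_last_sample(self):
        t = np.arange(10) * 0.05
        v = np.linspace(-60.0, -69.0, 10)
        q = Trace(t=t, v=v)
        assert resting_membrane_potential(q) == pytest.approx(-69.0)

    def test_firing_rate_counts_only_stimulus_window(self):
        proto = step_protocol(amplitude=500.0, delay=100.0, duration=800.0,
                              t_stop=1500.0)
        spec = SyntheticSpikeSpec(spike_times=(150.0, 400.0, 700.0, 1000.0),
                                  t_stop=1500.0)
        trace, truth = generate_trace(spec, protocol=proto)
        # spike at 1000 ms peaks after the 900 ms stimulus offset: excluded
        assert truth["firing_rate"] == pytest.approx(3 / 0.8)
        assert firing_rate(trace, proto) == pytest.approx(3 / 0.8)

    def test_zero_aps_zero_rate(self):
        proto = step_protocol(amplitude=100.0, delay=10.0, duration=800.0)
        trace = flat_trace(t_stop=1000.0)
        trace.protocol = proto
        assert firing_rate(trace) == 0.0


class TestInvariances:
    def test_time_offset_invariance(self):
        spec = SyntheticSpikeSpec(spike_times=(100.0,), t_stop=400.0)
        trace, _ = generate_trace(spec)
        shifted = Trace(t=trace.t + 250.0, v=trace.v.copy())
        for tr_a, tr_b in [(trace, shifted)]:
            ev_a, ev_b = detect_aps(tr_a)[0], detect_aps(tr_b)[0]
            assert (full_width(ev_a, tr_a, spec.threshold)
                    == pytest.approx(full_width(ev_b, tr_b, spec.threshold)))
            assert (ahp_tau(tr_a, ev_a)
                    == pytest.approx(ahp_tau(tr_b, ev_b), rel=1e-6))
            assert (threshold_voltage(tr_a)
                    == pytest.approx(threshold_voltage(tr_b)))


class TestComputeBiomarkers:
    def test_synthetic_end_to_end(self):
        proto = step_protocol(amplitude=500.0, delay=100.0, duration=800.0,
                              t_stop=1500.0)
        spec = SyntheticSpikeSpec(spike_times=(150.0,), t_stop=1500.0)
        step_tr, truth = generate_trace(spec, protocol=proto)
        ramp_tr, _ = generate_trace(spec)
        quiet = flat_trace(v=-65.0, t_stop=1500.0)
        bset = compute_biomarkers(step_tr, ramp_tr, quiet, rheobase=300.0)
        assert bset.threshold_voltage == pytest.approx(truth["threshold_voltage"], abs=1.0)
        assert bset.peak_voltage == pytest.approx(truth["peak_voltage"], abs=0.5)
        assert bset.full_width == pytest.approx(truth["full_width"], abs=0.05)
        assert bset.half_width == pytest.approx(truth["half_width"], abs=0.05)
        assert bset.ahp_tau == pytest.approx(truth["ahp_tau"], rel=0.02)
        assert bset.rmp == -65.0
        assert bset.rheobase == 300.0
        assert all(bset.valid.values())

    def test_non_spiking_model_flags_ap_fields(self):
        quiet = flat_trace(v=-65.0, t_stop=1500.0)
        bset = compute_biomarkers(None, None, quiet, rheobase=None)
        assert bset.rmp == -65.0
        for name, ok in bset.valid.items():
            assert ok == (name == "rmp")

    def test_toy_model_stable_under_solver_tolerance_change(
            self, toy_model, fast_protocols):
        from popneuron._engine import ModelRunner
        from popneuron.protocols import find_rheobase

        def run(rtol, atol):
            runner = ModelRunner(toy_model, rtol=rtol, atol=atol)
            step_res = find_rheobase(toy_model, fast_protocols.step,
                                     runner=runner)
            ramp_res = find_rheobase(toy_model, fast_protocols.ramp,
                                     runner=runner)
            quiet = runner.run(None, t_stop=fast_protocols.step.t_stop)
            return compute_biomarkers(step_res.trace, ramp_res.trace, quiet,
                                      step_res.amplitude)
        tight = run(1e-7, 1e-8)
        loose = run(1e-6, 1e-7)
        for name, value in tight.as_dict().items():
            assert loose.as_dict()[name] == pytest.approx(value, rel=0.02,
                                                          abs=0.02), name
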