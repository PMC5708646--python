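"""Filtering, baseline estimation, and half-amplitude event idealization."""

import dataclasses

import numpy as np
import pytest

from blmchan import idealize, io, pipeline, sim
from blmchan.exceptions import ValidationError
from conftest import rect_pulse_trace

RATE = 12500.0

#: Numerically measured 10-90% rise constant of the zero-phase 8-pole Bessel
#: (the classic 0.33/cutoff rule applies to the single-pass filter; the
#: forward-backward pass lengthens it).
ZERO_PHASE_RISE_CONSTANT = 0.48


class TestLowpass:
    def test_dc_gain_exactly_one(self, simple_trace):
        tr = simple_trace.replace(current=np.full(simple_trace.n_samples, 2.5))
        out = idealize.lowpass(tr, idealize.FilterSpec(1000.0))
        np.testing.assert_allclose(out.current, 2.5, rtol=1e-9)
        assert out.filter_cutoff == 1000.0

    @pytest.mark.parametrize("cutoff,order", [(1000.0, 8), (500.0, 8), (200.0, 4)])
    def test_step_response_rise_time(self, cutoff, order):
        n = 40000
        x = np.zeros(n)
        x[n // 2:] = 1.0
        y = idealize.lowpass_array(x, idealize.FilterSpec(cutoff, order), RATE)
        t10 = np.argmax(y > 0.1)
        t90 = np.argmax(y > 0.9)
        rise = (t90 - t10) / RATE
        assert rise == pytest.approx(ZERO_PHASE_RISE_CONSTANT / cutoff, rel=0.2)
        # monotone rise through the transition band
        mid = y[t10:t90]
        assert np.all(np.diff(mid) > -1e-9)

    def test_white_noise_variance_reduced(self, simple_trace):
        rng = np.random.default_rng(0)
        tr = simple_trace.replace(current=rng.normal(0, 1, simple_trace.n_samples))
        out = idealize.lowpass(tr, idealize.FilterSpec(1000.0))
        assert out.current.var() < tr.current.var()

    def test_cutoff_at_nyquist_rejected(self, simple_trace):
        with pytest.raises(ValidationError):
            idealize.lowpass(simple_trace, idealize.FilterSpec(RATE / 2))

    def test_bad_order_rejected(self):
        with pytest.raises(ValidationError):
            idealize.FilterSpec(1000.0, order=6)


class TestEstimateBaseline:
    def test_noiseless_pulses_give_exact_zero_baseline(self):
        tr = rect_pulse_trace(amplitude_pA=3.0, pulse_s=0.1, total_s=1.0)
        base, sd = idealize.estimate_baseline(tr)
        assert base == pytest.approx(0.0, abs=1e-9)
        assert sd == pytest.approx(0.0, abs=1e-3)

    def test_gaussian_noise_around_one_pa(self, simple_trace):
        rng = np.random.default_rng(1)
        tr = simple_trace.replace(
            current=rng.normal(1.0, 0.3, simple_trace.n_samples)
        )
        base, sd = idealize.estimate_baseline(tr)
        assert base == pytest.approx(1.0, abs=0.05)
        assert sd == pytest.approx(0.3, abs=0.05)

    def test_constant_trace_degenerates(self, simple_trace):
        tr = simple_trace.replace(current=np.full(simple_trace.n_samples, 0.7))
        assert idealize.estimate_baseline(tr) == (pytest.approx(0.7), 0.0)

    def test_short_trace_rejected(self):
        tr = io.Trace(time=np.arange(50) / RATE, current=np.zeros(50),
                      voltage=np.zeros(50), sample_rate=RATE)
        with pytest.raises(ValidationError):
            idealize.estimate_baseline(tr)

    def test_simulated_trace_baseline_matches_closed_state(self, nachbac_fixture):
        m = nachbac_fixture.model
        protocol = pipeline.fig4a_protocol(35.0, repeats=1)
        (tr,) = sim.simulate_experiment(m, protocol, seed=13)
        base, sd = idealize.estimate_baseline(tr)
        # closed-state mean is 0 pA; SE of the baseline is far below 0.05 pA
        assert base == pytest.approx(0.0, abs=0.05)
        assert 0.1 < sd < 0.4


class TestDetectEvents:
    def test_single_rectangular_pulse(self):
        tr = rect_pulse_trace(amplitude_pA=3.0, pulse_s=0.2)
        ev = idealize.detect_events(tr, 0.0, 3.0, 0.001)
        assert len(ev) == 1
        row = ev.iloc[0]
        assert row.amplitude_pA == pytest.approx(3.0)
        assert row.duration_s == pytest.approx(0.2, abs=2 / RATE)
        assert row.step_voltage_mV == 35.0

    def test_pulse_shorter_than_min_duration_dropped(self):
        tr = rect_pulse_trace(amplitude_pA=3.0, pulse_s=0.005)
        ev = idealize.detect_events(tr, 0.0, 3.0, min_duration_s=0.01)
        assert len(ev) == 0

    def test_negative_going_events_detected(self):
        tr = rect_pulse_trace(amplitude_pA=-3.0, pulse_s=0.2)
        ev = idealize.detect_events(tr, 0.0, 3.0, 0.001)
        assert len(ev) == 1
        assert ev.iloc[0].amplitude_pA == pytest.approx(-3.0)

    def test_event_split_at_voltage_step_boundary(self):
        n = 2500
        cur = np.full(n, 3.0)
        volt = np.concatenate([np.full(n // 2, 20.0), np.full(n - n // 2, 40.0)])
        tr = io.Trace(time=np.arange(n) / RATE, current=cur, voltage=volt,
                      sample_rate=RATE)
        ev = idealize.detect_events(tr, 0.0, 3.0, 0.001)
        assert len(ev) == 2
        assert sorted(ev.step_voltage_mV) == [20.0, 40.0]

    def test_low_threshold_logs_warning(self, caplog):
        tr = rect_pulse_trace()
        with caplog.at_level("WARNING"):
            idealize.detect_events(tr, 0.0, 0.5, 0.001, baseline_sd=0.3)
        assert any("false-event" in r.message or "false events" in r.message
                   for r in caplog.records)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValidationError):
            idealize.detect_events(rect_pulse_trace(), 0.0, 0.0, 0.001)


@pytest.fixture(scope="module")
def noiseless_run(toy_fixture):
    # slow opener: sub-resolution closed gaps are vanishingly rare,
    # so the symmetric dead time bridges almost nothing
    m = dataclasses.replace(toy_fixture.model, k_open=(2.0,), k_close=(10.0,))
    volt = np.full(int(60 * RATE), 35.0)
    path = sim.simulate_gating(m, volt, RATE, seed=21)
    tr = sim.render_current(path, m, volt, 0.0, None, RATE, seed=0)
    return m, path, tr


class TestIdealizationOracle:
    """Noiseless idealization must reproduce the simulator's state path."""

    @staticmethod
    def dead_time_filtered_openings(path, min_dur_samples):
        """Oracle: openings of the state path after imposing the symmetric
        dead time (sub-resolution gaps bridged, then short events dropped)."""
        st = (path[:, 0] > 0).astype(np.int8)
        edges = np.flatnonzero(np.diff(np.concatenate(([0], st, [0]))))
        starts, stops = list(edges[0::2]), list(edges[1::2])
        merged = [[starts[0], stops[0]]] if starts else []
        for s, e in zip(starts[1:], stops[1:]):
            if s - merged[-1][1] < min_dur_samples:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        return np.array([[s, e] for s, e in merged if e - s >= min_dur_samples],
                        dtype=int).reshape(-1, 2)

    def test_transitions_recovered_exactly(self, noiseless_run):
        m, path, tr = noiseless_run
        min_dur = 0.002
        true_ev = self.dead_time_filtered_openings(path, min_dur * RATE)
        amp = m.levels[0].conductance_pS * 35.0 / 1000.0
        ev = idealize.detect_events(tr, 0.0, amp, min_dur)
        assert len(ev) == len(true_ev)
        det_starts = np.round(ev.start_s.to_numpy() * RATE).astype(int)
        np.testing.assert_array_less(np.abs(det_starts - true_ev[:, 0]), 3)

    def test_total_open_time_matches_state_path(self, noiseless_run):
        m, path, tr = noiseless_run
        min_dur = 0.002
        ev = idealize.detect_events(tr, 0.0, m.levels[0].conductance_pS * 0.035,
                                    min_dur)
        true_ev = self.dead_time_filtered_openings(path, min_dur * RATE)
        true_open = (true_ev[:, 1] - true_ev[:, 0]).sum() / RATE
        assert ev.duration_s.sum() == pytest.approx(
            true_open, abs=2 * len(ev) / RATE
        )

    def test_noisy_event_count_within_20_percent_of_truth(self, nachbac_fixture):
        m = nachbac_fixture.model
        protocol = pipeline.fig4a_protocol(35.0, repeats=1)
        volt = io.render_protocol(protocol, RATE, include_repeats=False)
        path = sim.simulate_gating(m, volt, RATE, seed=3)
        tr = sim.render_current(path, m, volt, m.noise_sd_pA, 1000.0, RATE,
                                seed=3 + sim.NOISE_SEED_OFFSET)
        # final digital filter at 0.5 kHz for detection
        tr = idealize.lowpass(tr, idealize.FilterSpec(500.0))
        min_dur = idealize.default_min_duration(500.0)
        st = (path[:, 0] > 0).astype(np.int8)
        edges = np.flatnonzero(np.diff(np.concatenate(([0], st, [0]))))
        dwells = edges[1::2] - edges[0::2]
        true_n = int((dwells >= min_dur * RATE).sum())
        base, sd = idealize.estimate_baseline(tr)
        ev = idealize.detect_events(tr, base, max(6 * sd, 0.05), min_dur,
                                    baseline_sd=sd)
        assert len(ev) == pytest.approx(true_n, rel=0.2)
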