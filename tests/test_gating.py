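"""All-points histograms, mixture decomposition, open probability."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from blmchan import gating, idealize, io, pipeline, sim
from blmchan.exceptions import ValidationError

RATE = 12500.0


def _trace_from(current, voltage_mV=35.0):
    n = current.size
    return io.Trace(time=np.arange(n) / RATE, current=current,
                    voltage=np.full(n, voltage_mV), sample_rate=RATE)


class TestAllPointsHistogram:
    def test_two_level_square_wave_two_equal_bins(self):
        cur = np.tile([0.0] * 10 + [2.0] * 10, 50)
        hist = gating.all_points_histogram(_trace_from(cur), bin_width=0.5)
        occupied = hist.counts[hist.counts > 0]
        assert occupied.size == 2
        assert occupied[0] == occupied[1]

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(0)
        hist = gating.all_points_histogram(_trace_from(rng.normal(0, 1, 5000)),
                                           bin_width=0.1)
        assert np.sum(hist.density * hist.bin_width) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_samples_rejected(self):
        tr = io.Trace(time=np.arange(50) / RATE, current=np.zeros(50),
                      voltage=np.zeros(50), sample_rate=RATE)
        with pytest.raises(ValidationError):
            gating.all_points_histogram(tr, 0.1)

    def test_gaussian_density_matches_generator(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.5, 0.3, 125000)
        ks = stats.kstest(x, stats.norm(0.5, 0.3).cdf).statistic
        assert ks < 0.02  # the sample itself honors the generating normal
        hist = gating.all_points_histogram(_trace_from(x), bin_width=0.02)
        centers = 0.5 * (hist.bin_edges[:-1] + hist.bin_edges[1:])
        ref = stats.norm(0.5, 0.3).pdf(centers)
        assert np.max(np.abs(np.cumsum(hist.density) - np.cumsum(ref))
                      * hist.bin_width) < 0.02


class TestFitMixture:
    def test_two_separated_levels_recovered(self):
        cur = np.tile([0.0] * 10 + [2.0] * 10, 100)
        hist = gating.all_points_histogram(_trace_from(cur), bin_width=0.1)
        fitted = gating.fit_mixture(hist, max_components=3, seed=0, baseline=0.0)
        means = sorted(c.mean_pA for c in fitted.components)
        assert len(fitted.components) == 2
        assert means[0] == pytest.approx(0.0, abs=hist.bin_width)
        assert means[1] == pytest.approx(2.0, abs=hist.bin_width)
        assert fitted.closed.mean_pA == pytest.approx(0.0, abs=0.05)

    def test_pure_noise_single_closed_component(self):
        rng = np.random.default_rng(5)
        hist = gating.all_points_histogram(_trace_from(rng.normal(0, 0.2, 20000)),
                                           bin_width=0.04)
        fitted = gating.fit_mixture(hist, max_components=3, seed=0, baseline=0.0)
        assert fitted.conducting == []
        assert fitted.closed.weight == pytest.approx(1.0, abs=1e-6)

    def test_weights_sum_to_one(self, nachbac_fixture):
        (tr,) = sim.simulate_experiment(
            nachbac_fixture.model, pipeline.fig4a_protocol(35.0, repeats=1), seed=17
        )
        base, sd = idealize.estimate_baseline(tr)
        hist = gating.all_points_histogram(tr, gating.default_bin_width(sd))
        fitted = gating.fit_mixture(hist, seed=0, baseline=base)
        assert sum(c.weight for c in fitted.components) == pytest.approx(1.0,
                                                                         abs=1e-6)
        assert sum(c.role == "closed" for c in fitted.components) == 1

    def test_simulated_level_currents_recovered(self, nachbac_fixture):
        m = nachbac_fixture.model
        (tr,) = sim.simulate_experiment(m, pipeline.fig4a_protocol(35.0, repeats=1),
                                        seed=3)
        base, sd = idealize.estimate_baseline(tr)
        hist = gating.all_points_histogram(tr, gating.default_bin_width(sd))
        fitted = gating.fit_mixture(hist, seed=0, baseline=base)
        assert 1 <= len(fitted.conducting) <= 3
        true_currents = [lv.conductance_pS * 35.0 / 1000.0 for lv in m.levels]
        for comp in fitted.conducting:
            delta = comp.mean_pA - fitted.closed.mean_pA
            assert min(abs(delta - t) for t in true_currents) < 0.2


class TestOpenProbability:
    def test_identity_at_single_channel(self):
        hist = gating.HistogramModel(
            bin_edges=np.array([0.0, 1.0]), counts=np.array([1.0]),
            components=[
                gating.MixtureComponent(0.63, 0.0, 0.1, "closed"),
                gating.MixtureComponent(0.37, 3.0, 0.1, "conducting"),
            ],
            n_components_selected=2,
        )
        res = gating.open_probability(hist, 1)
        assert res.p_o == pytest.approx(0.37)
        assert res.per_level_probability == {1: pytest.approx(0.37)}

    def test_two_channel_correction_closed_form(self):
        hist = gating.HistogramModel(
            bin_edges=np.array([0.0, 1.0]), counts=np.array([1.0]),
            components=[
                gating.MixtureComponent(0.81, 0.0, 0.1, "closed"),
                gating.MixtureComponent(0.19, 3.0, 0.1, "conducting"),
            ],
            n_components_selected=2,
        )
        assert gating.open_probability(hist, 2).p_o == pytest.approx(0.1)

    def test_never_open_gives_zero(self):
        hist = gating.HistogramModel(
            bin_edges=np.array([0.0, 1.0]), counts=np.array([1.0]),
            components=[gating.MixtureComponent(1.0, 0.0, 0.1, "closed")],
            n_components_selected=1,
        )
        for n in (1, 3, 7):
            assert gating.open_probability(hist, n).p_o == 0.0

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        pa1=st.floats(0.0, 1.0),
        pa2=st.floats(0.0, 1.0),
        n1=st.integers(1, 10),
        n2=st.integers(1, 10),
    )
    def test_monotonicity_in_pa_and_n(self, pa1, pa2, n1, n2):
        def po(pa, n):
            return 1.0 - (1.0 - pa) ** (1.0 / n)

        lo, hi = sorted((pa1, pa2))
        assert po(hi, n1) >= po(lo, n1) - 1e-12
        a, b = sorted((n1, n2))
        assert po(pa1, a) >= po(pa1, b) - 1e-12

    @pytest.mark.parametrize("n_channels", [1, 2, 5])
    def test_multi_channel_correction_against_simulation(self, n_channels,
                                                         toy_fixture):
        """Brute-force oracle: measure p_a on N simulated channels, invert,
        and compare with the single-channel stationary open probability."""
        m = dataclasses.replace(toy_fixture.model, n_channels=n_channels)
        volt = np.zeros(int(60 * RATE))
        path = sim.simulate_gating(m, volt, RATE, seed=31 + n_channels)
        p_a = float(np.mean((path > 0).any(axis=1)))
        p_o_est = 1.0 - (1.0 - p_a) ** (1.0 / n_channels)
        pi = sim.stationary_distribution(m, 0.0, 1.0 / RATE)
        p_o_true = 1.0 - pi[0]
        # ~600 independent dwells per channel over 60 s
        assert p_o_est == pytest.approx(p_o_true, abs=0.05)


class TestAssignEventLevels:
    @pytest.fixture()
    def hist_two_levels(self):
        return gating.HistogramModel(
            bin_edges=np.array([0.0, 1.0]), counts=np.array([1.0]),
            components=[
                gating.MixtureComponent(0.6, 0.0, 0.4, "closed"),
                gating.MixtureComponent(0.25, 1.0, 0.4, "conducting"),
                gating.MixtureComponent(0.15, 3.0, 0.4, "conducting"),
            ],
            n_components_selected=3,
        )

    def _events(self, amps):
        return pd.DataFrame(
            {
                "trace_id": ["t"] * len(amps),
                "start_s": np.arange(len(amps)) * 1.0,
                "duration_s": [0.1] * len(amps),
                "amplitude_pA": amps,
                "step_voltage_mV": [35.0] * len(amps),
                "level": pd.array([pd.NA] * len(amps), dtype="Int64"),
            }
        )

    def test_exact_amplitude_assigned(self, hist_two_levels):
        out = gating.assign_event_levels(self._events([3.0]), hist_two_levels)
        assert out["level"].tolist() == [2]

    def test_equidistant_tie_goes_to_lower_level(self, hist_two_levels):
        out = gating.assign_event_levels(self._events([2.0]), hist_two_levels)
        assert out["level"].tolist() == [1]

    def test_outlier_left_unassigned(self, hist_two_levels):
        out = gating.assign_event_levels(self._events([9.0]), hist_two_levels)
        assert out["level"][0] is pd.NA

    def test_no_conducting_components_warns(self, caplog):
        hist = gating.HistogramModel(
            bin_edges=np.array([0.0, 1.0]), counts=np.array([1.0]),
            components=[gating.MixtureComponent(1.0, 0.0, 0.1, "closed")],
            n_components_selected=1,
        )
        with caplog.at_level("WARNING"):
            out = gating.assign_event_levels(self._events([1.0]), hist)
        assert out["level"][0] is pd.NA


class TestCountConductingLevels:
    def test_two_state_toy_counts_one(self, toy_fixture):
        m = dataclasses.replace(toy_fixture.model, noise_sd_pA=0.3)
        protocol = io.VoltageProtocol((io.Segment("step", 35.0, 5.0),), repeats=2)
        traces = sim.simulate_experiment(m, protocol, seed=5)
        assert gating.count_conducting_levels(traces, seed=0) == 1

    def test_pure_noise_counts_zero(self):
        rng = np.random.default_rng(7)
        traces = [_trace_from(rng.normal(0, 0.2, 20000)) for _ in range(2)]
        assert gating.count_conducting_levels(traces, seed=0) == 0


class TestEstimateChannelCount:
    def test_stacked_openings_counted(self):
        # two channels open simultaneously half the time
        cur = np.tile([0.0] * 5 + [2.0] * 5 + [4.0] * 10, 100)
        tr = _trace_from(cur)
        assert gating.estimate_channel_count(tr, 0.0, 2.0) == 2
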