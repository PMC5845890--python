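"""ΔF/F0 normalization, transient metrics, responder calls, rate estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sensortrace import synthetic as G
from sensortrace import traces as T


def make_trace(t, values, events=(), trace_id="t"):
    return T.TimeSeriesTrace(trace_id, np.asarray(t, float),
                             np.asarray(values, float), list(events))


class TestTimeSeriesTrace:
    def test_non_increasing_time_rejected(self):
        with pytest.raises(ValueError):
            make_trace([0, 1, 1], [1, 2, 3])

    def test_event_outside_span_rejected(self):
        with pytest.raises(ValueError):
            make_trace([0, 1], [1, 1], events=[("stimulus", 5.0)])

    def test_minimum_two_samples(self):
        with pytest.raises(ValueError):
            make_trace([0], [1])


class TestComputeDff:
    def test_constant_trace_is_zero(self):
        tr = make_trace(np.arange(10), np.full(10, 5.0))
        d = T.compute_dff(tr, baseline_window=(0, 3))
        assert np.allclose(d.values, 0.0)

    def test_known_peak(self):
        y = np.full(20, 2.0)
        y[10] = 6.0
        d = T.compute_dff(make_trace(np.arange(20), y), baseline_window=(0, 5))
        assert d.values.max() == pytest.approx(2.0)

    @given(gain=st.floats(1e-3, 1e3))
    @settings(max_examples=50, derandomize=True)
    def test_gain_invariance(self, gain):
        rng = np.random.default_rng(0)
        y = 5.0 + rng.random(50)
        tr1 = make_trace(np.arange(50), y)
        tr2 = make_trace(np.arange(50), gain * y)
        d1 = T.compute_dff(tr1, baseline_window=(0, 10))
        d2 = T.compute_dff(tr2, baseline_window=(0, 10))
        assert np.allclose(d1.values, d2.values, atol=1e-9)

    def test_nonpositive_baseline_rejected(self):
        tr = make_trace(np.arange(10), np.concatenate([np.zeros(5), np.ones(5)]))
        with pytest.raises(T.NormalizationError):
            T.compute_dff(tr, baseline_window=(0, 4))


def _exp_trace(amplitude=2.0, tau=1.5, stim=5.0, dt=0.05, dur=25.0):
    t = np.arange(0, dur, dt)
    y = np.zeros_like(t)
    after = t >= stim
    y[after] = amplitude * np.exp(-(t[after] - stim) / tau)
    return make_trace(t, y)


class TestTransientMetrics:
    def test_noiseless_exponential_decay(self):
        m = T.transient_metrics(_exp_trace(tau=1.5), stim_time=5.0)
        assert m.decay_time == pytest.approx(1.5, rel=1e-2)
        assert m.fit_quality > 0.99
        assert not m.decay_fallback

    def test_amplitude_scaling_leaves_tau_unchanged(self):
        m1 = T.transient_metrics(_exp_trace(amplitude=0.5), stim_time=5.0)
        m2 = T.transient_metrics(_exp_trace(amplitude=5.0), stim_time=5.0)
        assert m1.decay_time == pytest.approx(m2.decay_time, rel=1e-6)

    def test_flat_trace_not_a_responder(self):
        t = np.arange(0, 20, 0.1)
        m = T.transient_metrics(make_trace(t, np.zeros_like(t)), stim_time=5.0)
        assert not m.responder
        assert m.peak_dff == pytest.approx(0.0)

    def test_generator_tau_recovered_within_five_percent(self):
        # population-mean recovery at SNR 10 (single traces scatter ~7%)
        traces, truth = G.gen_dff_population(
            n_neurons=25, responder_fraction=1.0, amplitude=1.2, tau=2.0,
            snr=10.0, seed=1,
        )
        taus = [
            T.transient_metrics(tr, stim_time=10.0).decay_time for tr in traces
        ]
        assert np.mean(taus) == pytest.approx(2.0, rel=0.05)

    def test_non_decaying_tail_flags_fallback(self):
        t = np.arange(0, 20, 0.1)
        y = np.where(t >= 5.0, 1.0, 0.0) + 0.01 * np.sin(t)  # sustained step
        m = T.transient_metrics(make_trace(t, y), stim_time=5.0)
        assert m.decay_fallback

    def test_too_few_post_stimulus_samples(self):
        tr = make_trace(np.arange(10.0), np.ones(10))
        with pytest.raises(T.WindowError):
            T.transient_metrics(tr, stim_time=8.5)


class TestClassifyResponder:
    def _trace_with(self, peak, sigma, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(0, 30, 0.1)
        y = rng.normal(0, sigma, t.size)
        y[t >= 10.0] += peak * np.exp(-(t[t >= 10.0] - 10.0) / 2.0)
        return make_trace(t, y)

    def test_clear_transient_is_responder(self):
        tr = self._trace_with(peak=0.5, sigma=0.02)
        assert T.classify_responder(tr, baseline_window=(0, 10), stim_time=10.0)

    def test_subthreshold_transient_is_not(self):
        tr = self._trace_with(peak=0.05, sigma=0.02)
        assert not T.classify_responder(tr, baseline_window=(0, 10), stim_time=10.0)

    def test_zero_variance_zero_peak(self):
        t = np.arange(0, 30, 0.1)
        tr = make_trace(t, np.zeros_like(t))
        assert not T.classify_responder(tr, baseline_window=(0, 10), stim_time=10.0)

    def test_population_fraction_within_binomial_ci(self):
        from statsmodels.stats.proportion import proportion_confint

        traces, truth = G.gen_dff_population(
            n_neurons=100, responder_fraction=0.6, seed=5
        )
        hits = sum(
            T.classify_responder(tr, baseline_window=(0, 10), stim_time=10.0)
            for tr in traces
        )
        lo, hi = proportion_confint(hits, 100, method="wilson")
        assert lo <= 0.6 <= hi


class TestEstimateRate:
    def test_exact_line(self):
        t = np.linspace(0, 10, 101)
        est = T.estimate_rate(t, 2.0 - 0.1 * t, window=(0, 10))
        assert est.slope == pytest.approx(-0.1, abs=1e-12)
        assert est.r_squared == pytest.approx(1.0)

    def test_pure_noise_auto_select_unreliable(self):
        rng = np.random.default_rng(2)
        t = np.arange(0, 100.0)
        est = T.estimate_rate(t, rng.normal(0, 1, t.size))
        assert not est.reliable
        assert np.isnan(est.slope)

    def test_auto_select_finds_steep_segment(self):
        t = np.arange(0, 100.0)
        y = np.where(t < 50, 2.0, 2.0 - 0.05 * (t - 50))
        est = T.estimate_rate(t, y, auto_length=20.0)
        assert est.reliable
        assert est.slope == pytest.approx(-0.05, rel=1e-6)

    def test_window_with_too_few_samples(self):
        with pytest.raises(T.WindowError):
            T.estimate_rate(np.arange(10.0), np.arange(10.0), window=(0, 1))

    def test_generator_atp_decline_recovered(self):
        tr, truth = G.gen_atp_trace(seed=9)
        from sensortrace.assays import atp_fccp_assay

        res = atp_fccp_assay(tr)
        assert res.consumption_rate == pytest.approx(-0.04, rel=0.10)
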