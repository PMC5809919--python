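"""Trace segmentation, growth/yield fitting, simulator contracts."""

import numpy as np
import pytest

from fruits.cultivation import (
    CultivationTrace,
    drift_pvalue,
    fit_growth_rate,
    fit_qp_vs_mu,
    per_cycle_productivity,
    segment_cycles,
    simulate_turbidostat,
    yield_from_batch,
)


def batch_trace(mu=0.05, od0=0.05, hours=48.0, dt=0.25, yield_=0.2,
                dw_per_od=148.0):
    time = np.arange(0.0, hours + dt / 2, dt)
    od = od0 * np.exp(mu * time)
    product = yield_ * (od - od0) * dw_per_od / 1000.0
    return CultivationTrace(time=time, od=od, product_conc=product)


class TestTraceContainer:
    def test_time_must_increase(self):
        with pytest.raises(ValueError):
            CultivationTrace(time=[0.0, 1.0, 1.0], od=[0.1, 0.2, 0.3])

    def test_od_must_be_positive(self):
        with pytest.raises(ValueError):
            CultivationTrace(time=[0.0, 1.0], od=[0.1, -0.2])

    def test_csv_round_trip(self, tmp_path):
        trace = simulate_turbidostat(duration=6.0, seed=3)
        path = str(tmp_path / "trace.csv")
        trace.to_csv(path)
        back = CultivationTrace.from_csv(path)
        np.testing.assert_allclose(back.time, trace.time)
        np.testing.assert_allclose(back.od, trace.od)
        np.testing.assert_allclose(back.product_conc, trace.product_conc)
        assert back.dilution_events == trace.dilution_events


class TestSegmentCycles:
    def test_scripted_dilutions_define_cycles(self):
        trace = simulate_turbidostat(
            mu=0.1, duration=40.0, od0=0.3, noise_sd=0.0, seed=0
        )
        # with the short-cycle filter off, boundaries are exactly the events
        cycles = segment_cycles(trace, min_points=1)
        assert len(cycles) == len(trace.dilution_events) + 1

    def test_monotone_batch_is_one_cycle(self):
        trace = batch_trace()
        assert segment_cycles(trace) == [(0, len(trace.time))]

    def test_detection_from_od_drops_matches_events(self):
        trace = simulate_turbidostat(
            mu=0.1, duration=40.0, od0=0.3, noise_sd=0.005, seed=1
        )
        detected = segment_cycles(
            CultivationTrace(
                time=trace.time, od=trace.od,
                meta={"dilution_fraction": 0.08},
            )
        )
        scripted = segment_cycles(trace)
        assert detected == scripted

    def test_sensor_dropout_keeps_cycle_if_enough_points(self):
        trace = batch_trace(hours=2.0, dt=0.25)  # 9 points
        trace.od[3] = np.nan
        trace.od[5] = np.nan
        assert segment_cycles(trace) == [(0, len(trace.time))]

    def test_short_cycles_discarded(self):
        trace = batch_trace(hours=2.0, dt=0.25)
        trace.od[1:] = np.nan
        assert segment_cycles(trace) == []


class TestFitGrowthRate:
    def test_noiseless_exponential_recovered_exactly(self):
        estimate = fit_growth_rate(batch_trace(mu=0.05))
        assert estimate.mu == pytest.approx(0.05, abs=1e-12)
        assert estimate.r_squared == pytest.approx(1.0, abs=1e-9)
        assert estimate.n_cycles == 1

    def test_flat_od_gives_zero_mu(self):
        trace = CultivationTrace(
            time=np.arange(10.0), od=np.full(10, 0.3)
        )
        estimate = fit_growth_rate(trace)
        assert estimate.mu == pytest.approx(0.0, abs=1e-12)

    def test_mu_is_mean_of_cycle_slopes(self):
        trace = simulate_turbidostat(duration=48.0, noise_sd=0.01, seed=5)
        estimate = fit_growth_rate(trace)
        assert estimate.mu == pytest.approx(
            float(np.mean(estimate.per_cycle_mu)), abs=1e-15
        )
        assert 0.0 <= estimate.r_squared <= 1.0

    def test_invariant_to_od_rescaling(self):
        trace = simulate_turbidostat(duration=48.0, noise_sd=0.01, seed=6)
        scaled = CultivationTrace(
            time=trace.time, od=trace.od * 3.7,
            dilution_events=trace.dilution_events,
        )
        assert fit_growth_rate(scaled).mu == pytest.approx(
            fit_growth_rate(trace).mu, abs=1e-12
        )


class TestYieldFromBatch:
    def test_constructed_slope_recovered(self):
        trace = batch_trace(yield_=0.192)
        assert yield_from_batch(trace, (0.0, 48.0)) == pytest.approx(
            0.192, abs=1e-9
        )

    def test_zero_product_means_zero_yield(self):
        trace = batch_trace(yield_=0.0)
        assert yield_from_batch(trace, (0.0, 48.0)) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_insufficient_pairs_error(self):
        trace = batch_trace()
        with pytest.raises(ValueError, match="observations"):
            yield_from_batch(trace, (47.9, 48.0))

    def test_missing_product_channel_error(self):
        trace = simulate_turbidostat(duration=2.0, seed=0)
        trace.product_conc = None
        with pytest.raises(ValueError):
            yield_from_batch(trace, (0.0, 2.0))


class TestQpVsMu:
    def test_collinear_points_recovered_exactly(self):
        mus = np.linspace(0.02, 0.09, 8)
        points = [(m, 0.195 * m) for m in mus]
        slope, intercept, r2 = fit_qp_vs_mu(points)
        assert slope == pytest.approx(0.195, abs=1e-12)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_no_mu_spread_rejected(self):
        with pytest.raises(ValueError, match="spread"):
            fit_qp_vs_mu([(0.05, 0.01), (0.05, 0.02), (0.05, 0.03)])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_qp_vs_mu([(0.04, 0.008), (0.05, 0.01)])


class TestSimulator:
    def test_same_seed_reproduces_trace_exactly(self):
        a = simulate_turbidostat(duration=24.0, seed=11)
        b = simulate_turbidostat(duration=24.0, seed=11)
        np.testing.assert_array_equal(a.od, b.od)
        np.testing.assert_array_equal(a.product_conc, b.product_conc)
        assert a.dilution_events == b.dilution_events

    def test_noiseless_cycles_are_exactly_loglinear(self):
        trace = simulate_turbidostat(duration=24.0, noise_sd=0.0, seed=0)
        for start, stop in segment_cycles(trace):
            t = trace.time[start:stop]
            log_od = np.log(trace.od[start:stop])
            slope = np.diff(log_od) / np.diff(t)
            np.testing.assert_allclose(slope, slope[0], rtol=1e-9)

    def test_post_dilution_od_is_threshold_times_retained_fraction(self):
        trace = simulate_turbidostat(
            duration=100.0, noise_sd=0.0, od0=0.34, seed=0
        )
        post = trace.od[np.searchsorted(trace.time, trace.dilution_events)]
        # dilution triggers within one sampling step of the threshold
        assert np.all(post > 0.35 * 0.92 * 0.999)
        assert np.all(post < 0.35 * 0.92 * np.exp(0.048 * 5 / 60) * 1.001)

    def test_product_tracks_yield_times_new_biomass(self):
        trace = simulate_turbidostat(
            duration=24.0, noise_sd=0.0, od_threshold=1e6,
            yield_mM_per_gDW=0.3, seed=0,
        )
        recovered = yield_from_batch(trace, (0.0, 24.0))
        assert recovered == pytest.approx(0.3, rel=1e-6)


class TestStability:
    """A month-long constant-parameter run shows no systematic drift."""

    def test_mu_and_qp_estimates_show_no_time_trend(self):
        trace = simulate_turbidostat(
            mu=0.048, duration=720.0, noise_sd=0.01,
            product_noise_sd=0.01, seed=0,
        )
        cycles = segment_cycles(trace)
        assert len(cycles) > 100
        estimate = fit_growth_rate(trace)
        midpoints = [
            float(trace.time[start:stop].mean()) for start, stop in cycles
        ]
        mu_series = list(zip(midpoints, estimate.per_cycle_mu))
        assert drift_pvalue(mu_series) > 0.05
        qp_series = per_cycle_productivity(trace)
        assert drift_pvalue(qp_series) > 0.05
        # and the estimates stay centred on the simulated truth
        assert estimate.mu == pytest.approx(0.048, rel=0.02)
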