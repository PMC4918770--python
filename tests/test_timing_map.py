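import numpy as np
import pytest

from cnswave import timing_map as tm
from cnswave.errors import EmptyStatsError
from cnswave.volume_io import VolumeSeries
from cnswave.wave_detection import WaveEvent


def stats_from(mu, var, dt=1.0, window=None):
    """Build TriggeredStats carrying prescribed per-offset mean/variance."""
    mu = np.asarray(mu, dtype=float)
    var = np.asarray(var, dtype=float)
    n = 2
    if window is None:
        window = (0.0, (mu.shape[-1] - 1) * dt)
    return tm.TriggeredStats(
        n=n, mean=mu, m2=var * n, window=window, frame_interval=dt
    )


def exhaustive_boxcar_fit(mu, var, radius):
    """Independent oracle: least squares over all (tau, lam0, lam1), lam0<=lam1."""
    T = len(mu)
    W = 2 * radius + 1
    lam_flat = mu.mean()
    E_flat = (var.sum() + ((mu - lam_flat) ** 2).sum()) / T
    best = None
    for tau in range(radius, T - radius):
        inside = np.zeros(T, dtype=bool)
        inside[tau - radius : tau + radius + 1] = True
        lam1 = mu[inside].mean()
        lam0 = mu[~inside].mean() if (~inside).any() else lam1
        if lam1 < lam0:
            lam0 = lam1 = lam_flat
            E = E_flat
            tau_eff = radius
        else:
            E = (
                var.sum()
                + ((mu[inside] - lam1) ** 2).sum()
                + ((mu[~inside] - lam0) ** 2).sum()
            ) / T
            tau_eff = tau
        if best is None or E < best[0] - 1e-15:
            best = (E, tau_eff, lam0, lam1)
    return best


class TestAccumulateTriggered:
    def _series(self, data, dt=1.0):
        return VolumeSeries(np.asarray(data, dtype=float), frame_interval=dt)

    def test_single_event_mean_is_trace_var_zero(self):
        data = np.arange(40, dtype=float).reshape(1, 1, 1, 40)
        s = self._series(data)
        stats = tm.accumulate_triggered(
            s, [WaveEvent(20.0, "forward", 1, 1)], "forward", window=(-3.0, 3.0)
        )
        assert stats.n == 1
        np.testing.assert_allclose(stats.mean[0, 0, 0], data[0, 0, 0, 17:24])
        np.testing.assert_allclose(stats.var, 0.0)

    def test_two_events_match_hand_computation(self):
        data = np.zeros((1, 1, 1, 60))
        data[..., 10] = 4.0
        data[..., 40] = 8.0
        s = self._series(data)
        events = [WaveEvent(10.0, "forward", 1, 1), WaveEvent(40.0, "forward", 1, 1)]
        stats = tm.accumulate_triggered(s, events, "forward", window=(-1.0, 1.0))
        a = data[0, 0, 0, 9:12]
        b = data[0, 0, 0, 39:42]
        np.testing.assert_allclose(stats.mean[0, 0, 0], (a + b) / 2)
        np.testing.assert_allclose(
            stats.var[0, 0, 0], ((a - (a + b) / 2) ** 2 + (b - (a + b) / 2) ** 2) / 2
        )

    def test_streaming_agrees_with_two_pass_batch(self, rng):
        data = rng.random((3, 2, 2, 2000))
        s = self._series(data)
        times = np.arange(50.0, 50.0 + 50 * 38, 38.0)
        events = [WaveEvent(float(t), "forward", 1, 1) for t in times]
        stats = tm.accumulate_triggered(s, events, "forward", window=(-5.0, 5.0))
        windows = np.stack(
            [data[..., int(t) - 5 : int(t) + 6] for t in times], axis=0
        )
        batch_mean = windows.mean(axis=0)
        batch_var = windows.var(axis=0)  # divisor N
        assert stats.n == 50
        np.testing.assert_allclose(stats.mean, batch_mean, rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(stats.var, batch_var, rtol=1e-10, atol=1e-12)

    def test_out_of_bounds_events_discarded(self):
        s = self._series(np.zeros((1, 1, 1, 30)))
        events = [WaveEvent(2.0, "forward", 1, 1), WaveEvent(15.0, "forward", 1, 1)]
        stats = tm.accumulate_triggered(s, events, "forward", window=(-5.0, 5.0))
        assert stats.n == 1

    def test_overlapping_event_windows_both_discarded(self):
        s = self._series(np.zeros((1, 1, 1, 100)))
        events = [
            WaveEvent(30.0, "forward", 1, 1),
            WaveEvent(35.0, "forward", 1, 1),
            WaveEvent(70.0, "forward", 1, 1),
        ]
        stats = tm.accumulate_triggered(s, events, "forward", window=(-5.0, 5.0))
        assert stats.n == 1

    def test_no_usable_events_raises(self):
        s = self._series(np.zeros((1, 1, 1, 10)))
        with pytest.raises(EmptyStatsError):
            tm.accumulate_triggered(s, [], "forward", window=(-2.0, 2.0))


class TestFitTimeModel:
    def test_exact_boxcar_recovered(self):
        mu = np.array([0, 0, 1, 1, 1, 0, 0], dtype=float)
        stats = stats_from(mu, np.zeros(7))
        fit = tm.fit_time_model(stats, radius=1)
        assert fit.tau == 3
        assert fit.lambda1 == pytest.approx(1.0)
        assert fit.lambda0 == pytest.approx(0.0)
        assert fit.E_time == pytest.approx(0.0, abs=1e-15)
        lam, E_flat = tm.fit_flat_model(stats)
        assert E_flat == pytest.approx(12 / 49)
        gain = np.sqrt(E_flat) - np.sqrt(fit.E_time)
        assert gain == pytest.approx(np.sqrt(12 / 49))

    def test_flat_signal_collapses_with_tie_rule(self):
        mu = np.full(9, 2.5)
        stats = stats_from(mu, np.full(9, 0.3))
        fit = tm.fit_time_model(stats, radius=2)
        assert fit.tau == 2  # smallest valid centre
        assert fit.lambda0 == fit.lambda1 == pytest.approx(2.5)
        _, E_flat = tm.fit_flat_model(stats)
        assert fit.E_time == pytest.approx(E_flat) == pytest.approx(0.3)

    def test_dip_collapses_to_flat_with_zero_gain(self):
        # bright voxels only at the edges, unreachable by any valid box:
        # the best box is dimmer than its surround, so the fit collapses
        mu = np.array([5, 0, 0, 0, 5], dtype=float)
        stats = stats_from(mu, np.zeros(5))
        fit = tm.fit_time_model(stats, radius=1)
        assert bool(fit.collapsed)
        _, E_flat = tm.fit_flat_model(stats)
        assert fit.E_time == pytest.approx(E_flat)

    def test_window_too_large_rejected(self):
        stats = stats_from(np.zeros(5), np.zeros(5))
        with pytest.raises(ValueError):
            tm.fit_time_model(stats, radius=3)

    def test_matches_exhaustive_least_squares_on_random_instances(self, rng):
        for _ in range(200):
            T = int(rng.integers(5, 41))
            radius = int(rng.integers(1, min(6, (T - 1) // 2 + 1)))
            N = int(rng.integers(1, 11))
            samples = rng.standard_normal((N, T)) + 3 * rng.random(T)
            mu = samples.mean(axis=0)
            var = samples.var(axis=0)
            stats = stats_from(mu, var)
            fit = tm.fit_time_model(stats, radius)
            E, tau, lam0, lam1 = exhaustive_boxcar_fit(mu, var, radius)
            assert fit.tau == tau
            assert fit.E_time == pytest.approx(E, abs=1e-9)
            assert fit.lambda0 == pytest.approx(lam0, abs=1e-9)
            assert fit.lambda1 == pytest.approx(lam1, abs=1e-9)

    def test_uniform_extra_variance_preserves_tau_and_reduces_gain(self, rng):
        mu = np.concatenate([np.zeros(10), np.ones(5), np.zeros(10)])
        base_var = np.full(25, 0.1)
        s1 = stats_from(mu, base_var)
        s2 = stats_from(mu, base_var + 1.0)
        f1 = tm.fit_time_model(s1, 2)
        f2 = tm.fit_time_model(s2, 2)
        assert f1.tau == f2.tau
        g1 = np.sqrt(tm.fit_flat_model(s1)[1]) - np.sqrt(f1.E_time)
        g2 = np.sqrt(tm.fit_flat_model(s2)[1]) - np.sqrt(f2.E_time)
        assert g2 < g1


class TestFitFlatModel:
    def test_constant_mean_zero_variance(self):
        stats = stats_from(np.full(6, 5.0), np.zeros(6))
        lam, E = tm.fit_flat_model(stats)
        assert lam == pytest.approx(5.0)
        assert E == pytest.approx(0.0)

    def test_two_point_mean(self):
        stats = stats_from(np.array([0.0, 2.0]), np.zeros(2))
        lam, E = tm.fit_flat_model(stats)
        assert lam == pytest.approx(1.0)
        assert E == pytest.approx(1.0)

    def test_equals_pooled_sample_variance(self, rng):
        N, T = 7, 15
        samples = rng.standard_normal((N, T)) * 2 + 1
        mu = samples.mean(axis=0)
        var = samples.var(axis=0)
        stats = stats_from(mu, var)
        _, E = tm.fit_flat_model(stats)
        pooled = samples.ravel()
        assert E == pytest.approx(((pooled - pooled.mean()) ** 2).mean(), rel=1e-10)


class TestBuildTimingMap:
    def test_all_zero_input_gives_zero_gain_everywhere(self):
        s = VolumeSeries(np.zeros((3, 3, 2, 120)), frame_interval=1.0)
        events = [WaveEvent(30.0, "forward", 1, 1), WaveEvent(80.0, "forward", 1, 1)]
        tmap = tm.build_timing_map(s, events, "forward", window=(-10.0, 10.0), radius=3)
        np.testing.assert_allclose(tmap.gain, 0.0)

    def test_scheduled_boxcar_offsets_recovered_exactly(self):
        T = 400
        dt = 1.0
        offsets = {(0, 0, 0): -4, (1, 0, 0): 0, (2, 0, 0): 5}
        data = np.zeros((3, 1, 1, T))
        times = [50.0, 150.0, 250.0, 350.0]
        for (x, y, z), off in offsets.items():
            for t0 in times:
                c = int(t0) + off
                data[x, y, z, c - 1 : c + 2] = 1.0
        s = VolumeSeries(data, frame_interval=dt)
        events = [WaveEvent(t, "forward", 1, 1) for t in times]
        tmap = tm.build_timing_map(s, events, "forward", window=(-10.0, 10.0), radius=1)
        for (x, y, z), off in offsets.items():
            assert tmap.tau_s[x, y, z] == pytest.approx(off * dt)
            assert tmap.gain[x, y, z] > 0
        assert tmap.n_events == len(times)

    def test_gain_nonnegative_on_noisy_input(self, rng):
        data = rng.standard_normal((4, 3, 2, 300))
        s = VolumeSeries(data, frame_interval=1.0)
        events = [WaveEvent(t, "forward", 1, 1) for t in (50.0, 120.0, 200.0, 270.0)]
        tmap = tm.build_timing_map(s, events, "forward", window=(-8.0, 8.0), radius=2)
        assert (tmap.gain >= 0).all()

    def test_save_round_trip(self, tmp_path, rng):
        import h5py

        data = rng.random((2, 2, 2, 100))
        s = VolumeSeries(data, frame_interval=1.0)
        events = [WaveEvent(50.0, "forward", 1, 1)]
        tmap = tm.build_timing_map(s, events, "forward", window=(-5.0, 5.0), radius=1)
        p = tmp_path / "map.h5"
        tmap.save(p)
        with h5py.File(p) as f:
            np.testing.assert_allclose(f["tau_s"][()], tmap.tau_s)
            np.testing.assert_allclose(f["gain"][()], tmap.gain)


class TestSignTest:
    @staticmethod
    def exact_minlike_pvalue(k, n):
        from fractions import Fraction
        from math import comb

        probs = [Fraction(comb(n, i), 2**n) for i in range(n + 1)]
        pk = probs[k]
        return float(sum(p for p in probs if p <= pk))

    def test_symmetric_split_gives_p_one(self):
        a = np.arange(30, dtype=float)
        b = a + np.array([1.0] * 15 + [-1.0] * 15)
        k, p = tm.compare_peak_timing(a, b)
        assert k == 15
        assert p == pytest.approx(1.0)

    def test_29_of_30_closed_form(self):
        a = np.zeros(30)
        b = np.ones(30)
        b[0] = -1.0
        k, p = tm.compare_peak_timing(a, b)
        assert k == 29
        assert p == pytest.approx(62 / 2**30, rel=1e-12)

    def test_30_of_30_closed_form(self):
        k, p = tm.compare_peak_timing(np.zeros(30), np.ones(30))
        assert k == 30
        assert p == pytest.approx(2 / 2**30, rel=1e-12)

    def test_matches_exact_binomial_oracle_all_n_up_to_30(self):
        for n in range(1, 31):
            for k in range(n + 1):
                a = np.zeros(n)
                b = np.concatenate([np.ones(k), -np.ones(n - k)])
                got_k, got_p = tm.compare_peak_timing(a, b)
                assert got_k == k
                assert got_p == pytest.approx(
                    self.exact_minlike_pvalue(k, n), rel=1e-9
                )

    def test_all_ties_undefined(self):
        k, p = tm.compare_peak_timing(np.ones(5), np.ones(5))
        assert np.isnan(p)
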