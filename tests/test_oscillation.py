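"""Peak statistics, phase diffusion, autocorrelation/PSD and phase
coherence, against constructed signals with known properties."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fluxcycle as fc


class TestDetectPeaks:
    def test_sinusoid_peak_times(self):
        T, dt = 3.0, 0.002
        t = np.arange(0, 10 * T, dt)
        table = fc.detect_peaks(np.sin(2 * np.pi * t / T), dt, window=1)
        expected = T / 4 + T * np.arange(len(table.peak_times))
        assert np.allclose(table.peak_times, expected, atol=2 * dt)

    def test_constant_signal_flagged_empty(self):
        table = fc.detect_peaks(np.ones(1000), 0.01, window=21)
        assert len(table.peak_times) == 0

    def test_noisy_sinusoid_recovery(self):
        T, dt = 3.0, 0.01
        rng = np.random.default_rng(0)
        t = np.arange(0, 40 * T, dt)
        x = np.sin(2 * np.pi * t / T)
        noisy = x + (x.std() / 5) * rng.standard_normal(len(t))
        table = fc.detect_peaks(noisy, dt, window=51)
        true_peaks = T / 4 + T * np.arange(40)
        matched = sum(np.min(np.abs(table.peak_times - tp)) < T / 10
                      for tp in true_peaks)
        assert matched >= 0.95 * len(true_peaks)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            fc.detect_peaks(np.sin(np.arange(100.0)), 0.01, window=4)


class TestPeakTimeStatistics:
    def test_noiseless_hopf_has_zero_peak_diffusion(self, hopf):
        cfg = fc.SDEConfig(D=0.0, dt=0.002, t_total=40 * np.pi, burn_in=0.0,
                           n_traj=4, seed=0, init="supplied",
                           init_states=np.array([[1.0, 0.0]]))
        ens = fc.simulate_langevin(hopf, cfg)
        tabs = [fc.detect_peaks(tr, ens.dt, window=1) for tr in ens.states]
        stats = fc.peak_time_statistics(tabs)
        assert np.allclose(stats.var_i, 0.0, atol=1e-12)
        assert stats.D_peak == pytest.approx(0.0, abs=1e-10)
        assert stats.period_T == pytest.approx(2 * np.pi, abs=0.01)

    def test_recovers_known_peak_time_diffusion(self):
        """Peak times i*T + sqrt(D i T) z have var_i = D m_i exactly."""
        rng = np.random.default_rng(5)
        T, D_true, N = 3.0, 0.05, 500
        i = np.arange(1, 41)
        tables = [
            fc.PeakTable(i * T + np.sqrt(D_true * i * T) * rng.standard_normal(40),
                         smoothing_window=1)
            for _ in range(N)
        ]
        stats = fc.peak_time_statistics(tables)
        assert stats.D_peak == pytest.approx(D_true, rel=0.15)
        assert stats.period_T == pytest.approx(T, rel=0.01)

    def test_phase_diffusion_conversion(self):
        assert fc.phase_diffusion(0.0, 3.0) == 0.0
        a = fc.phase_diffusion(0.1, 3.0)
        assert fc.phase_diffusion(0.2, 3.0) == pytest.approx(2 * a)
        assert fc.phase_diffusion(0.1, 6.0) < a
        with pytest.raises(ValueError):
            fc.phase_diffusion(0.1, 0.0)


class TestAutocorrelation:
    def test_pure_cosine_period_and_uncapped_tau(self):
        dt, T = 0.01, 3.0
        t = np.arange(0, 60, dt)
        res = fc.autocorrelation_fit(np.cos(2 * np.pi * t / T), dt, max_lag=3000)
        assert res.C[0] == pytest.approx(1.0, abs=1e-9)
        assert res.T_fit == pytest.approx(T, rel=0.01)
        assert res.tau_c >= 3000 * dt  # effectively infinite coherence

    def test_synthesized_curve_parameters_recovered(self):
        dt = 0.01
        lags = np.arange(0, 30, dt)
        C = np.exp(-lags / 5.0) * np.cos(2 * np.pi * lags / 3.0)
        res = fc.fit_autocorrelation_curve(lags, C)
        assert res.tau_c == pytest.approx(5.0, rel=0.02)
        assert res.T_fit == pytest.approx(3.0, rel=0.01)


class TestPowerSpectrum:
    def test_parseval_total_power_of_sinusoid(self):
        dt, a = 0.01, 1.7
        t = np.arange(0, 200, dt)
        sp = fc.power_spectrum(a * np.sin(2 * np.pi * t / 3), dt, window_len=4096)
        total = np.trapezoid(sp.S, sp.omega)
        assert total == pytest.approx(a**2 / 2, rel=0.05)
        bin_width = 2 * np.pi / (4096 * dt)
        assert abs(sp.peak_frequency - 2 * np.pi / 3) <= bin_width

    def test_wiener_khinchin_consistency(self):
        """FFT of the measured autocorrelation matches the periodogram."""
        rng = np.random.default_rng(3)
        dt, n = 0.01, 2**15
        # noisy oscillator signal: phase-diffusing cosine
        phase = np.cumsum(rng.standard_normal(n)) * np.sqrt(0.05 * dt)
        x = np.cos(2 * np.pi * np.arange(n) * dt / 3 + phase)
        x = x - x.mean()
        sp = fc.power_spectrum(x, dt, window_len=n, window="boxcar")
        # independent route: transform of the biased autocorrelation
        acf = fc.autocorrelation(x, max_lag=n - 1) * x.var()
        sym = np.r_[acf, acf[-1:0:-1]]
        S_acf = np.abs(np.fft.rfft(sym)) * dt / (2 * np.pi)
        w_acf = 2 * np.pi * np.fft.rfftfreq(len(sym), dt)
        S_interp = np.interp(sp.omega, w_acf, S_acf)
        sel = sp.S > 1e-4 * sp.S.max()
        num = np.sqrt(np.mean((S_interp[sel] - sp.S[sel]) ** 2))
        assert num / sp.S.max() < 0.05

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            fc.power_spectrum(np.ones(100), 0.01, window_len=200)


class TestPhaseCoherence:
    @staticmethod
    def circle(n=20000, ccw=True):
        th = np.linspace(0, 20 * np.pi, n)
        if not ccw:
            th = th[::-1]
        return np.column_stack([np.cos(th), np.sin(th)])

    def test_deterministic_cycle_is_fully_coherent(self):
        res = fc.phase_coherence(self.circle(), dt=0.01, lag_tau=0.25, center=(0, 0))
        assert res.xi == pytest.approx(1.0)

    def test_time_reversal_flips_sign_exactly(self):
        rng = np.random.default_rng(1)
        traj = self.circle() + 0.1 * rng.standard_normal((20000, 2))
        fwd = fc.phase_coherence(traj, 0.01, 0.25, (0, 0)).xi
        rev = fc.phase_coherence(traj[::-1], 0.01, 0.25, (0, 0)).xi
        assert rev == pytest.approx(-fwd, abs=1e-12)
        assert -1.0 <= fwd <= 1.0

    def test_isotropic_brownian_motion_is_incoherent(self):
        rng = np.random.default_rng(2)
        traj = np.cumsum(rng.standard_normal((100000, 2)), axis=0) * 0.01
        res = fc.phase_coherence(traj, dt=0.01, lag_tau=0.25,
                                 center=traj.mean(axis=0))
        assert abs(res.xi) < 0.05

    @given(lag=st.floats(0.05, 0.5), seed=st.integers(0, 100))
    @settings(max_examples=10, deadline=None)
    def test_xi_bounded_and_antisymmetric(self, lag, seed):
        rng = np.random.default_rng(seed)
        traj = np.cumsum(rng.standard_normal((2000, 2)), axis=0) * 0.05 + 5.0
        res = fc.phase_coherence(traj, dt=0.01, lag_tau=lag, center=(5.0, 5.0))
        assert -1.0 <= res.xi <= 1.0
        rev = fc.phase_coherence(traj[::-1], dt=0.01, lag_tau=lag, center=(5.0, 5.0))
        assert rev.xi == pytest.approx(-res.xi, abs=1e-9)

    def test_bad_lag_rejected(self):
        with pytest.raises(ValueError):
            fc.phase_coherence(self.circle(), 0.01, lag_tau=0.0, center=(0, 0))
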