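"""Analysis stage: wavelet alpha power/phase, MUA envelopes, HRF and BOLD
prediction, coherence, phase binning and repetition statistics -- each
checked against an independent oracle or closed form."""

import numpy as np
import pytest
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from tcalpha.analysis import (
    ALPHA_BAND,
    AlphaTimecourse,
    CorrelationSummary,
    MuaEnvelope,
    alpha_bold_regressor,
    alpha_timecourse,
    coherence,
    correlate,
    hrf_kernel,
    mua_envelope,
    phase_bin_mua,
    predict_bold,
    rep_statistics,
)
from tcalpha.signals import ANALYSIS_RATE, BandSignal

RATE = ANALYSIS_RATE


def _lfp(x):
    return BandSignal(x, RATE, (5.0, 60.0), "LFP")


def _mua(x):
    return BandSignal(x, RATE, (500.0, 900.0), "MUA")


class TestAlphaTimecourse:
    def test_pure_sinusoid_power_and_phase(self):
        t = np.arange(int(20 * RATE)) / RATE
        at = alpha_timecourse(_lfp(np.cos(2 * np.pi * 10 * t)))
        mid = slice(int(2 * RATE), -int(2 * RATE))
        # constant power after edge trim
        p = at.power[mid]
        assert p.std() / p.mean() < 0.02
        # phase advances at 2*pi*10 rad/s
        dph = np.diff(np.unwrap(at.phase[mid])) * RATE / (2 * np.pi)
        assert dph.mean() == pytest.approx(10.0, rel=1e-3)

    def test_am_carrier_tracks_squared_modulator(self):
        """Wavelet power of an AM 10 Hz carrier follows the squared
        modulator (Hilbert-envelope oracle)."""
        t = np.arange(int(60 * RATE)) / RATE
        mod = 1.0 + 0.5 * np.sin(2 * np.pi * 0.5 * t)
        x = mod * np.cos(2 * np.pi * 10 * t)
        at = alpha_timecourse(_lfp(x))
        analytic = sps.hilbert(x)
        oracle = np.abs(analytic) ** 2
        mid = slice(int(2 * RATE), -int(2 * RATE))
        r = np.corrcoef(at.power[mid], oracle[mid])[0, 1]
        assert r > 0.95

    def test_dc_input_zero_power(self):
        at = alpha_timecourse(_lfp(np.full(int(10 * RATE), 2.0)))
        mid = slice(int(2 * RATE), -int(2 * RATE))
        assert np.max(at.power[mid]) < 1e-6  # ~1e-7 of the DC power

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            alpha_timecourse(_lfp(np.zeros(100)))

    def test_requires_lfp_kind(self):
        with pytest.raises(ValueError):
            alpha_timecourse(_mua(np.zeros(int(10 * RATE))))


class TestMuaEnvelope:
    def test_constant_sinusoid_power(self):
        t = np.arange(int(10 * RATE)) / RATE
        x = 0.8 * np.sin(2 * np.pi * 700 * t)
        env = mua_envelope(_mua(x))
        mid = env.envelope[2000:-2000]
        assert mid.mean() == pytest.approx(0.8**2 / 2, rel=1e-3)

    def test_silent_signal(self):
        env = mua_envelope(_mua(np.zeros(int(5 * RATE))))
        np.testing.assert_array_equal(env.envelope, 0.0)

    def test_burst_train_matches_hilbert_oracle(self):
        """On/off bursts of a 700 Hz tone: the smoothed power envelope
        matches the identically smoothed squared Hilbert magnitude."""
        t = np.arange(int(30 * RATE)) / RATE
        gate = (np.sin(2 * np.pi * 0.7 * t) > 0).astype(float)
        x = gate * np.sin(2 * np.pi * 700 * t)
        env = mua_envelope(_mua(x)).envelope
        oracle = np.abs(sps.hilbert(x)) ** 2
        size = 2 * int(round(0.375 * RATE)) + 1
        oracle = uniform_filter1d(oracle, size, mode="nearest")
        mid = slice(2000, -2000)
        assert np.corrcoef(env[mid], oracle[mid])[0, 1] > 0.99

    def test_zero_halfwidth_gives_instantaneous_power(self):
        x = np.sin(2 * np.pi * 700 * np.arange(4000) / RATE)
        env = mua_envelope(_mua(x), halfwidth=0.0)
        np.testing.assert_allclose(env.envelope, x**2)


class TestCorrelate:
    def test_identity_and_sign_flip(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=500)
        assert correlate(a, a) == pytest.approx(1.0)
        assert correlate(a, -a) == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate(np.ones(10), np.arange(10.0))

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            correlate(np.ones(2), np.ones(2))


class TestHrfKernel:
    def test_peak_latency(self):
        for rate in (1.0, 16.0, 2000.0):
            k = hrf_kernel(rate)
            assert 4.5 <= k.peak_time <= 5.5

    def test_net_positive_integral(self):
        k = hrf_kernel(16.0)
        assert k.kernel.sum() > 0

    def test_unimodal_main_lobe(self):
        k = hrf_kernel(16.0)
        peak = np.argmax(k.kernel)
        d = np.diff(k.kernel)
        assert np.all(d[: peak - 1] >= -1e-12)  # rising to the peak

    def test_impulse_reproduces_kernel(self):
        from tcalpha.analysis import _hrf_convolve

        k = hrf_kernel(16.0)
        x = np.zeros(1024)
        x[0] = 1.0
        y = _hrf_convolve(x, 16.0, k)
        np.testing.assert_allclose(y[: k.kernel.size],
                                   k.kernel / 16.0, atol=1e-12)

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            hrf_kernel(0.0)


@pytest.fixture()
def fabricated_sim(short_sim):
    """A 60-s pseudo-result at 2 kHz with known random traces (long enough
    for the 32-s HRF kernel)."""
    import dataclasses

    rng = np.random.default_rng(7)
    n = int(60 * RATE)
    return dataclasses.replace(short_sim,
                               xi=rng.normal(size=(3, 3, n)).astype(np.float32),
                               alpha=rng.normal(size=(3, 3, n)).astype(np.float32),
                               rate=RATE)


class TestPredictBold:
    def test_zero_state_zero_bold(self, fabricated_sim):
        import dataclasses

        sim = dataclasses.replace(fabricated_sim,
                                  xi=np.zeros_like(fabricated_sim.xi),
                                  alpha=np.zeros_like(fabricated_sim.alpha))
        bold = predict_bold(sim, "cortex", rate=RATE)
        np.testing.assert_allclose(bold, 0.0, atol=1e-12)

    def test_weighting_identity(self, fabricated_sim):
        """BOLD is linear in the traces with weights 2/3 (xi) + 1/3 (alpha);
        the inhibitory-only node carries only the alpha contribution."""
        import dataclasses

        sim = fabricated_sim
        sim_x = dataclasses.replace(sim, alpha=np.zeros_like(sim.alpha))
        sim_a = dataclasses.replace(sim, xi=np.zeros_like(sim.xi))
        full = predict_bold(sim, "cortex", rate=RATE)
        bx = predict_bold(sim_x, "cortex", rate=RATE)
        ba = predict_bold(sim_a, "cortex", rate=RATE)
        np.testing.assert_allclose(full, bx + ba, rtol=1e-9, atol=1e-9)
        np.testing.assert_allclose(predict_bold(sim, "reticular", rate=RATE),
                                   predict_bold(sim_a, "reticular", rate=RATE))

    def test_step_rises_at_kernel_peak_vs_convolution_oracle(self):
        """A step in the driving potential produces a BOLD rise lagged by
        the kernel peak, matching brute-force discrete convolution."""
        from tcalpha.analysis import _hrf_convolve

        rate = 16.0
        k = hrf_kernel(rate)
        x = np.zeros(int(80 * rate))
        x[int(20 * rate):] = 1.0
        y = _hrf_convolve(x, rate, k)
        brute = np.convolve(x, k.kernel)[: x.size] / rate
        np.testing.assert_allclose(y, brute, atol=1e-9)
        half = np.argmax(y > 0.5 * y[int(60 * rate)]) / rate - 20.0
        assert 3.0 < half < 7.0


class TestAlphaBoldRegressor:
    def test_constant_power_constant_regressor(self):
        at = AlphaTimecourse(power=np.ones(int(120 * RATE)),
                             phase=np.zeros(int(120 * RATE)), rate=RATE)
        reg = alpha_bold_regressor(at)
        tail = reg[40:90]  # past the kernel ramp, clear of the end edge
        assert tail.std() / tail.mean() < 1e-6

    def test_boxcar_matches_convolution_oracle(self):
        rate = 16.0
        n = int(200 * rate)
        power = np.zeros(n)
        power[int(60 * rate): int(120 * rate)] = 1.0
        k = hrf_kernel(rate)
        at = AlphaTimecourse(power=power, phase=np.zeros(n), rate=rate)
        reg = alpha_bold_regressor(at, k)
        oracle_full = np.convolve(power, k.kernel)[:n] / rate
        from tcalpha.integrator import downsample

        oracle = downsample(oracle_full, rate, 1.0)
        np.testing.assert_allclose(reg[5:-5], oracle[5:-5], atol=5e-3)


class TestCoherence:
    def test_identical_signals_coherence_one(self):
        rng = np.random.default_rng(1)
        x = _lfp(rng.normal(size=int(30 * RATE)))
        f, c = coherence(x, x)
        np.testing.assert_allclose(c, 1.0, atol=1e-9)
        assert np.all((c >= 0) & (c <= 1.0 + 1e-12))

    def test_independent_noise_matches_welch_bias(self):
        """Mean coherence of independent white noise approximates the known
        1/K small-sample bias of the Welch estimator."""
        rng = np.random.default_rng(2)
        n = int(120 * RATE)
        a, b = _lfp(rng.normal(size=n)), _lfp(rng.normal(size=n))
        f, c = coherence(a, b)
        n_seg = 2 * int(120 / 2) - 1  # 50% overlap segment count
        bias = 1.0 / n_seg
        mean_c = c[(f > 1) & (f < 900)].mean()
        assert 0.4 * bias < mean_c < 2.5 * bias

    def test_segment_longer_than_signal_rejected(self):
        x = _lfp(np.zeros(1000))
        with pytest.raises(ValueError):
            coherence(x, x, segment_s=10.0)


class TestPhaseBinning:
    def test_independent_envelope_flat_profile(self):
        rng = np.random.default_rng(3)
        n = 400000
        phase = rng.uniform(-np.pi, np.pi, n)
        at = AlphaTimecourse(power=np.ones(n), phase=phase, rate=RATE)
        env = MuaEnvelope(envelope=1.0 + 0.1 * rng.random(n), rate=RATE,
                          halfwidth=0.0)
        prof = phase_bin_mua(at, env)
        assert prof.n_bins == 20
        assert prof.modulation_depth / prof.mean_mua.mean() < 0.01

    def test_sinusoidal_modulation_recovered(self):
        """envelope = 1 + cos(phase) yields a sinusoidal profile peaking at
        phase 0 (construction oracle)."""
        n = 400000
        rng = np.random.default_rng(4)
        phase = rng.uniform(-np.pi, np.pi, n)
        env = MuaEnvelope(envelope=1.0 + np.cos(phase), rate=RATE,
                          halfwidth=0.0)
        at = AlphaTimecourse(power=np.ones(n), phase=phase, rate=RATE)
        prof = phase_bin_mua(at, env)
        np.testing.assert_allclose(prof.mean_mua,
                                   1.0 + np.cos(prof.bin_centers), atol=0.02)
        assert abs(prof.bin_centers[np.argmax(prof.mean_mua)]) < 0.2

    def test_empty_bins_flagged(self):
        at = AlphaTimecourse(power=np.ones(100),
                             phase=np.full(100, 0.1), rate=RATE)
        env = MuaEnvelope(envelope=np.ones(100), rate=RATE, halfwidth=0.0)
        with pytest.warns(UserWarning, match="empty phase bins"):
            prof = phase_bin_mua(at, env)
        assert np.isnan(prof.mean_mua[0])
        assert prof.counts.sum() == 100


class TestRepStatistics:
    def test_degenerate_identical_values(self):
        s = rep_statistics([0.3, 0.3, 0.3])
        assert s.mean_r == pytest.approx(0.3)
        assert s.ci95_halfwidth == 0.0
        assert s.p_value == 0.0

    def test_null_symmetric_values(self):
        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(50):
            r = rng.normal(0, 0.1, size=10).clip(-0.9, 0.9)
            pvals.append(rep_statistics(r).p_value)
        assert np.mean(np.array(pvals) > 0.05) > 0.8

    def test_ci_coverage(self):
        """95% t-interval on Fisher-z values covers the true mean r in
        ~95% of meta-repetitions (coverage-simulation oracle)."""
        rng = np.random.default_rng(6)
        true_r = -0.2
        cover = 0
        n_meta = 400
        for _ in range(n_meta):
            z = rng.normal(np.arctanh(true_r), 0.1, size=10)
            s = rep_statistics(np.tanh(z))
            if abs(np.tanh(np.mean(z)) - true_r) <= s.ci95_halfwidth:
                cover += 1
        assert 0.90 < cover / n_meta < 0.99

    def test_too_few_reps_rejected(self):
        with pytest.raises(ValueError):
            rep_statistics([0.1])

    def test_bounds_validation(self):
        with pytest.raises(ValueError):
            rep_statistics([0.5, 1.5])
        with pytest.raises(ValueError):
            CorrelationSummary(mean_r=2.0, p_value=0.5,
                               ci95_halfwidth=0.1, n_reps=3)
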