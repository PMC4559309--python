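"""Surrogate signals with known, controllable statistical structure.

These generators emulate the features the analysis stage assumes -- a
narrowband ~10 Hz carrier with fluctuating amplitude, a high-frequency burst
train phase-locked to the carrier, and a controllable (typically negative)
correlation between carrier amplitude and burst-rate envelope -- so every
analysis operation can be tested against a construction with a known answer,
without running the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = ["SurrogateSpec", "make_surrogate", "make_correlated_pair"]


@dataclass(frozen=True)
class SurrogateSpec:
    """Parameters of the structured LFP/MUA surrogate pair.

    ``phase_lock_depth`` modulates the burst intensity by the carrier phase
    (0 = none, 1 = full on/off modulation); ``target_amp_rate_corr`` is the
    imposed sample correlation between the slow carrier-amplitude envelope
    and the slow burst-rate envelope.
    """

    duration: float = 300.0
    rate: float = 2000.0
    carrier_freq: float = 10.0
    am_freq: float = 0.3
    am_depth: float = 0.4
    burst_freq: float = 700.0
    phase_lock_depth: float = 0.0
    target_amp_rate_corr: float = 0.0
    noise_level: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.carrier_freq < self.rate / 2:
            raise ValueError("carrier frequency outside (0, Nyquist)")
        if not 500.0 <= self.burst_freq <= 900.0:
            raise ValueError("burst frequency must lie in the 500-900 Hz band")
        if not 0 <= self.phase_lock_depth <= 1:
            raise ValueError("phase_lock_depth must be in [0, 1]")
        if not -1 <= self.target_amp_rate_corr <= 1:
            raise ValueError("target_amp_rate_corr must be in [-1, 1]")
        if self.am_depth >= 1:
            raise ValueError("am_depth must be < 1 to keep amplitude positive")
        if self.duration * self.rate < 64:
            raise ValueError("surrogate too short")


def _standardize(x):
    return (x - x.mean()) / x.std()


def _slow_gaussian(rng, n, rate, cutoff_hz):
    """Unit-variance stationary Gaussian process band-limited below
    cutoff_hz (FFT spectral synthesis; no filter edge transients)."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    spec *= np.exp(-0.5 * (f / cutoff_hz) ** 2)
    spec[0] = 0.0
    return _standardize(np.fft.irfft(spec, n))


def _pink_noise(rng, n):
    """Approximate 1/f noise via spectral shaping."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec /= np.sqrt(f)
    out = np.fft.irfft(spec, n)
    return _standardize(out)


def make_correlated_pair(n: int, target_r: float, seed: int = 0):
    """Gaussian pair with *exact* sample correlation ``target_r``.

    Orthogonalize-then-mix: b = r * za + sqrt(1 - r^2) * zb where za, zb are
    standardized and zb is made exactly orthogonal to za in sample terms.
    """
    if not -1 <= target_r <= 1:
        raise ValueError("|target_r| must be <= 1")
    if n < 3:
        raise ValueError("need n >= 3")
    rng = np.random.default_rng(seed)
    a = _standardize(rng.standard_normal(n))
    b0 = rng.standard_normal(n)
    b0 = b0 - b0.mean()
    b0 = b0 - (a @ b0) / (a @ a) * a  # exact sample orthogonalization
    b0 = b0 / b0.std()
    b = target_r * a + np.sqrt(1.0 - target_r**2) * b0
    return a, b


def make_surrogate(spec: SurrogateSpec):
    """LFP-like and MUA-like surrogate series (returned as a tuple).

    lfp_like: amplitude-modulated carrier plus pink noise.  The amplitude
    envelope combines a deterministic slow sinusoid (am_freq, am_depth) with
    a slow Gaussian component.  mua_like: 500-900 Hz band-limited noise whose
    instantaneous power follows (a) the carrier phase with
    ``phase_lock_depth`` and (b) a slow rate envelope constructed to have an
    exact sample correlation ``target_amp_rate_corr`` with the slow carrier
    *power* envelope.
    """
    n = int(round(spec.duration * spec.rate))
    rng = np.random.default_rng(spec.seed)
    t = np.arange(n) / spec.rate
    phase = 2 * np.pi * spec.carrier_freq * t

    slow_a = _slow_gaussian(rng, n, spec.rate, 0.4)
    amp = 1.0 + spec.am_depth * (
        0.6 * np.sin(2 * np.pi * spec.am_freq * t) + 0.4 * slow_a)
    amp = np.clip(amp, 0.05, None)
    lfp_like = amp * np.cos(phase) + spec.noise_level * _pink_noise(rng, n)

    # slow power envelope the wavelet analysis will recover (~ amp^2 / 2);
    # the imposed correlation is made exact on the interior region that the
    # analysis evaluates (2-s edges excluded for wavelet/filter transients)
    core = slice(int(2 * spec.rate), n - int(2 * spec.rate))
    u = amp**2
    u = (u - u[core].mean()) / u[core].std()
    v0 = _slow_gaussian(rng, n, spec.rate, 0.4)
    v0 = v0 - v0[core].mean()
    v0 = v0 - (u[core] @ v0[core]) / (u[core] @ u[core]) * u
    v0 = v0 / v0[core].std()
    rho = spec.target_amp_rate_corr
    mix = rho * u + np.sqrt(1.0 - rho**2) * v0
    rate_env = np.clip(1.0 + 0.45 * mix, 0.02, None)

    lock = 1.0 + spec.phase_lock_depth * np.cos(phase)
    hf = rng.standard_normal(n)
    sos = sps.butter(4, (500.0, 900.0), btype="bandpass", fs=spec.rate,
                     output="sos")
    hf = _standardize(sps.sosfiltfilt(sos, hf))
    mua_like = np.sqrt(rate_env * lock) * hf
    return lfp_like, mua_like
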