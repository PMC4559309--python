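"""Alpha power/phase, MUA envelopes, BOLD prediction, coherence, phase
binning, repetition statistics and the CSF sweep.

The analysis chain mirrors common EEG/LFP practice: a 3-cycle Morlet wavelet
decomposition of the LFP gives the 8-12 Hz alpha power time course (and the
alpha phase at the 10 Hz band centre); the MUA firing-rate proxy is the
squared 500-900 Hz signal smoothed with a +/-375 ms moving average; the
predicted BOLD signal convolves the weighted membrane potentials (2/3
excitatory + 1/3 inhibitory) with the SPM-style canonical double-gamma HRF
(peak ~5 s); the "alpha BOLD regressor" convolves the alpha power itself
with the same kernel.  Alpha-vs-MUA correlations are evaluated at the 2 kHz
analysis rate, alpha-vs-BOLD correlations at 1 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats
from scipy.ndimage import uniform_filter1d

from .integrator import IntegrationConfig, SimulationResult, downsample, simulate
from .network import build_default_network
from .signals import ANALYSIS_RATE, BandSignal, extract_lfp, extract_mua

__all__ = [
    "AlphaTimecourse",
    "MuaEnvelope",
    "HrfKernel",
    "CorrelationSummary",
    "PhaseBinProfile",
    "SweepResult",
    "alpha_timecourse",
    "mua_envelope",
    "correlate",
    "hrf_kernel",
    "predict_bold",
    "alpha_bold_regressor",
    "coherence",
    "phase_bin_mua",
    "rep_statistics",
    "analyze_run",
    "reference_condition",
    "csf_sweep",
    "ALPHA_BAND",
    "BOLD_RATE",
]

ALPHA_BAND = (8.0, 12.0)
BOLD_RATE = 1.0
EDGE_TRIM_S = 1.0        # wavelet/filter edge discarded at 2 kHz
HRF_LENGTH_S = 32.0
SMOOTH_HALFWIDTH_S = 0.375


# ---------------------------------------------------------------------------
# Alpha power and phase (Morlet wavelets)
# ---------------------------------------------------------------------------

@dataclass
class AlphaTimecourse:
    """8-12 Hz mean wavelet power and band-centre phase at the LFP rate."""

    power: np.ndarray
    phase: np.ndarray
    rate: float
    band: tuple = ALPHA_BAND

    def __post_init__(self):
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


def _morlet_coeffs(x, rate, freqs, n_cycles=3.0):
    """Complex Morlet coefficients, shape (n_freqs, T)."""
    from mne.time_frequency import tfr_array_morlet

    data = np.asarray(x, dtype=np.float64)[None, None, :]
    out = tfr_array_morlet(data, sfreq=rate, freqs=np.asarray(freqs, float),
                           n_cycles=n_cycles, output="complex", zero_mean=True,
                           verbose="error")
    return out[0, 0]


def alpha_timecourse(lfp: BandSignal, freqs=None, n_cycles: float = 3.0,
                     phase_freq: float = 10.0,
                     phase_mode: str = "center") -> AlphaTimecourse:
    """Morlet (3-cycle) wavelet alpha power and phase of an LFP.

    Power is the mean squared wavelet modulus over the 8-12 Hz grid (1 Hz
    spacing by default); phase is taken at the band-centre frequency
    (``phase_mode="center"``) or as the circular mean of the per-frequency
    phases (``phase_mode="circmean"``).
    """
    if lfp.kind != "LFP":
        raise ValueError(f"alpha_timecourse expects an LFP, got {lfp.kind}")
    if freqs is None:
        freqs = np.arange(ALPHA_BAND[0], ALPHA_BAND[1] + 1.0, 1.0)
    freqs = np.asarray(freqs, dtype=float)
    support = n_cycles / freqs.min()
    if lfp.samples.size < support * lfp.rate:
        raise ValueError("signal shorter than one wavelet support")
    W = _morlet_coeffs(lfp.samples, lfp.rate, freqs, n_cycles)
    power = np.mean(np.abs(W) ** 2, axis=0)
    if phase_mode == "center":
        idx = int(np.argmin(np.abs(freqs - phase_freq)))
        phase = np.angle(W[idx])
    elif phase_mode == "circmean":
        phase = np.angle(np.mean(np.exp(1j * np.angle(W)), axis=0))
    else:
        raise ValueError(f"unknown phase_mode {phase_mode!r}")
    return AlphaTimecourse(power=power, phase=phase, rate=lfp.rate)


# ---------------------------------------------------------------------------
# MUA power envelope
# ---------------------------------------------------------------------------

@dataclass
class MuaEnvelope:
    """Instantaneous MUA power, optionally smoothed by a centred moving
    average of +/- ``halfwidth`` seconds."""

    envelope: np.ndarray
    rate: float
    halfwidth: float

    def __post_init__(self):
        if np.any(self.envelope < -1e-12):
            raise ValueError("envelope must be non-negative")
        self.envelope = np.clip(self.envelope, 0.0, None)


def mua_envelope(mua: BandSignal,
                 halfwidth: float = SMOOTH_HALFWIDTH_S) -> MuaEnvelope:
    """Squared band-passed MUA smoothed by a centred +/-halfwidth-s window.

    ``halfwidth=0`` returns the raw instantaneous power (used for the
    phase-binning analysis, where smoothing across alpha cycles would erase
    the phase structure).
    """
    if mua.kind != "MUA":
        raise ValueError(f"mua_envelope expects a MUA signal, got {mua.kind}")
    power = mua.samples ** 2
    if halfwidth > 0:
        size = 2 * int(round(halfwidth * mua.rate)) + 1
        power = uniform_filter1d(power, size=size, mode="nearest")
    return MuaEnvelope(envelope=power, rate=mua.rate, halfwidth=halfwidth)


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

def correlate(a, b) -> float:
    """Pearson correlation coefficient of two equal-length series."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D series")
    if a.size < 3:
        raise ValueError("need at least 3 samples")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("undefined correlation for zero-variance input")
    return float(spstats.pearsonr(a, b).statistic)


# ---------------------------------------------------------------------------
# Hemodynamics
# ---------------------------------------------------------------------------

@dataclass
class HrfKernel:
    """Sampled canonical double-gamma hemodynamic response kernel."""

    kernel: np.ndarray
    rate: float

    @property
    def peak_time(self) -> float:
        return float(np.argmax(self.kernel) / self.rate)


def hrf_kernel(rate: float, length: float = HRF_LENGTH_S,
               response_delay: float = 6.0, undershoot_delay: float = 16.0,
               response_dispersion: float = 1.0,
               undershoot_dispersion: float = 1.0,
               undershoot_ratio: float = 6.0) -> HrfKernel:
    """Canonical double-gamma HRF (SPM parameterization), peak near 5 s.

    h(t) = pdf_gamma(t; 6, 1) - pdf_gamma(t; 16, 1) / 6, sampled on
    [0, length) at ``rate``.
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    t = np.arange(0.0, length, 1.0 / rate)
    h = (spstats.gamma.pdf(t, response_delay / response_dispersion,
                           scale=response_dispersion)
         - spstats.gamma.pdf(t, undershoot_delay / undershoot_dispersion,
                             scale=undershoot_dispersion) / undershoot_ratio)
    return HrfKernel(kernel=h, rate=rate)


def _hrf_convolve(x, rate, kernel: HrfKernel):
    """Causal convolution with the HRF (same length as the input), with the
    kernel resampled/validated against the series rate."""
    if abs(kernel.rate - rate) > 1e-9:
        kernel = hrf_kernel(rate)
    y = sps.fftconvolve(np.asarray(x, dtype=np.float64), kernel.kernel,
                        mode="full")[: len(x)]
    return y / kernel.rate  # Riemann normalisation: invariant under rate


def _to_bold_rate(y, rate):
    return downsample(y, rate, BOLD_RATE)


def predict_bold(sim: SimulationResult, node, kernel: HrfKernel | None = None,
                 rate: float = ANALYSIS_RATE) -> np.ndarray:
    """Predicted hemodynamic signal of a node at 1 Hz.

    Per-mode xi and alpha traces are convolved with the canonical HRF and
    summed with weights 2/3 (excitatory) and 1/3 (inhibitory).  For the
    inhibitory-only reticular node only the alpha contribution exists.
    Convolution is linear, so the weighted mode sum is formed first and
    convolved once.
    """
    i = sim.node_index(node)
    if kernel is None:
        kernel = hrf_kernel(rate)
    al = downsample(sim.alpha[i].sum(axis=0).astype(np.float64), sim.rate, rate)
    if len(al) < kernel.kernel.size:
        raise ValueError("series shorter than the HRF kernel")
    drive = al / 3.0
    if not sim.kinds[i].inhibitory_only:
        xi = downsample(sim.xi[i].sum(axis=0).astype(np.float64), sim.rate, rate)
        drive = drive + 2.0 * xi / 3.0
    bold = _hrf_convolve(drive, rate, kernel)
    return _to_bold_rate(bold, rate)


def alpha_bold_regressor(alpha: AlphaTimecourse,
                         kernel: HrfKernel | None = None) -> np.ndarray:
    """HRF-convolved alpha-power time course sampled at 1 Hz."""
    if kernel is None:
        kernel = hrf_kernel(alpha.rate)
    if alpha.power.size < kernel.kernel.size and abs(kernel.rate - alpha.rate) < 1e-9:
        raise ValueError("series shorter than the HRF kernel")
    reg = _hrf_convolve(alpha.power, alpha.rate, kernel)
    return _to_bold_rate(reg, alpha.rate)


# ---------------------------------------------------------------------------
# Coherence
# ---------------------------------------------------------------------------

def coherence(lfp_a: BandSignal, lfp_b: BandSignal, segment_s: float = 2.0):
    """Welch magnitude-squared coherence (Hann segments, 50% overlap)."""
    if abs(lfp_a.rate - lfp_b.rate) > 1e-9 or len(lfp_a) != len(lfp_b):
        raise ValueError("signals must share rate and length")
    nperseg = int(round(segment_s * lfp_a.rate))
    if nperseg > len(lfp_a):
        raise ValueError("segment longer than signal")
    f, coh = sps.coherence(lfp_a.samples, lfp_b.samples, fs=lfp_a.rate,
                           window="hann", nperseg=nperseg,
                           noverlap=nperseg // 2)
    return f, coh


# ---------------------------------------------------------------------------
# Phase binning
# ---------------------------------------------------------------------------

@dataclass
class PhaseBinProfile:
    """Mean MUA per alpha-phase bin over a uniform partition of (-pi, pi]."""

    bin_centers: np.ndarray
    mean_mua: np.ndarray
    counts: np.ndarray
    n_bins: int = 20

    @property
    def modulation_depth(self) -> float:
        valid = self.counts > 0
        return float(self.mean_mua[valid].max() - self.mean_mua[valid].min())


def phase_bin_mua(alpha: AlphaTimecourse, env: MuaEnvelope,
                  n_bins: int = 20) -> PhaseBinProfile:
    """Sort MUA into alpha-phase bins and average per bin.

    A flat profile indicates no phase coupling; a sinusoidal modulation
    indicates phase-dependent firing.  Empty bins are flagged (count 0,
    mean NaN) and excluded from the modulation depth.
    """
    if alpha.phase.size != env.envelope.size:
        raise ValueError("phase and envelope series must be aligned")
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    idx = np.clip(np.digitize(alpha.phase, edges[1:-1]), 0, n_bins - 1)
    sums = np.bincount(idx, weights=env.envelope, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    if np.any(counts == 0):
        import warnings

        warnings.warn(f"{int((counts == 0).sum())} empty phase bins excluded")
    centers = 0.5 * (edges[:-1] + edges[1:])
    return PhaseBinProfile(bin_centers=centers, mean_mua=means,
                           counts=counts, n_bins=n_bins)


# ---------------------------------------------------------------------------
# Repetition statistics
# ---------------------------------------------------------------------------

@dataclass
class CorrelationSummary:
    """Across-repetition summary of one correlation: mean r, two-sided
    p-value and 95% CI half-width (Fisher-z one-sample t procedure)."""

    mean_r: float
    p_value: float
    ci95_halfwidth: float
    n_reps: int

    def __post_init__(self):
        if not -1.0 <= self.mean_r <= 1.0:
            raise ValueError("mean_r outside [-1, 1]")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def rep_statistics(r_values, method: str = "fisher") -> CorrelationSummary:
    """Aggregate per-repetition correlation coefficients.

    ``fisher``: one-sample two-sided t-test of the Fisher-z transformed
    values against 0, with the 95% t-interval mapped back to the r scale
    (half the width of the back-transformed interval).  ``plain``: the same
    procedure on the raw r values.  Degenerate (zero-variance) inputs yield
    p = 0 (r != 0) or p = 1 (r = 0) and a zero half-width.
    """
    r = np.asarray(r_values, dtype=np.float64)
    if r.ndim != 1 or r.size < 2:
        raise ValueError("need at least 2 repetitions")
    if np.any(np.abs(r) > 1):
        raise ValueError("correlations must lie in [-1, 1]")
    if method == "fisher":
        z = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
    elif method == "plain":
        z = r
    else:
        raise ValueError(f"unknown method {method!r}")
    n = r.size
    mean_z = z.mean()
    sd_z = z.std(ddof=1)
    if sd_z == 0:
        p = 1.0 if mean_z == 0 else 0.0
        return CorrelationSummary(float(r.mean()), p, 0.0, n)
    se = sd_z / np.sqrt(n)
    tstat = mean_z / se
    p = float(2 * spstats.t.sf(abs(tstat), df=n - 1))
    tcrit = spstats.t.ppf(0.975, df=n - 1)
    lo, hi = mean_z - tcrit * se, mean_z + tcrit * se
    if method == "fisher":
        lo, hi = np.tanh(lo), np.tanh(hi)
    return CorrelationSummary(float(r.mean()), p, float((hi - lo) / 2), n)


# ---------------------------------------------------------------------------
# Per-run pipeline and multi-repetition conditions
# ---------------------------------------------------------------------------

def _trim(x, rate, start_s, end_s):
    a = int(round(start_s * rate))
    b = x.size - int(round(end_s * rate))
    if b - a < 3:
        raise ValueError("series too short after edge trimming")
    return x[a:b]


def analyze_run(sim: SimulationResult, alpha_node: str = "cortex",
                with_spectra: bool = False):
    """All per-run statistics relating cortical alpha to each node.

    Returns a dict with keys ``("alpha_mua", node)`` and
    ``("alpha_bold", node)`` mapping to Pearson r, plus the alpha
    time course and (optionally) Welch LFP spectra and cortex-thalamus
    coherence.
    """
    lfp = extract_lfp(sim, alpha_node)
    alpha = alpha_timecourse(lfp)
    kernel2k = hrf_kernel(ANALYSIS_RATE)
    regressor = alpha_bold_regressor(alpha, kernel2k)

    duration = sim.n_samples / sim.rate
    # validity margins: wavelet/filter edges at 2 kHz; HRF ramp at 1 Hz
    hrf_trim = HRF_LENGTH_S + 1.0
    if duration <= hrf_trim + 3:
        raise ValueError("run too short for BOLD-level analysis")

    alpha_trimmed = _trim(alpha.power, ANALYSIS_RATE, EDGE_TRIM_S, EDGE_TRIM_S)
    out = {"alpha": alpha, "lfp": lfp}
    for node in sim.names:
        env = mua_envelope(extract_mua(sim, node))
        env_trimmed = _trim(env.envelope, ANALYSIS_RATE, EDGE_TRIM_S, EDGE_TRIM_S)
        out[("alpha_mua", node)] = correlate(alpha_trimmed, env_trimmed)
        bold = predict_bold(sim, node, kernel2k)
        n = min(bold.size, regressor.size)
        out[("alpha_bold", node)] = correlate(
            _trim(regressor[:n], BOLD_RATE, hrf_trim, 1.0),
            _trim(bold[:n], BOLD_RATE, hrf_trim, 1.0))
    if with_spectra:
        f, pxx = sps.welch(lfp.samples - lfp.samples.mean(), fs=lfp.rate,
                           window="hann", nperseg=int(2 * lfp.rate))
        out["spectrum"] = (f, pxx)
        out["coherence"] = coherence(lfp, extract_lfp(sim, "thalamus"))
    return out


def _condition_runs(csf, n_reps, cfg: IntegrationConfig, coeffs, seed_base):
    """Simulate n_reps repetitions at one CSF with randomized initial
    conditions/noise, yielding analyze_run dicts; blown-up repetitions are
    recorded and excluded."""
    from .integrator import SimulationBlowUp

    results, failures = [], []
    for rep in range(n_reps):
        spec = build_default_network(csf=csf)
        cfg_rep = replace(cfg, seed=int(seed_base + rep))
        try:
            sim = simulate(spec, coeffs, cfg_rep)
        except SimulationBlowUp as err:
            failures.append((rep, str(err)))
            continue
        results.append(analyze_run(sim, with_spectra=True))
    return results, failures


@dataclass
class SweepResult:
    """CSF-sweep output: per-level correlation summaries, mean LFP spectra
    and cortex-thalamus coherence, plus any excluded (blown-up) runs."""

    levels: np.ndarray
    summaries: dict  # (pairing, node) -> list of CorrelationSummary per level
    spectra: dict    # level -> (f, mean pxx)
    coherences: dict  # level -> (f, mean coh)
    alpha_power: np.ndarray  # mean 8-12 Hz cortical LFP power per level
    failures: list


def reference_condition(n_reps: int = 10, csf: float = 0.6,
                        cfg: IntegrationConfig | None = None,
                        coeffs=None, seed: int = 0):
    """The study's reference condition: ``n_reps`` repetitions at CSF=0.6.

    Returns (summary dict {(pairing, node): CorrelationSummary},
    per-repetition r dict, failures).
    """
    from .model import ExcitabilityDistribution, derive_mode_coefficients

    if cfg is None:
        cfg = IntegrationConfig()
    if coeffs is None:
        coeffs = derive_mode_coefficients(ExcitabilityDistribution())
    runs, failures = _condition_runs(csf, n_reps, cfg, coeffs, seed)
    if len(runs) < 2:
        raise RuntimeError(f"too few usable repetitions ({len(runs)})")
    r_per = {}
    names = [k[1] for k in runs[0] if isinstance(k, tuple) and k[0] == "alpha_mua"]
    summary = {}
    for pairing in ("alpha_mua", "alpha_bold"):
        for node in names:
            rs = [run[(pairing, node)] for run in runs]
            r_per[(pairing, node)] = rs
            summary[(pairing, node)] = rep_statistics(rs)
    return summary, r_per, failures


def csf_sweep(levels=None, n_reps: int = 10,
              cfg: IntegrationConfig | None = None, coeffs=None,
              seed: int = 0) -> SweepResult:
    """Repeat the full analysis across a ladder of CSF levels.

    The default ladder {0.0, 0.1, 0.2, 0.4, 0.6, 0.8, 1.6, 3.2, 6.4} spans
    the usable coupling range from the disconnected model to saturation.
    """
    from .model import ExcitabilityDistribution, derive_mode_coefficients

    if levels is None:
        levels = np.array([0.0, 0.1, 0.2, 0.4, 0.6, 0.8, 1.6, 3.2, 6.4])
    levels = np.asarray(levels, dtype=float)
    if np.any(levels < 0) or np.any(levels > 6.4):
        raise ValueError("CSF levels must lie in [0, 6.4]")
    if cfg is None:
        cfg = IntegrationConfig()
    if coeffs is None:
        coeffs = derive_mode_coefficients(ExcitabilityDistribution())

    summaries = {}
    spectra, coherences, failures = {}, {}, []
    alpha_power = np.zeros(levels.size)
    for li, level in enumerate(levels):
        runs, fails = _condition_runs(level, n_reps, cfg, coeffs,
                                      seed + 1000 * li)
        failures.extend((level,) + f for f in fails)
        if not runs:
            alpha_power[li] = np.nan
            continue
        f = runs[0]["spectrum"][0]
        pxx = np.mean([run["spectrum"][1] for run in runs], axis=0)
        spectra[float(level)] = (f, pxx)
        fc = runs[0]["coherence"][0]
        coh = np.mean([run["coherence"][1] for run in runs], axis=0)
        coherences[float(level)] = (fc, coh)
        alpha_power[li] = pxx[(f >= 8) & (f <= 12)].mean()
        for pairing in ("alpha_mua", "alpha_bold"):
            for node in ("cortex", "thalamus", "reticular"):
                rs = [run[(pairing, node)] for run in runs]
                summaries.setdefault((pairing, node), []).append(
                    rep_statistics(rs) if len(rs) >= 2 else None)
    return SweepResult(levels=levels, summaries=summaries, spectra=spectra,
                       coherences=coherences, alpha_power=alpha_power,
                       failures=failures)
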