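"""Approximated LFP and MUA signals from raw membrane-potential traces.

The local field potential (LFP) is the 5-60 Hz band and the multi-unit
activity proxy (MUA) the 500-900 Hz band of the summed principal membrane
potential of a node (xi over the three modes; alpha for the inhibitory-only
reticular node), after downsampling the raw 20 kHz output to the 2 kHz
analysis rate.  Filtering uses a 2nd-order Butterworth applied forward and
backward (zero phase), so later phase-binning is not biased by filter delay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .integrator import SimulationResult, downsample

__all__ = [
    "BandSignal",
    "ANALYSIS_RATE",
    "LFP_BAND",
    "MUA_BAND",
    "summed_excitatory",
    "bandpass",
    "extract_lfp",
    "extract_mua",
]

ANALYSIS_RATE = 2000.0
LFP_BAND = (5.0, 60.0)
MUA_BAND = (500.0, 900.0)


@dataclass
class BandSignal:
    """A band-limited time series with its sampling rate and provenance."""

    samples: np.ndarray
    rate: float
    band: tuple
    kind: str  # "LFP" or "MUA"
    node: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        lo, hi = self.band
        if not (0 < lo < hi < self.rate / 2):
            raise ValueError(
                f"band {self.band} invalid for Nyquist {self.rate / 2}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("non-finite samples in BandSignal")

    @property
    def times(self):
        return np.arange(self.samples.size) / self.rate

    def __len__(self):
        return self.samples.size


def summed_excitatory(mode_series, include_all=None) -> np.ndarray:
    """Elementwise sum of the three per-mode membrane-potential series.

    ``mode_series`` is a (3, T) array (or a sequence of three equal-length
    series).  ``include_all`` may extend the sum with further (3, T) blocks
    (e.g. the spiking and bursting variables) for sensitivity analyses.
    """
    arr = np.asarray(mode_series, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] != 3:
        raise ValueError(f"expected (3, T) mode series, got {arr.shape}")
    out = arr.sum(axis=0)
    if include_all is not None:
        for block in include_all:
            block = np.asarray(block, dtype=np.float64)
            if block.shape != arr.shape:
                raise ValueError("extra state blocks must match (3, T) shape")
            out = out + block.sum(axis=0)
    return out


def bandpass(series, band, rate, order: int = 2, kind: str = "LFP",
             node: str = "") -> BandSignal:
    """Zero-phase Butterworth band-pass of the given order.

    Forward-backward application squares the magnitude response, so the
    band edges sit at -6 dB rather than the single-pass -3 dB.
    """
    lo, hi = band
    if not (0 < lo < hi < rate / 2):
        raise ValueError(f"band {band} outside (0, Nyquist={rate / 2}) Hz")
    sos = sps.butter(order, (lo, hi), btype="bandpass", fs=rate, output="sos")
    filtered = sps.sosfiltfilt(sos, np.asarray(series, dtype=np.float64))
    return BandSignal(filtered, rate, (lo, hi), kind=kind, node=node)


def _node_band(sim: SimulationResult, node, band, kind) -> BandSignal:
    raw = sim.summed_output(node)  # raises KeyError-ish for unknown node
    x = downsample(raw, sim.rate, ANALYSIS_RATE)
    name = node if isinstance(node, str) else sim.names[node]
    return bandpass(x, band, ANALYSIS_RATE, order=2, kind=kind, node=name)


def extract_lfp(sim: SimulationResult, node) -> BandSignal:
    """Approximated local field potential: 5-60 Hz band at 2 kHz."""
    return _node_band(sim, node, LFP_BAND, "LFP")


def extract_mua(sim: SimulationResult, node) -> BandSignal:
    """Approximated multi-unit activity: 500-900 Hz band at 2 kHz."""
    return _node_band(sim, node, MUA_BAND, "MUA")
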