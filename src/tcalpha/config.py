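"""Run configuration: one flat, human-readable YAML file is the single
source of truth; every default equals the published parameter set."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import yaml

from .integrator import IntegrationConfig
from .model import ExcitabilityDistribution, HRParams, NodeKind
from .network import NetworkSpec, build_default_network

__all__ = ["AnalysisConfig", "RunConfig", "load_config", "save_config"]

DEFAULT_SWEEP_LEVELS = (0.0, 0.1, 0.2, 0.4, 0.6, 0.8, 1.6, 3.2, 6.4)


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis-stage settings (bands in Hz, windows in seconds)."""

    lfp_band: tuple = (5.0, 60.0)
    mua_band: tuple = (500.0, 900.0)
    alpha_band: tuple = (8.0, 12.0)
    wavelet_cycles: float = 3.0
    phase_mode: str = "center"  # or "circmean"
    mua_smooth_halfwidth: float = 0.375
    n_phase_bins: int = 20
    coherence_segment: float = 2.0
    n_reps: int = 10
    sweep_levels: tuple = DEFAULT_SWEEP_LEVELS
    rep_stat_method: str = "fisher"  # or "plain"
    excitatory_sum: str = "xi"  # or "all" (literal xi+eta+tau sum)


@dataclass(frozen=True)
class RunConfig:
    """Complete description of a simulation + analysis run."""

    hr: HRParams = HRParams()
    excitability: ExcitabilityDistribution = ExcitabilityDistribution()
    K11: float = 0.5
    K12: float = 0.25
    K21: float = 0.5
    csf: float = 0.6
    coupling: str = "modewise"
    cortex_reticular_distance: float = 8.8
    integration: IntegrationConfig = IntegrationConfig()
    analysis: AnalysisConfig = AnalysisConfig()
    output_dir: str = "runs"
    seed: int = 0

    def network(self, csf: float | None = None) -> NetworkSpec:
        spec = build_default_network(self.csf if csf is None else csf)
        full = NodeKind("full", K11=self.K11, K12=self.K12, K21=self.K21)
        spec.nodes = [(name, full if not k.inhibitory_only else k)
                      for name, k in spec.nodes]
        d = self.cortex_reticular_distance
        spec.distances[0, 2] = spec.distances[2, 0] = d
        spec.coupling = self.coupling
        return spec

    def integration_config(self) -> IntegrationConfig:
        return dataclasses.replace(self.integration, seed=self.seed)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, (tuple, list)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _tupled(d):
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(cfg), fh, sort_keys=False)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    raw = dict(raw)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {}
    if "hr" in raw:
        kwargs["hr"] = HRParams(**raw.pop("hr"))
    if "excitability" in raw:
        kwargs["excitability"] = ExcitabilityDistribution(**raw.pop("excitability"))
    if "integration" in raw:
        d = raw.pop("integration")
        if d.get("stream_keys") is not None:
            d["stream_keys"] = tuple(d["stream_keys"])
        kwargs["integration"] = IntegrationConfig(**d)
    if "analysis" in raw:
        kwargs["analysis"] = AnalysisConfig(**_tupled(raw.pop("analysis")))
    kwargs.update(raw)
    return RunConfig(**kwargs)
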