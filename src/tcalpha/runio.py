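"""Result persistence: HDF5 traces with a config echo and a JSON manifest
carrying the seed and content hashes, so any output can be regenerated from
its manifest alone."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import h5py
import numpy as np
import yaml

from .config import RunConfig, _to_plain
from .integrator import IntegrationConfig, SimulationResult
from .model import NodeKind
from .network import NetworkSpec

__all__ = ["save_result", "load_result", "write_manifest", "content_hash"]


def content_hash(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()


def save_result(sim: SimulationResult, path, run_config: RunConfig | None = None):
    """Write a simulation result (and its provenance) to an HDF5 file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("xi", data=sim.xi, compression="gzip", shuffle=True)
        f.create_dataset("alpha", data=sim.alpha, compression="gzip",
                         shuffle=True)
        if sim.extra is not None:
            f.create_dataset("extra", data=sim.extra, compression="gzip",
                             shuffle=True)
        f.attrs["rate"] = sim.rate
        f.attrs["names"] = json.dumps(sim.names)
        f.attrs["kinds"] = json.dumps(
            [dataclasses.asdict(k) for k in sim.kinds])
        f.attrs["config"] = yaml.safe_dump(_to_plain(sim.config))
        f.attrs["weights"] = sim.spec.weights
        f.attrs["distances"] = sim.spec.distances
        f.attrs["inverse_speed"] = sim.spec.inverse_speed
        f.attrs["csf"] = sim.spec.csf
        f.attrs["coupling"] = sim.spec.coupling
        if run_config is not None:
            f.attrs["run_config"] = yaml.safe_dump(_to_plain(run_config))
    digest = content_hash(sim.xi, sim.alpha)
    write_manifest(path.with_suffix(".manifest.json"), sim, digest)
    return digest


def write_manifest(path, sim: SimulationResult, digest: str) -> None:
    manifest = {
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": sim.config.seed,
        "csf": sim.spec.csf,
        "duration_s": sim.config.duration,
        "dt_ms": sim.config.dt,
        "noise_sd": sim.config.noise_sd,
        "noise_mode": sim.config.noise_mode,
        "n_samples": int(sim.n_samples),
        "sha256": digest,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)


def load_result(path) -> SimulationResult:
    with h5py.File(path, "r") as f:
        xi = f["xi"][()]
        alpha = f["alpha"][()]
        extra = f["extra"][()] if "extra" in f else None
        names = json.loads(f.attrs["names"])
        kinds = [NodeKind(**d) for d in json.loads(f.attrs["kinds"])]
        cfg = IntegrationConfig(**{
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in yaml.safe_load(f.attrs["config"]).items()})
        spec = NetworkSpec(nodes=list(zip(names, kinds)),
                           weights=f.attrs["weights"][()],
                           distances=f.attrs["distances"][()],
                           inverse_speed=float(f.attrs["inverse_speed"]),
                           csf=float(f.attrs["csf"]),
                           coupling=str(f.attrs["coupling"]))
    return SimulationResult(xi=xi, alpha=alpha, rate=cfg.native_rate,
                            names=names, kinds=kinds, config=cfg, spec=spec,
                            extra=extra)
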