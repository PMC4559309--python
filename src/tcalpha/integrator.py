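"""Stochastic Heun integration of the delay-coupled network.

Time is measured in the model's millisecond-like unit: the default step is
dt = 0.05, i.e. a native output rate of 20 kHz.  Noise is additive white
Gaussian injected independently into every mode equation (default; a
membrane-potential-only variant is switchable), with amplitude 0.1 read as
a continuous-time intensity (increment sd = 0.1 * sqrt(dt)); a per-step
convention at the native step is switchable.

The production path is a numba-compiled kernel; :func:`reference_simulate`
is a slow pure-Python stepper built directly from the model/network modules,
used as an equivalence oracle in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import signal as sps

from .model import BlowUpError, ModeCoefficients, N_MODES, NodeState
from .network import DelayBuffer, NetworkSpec, coupling_drive, node_output

__all__ = [
    "IntegrationConfig",
    "SimulationResult",
    "heun_step",
    "simulate",
    "reference_simulate",
    "downsample",
    "SimulationBlowUp",
]

NATIVE_DT = 0.05  # reference step (ms) at which noise_sd is defined


class SimulationBlowUp(BlowUpError):
    """The coupled system diverged (e.g. hyper-excitation at high CSF)."""

    def __init__(self, msg, t=None):
        super().__init__(msg)
        self.t = t


@dataclass(frozen=True)
class IntegrationConfig:
    """Integration and recording settings.

    dt: step size in model time units (ms); 0.05 -> 20 kHz native rate.
    duration / burn_in: total and discarded simulated time in seconds.
    noise_sd: additive Gaussian noise amplitude (see noise_mode).
    noise_mode: 'intensity' (default) -- noise_sd is a continuous-time
        intensity, increment sd = noise_sd * sqrt(dt); 'per_step_native' --
        noise_sd is the per-step increment sd at dt = 0.05 ms, rescaled by
        sqrt(dt/0.05) for other steps.
    noise_all_states: inject independent noise into all six mode equations
        (default, matching the reference toolbox's additive-noise
        convention); False restricts injection to the membrane-potential
        equations (xi; alpha for inhibitory-only nodes).
    init_halfwidth: initial conditions are drawn uniformly from
        [-init_halfwidth, +init_halfwidth] per state variable.
    stream_keys: optional per-node RNG spawn keys (defaults to node index);
        lets a single-node run reproduce one node's noise stream from a
        multi-node run exactly.
    """

    dt: float = NATIVE_DT
    duration: float = 300.0
    burn_in: float = 2.0
    noise_sd: float = 0.1
    noise_mode: str = "intensity"
    noise_all_states: bool = True
    init_halfwidth: float = 0.1
    record_full_state: bool = False
    seed: int = 0
    stream_keys: tuple | None = None
    blowup_limit: float = 1e5
    chunk_steps: int = 100_000

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if not 0 <= self.burn_in < self.duration:
            raise ValueError("need 0 <= burn_in < duration")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_mode not in ("per_step_native", "intensity"):
            raise ValueError(f"unknown noise_mode {self.noise_mode!r}")

    @property
    def native_rate(self) -> float:
        """Output sampling rate in Hz implied by dt (dt in ms)."""
        return 1000.0 / self.dt

    @property
    def increment_sd(self) -> float:
        """Per-step noise increment standard deviation."""
        if self.noise_mode == "per_step_native":
            return self.noise_sd * np.sqrt(self.dt / NATIVE_DT)
        return self.noise_sd * np.sqrt(self.dt)

    @property
    def n_steps(self) -> int:
        return int(round(self.duration * 1000.0 / self.dt))

    @property
    def burn_steps(self) -> int:
        return int(round(self.burn_in * 1000.0 / self.dt))


@dataclass
class SimulationResult:
    """Recorded per-node, per-mode xi and alpha traces at the native rate."""

    xi: np.ndarray      # (n_nodes, 3, T) float32
    alpha: np.ndarray   # (n_nodes, 3, T) float32
    rate: float
    names: list
    kinds: list
    config: IntegrationConfig
    spec: NetworkSpec
    extra: np.ndarray | None = None  # (n_nodes, 4, 3, T): eta, tau, beta, gamma

    @property
    def eta(self):
        return None if self.extra is None else self.extra[:, 0]

    @property
    def tau(self):
        return None if self.extra is None else self.extra[:, 1]

    @property
    def n_samples(self) -> int:
        return self.xi.shape[-1]

    def node_index(self, node) -> int:
        if isinstance(node, str):
            if node not in self.names:
                raise KeyError(f"unknown node {node!r}; have {self.names}")
            return self.names.index(node)
        return int(node)

    def summed_output(self, node) -> np.ndarray:
        """Summed principal membrane potential (xi, or alpha if
        inhibitory-only) of one node, float64."""
        i = self.node_index(node)
        arr = self.alpha if self.kinds[i].inhibitory_only else self.xi
        return arr[i].sum(axis=0).astype(np.float64)


# ---------------------------------------------------------------------------
# Generic stochastic Heun step
# ---------------------------------------------------------------------------

def heun_step(state, drift_fn, noise_sd, dt, rng=None):
    """One stochastic Heun (predictor-corrector) step.

    predictor  y* = y + dt f(y) + dW
    corrector  y' = y + dt/2 (f(y) + f(y*)) + dW

    ``noise_sd`` is the per-step increment standard deviation; with
    noise_sd = 0 this is the deterministic trapezoidal Heun map.
    """
    state = np.asarray(state, dtype=float)
    f1 = np.asarray(drift_fn(state), dtype=float)
    if noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        dw = rng.normal(0.0, noise_sd, size=state.shape)
    else:
        dw = 0.0
    pred = state + dt * f1 + dw
    f2 = np.asarray(drift_fn(pred), dtype=float)
    out = state + 0.5 * dt * (f1 + f2) + dw
    if not np.all(np.isfinite(out)):
        raise BlowUpError(f"non-finite state after Heun step: {out!r}")
    return out


# ---------------------------------------------------------------------------
# Compiled network kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _drift(state, drive, A, B, C, av, bv, cv, dv, ev, fv, hv, pv,
           IEv, IIv, mv, nv, r, s, K11v, K12v, K21v, inhib, out):
    n_nodes = state.shape[0]
    for n in range(n_nodes):
        for i in range(N_MODES):
            al = state[n, 3, i]
            sc = 0.0
            for k in range(N_MODES):
                sc += C[n, i, k] * state[n, 0, k]
            dal = (state[n, 4, i] - ev[n, i] * al**3 + fv[n, i] * al**2
                   - state[n, 5, i] + K21v[n] * (sc - al) + IIv[n, i])
            out[n, 4, i] = hv[n, i] - pv[n, i] * al * al - state[n, 4, i]
            out[n, 5, i] = r * s * al - r * state[n, 5, i] - nv[n, i]
            if inhib[n]:
                out[n, 0, i] = 0.0
                out[n, 1, i] = 0.0
                out[n, 2, i] = 0.0
                out[n, 3, i] = dal + drive[n, i]
            else:
                xi = state[n, 0, i]
                sa = 0.0
                sb = 0.0
                for k in range(N_MODES):
                    sa += A[n, i, k] * state[n, 0, k]
                    sb += B[n, i, k] * state[n, 3, k]
                out[n, 0, i] = (state[n, 1, i] - av[n, i] * xi**3
                                + bv[n, i] * xi**2 - state[n, 2, i]
                                + K11v[n] * (sa - xi) - K12v[n] * (sb - xi)
                                + IEv[n, i] + drive[n, i])
                out[n, 1, i] = cv[n, i] - dv[n, i] * xi * xi - state[n, 1, i]
                out[n, 2, i] = r * s * xi - r * state[n, 2, i] - mv[n, i]
                out[n, 3, i] = dal
    return out


@njit(cache=True)
def _run_chunk(state, hist, t0, nsteps, w, lags, csf, dt, modewise, noise,
               A, B, C, av, bv, cv, dv, ev, fv, hv, pv,
               IEv, IIv, mv, nv, r, s, K11v, K12v, K21v, inhib,
               rec_xi, rec_al, rec_full, rec_start):
    n_nodes = state.shape[0]
    L = hist.shape[2]
    f1 = np.empty_like(state)
    f2 = np.empty_like(state)
    pred = np.empty_like(state)
    drive = np.zeros((n_nodes, N_MODES))
    for step in range(nsteps):
        t = t0 + step
        pos = t % L
        # principal-population outputs into the ring buffer
        for n in range(n_nodes):
            v = 3 if inhib[n] else 0
            if modewise:
                for i in range(N_MODES):
                    hist[n, i, pos] = state[n, v, i]
            else:
                o = 0.0
                for i in range(N_MODES):
                    o += state[n, v, i]
                for i in range(N_MODES):
                    hist[n, i, pos] = o
        # delayed coupling drive, held constant across the two Heun stages
        for n in range(n_nodes):
            for i in range(N_MODES):
                acc = 0.0
                for j in range(n_nodes):
                    if w[n, j] != 0.0:
                        acc += w[n, j] * hist[j, i, (pos - lags[n, j]) % L]
                drive[n, i] = csf * acc
        _drift(state, drive, A, B, C, av, bv, cv, dv, ev, fv, hv, pv,
               IEv, IIv, mv, nv, r, s, K11v, K12v, K21v, inhib, f1)
        for n in range(n_nodes):
            for v in range(6):
                for i in range(N_MODES):
                    pred[n, v, i] = (state[n, v, i] + dt * f1[n, v, i]
                                     + noise[step, n, v, i])
        _drift(pred, drive, A, B, C, av, bv, cv, dv, ev, fv, hv, pv,
               IEv, IIv, mv, nv, r, s, K11v, K12v, K21v, inhib, f2)
        for n in range(n_nodes):
            for v in range(6):
                for i in range(N_MODES):
                    state[n, v, i] = (state[n, v, i]
                                      + 0.5 * dt * (f1[n, v, i] + f2[n, v, i])
                                      + noise[step, n, v, i])
        if t >= rec_start:
            ridx = t - rec_start
            for n in range(n_nodes):
                for i in range(N_MODES):
                    rec_xi[n, i, ridx] = state[n, 0, i]
                    rec_al[n, i, ridx] = state[n, 3, i]
            if rec_full.shape[3] > 0:
                for n in range(n_nodes):
                    for i in range(N_MODES):
                        rec_full[n, 0, i, ridx] = state[n, 1, i]
                        rec_full[n, 1, i, ridx] = state[n, 2, i]
                        rec_full[n, 2, i, ridx] = state[n, 4, i]
                        rec_full[n, 3, i, ridx] = state[n, 5, i]
    return state


def _pack_coeffs(coeffs_list, kinds):
    n = len(coeffs_list)
    A = np.stack([c.A for c in coeffs_list])
    B = np.stack([c.B for c in coeffs_list])
    C = np.stack([c.C for c in coeffs_list])
    vecs = {}
    for name in ("a", "b", "c", "d", "e", "f", "h", "p", "IE", "II", "m", "n"):
        vecs[name] = np.stack([getattr(c, name) for c in coeffs_list])
    r = coeffs_list[0].r
    s = coeffs_list[0].s
    for c in coeffs_list:
        if c.r != r or c.s != s:
            raise ValueError("all nodes must share r and s")
    K11 = np.array([k.couplings()[0] for k in kinds])
    K12 = np.array([k.couplings()[1] for k in kinds])
    K21 = np.array([k.couplings()[2] for k in kinds])
    inhib = np.array([k.inhibitory_only for k in kinds])
    return A, B, C, vecs, r, s, K11, K12, K21, inhib


def _node_rngs(cfg: IntegrationConfig, n_nodes: int):
    keys = cfg.stream_keys
    if keys is None:
        keys = tuple(range(n_nodes))
    if len(keys) != n_nodes:
        raise ValueError("stream_keys must have one entry per node")
    return [np.random.Generator(np.random.Philox(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(int(k),))))
        for k in keys]


def _draw_initial_state(rngs, kinds, halfwidth):
    states = []
    for rng, kind in zip(rngs, kinds):
        s = rng.uniform(-halfwidth, halfwidth, size=(6, N_MODES))
        if kind.inhibitory_only:
            s[0:3] = 0.0  # excitatory triplet is dormant
        states.append(s)
    return np.stack(states)


def _noise_mask(kinds, all_states):
    n = len(kinds)
    mask = np.zeros((n, 6, N_MODES), dtype=bool)
    for i, kind in enumerate(kinds):
        if all_states:
            mask[i] = True
            if kind.inhibitory_only:
                mask[i, 0:3] = False
        elif kind.inhibitory_only:
            mask[i, 3] = True  # alpha equations
        else:
            mask[i, 0] = True  # xi equations
    return mask


def simulate(spec: NetworkSpec, coeffs, cfg: IntegrationConfig) -> SimulationResult:
    """Integrate the delay-coupled network and record xi/alpha traces.

    ``coeffs`` is a single :class:`ModeCoefficients` shared by all nodes or a
    per-node list.  Burn-in is discarded; recording is at the native rate.
    Raises :class:`SimulationBlowUp` (reporting the divergence time) if any
    state variable becomes non-finite or exceeds ``cfg.blowup_limit`` --
    expected behaviour under hyper-excitation at very large CSF.
    """
    n = spec.n_nodes
    kinds = spec.kinds
    if isinstance(coeffs, ModeCoefficients):
        coeffs_list = [coeffs] * n
    else:
        coeffs_list = list(coeffs)
        if len(coeffs_list) != n:
            raise ValueError("need one ModeCoefficients per node")
    A, B, C, vecs, r, s, K11, K12, K21, inhib = _pack_coeffs(coeffs_list, kinds)

    dt = cfg.dt
    lags = spec.delay_steps(dt)
    horizon = int(lags.max()) if lags.size else 0
    n_steps = cfg.n_steps
    rec_start = cfg.burn_steps
    n_rec = n_steps - rec_start

    rngs = _node_rngs(cfg, n)
    state = _draw_initial_state(rngs, kinds, cfg.init_halfwidth)
    modewise = spec.coupling == "modewise"
    hist = np.empty((n, N_MODES, horizon + 1))
    # constant pre-history from the initial outputs
    for i, kind in enumerate(kinds):
        v = state[i, 3] if kind.inhibitory_only else state[i, 0]
        hist[i] = v[:, None] if modewise else v.sum()

    rec_xi = np.empty((n, N_MODES, n_rec), dtype=np.float32)
    rec_al = np.empty((n, N_MODES, n_rec), dtype=np.float32)
    rec_full = np.empty((n, 4, N_MODES, n_rec if cfg.record_full_state else 0),
                        dtype=np.float32)

    mask = _noise_mask(kinds, cfg.noise_all_states)
    sd = cfg.increment_sd
    chunk = int(cfg.chunk_steps)
    t0 = 0
    while t0 < n_steps:
        m = min(chunk, n_steps - t0)
        noise = np.zeros((m, n, 6, N_MODES))
        if sd > 0:
            for i, rng in enumerate(rngs):
                cnt = int(mask[i].sum())
                if cnt:
                    draws = rng.normal(0.0, sd, size=(m, cnt))
                    noise[:, i][:, mask[i]] = draws
        _run_chunk(state, hist, t0, m, spec.weights, lags, spec.csf, dt,
                   modewise, noise,
                   A, B, C, vecs["a"], vecs["b"], vecs["c"], vecs["d"],
                   vecs["e"], vecs["f"], vecs["h"], vecs["p"],
                   vecs["IE"], vecs["II"], vecs["m"], vecs["n"],
                   r, s, K11, K12, K21, inhib, rec_xi, rec_al, rec_full,
                   rec_start)
        t0 += m
        if not np.all(np.isfinite(state)) or np.abs(state).max() > cfg.blowup_limit:
            raise SimulationBlowUp(
                f"state diverged by t = {t0 * dt / 1000.0:.3f} s "
                f"(max |state| = {np.abs(state).max():.3g})",
                t=t0 * dt / 1000.0)

    return SimulationResult(xi=rec_xi, alpha=rec_al, rate=cfg.native_rate,
                            names=spec.names, kinds=kinds, config=cfg,
                            spec=spec,
                            extra=rec_full if cfg.record_full_state else None)


def reference_simulate(spec: NetworkSpec, coeffs, cfg: IntegrationConfig
                       ) -> SimulationResult:
    """Pure-Python stepper equivalent to :func:`simulate` (oracle for tests).

    Built directly from :func:`tcalpha.model.sj3d_derivatives`,
    :class:`tcalpha.network.DelayBuffer` and the same noise-stream layout.
    Orders of magnitude slower; only for short runs.
    """
    from .model import sj3d_derivatives

    n = spec.n_nodes
    kinds = spec.kinds
    coeffs_list = [coeffs] * n if isinstance(coeffs, ModeCoefficients) else list(coeffs)
    dt = cfg.dt
    lags = spec.delay_steps(dt)
    horizon = int(lags.max()) if lags.size else 0
    n_steps = cfg.n_steps
    rec_start = cfg.burn_steps
    n_rec = n_steps - rec_start

    rngs = _node_rngs(cfg, n)
    state = _draw_initial_state(rngs, kinds, cfg.init_halfwidth)
    modewise = spec.coupling == "modewise"

    def per_mode_outputs(st):
        return np.stack([st[i, 3] if kinds[i].inhibitory_only else st[i, 0]
                         for i in range(n)])

    if modewise:
        # one scalar delay buffer per mode channel
        bufs = [DelayBuffer(n, horizon) for _ in range(N_MODES)]
        o0 = per_mode_outputs(state)
        for k, b in enumerate(bufs):
            b.fill(o0[:, k])
    else:
        buf = DelayBuffer(n, horizon)
        buf.fill([node_output(NodeState.from_array(state[i]), kinds[i])
                  for i in range(n)])

    mask = _noise_mask(kinds, cfg.noise_all_states)
    sd = cfg.increment_sd

    rec_xi = np.empty((n, N_MODES, n_rec), dtype=np.float32)
    rec_al = np.empty((n, N_MODES, n_rec), dtype=np.float32)

    # pre-draw the same chunked noise stream as the compiled path
    noises = []
    t0 = 0
    while t0 < n_steps:
        m = min(int(cfg.chunk_steps), n_steps - t0)
        noise = np.zeros((m, n, 6, N_MODES))
        if sd > 0:
            for i, rng in enumerate(rngs):
                cnt = int(mask[i].sum())
                if cnt:
                    noise[:, i][:, mask[i]] = rng.normal(0.0, sd, size=(m, cnt))
        noises.append(noise)
        t0 += m
    noise_all = np.concatenate(noises, axis=0) if noises else np.zeros((0, n, 6, N_MODES))

    lag_mat = spec.delay_steps(dt)
    for t in range(n_steps):
        if modewise:
            o = per_mode_outputs(state)
            drive = np.zeros((n, N_MODES))
            for k, b in enumerate(bufs):
                b.push(o[:, k])
                for i in range(n):
                    acc = 0.0
                    for j in range(n):
                        if spec.weights[i, j] != 0.0:
                            acc += spec.weights[i, j] * b.read(j, int(lag_mat[i, j]))
                    drive[i, k] = spec.csf * acc
        else:
            buf.push([node_output(NodeState.from_array(state[i]), kinds[i])
                      for i in range(n)])
            drive = np.repeat(coupling_drive(spec, buf, dt)[:, None],
                              N_MODES, axis=1)
        f1 = np.stack([
            sj3d_derivatives(NodeState.from_array(state[i]), coeffs_list[i],
                             kinds[i], drive[i]).to_array()
            for i in range(n)])
        pred = state + dt * f1 + noise_all[t]
        f2 = np.stack([
            sj3d_derivatives(NodeState.from_array(pred[i]), coeffs_list[i],
                             kinds[i], drive[i]).to_array()
            for i in range(n)])
        state = state + 0.5 * dt * (f1 + f2) + noise_all[t]
        if t >= rec_start:
            rec_xi[:, :, t - rec_start] = state[:, 0, :]
            rec_al[:, :, t - rec_start] = state[:, 3, :]

    return SimulationResult(xi=rec_xi, alpha=rec_al, rate=cfg.native_rate,
                            names=spec.names, kinds=kinds, config=cfg,
                            spec=spec)


# ---------------------------------------------------------------------------
# Downsampling
# ---------------------------------------------------------------------------

def _decimation_factors(q: int):
    """Split an integer decimation into stages of at most 10."""
    factors = []
    while q > 10:
        for f in (10, 9, 8, 7, 6, 5, 4, 3, 2):
            if q % f == 0:
                factors.append(f)
                q //= f
                break
        else:
            raise ValueError(f"cannot factor decimation {q} into stages <= 10")
    factors.append(q)
    return factors


def downsample(series, from_rate: float, to_rate: float) -> np.ndarray:
    """Anti-alias low-pass and decimate by the integer factor
    from_rate / to_rate (zero-phase FIR stages of at most 10x each)."""
    ratio = from_rate / to_rate
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 or q < 1:
        raise ValueError(
            f"from_rate {from_rate} must be an integer multiple of to_rate {to_rate}")
    x = np.asarray(series, dtype=np.float64)
    if q == 1:
        return x.copy()
    for f in _decimation_factors(q):
        if f > 1:
            x = sps.decimate(x, f, ftype="fir", zero_phase=True)
    return x
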