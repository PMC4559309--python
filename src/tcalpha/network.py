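"""Three-node thalamo-cortical graph: signed weights, conduction delays and
the delayed linear coupling drive.

Node order is (cortex, thalamus, reticular).  Weights ``w[i, j]`` act from
source ``j`` onto target ``i`` and are scaled globally by the connectivity
scaling factor (CSF) ``c``; the drive entering node i at time t is

    drive_i(t) = c * sum_j w_ij * o_j(t - d_ij / v)

where o_j is the node output (summed excitatory membrane potential xi for
full nodes, summed inhibitory alpha for the inhibitory-only reticular node)
and d_ij / v the conduction delay from the inter-node distance and the
inverse conduction speed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import FULL_NODE, INHIBITORY_NODE, NodeKind, NodeState

__all__ = [
    "NetworkSpec",
    "DelayBuffer",
    "build_default_network",
    "node_output",
    "coupling_drive",
    "CORTEX",
    "THALAMUS",
    "RETICULAR",
]

CORTEX, THALAMUS, RETICULAR = "cortex", "thalamus", "reticular"


@dataclass
class NetworkSpec:
    """Directed weighted graph of neural-mass nodes with conduction delays."""

    nodes: list  # list of (name, NodeKind)
    weights: np.ndarray  # signed, target i <- source j
    distances: np.ndarray  # same shape, model length units
    inverse_speed: float = 1.0 / 7.0
    csf: float = 0.6
    coupling: str = "modewise"  # "modewise": mode i -> mode i; "summed":
    #   scalar node output (summed over modes) broadcast to every mode

    def __post_init__(self):
        if self.coupling not in ("modewise", "summed"):
            raise ValueError(f"unknown coupling convention {self.coupling!r}")
        n = len(self.nodes)
        self.weights = np.asarray(self.weights, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.weights.shape != (n, n) or self.distances.shape != (n, n):
            raise ValueError("weights and distances must be n_nodes x n_nodes")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("self-coupling weights must be zero")
        if np.any(self.distances < 0):
            raise ValueError("distances must be >= 0")
        if self.inverse_speed < 0:
            raise ValueError("inverse_speed must be >= 0")
        if self.csf < 0:
            raise ValueError("csf must be >= 0")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def names(self):
        return [name for name, _ in self.nodes]

    @property
    def kinds(self):
        return [kind for _, kind in self.nodes]

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown node {name!r}; have {self.names}") from None

    def delays(self) -> np.ndarray:
        """Edge delays in model time units (distance x inverse speed)."""
        return self.distances * self.inverse_speed

    def delay_steps(self, dt: float) -> np.ndarray:
        """Delays rounded to the nearest integration step."""
        return np.rint(self.delays() / dt).astype(np.int64)


def build_default_network(csf: float = 0.6) -> NetworkSpec:
    """The study's thalamo-cortical graph.

    Excitatory edges: thalamus->cortex (2), thalamus->reticular (0.5),
    cortex->thalamus (1), cortex->reticular (1).  Inhibitory edge:
    reticular->thalamus (-2).  The thalamus-cortex distance is 8.8 length
    units, the reticular nucleus is co-located with the thalamus (distance
    0), hence cortex-reticular distance is also taken as 8.8.
    """
    if csf < 0:
        raise ValueError("csf must be >= 0")
    nodes = [
        (CORTEX, FULL_NODE),
        (THALAMUS, FULL_NODE),
        (RETICULAR, INHIBITORY_NODE),
    ]
    C, T, R = 0, 1, 2
    w = np.zeros((3, 3))
    w[C, T] = 2.0    # thalamo-cortical
    w[R, T] = 0.5    # thalamo-reticular
    w[T, C] = 1.0    # cortico-thalamic
    w[R, C] = 1.0    # cortico-reticular
    w[T, R] = -2.0   # reticulo-thalamic (inhibitory)
    d = np.zeros((3, 3))
    d[C, T] = d[T, C] = 8.8
    d[R, T] = d[T, R] = 0.0
    d[R, C] = d[C, R] = 8.8  # reticular co-located with thalamus
    return NetworkSpec(nodes=nodes, weights=w, distances=d,
                       inverse_speed=1.0 / 7.0, csf=csf)


def node_output(state: NodeState, kind: NodeKind) -> float:
    """Transmitted output of a node: sum over modes of the membrane potential
    of its principal population (xi; alpha for inhibitory-only nodes)."""
    if kind.inhibitory_only:
        v = state.alpha
    else:
        v = state.xi
    if not np.all(np.isfinite(v)):
        raise FloatingPointError(f"non-finite node output {v!r}")
    return float(np.sum(v))


class DelayBuffer:
    """Ring buffer of node outputs at integration-step resolution.

    ``horizon`` is the maximum lag (in steps) that can be read back.  The
    buffer must be warmed (via :meth:`fill`) or pushed past the largest
    delay before delayed reads are valid.
    """

    def __init__(self, n_nodes: int, horizon: int):
        self.horizon = int(horizon)
        self._buf = np.zeros((n_nodes, self.horizon + 1))
        self._count = 0  # number of pushes so far

    def fill(self, outputs) -> None:
        """Pre-fill the whole history with constant per-node outputs."""
        self._buf[:] = np.asarray(outputs, dtype=float)[:, None]
        self._count = self.horizon + 1

    def push(self, outputs) -> None:
        """Append outputs for the current step."""
        pos = self._count % self._buf.shape[1]
        self._buf[:, pos] = outputs
        self._count += 1

    def read(self, node: int, lag: int) -> float:
        """Output of ``node`` exactly ``lag`` steps before the last push
        (lag 0 = the most recent push)."""
        if lag > self.horizon:
            raise ValueError(f"lag {lag} exceeds buffer horizon {self.horizon}")
        if self._count <= lag:
            raise RuntimeError(
                f"delay buffer underrun reading node {node} at lag {lag}: "
                f"only {self._count} steps of history")
        pos = (self._count - 1 - lag) % self._buf.shape[1]
        return float(self._buf[node, pos])


def coupling_drive(spec: NetworkSpec, buffers: DelayBuffer, dt: float) -> np.ndarray:
    """Per-node delayed coupling drive c * sum_j w_ij o_j(t - dt_ij).

    Reads delayed outputs for the most recent pushed step; raises (naming the
    edge) if the buffer holds insufficient history for some delay.
    """
    lags = spec.delay_steps(dt)
    n = spec.n_nodes
    drive = np.zeros(n)
    if spec.csf == 0:
        return drive
    for i in range(n):
        acc = 0.0
        for j in range(n):
            w = spec.weights[i, j]
            if w == 0.0:
                continue
            try:
                acc += w * buffers.read(j, int(lags[i, j]))
            except RuntimeError as err:
                raise RuntimeError(
                    f"underrun on edge {spec.names[j]} -> {spec.names[i]}: {err}"
                ) from err
        drive[i] = spec.csf * acc
    return drive
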