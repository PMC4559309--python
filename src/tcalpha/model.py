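"""Hindmarsh-Rose single-neuron dynamics and the reduced three-mode
(Stefanescu-Jirsa 3D) neural-mass equations.

The neural-mass node describes a population of excitatory and a population of
inhibitory Hindmarsh-Rose neurons whose input currents ``I`` are dispersed
according to a Gaussian with mean ``mu`` and standard deviation ``sigma``.
Projecting the population field onto three orthonormal *rectangular* basis
functions over the excitability axis (one per equal-probability third of the
distribution) closes the dynamics into three interacting "modes", each
carrying a six-dimensional state: the excitatory triplet (xi, eta, tau) and
the inhibitory triplet (alpha, beta, gamma).

All mode constants are quadrature integrals of the basis functions against
the excitability density; see :func:`derive_mode_coefficients`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import trapezoid
from scipy.stats import norm

__all__ = [
    "HRParams",
    "ExcitabilityDistribution",
    "ModeCoefficients",
    "NodeState",
    "NodeKind",
    "hr_derivatives",
    "derive_mode_coefficients",
    "sj3d_derivatives",
    "N_MODES",
]

N_MODES = 3


class BlowUpError(FloatingPointError):
    """A state variable left the finite envelope of the model."""


def _check_finite(name, value):
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise BlowUpError(f"non-finite value in {name}: {value!r}")
    return arr


# ---------------------------------------------------------------------------
# Single Hindmarsh-Rose neuron
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HRParams:
    """Parameters of the three-variable Hindmarsh-Rose neuron.

    ``a, b`` shape the fast cubic membrane nonlinearity, ``c, d`` the fast
    recovery variable, ``r`` sets the (slow) adaptation rate, ``s`` the
    bursting strength and ``x_rest`` the resting offset in the slow equation.
    ``I`` is the external input current controlling excitability.  Defaults
    are the classic spike-burst regime values (time in ms-like model units).
    """

    a: float = 1.0
    b: float = 3.0
    c: float = 1.0
    d: float = 5.0
    r: float = 0.006
    s: float = 4.0
    x_rest: float = -1.6
    I: float = 3.1

    def __post_init__(self):
        vals = (self.a, self.b, self.c, self.d, self.r, self.s, self.x_rest, self.I)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite HR parameter in {vals}")
        if self.r <= 0:
            raise ValueError("r must be > 0")
        if self.s <= 0:
            raise ValueError("s must be > 0")


def hr_derivatives(state, params: HRParams):
    """Time derivative (dx, dy, dz) of a single Hindmarsh-Rose neuron.

    dx = y - a x^3 + b x^2 + I - z
    dy = c - d x^2 - y
    dz = r (s (x - x_rest) - z)
    """
    x, y, z = _check_finite("HR state", state)
    p = params
    dx = y - p.a * x**3 + p.b * x**2 + p.I - z
    dy = p.c - p.d * x**2 - y
    dz = p.r * (p.s * (x - p.x_rest) - z)
    return dx, dy, dz


# ---------------------------------------------------------------------------
# Mode decomposition of the dispersed population
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExcitabilityDistribution:
    """Gaussian dispersion of the input current across the population.

    ``n_quad`` is the number of quantile-grid points used for the quadrature;
    the grid spans the distribution between its ``tail_mass`` and
    ``1 - tail_mass`` quantiles (fixed range, so refining n_quad converges)
    and is split into ``n_modes`` equal-probability blocks.
    """

    mu: float = 3.1
    sigma: float = 0.5
    n_modes: int = N_MODES
    n_quad: int = 1500
    tail_mass: float = 1.0 / 1501.0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_modes != N_MODES:
            raise ValueError("the reduced model is defined for exactly 3 modes")
        if self.n_quad < 3 * self.n_modes:
            raise ValueError("n_quad too small for a 3-interval partition")
        if not 0 < self.tail_mass < 0.5:
            raise ValueError("tail_mass must be in (0, 0.5)")

    def quantile_grid(self):
        """Quadrature abscissae: n_quad quantiles of the Gaussian spanning
        the fixed probability range [tail_mass, 1 - tail_mass]."""
        if self.sigma == 0:
            raise ValueError("sigma = 0: degenerate excitability distribution")
        probs = np.linspace(self.tail_mass, 1.0 - self.tail_mass, self.n_quad)
        return norm.ppf(probs, loc=self.mu, scale=self.sigma)


@dataclass(frozen=True)
class ModeCoefficients:
    """All per-mode constants of the reduced three-mode node.

    ``A, B, C`` are 3x3 mean-field coupling matrices (excitatory->excitatory,
    inhibitory->excitatory, excitatory->inhibitory).  ``a..p`` are the
    projected nonlinearity/offset coefficients, ``IE/II`` the per-mode input
    currents, ``m/n`` the slow-equation offsets.  Everything is a
    deterministic function of the excitability distribution and the base
    Hindmarsh-Rose parameters.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    e: np.ndarray
    f: np.ndarray
    h: np.ndarray
    p: np.ndarray
    IE: np.ndarray
    II: np.ndarray
    m: np.ndarray
    n: np.ndarray
    r: float
    s: float

    def __post_init__(self):
        for name in ("A", "B", "C"):
            if np.shape(getattr(self, name)) != (N_MODES, N_MODES):
                raise ValueError(f"{name} must be 3x3")
        for name in ("a", "b", "c", "d", "e", "f", "h", "p", "IE", "II", "m", "n"):
            if np.shape(getattr(self, name)) != (N_MODES,):
                raise ValueError(f"{name} must have length 3")
            _check_finite(name, getattr(self, name))

    def as_table(self):
        """Flat (name, mode, value) rows, for plain-text fixture export."""
        rows = []
        for name in ("a", "b", "c", "d", "e", "f", "h", "p", "IE", "II", "m", "n"):
            for i, v in enumerate(getattr(self, name)):
                rows.append((name, i, float(v)))
        for name in ("A", "B", "C"):
            mat = getattr(self, name)
            for i in range(N_MODES):
                for k in range(N_MODES):
                    rows.append((f"{name}{i}{k}", i, float(mat[i, k])))
        return rows


def derive_mode_coefficients(
    dist: ExcitabilityDistribution, base: HRParams = HRParams()
) -> ModeCoefficients:
    """Galerkin projection of the dispersed Hindmarsh-Rose population.

    The population field X(I, t) is expanded as sum_i xi_i(t) V_i(I) where the
    V_i are indicator functions of the three equal-probability intervals of
    the Gaussian excitability density g(I), normalised to unit L2 norm over
    the quadrature range.  Because the modes are disjoint, the cubic and
    quadratic nonlinearities project diagonally:

        a_i = a * int V_i^4 dI        b_i = b * int V_i^3 dI
        c_i = c * int V_i dI          d_i = d * int V_i^3 dI
        IE_i = int I V_i(I) dI        m_i = r s x_rest * int V_i dI

    while the intra-node mean-field coupling (each neuron feels the
    g-weighted population mean) produces rank-one matrices

        A_ik = int V_i dI * int g V_k dI     (excitatory -> excitatory)
        B_ik = int V_i dI * int g U_k dI     (inhibitory -> excitatory)
        C_ik = int U_i dI * int g V_k dI     (excitatory -> inhibitory)

    The inhibitory population shares the same excitability distribution, so
    its basis U equals V and (e, f, h, p, II, n) mirror (a, b, c, d, IE, m).
    All integrals use trapezoidal quadrature on the Gaussian quantile grid.
    """
    if dist.sigma <= 0:
        raise ValueError("sigma must be > 0 to partition the distribution")
    z = dist.quantile_grid()
    nq = dist.n_quad
    per = nq // dist.n_modes

    V = np.zeros((dist.n_modes, nq))
    for i in range(dist.n_modes):
        lo = i * per
        hi = (i + 1) * per if i < dist.n_modes - 1 else nq
        V[i, lo:hi] = 1.0

    # unit L2 norm over the quadrature range
    norms = np.sqrt(trapezoid(V * V, z, axis=1))
    V = V / norms[:, None]

    g = norm.pdf(z, loc=dist.mu, scale=dist.sigma)

    int_V = trapezoid(V, z, axis=1)              # int V_i dI
    int_gV = trapezoid(g[None, :] * V, z, axis=1)  # int g V_i dI
    int_V3 = trapezoid(V**3, z, axis=1)
    int_V4 = trapezoid(V**4, z, axis=1)
    int_IV = trapezoid(z[None, :] * V, z, axis=1)

    A = np.outer(int_V, int_gV)
    p = base
    return ModeCoefficients(
        A=A,
        B=A.copy(),
        C=A.copy(),
        a=p.a * int_V4,
        b=p.b * int_V3,
        c=p.c * int_V,
        d=p.d * int_V3,
        e=p.a * int_V4,
        f=p.b * int_V3,
        h=p.c * int_V,
        p=p.d * int_V3,
        IE=int_IV,
        II=int_IV.copy(),
        m=p.r * p.s * p.x_rest * int_V,
        n=p.r * p.s * p.x_rest * int_V,
        r=p.r,
        s=p.s,
    )


# ---------------------------------------------------------------------------
# Node state and the six mode equations
# ---------------------------------------------------------------------------

@dataclass
class NodeState:
    """State of one node: per-mode excitatory (xi, eta, tau) and inhibitory
    (alpha, beta, gamma) triplets, each of length 3."""

    xi: np.ndarray
    eta: np.ndarray
    tau: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray

    _FIELDS = ("xi", "eta", "tau", "alpha", "beta", "gamma")

    def __post_init__(self):
        for name in self._FIELDS:
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (N_MODES,):
                raise ValueError(f"{name} must have length 3, got {v.shape}")
            setattr(self, name, v)

    @classmethod
    def zeros(cls):
        return cls(*(np.zeros(N_MODES) for _ in cls._FIELDS))

    @classmethod
    def from_array(cls, arr):
        arr = np.asarray(arr, dtype=float).reshape(6, N_MODES)
        return cls(*(arr[i].copy() for i in range(6)))

    def to_array(self):
        return np.stack([getattr(self, n) for n in self._FIELDS])


@dataclass(frozen=True)
class NodeKind:
    """Node composition: a full excitatory+inhibitory node with intrinsic
    couplings, or an inhibitory-only node (reticular nucleus) with none."""

    kind: str = "full"
    K11: float = 0.5
    K12: float = 0.25
    K21: float = 0.5

    def __post_init__(self):
        if self.kind not in ("full", "inhibitory_only"):
            raise ValueError(f"unknown node kind {self.kind!r}")

    @property
    def inhibitory_only(self) -> bool:
        return self.kind == "inhibitory_only"

    def couplings(self):
        """Effective (K11, K12, K21); identically zero for inhibitory-only."""
        if self.inhibitory_only:
            return 0.0, 0.0, 0.0
        return self.K11, self.K12, self.K21


FULL_NODE = NodeKind("full")
INHIBITORY_NODE = NodeKind("inhibitory_only")


def sj3d_derivatives(
    state: NodeState,
    coeffs: ModeCoefficients,
    kind: NodeKind = FULL_NODE,
    ext_input=0.0,
) -> NodeState:
    """Six mode equations of the reduced node.

    For mode i (K-terms dropped for inhibitory-only nodes):

        dxi_i    = eta_i - a_i xi_i^3 + b_i xi_i^2 - tau_i
                   + K11 (sum_k A_ik xi_k - xi_i) - K12 (sum_k B_ik alpha_k - xi_i)
                   + IE_i + ext_i
        deta_i   = c_i - d_i xi_i^2 - eta_i
        dtau_i   = r s xi_i - r tau_i - m_i
        dalpha_i = beta_i - e_i alpha_i^3 + f_i alpha_i^2 - gamma_i
                   + K21 (sum_k C_ik xi_k - alpha_i) + II_i
        dbeta_i  = h_i - p_i alpha_i^2 - beta_i
        dgamma_i = r s alpha_i - r gamma_i - n_i

    ``ext_input`` (scalar or length-3) is the delayed network drive; it is
    broadcast identically into every excitatory mode equation (into the
    alpha equations for inhibitory-only nodes).  Inhibitory-only nodes have
    frozen excitatory triplets (derivative zero).
    """
    ext = np.broadcast_to(np.asarray(ext_input, dtype=float), (N_MODES,))
    _check_finite("ext_input", ext)
    xi, eta, tau = state.xi, state.eta, state.tau
    al, be, ga = state.alpha, state.beta, state.gamma
    for name, v in (("xi", xi), ("eta", eta), ("tau", tau),
                    ("alpha", al), ("beta", be), ("gamma", ga)):
        _check_finite(name, v)
    c = coeffs
    K11, K12, K21 = kind.couplings()

    dal = (be - c.e * al**3 + c.f * al**2 - ga
           + K21 * (c.C @ xi - al) + c.II)
    dbe = c.h - c.p * al**2 - be
    dga = c.r * c.s * al - c.r * ga - c.n

    if kind.inhibitory_only:
        dal = dal + ext
        out = NodeState(np.zeros(N_MODES), np.zeros(N_MODES), np.zeros(N_MODES),
                        dal, dbe, dga)
    else:
        dxi = (eta - c.a * xi**3 + c.b * xi**2 - tau
               + K11 * (c.A @ xi - xi) - K12 * (c.B @ al - xi)
               + c.IE + ext)
        deta = c.c - c.d * xi**2 - eta
        dtau = c.r * c.s * xi - c.r * tau - c.m
        out = NodeState(dxi, deta, dtau, dal, dbe, dga)
    for name in NodeState._FIELDS:
        _check_finite(f"d{name}", getattr(out, name))
    return out
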