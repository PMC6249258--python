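"""Connectome-style recurrent network trained to generate gradient representations.

A recurrent network over a curated set of 22 chemotaxis-circuit neurons
(ASE, AIA, AIB, AIY, AIZ, RIA, RIB, RIM, RIV, AVB, PVC left/right pairs)
receives the encoded nose-tip concentration derivative through the ASEL/ASER
sensory models and the head-bending angle through RIV, and is trained so
that designated output neurons reproduce the normalised true chemical
gradients.  Neuron dynamics follow a discrete leaky integrator with three
kinds of connections:

    u_i(t+1) = u_i(t)/(1+Ts*tau_i)
             + Ts/(1+Ts*tau_i) * [ sum_j w_ij z_j(t) + sum_j s_ij (u_j(t)-u_i(t)) ]
             + 1/(1+Ts*tau_i)  *   sum_j w^d_ij (z_j(t) - z_j(t-1))
    U_i(t)   = 1 / (1 + exp(-u_i(t)))

``u`` is the membrane current, ``U`` the (sigmoid) potential, ``w`` chemical
weights, ``w^d`` derivative-synapse weights on the same edges, ``s``
symmetric gap-junction conductances (difference coupling), ``tau >= 0``
leak time constants and ``Ts`` the sampling time.  By default chemical and
derivative synapses transmit the potential ``U_j`` (``transmit="potential"``),
which makes the recurrence nonlinear and lets sigmoid gating demodulate the
head-bend-locked concentration signal; ``transmit="current"`` switches to
transmitting ``u_j`` directly (a purely linear recurrence with the sigmoid
acting only on the read-out).

Training is batch gradient descent on the masked squared error using exact
reverse-mode (backpropagation-through-time) gradients that include the gap
coupling, the two-step derivative-synapse term and the tau-dependence of the
leak factors.  Gap symmetry is preserved exactly (the shared conductance is
updated with the sum of both directional partials) and tau is clamped at 0.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

try:  # optional acceleration of the per-step recursions
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional dependency
    _HAVE_NUMBA = False

__all__ = [
    "NetworkTopology",
    "NetworkParams",
    "SensoryParams",
    "TrainingConfig",
    "load_topology",
    "default_topology",
    "init_params",
    "asel_input",
    "aser_input",
    "network_step",
    "forward_trace",
    "normalize_teacher",
    "loss",
    "bptt_gradients",
    "train",
    "evaluate_outputs",
    "TrainingDiverged",
]

DEFAULT_NEURONS = (
    "ASEL", "ASER", "AIAL", "AIAR", "AIBL", "AIBR", "AIYL", "AIYR",
    "AIZL", "AIZR", "RIAL", "RIAR", "RIBL", "RIBR", "RIML", "RIMR",
    "RIVL", "RIVR", "AVBL", "AVBR", "PVCL", "PVCR",
)
DEFAULT_INPUTS = ("I1", "I2", "q0")
DEFAULT_OUTPUTS = {
    "parallel": ("PVCL", "PVCR", "AVBL", "AVBR"),
    "perpendicular": ("RIAL", "RIAR", "AIZL", "AIZR"),
}


def _sigmoid(x):
    with np.errstate(over="ignore"):  # saturates cleanly at 0/1
        return 1.0 / (1.0 + np.exp(-x))


@dataclass
class NetworkTopology:
    """Edge structure: who connects to whom, and which neurons are outputs."""

    neuron_names: tuple
    input_names: tuple
    chem_edges: tuple  # directed (pre, post); pre may be an input name
    gap_edges: tuple  # undirected (a, b), each listed once, neurons only
    output_assignment: Mapping[str, tuple] = field(default_factory=lambda: dict(DEFAULT_OUTPUTS))

    def __post_init__(self) -> None:
        names = set(self.neuron_names)
        valid_pre = names | set(self.input_names)
        for pre, post in self.chem_edges:
            if pre not in valid_pre or post not in names:
                raise ValueError(f"invalid chemical edge {pre}->{post}")
        for a, b in self.gap_edges:
            if a not in names or b not in names:
                raise ValueError(f"invalid gap edge {a}-{b}")
            if a == b:
                raise ValueError("self gap junctions are not allowed")
        for key, neurons in self.output_assignment.items():
            for nm in neurons:
                if nm not in names:
                    raise ValueError(f"output neuron {nm} not in network")

    @property
    def n(self) -> int:
        return len(self.neuron_names)

    @property
    def m(self) -> int:
        return len(self.input_names)

    def index(self, name: str) -> int:
        """Column index of a neuron or input in the stacked z vector."""
        if name in self.neuron_names:
            return self.neuron_names.index(name)
        return self.n + self.input_names.index(name)

    def chem_mask(self) -> np.ndarray:
        """(n, n+m) boolean mask of chemical (and derivative) synapses."""
        mask = np.zeros((self.n, self.n + self.m), dtype=bool)
        for pre, post in self.chem_edges:
            mask[self.neuron_names.index(post), self.index(pre)] = True
        return mask

    def gap_mask(self) -> np.ndarray:
        """(n, n) symmetric boolean mask of gap junctions, zero diagonal."""
        mask = np.zeros((self.n, self.n), dtype=bool)
        for a, b in self.gap_edges:
            i, j = self.neuron_names.index(a), self.neuron_names.index(b)
            mask[i, j] = mask[j, i] = True
        return mask

    def output_mask(self) -> np.ndarray:
        """Per-neuron 0/1 mask over all output-assigned neurons."""
        mu = np.zeros(self.n)
        for neurons in self.output_assignment.values():
            for nm in neurons:
                mu[self.neuron_names.index(nm)] = 1.0
        return mu


def load_topology(
    path,
    neuron_names: Sequence[str] = DEFAULT_NEURONS,
    input_names: Sequence[str] = DEFAULT_INPUTS,
    output_assignment: Mapping[str, tuple] | None = None,
) -> NetworkTopology:
    """Read a tab-separated edge list with columns ``pre  post  type``.

    ``type`` is ``chem``, ``gap`` or ``input``; gap rows are listed once.
    Lines starting with ``#`` are comments.
    """
    chem, gap = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            pre, post, kind = line.split("\t")
            if kind == "gap":
                gap.append((pre, post))
            elif kind in ("chem", "input"):
                chem.append((pre, post))
            else:
                raise ValueError(f"unknown edge type {kind!r}")
    return NetworkTopology(
        neuron_names=tuple(neuron_names),
        input_names=tuple(input_names),
        chem_edges=tuple(chem),
        gap_edges=tuple(gap),
        output_assignment=dict(output_assignment or DEFAULT_OUTPUTS),
    )


def default_topology() -> NetworkTopology:
    """Curated approximation of the chemotaxis circuit (replaceable)."""
    ref = importlib.resources.files("nemataxis") / "data" / "chemotaxis_circuit.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_topology(path)


@dataclass
class NetworkParams:
    """Trainable parameters; masks live in the topology."""

    W: np.ndarray  # (n, n+m) chemical weights
    Wd: np.ndarray  # (n, n+m) derivative-synapse weights
    S: np.ndarray  # (n, n) symmetric gap conductances, zero diagonal
    tau: np.ndarray  # (n,) leak time constants, >= 0
    T_s: float = 0.1  # sampling time, s
    transmit: str = "potential"  # "potential" (z=U) or "current" (z=u)

    def __post_init__(self) -> None:
        if self.transmit not in ("potential", "current"):
            raise ValueError("transmit must be 'potential' or 'current'")
        if np.any(self.tau < 0):
            raise ValueError("tau must be >= 0")
        if not np.allclose(self.S, self.S.T):
            raise ValueError("gap conductances must be symmetric")

    def copy(self) -> "NetworkParams":
        return NetworkParams(self.W.copy(), self.Wd.copy(), self.S.copy(),
                             self.tau.copy(), self.T_s, self.transmit)


def init_params(
    topology: NetworkTopology,
    rng: np.random.Generator,
    T_s: float = 0.1,
    weight_scale: float = 0.1,
    gap_init: float = 0.01,
    tau_init: float = 1.0,
    transmit: str = "potential",
) -> NetworkParams:
    """Seeded initialisation: chemical weights ~ N(0, weight_scale), derivative
    weights 0, small positive gap conductances, tau = tau_init."""
    cmask = topology.chem_mask()
    gmask = topology.gap_mask()
    W = np.where(cmask, rng.normal(0.0, weight_scale, cmask.shape), 0.0)
    S = np.where(gmask, gap_init, 0.0)
    S = 0.5 * (S + S.T)
    return NetworkParams(
        W=W,
        Wd=np.zeros_like(W),
        S=S,
        tau=np.full(topology.n, float(tau_init)),
        T_s=T_s,
        transmit=transmit,
    )


# --------------------------------------------------------------------------
# Sensory encoders


@dataclass
class SensoryParams:
    """Log-compressive ASEL/ASER response models.

    ASEL is an ON cell (responds to concentration increases only); ASER has
    ON and OFF branches with a stronger OFF limb.  Slopes ``a*b`` are chosen
    so the encoders produce order-one responses at the concentration-
    derivative scale of the default environment.  The sign constraints keep
    the logarithm arguments positive on each active branch for any input.
    """

    a_L: float = 0.6
    b_L: float = 1.0e5  # per (mM/s); ON branch, must be >= 0
    a_R_pos: float = 0.4
    b_R_pos: float = 1.0e5  # >= 0
    a_R_neg: float = 1.0
    b_R_neg: float = -1.0e5  # <= 0 so the OFF branch log argument stays >= 1

    def __post_init__(self) -> None:
        if self.b_L < 0 or self.b_R_pos < 0 or self.b_R_neg > 0:
            raise ValueError(
                "branch slopes must satisfy b_L >= 0, b_R_pos >= 0, b_R_neg <= 0 "
                "so that log arguments stay positive on the active branches"
            )


def asel_input(params: SensoryParams, dcdt):
    """ASEL drive ``I1``: ON-cell, zero for non-increasing concentration."""
    dcdt = np.asarray(dcdt, dtype=float)
    on = np.log1p(np.maximum(params.b_L * dcdt, 0.0)) * params.a_L
    out = np.where(dcdt > 0, on, 0.0)
    return float(out) if out.ndim == 0 else out


def aser_input(params: SensoryParams, dcdt):
    """ASER drive ``I2``: ON/OFF cell, continuous at zero."""
    dcdt = np.asarray(dcdt, dtype=float)
    on = np.log1p(np.maximum(params.b_R_pos * dcdt, 0.0)) * params.a_R_pos
    off = np.log1p(np.maximum(params.b_R_neg * dcdt, 0.0)) * params.a_R_neg
    out = np.where(dcdt > 0, on, off)
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# Forward dynamics

def _split(params: NetworkParams, n: int):
    return params.W[:, :n], params.W[:, n:], params.Wd[:, :n], params.Wd[:, n:]


def network_step(
    topology: NetworkTopology,
    params: NetworkParams,
    u: np.ndarray,
    inputs: np.ndarray,
    z_prev: np.ndarray | None = None,
):
    """One update of the neuron dynamics.

    ``u`` is the (n,) current vector, ``inputs`` the (m,) external drive,
    ``z_prev`` the previous full transmission vector (n+m,) for the
    derivative-synapse term (defaults to the current one, i.e. zero
    difference).  Returns ``(u_next, U_next, z)`` where ``z`` is this step's
    transmission vector.
    """
    n = topology.n
    u = np.asarray(u, dtype=float)
    inputs = np.asarray(inputs, dtype=float)
    if inputs.shape != (topology.m,):
        raise ValueError("inputs must have length m")
    zn = _sigmoid(u) if params.transmit == "potential" else u
    z = np.concatenate([zn, inputs])
    if z_prev is None:
        z_prev = z
    beta = 1.0 / (1.0 + params.T_s * params.tau)
    rho = params.S.sum(axis=1)
    a = (
        u
        + params.T_s * (params.W @ z + params.S @ u - rho * u)
        + params.Wd @ (z - z_prev)
    )
    u_next = beta * a
    return u_next, _sigmoid(u_next), z


def _forward_kernel_py(W, Wd, S, tau, T_s, inputs, potential, u, z, dz):
    B, T, m = inputs.shape
    n = W.shape[1]
    for b in range(B):
        beta = 1.0 / (1.0 + T_s * tau[b])
        rho = S[b].sum(axis=1)
        zfull = np.zeros(n + m)
        prev = np.zeros(n + m)
        for t in range(T):
            ut = u[t, b]
            if potential:
                zn = 1.0 / (1.0 + np.exp(-ut))
            else:
                zn = ut.copy()
            zfull[:n] = zn
            zfull[n:] = inputs[b, t]
            if t == 0:
                prev[:] = zfull
            d = zfull - prev
            a = ut + T_s * (W[b] @ zfull + S[b] @ ut - rho * ut) + Wd[b] @ d
            u[t + 1, b] = beta * a
            z[t, b] = zfull
            dz[t, b] = d
            prev[:] = zfull


def _backward_kernel_py(W, Wd, S, tau, T_s, u, teachers, mu, window, potential, phi):
    """Adjoint recursion; fills ``phi[t] = beta * dH/du(t)`` for t = 1..T."""
    T, B, n = u.shape[0] - 1, u.shape[1], u.shape[2]
    for b in range(B):
        beta = 1.0 / (1.0 + T_s * tau[b])
        rho = S[b].sum(axis=1)
        Wn_T = (T_s * W[b, :, :n] + Wd[b, :, :n]).T.copy()
        Wdn_T = Wd[b, :, :n].T.copy()
        for t in range(T, 0, -1):
            p1 = phi[t + 1, b]
            p2 = phi[t + 2, b]
            U_t = 1.0 / (1.0 + np.exp(-u[t, b]))
            g = p1 + T_s * (S[b] @ p1 - rho * p1)
            if window[t - 1]:
                g = g + mu * (U_t - teachers[t - 1, b]) * U_t * (1.0 - U_t)
            back = Wn_T @ p1 - Wdn_T @ p2
            if potential:
                back = U_t * (1.0 - U_t) * back  # z(t) is built from u(t)
            phi[t, b] = beta * (g + back)


if _HAVE_NUMBA:
    _forward_kernel = _njit(cache=False)(_forward_kernel_py)
    _backward_kernel = _njit(cache=False)(_backward_kernel_py)
else:
    _forward_kernel = _forward_kernel_py
    _backward_kernel = _backward_kernel_py


class TrainingDiverged(FloatingPointError):
    """Raised when a rollout goes non-finite; carries which batch members did."""

    def __init__(self, message: str, bad_members=None, epoch: int | None = None):
        super().__init__(message)
        self.bad_members = bad_members
        self.epoch = epoch


def _forward_batched(W, Wd, S, tau, T_s, inputs, transmit):
    """Rollout for ``B`` independent networks at once.

    ``W``/``Wd`` are (B, n, n+m), ``S`` (B, n, n), ``tau`` (B, n), ``inputs``
    (B, T, m).  Returns ``u`` (T+1, B, n), ``z`` (T, B, n+m) and
    ``dz`` (T, B, n+m).  Non-finite states are returned as-is; callers check.
    """
    B, T, m = inputs.shape
    n = W.shape[1]
    if _HAVE_NUMBA and T * B > 512:
        u = np.zeros((T + 1, B, n))
        z = np.zeros((T, B, n + m))
        dz = np.zeros((T, B, n + m))
        with np.errstate(over="ignore", invalid="ignore"):
            _forward_kernel(
                np.ascontiguousarray(W), np.ascontiguousarray(Wd), np.ascontiguousarray(S),
                np.ascontiguousarray(tau), T_s, np.ascontiguousarray(inputs),
                transmit == "potential", u, z, dz,
            )
        return u, z, dz
    beta = 1.0 / (1.0 + T_s * tau)  # (B, n)
    rho = S.sum(axis=2)
    Wn, Wm = W[:, :, :n], W[:, :, n:]
    Wdn, Wdm = Wd[:, :, :n], Wd[:, :, n:]
    u = np.zeros((T + 1, B, n))
    z = np.empty((T, B, n + m))
    dz = np.zeros((T, B, n + m))
    prev_zn = None
    prev_inp = inputs[:, 0]
    for t in range(T):
        ut = u[t]
        zn = _sigmoid(ut) if transmit == "potential" else ut
        inp = inputs[:, t]
        if prev_zn is None:
            prev_zn = zn
        d_zn = zn - prev_zn
        d_in = inp - prev_inp
        a = (
            ut
            + T_s * (
                np.einsum("bij,bj->bi", Wn, zn)
                + np.einsum("bim,bm->bi", Wm, inp)
                + np.einsum("bij,bj->bi", S, ut)
                - rho * ut
            )
            + np.einsum("bij,bj->bi", Wdn, d_zn)
            + np.einsum("bim,bm->bi", Wdm, d_in)
        )
        u[t + 1] = beta * a
        z[t, :, :n] = zn
        z[t, :, n:] = inp
        dz[t, :, :n] = d_zn
        dz[t, :, n:] = d_in
        prev_zn, prev_inp = zn, inp
    return u, z, dz


def forward_trace(topology: NetworkTopology, params: NetworkParams, input_series) -> np.ndarray:
    """Deterministic rollout from ``u(0) = 0``; returns the potentials ``U``.

    ``input_series`` is (T, m); the returned array is (T, n): the potential
    after consuming each input sample.
    """
    input_series = np.asarray(input_series, dtype=float)
    if input_series.size == 0:
        return np.zeros((0, topology.n))
    u, _, _ = _forward_batched(
        params.W[None], params.Wd[None], params.S[None], params.tau[None],
        params.T_s, input_series[None], params.transmit,
    )
    finite = np.isfinite(u[:, 0, :]).all(axis=1)
    if not finite.all():
        step = int(np.argmin(finite))
        raise FloatingPointError(f"non-finite network state at step {step}")
    return _sigmoid(u[1:, 0, :])


# --------------------------------------------------------------------------
# Teacher, loss, gradients

def normalize_teacher(series) -> np.ndarray:
    """Min-max normalise a teacher series to [0, 1]."""
    series = np.asarray(series, dtype=float)
    lo, hi = series.min(), series.max()
    if hi == lo:
        raise ValueError("degenerate teacher: series is constant")
    return (series - lo) / (hi - lo)


def loss(U_trace, teachers, mu, window=None) -> float:
    """Masked halved sum of squared errors over the (boolean or slice) window."""
    U_trace = np.asarray(U_trace, dtype=float)
    teachers = np.asarray(teachers, dtype=float)
    if window is not None:
        U_trace = U_trace[window]
        teachers = teachers[window]
    err = (U_trace - teachers) * np.asarray(mu, dtype=float)
    return 0.5 * float((err ** 2).sum())


def _backward_batched(W, Wd, S, tau, T_s, u, z, dz, teachers, mu, window, transmit):
    """Exact BPTT gradients for a batch of independent networks.

    ``teachers`` (T, B, n), ``mu`` (n,), ``window`` boolean (T,).  Returns
    per-network gradients for W, Wd, the independent directional gap
    partials, and tau.
    """
    T, B, n = u.shape[0] - 1, u.shape[1], u.shape[2]
    phi = np.zeros((T + 3, B, n))
    window = np.ascontiguousarray(window)
    if _HAVE_NUMBA and T * B > 512:
        _backward_kernel(
            np.ascontiguousarray(W), np.ascontiguousarray(Wd), np.ascontiguousarray(S),
            np.ascontiguousarray(tau), T_s, np.ascontiguousarray(u),
            np.ascontiguousarray(teachers), np.ascontiguousarray(mu, dtype=float),
            window, transmit == "potential", phi,
        )
    else:
        beta = 1.0 / (1.0 + T_s * tau)
        rho = S.sum(axis=2)
        Wn = W[:, :, :n]
        Wdn = Wd[:, :, :n]
        U = _sigmoid(u)  # (T+1, B, n)
        sig_grad = U * (1.0 - U)
        for t in range(T, 0, -1):
            if window[t - 1]:
                delta = mu * (U[t] - teachers[t - 1]) * sig_grad[t]
            else:
                delta = np.zeros((B, n))
            p1 = phi[t + 1]
            p2 = phi[t + 2]
            g = delta + p1 + T_s * (np.einsum("bij,bj->bi", S, p1) - rho * p1)
            back = np.einsum("bji,bj->bi", T_s * Wn + Wdn, p1) - np.einsum("bji,bj->bi", Wdn, p2)
            if transmit == "potential":
                back = sig_grad[t] * back  # z(t) is built from u(t)
            g = g + back
            phi[t] = beta * g
    phis = phi[1:T + 1]  # (T, B, n) = beta * dH/du(t), t = 1..T
    us_prev = u[:T]  # u(t), t = 0..T-1
    phis_b = np.ascontiguousarray(phis.transpose(1, 2, 0))  # (B, n, T)
    gW = T_s * (phis_b @ np.ascontiguousarray(z.transpose(1, 0, 2)))
    gWd = phis_b @ np.ascontiguousarray(dz.transpose(1, 0, 2))
    P = phis_b @ np.ascontiguousarray(us_prev.transpose(1, 0, 2))
    Q = np.einsum("tbi,tbi->bi", phis, us_prev)
    gS_dir = T_s * (P - Q[:, :, None])
    gTau = -T_s * np.einsum("tbi,tbi->bi", phis, u[1:T + 1])
    return gW, gWd, gS_dir, gTau


def bptt_gradients(topology, params, input_series, teachers, window=None):
    """Partials of the masked loss with respect to every parameter.

    ``teachers`` is (T, n) (only masked columns matter); ``window`` an
    optional boolean array over the T samples (default: all).  Returns a dict
    with ``W``, ``Wd``, ``S_dir`` (independent directional gap partials),
    ``S_shared`` (their symmetrised sum, the Eq-style shared-parameter
    gradient), and ``tau``.  Entries outside the topology masks are zero.
    """
    input_series = np.asarray(input_series, dtype=float)
    teachers = np.asarray(teachers, dtype=float)
    T = len(input_series)
    if window is None:
        window = np.ones(T, dtype=bool)
    mu = topology.output_mask()
    u, z, dz = _forward_batched(
        params.W[None], params.Wd[None], params.S[None], params.tau[None],
        params.T_s, input_series[None], params.transmit,
    )
    gW, gWd, gS_dir, gTau = _backward_batched(
        params.W[None], params.Wd[None], params.S[None], params.tau[None],
        params.T_s, u, z, dz, teachers[:, None, :], mu, np.asarray(window, dtype=bool),
        params.transmit,
    )
    cmask = topology.chem_mask()
    gmask = topology.gap_mask()
    gS = np.where(gmask, gS_dir[0], 0.0)
    return {
        "W": np.where(cmask, gW[0], 0.0),
        "Wd": np.where(cmask, gWd[0], 0.0),
        "S_dir": gS,
        "S_shared": gS + gS.T,
        "tau": gTau[0],
    }


# --------------------------------------------------------------------------
# Training


@dataclass
class TrainingConfig:
    """Gradient-descent settings for fitting the gradient representations."""

    eta_w: float = 0.05  # learning rate, chemical and derivative weights
    eta_g: float = 0.002  # learning rate, gap conductances (gap growth
    # destabilises the recurrence, so the shared conductances move slowly)
    eta_tau: float = 0.002  # learning rate, leak time constants
    epochs: int = 9000
    train_window: tuple = (0.0, 300.0)  # s
    validation_window: tuple = (300.0, 600.0)  # s
    downsample: int = 10  # trace steps per network sample (T_s = 0.1 s)
    seed: int = 0  # initialisation seed
    init_weight_scale: float = 1.0  # chemical-weight init std (order one so
    # the sensory signal survives the multi-hop sigmoid attenuation)
    init_gap: float = 0.05  # initial gap conductance
    init_tau: float = 1.0  # initial leak time constant

    def __post_init__(self) -> None:
        if self.train_window[1] > self.validation_window[0]:
            raise ValueError("training and validation windows must be disjoint")


def _window_mask(times, window):
    times = np.asarray(times, dtype=float)
    return (times >= window[0]) & (times < window[1])


def train(
    topology: NetworkTopology,
    params: NetworkParams | Sequence[NetworkParams],
    datasets: Sequence[Mapping],
    config: TrainingConfig,
    eta_scale=None,
):
    """Fit one network per dataset by full-batch gradient descent.

    Each dataset is a mapping with keys ``inputs`` (T, m), ``teachers``
    (T, n) and ``times`` (T,).  ``params`` is a single initial parameter set
    (copied per dataset) or one per dataset.  All networks are trained
    simultaneously (stacked), which is exactly equivalent to training them
    one at a time because they share no parameters.  ``eta_scale``
    optionally scales all three learning rates per network (length B).

    Returns ``(trained, history)`` where ``trained`` is a list of
    :class:`NetworkParams` and ``history`` maps ``"train"``/``"validation"``
    to (epochs, n_datasets) loss arrays.  Raises :class:`TrainingDiverged`
    (with the epoch index and the affected networks) on divergence.
    """
    if len(datasets) == 0:
        raise ValueError("at least one dataset required")
    if isinstance(params, NetworkParams):
        plist = [params.copy() for _ in datasets]
    else:
        plist = [p.copy() for p in params]
        if len(plist) != len(datasets):
            raise ValueError("need one parameter set per dataset")
    T_s = plist[0].T_s
    transmit = plist[0].transmit
    B = len(datasets)
    n, p = plist[0].W.shape
    T = len(datasets[0]["inputs"])
    for ds in datasets:
        if len(ds["inputs"]) != T:
            raise ValueError("all datasets must have equal length")

    W = np.stack([q.W for q in plist])
    Wd = np.stack([q.Wd for q in plist])
    S = np.stack([q.S for q in plist])
    tau = np.stack([q.tau for q in plist])
    inputs = np.stack([np.asarray(ds["inputs"], dtype=float) for ds in datasets])
    teachers = np.stack([np.asarray(ds["teachers"], dtype=float) for ds in datasets], axis=1)  # (T,B,n)
    times = np.asarray(datasets[0]["times"], dtype=float)
    train_mask = _window_mask(times, config.train_window)
    val_mask = _window_mask(times, config.validation_window)
    mu = topology.output_mask()
    cmask = topology.chem_mask()
    gmask = topology.gap_mask()

    scale = np.ones(B) if eta_scale is None else np.asarray(eta_scale, dtype=float)
    if scale.shape != (B,):
        raise ValueError("eta_scale must have one entry per dataset")
    sc_w = (config.eta_w * scale)[:, None, None]
    sc_g = (config.eta_g * scale)[:, None, None]
    sc_tau = (config.eta_tau * scale)[:, None]

    hist_train = np.empty((config.epochs, B))
    hist_val = np.empty((config.epochs, B))
    for epoch in range(config.epochs):
        u, z, dz = _forward_batched(W, Wd, S, tau, T_s, inputs, transmit)
        finite = np.isfinite(u[-1]).all(axis=1)  # per network
        if not finite.all():
            raise TrainingDiverged(
                f"training diverged at epoch {epoch} "
                f"(networks {np.where(~finite)[0].tolist()})",
                bad_members=~finite,
                epoch=epoch,
            )
        U = _sigmoid(u[1:])  # (T, B, n)
        err = (U - teachers) * mu
        hist_train[epoch] = 0.5 * (err[train_mask] ** 2).sum(axis=(0, 2))
        hist_val[epoch] = 0.5 * (err[val_mask] ** 2).sum(axis=(0, 2))
        if not np.isfinite(hist_train[epoch]).all():
            bad = ~np.isfinite(hist_train[epoch])
            raise TrainingDiverged(
                f"training diverged at epoch {epoch}", bad_members=bad, epoch=epoch
            )
        gW, gWd, gS_dir, gTau = _backward_batched(
            W, Wd, S, tau, T_s, u, z, dz, teachers, mu, train_mask, transmit
        )
        W -= sc_w * np.where(cmask, gW, 0.0)
        Wd -= sc_w * np.where(cmask, gWd, 0.0)
        gS_sym = np.where(gmask, gS_dir + np.transpose(gS_dir, (0, 2, 1)), 0.0)
        S -= sc_g * gS_sym
        tau = np.maximum(0.0, tau - sc_tau * gTau)

    trained = [
        NetworkParams(W[b], Wd[b], S[b], tau[b], T_s, transmit) for b in range(B)
    ]
    return trained, {"train": hist_train, "validation": hist_val}


def evaluate_outputs(U_trace, teachers, topology: NetworkTopology, window=None):
    """Pearson r (and p) between each output neuron's potential and its teacher.

    Returns ``{output_name: {neuron: (r, p)}}``; raises on zero-variance
    series (undefined correlation).
    """
    U_trace = np.asarray(U_trace, dtype=float)
    teachers = np.asarray(teachers, dtype=float)
    if window is not None:
        U_trace = U_trace[window]
        teachers = teachers[window]
    out = {}
    for key, neurons in topology.output_assignment.items():
        res = {}
        for nm in neurons:
            i = topology.neuron_names.index(nm)
            x = U_trace[:, i]
            y = teachers[:, i]
            if np.std(x) == 0 or np.std(y) == 0:
                raise ValueError(f"undefined correlation for {nm}: zero-variance series")
            r, pval = stats.pearsonr(x, y)
            res[nm] = (float(r), float(pval))
        out[key] = res
    return out
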