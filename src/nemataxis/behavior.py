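"""Behavioural strategy layer: weathervane, pirouette and random-walk curvature.

Three mechanisms steer the worm:

* **Weathervane** (klinotaxis): a curvature bias proportional to the
  perceived lateral gradient, ``kappa_w = -C_w * d_s`` with ``d_s`` in mM/mm.
  The path gradually curves toward the side of higher concentration.
* **Pirouette** (klinokinesis): a reversal followed by a sharp omega-shaped
  turn.  Initiation is stochastic with rate

      f_p(d_t) = 0.023 / (0.4 + exp(140 * d_t)) + 0.0033   [events/s]

  which decreases when the worm climbs the gradient (``d_t`` in mM/s) - the
  biased-random-walk mechanism.  Each simulation step initiates with
  probability ``f_p * dt`` so the realised event rate matches the events/s
  unit.  The reversal lasts ``T_b = 6.0 s`` (the travelling body wave flips
  direction via the phase map ``phi -> pi + 2*omega*T_p0 - phi``, which is
  posture-continuous), then a sharp turn of total duration 3.18 s ramps a
  tailward-graded phase delay up, holds, and ramps it back down while a
  ventral curvature bias follows the same envelope, transiently reshaping
  the body S -> Omega -> S and reorienting it by more than 1.75 rad.
* **Random walk**: in the absence of a gradient the path still curves; every
  ``Delta_T = 12 s`` a new curvature target is drawn from ``N(0, C_r)``
  (``C_r`` is the standard deviation) and the applied curvature moves
  linearly from the previous target to the new one over the interval.

During reversal and turn the weathervane and random-walk biases are
suspended (the bias applied to the gait is 0).  Mode transitions are strictly
forward -> reversal -> omega_turn -> forward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .body import forward_phases
from .environment import MM_PER_CM_TO_MM_PER_MM

__all__ = [
    "BehaviorParams",
    "BehaviorState",
    "FORWARD",
    "REVERSAL",
    "OMEGA_TURN",
    "MODE_NAMES",
    "weathervane_bias",
    "pirouette_rate",
    "maybe_initiate_pirouette",
    "reversal_phase",
    "omega_turn_phase",
    "random_walk_update",
    "behavior_step",
]

FORWARD, REVERSAL, OMEGA_TURN = 0, 1, 2
MODE_NAMES = {FORWARD: "forward", REVERSAL: "reversal", OMEGA_TURN: "omega_turn"}

#: Fixed constants of the pirouette-rate law (events/s).
PIROUETTE_RATE_CONSTANTS = (0.023, 0.4, 140.0, 0.0033)


@dataclass
class BehaviorParams:
    """Gains, durations and rate constants of the strategy layer.

    ``C_w`` is calibrated so that, at the lateral-gradient scale of the
    default environment, the curving bias reaches the few-hundredths-of-a-
    radian range that produces turn radii of a few millimetres; ``C_p`` is
    calibrated so the sharp turn reorients by more than 1.75 rad.
    """

    C_w: float = -450.0  # weathervane gain, rad per (mM/mm); sign absorbs the
    # dorsoventral orientation of the body model relative to the right-handed
    # lateral convention of the gradient oracle (negative = attraction).
    C_r: float = 0.008  # random-walk curvature std, rad (no-gradient curving scale)
    C_p: float = 7.2  # maximum phase delay of the sharp turn, rad
    kappa_turn: float = 1.2  # ventral curvature bias during the sharp turn, rad/joint
    T_b: float = 6.0  # reversal duration, s
    T_p1: float = 1.06  # turn ramp-up duration, s
    T_p2: float = 1.06  # turn hold duration, s
    T_p3: float = 1.06  # turn ramp-down duration, s
    Delta_T: float = 12.0  # random-walk renewal interval, s
    sharp_turn_threshold: float = 1.75  # rad, definition of a sharp turn
    rate_constants: tuple = PIROUETTE_RATE_CONSTANTS

    def __post_init__(self) -> None:
        for name in ("T_b", "T_p1", "T_p2", "T_p3", "Delta_T"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def turn_duration(self) -> float:
        return self.T_p1 + self.T_p2 + self.T_p3


@dataclass
class BehaviorState:
    """Finite-state machine state plus curvature accumulators."""

    mode: int = FORWARD
    phases: np.ndarray | None = None  # current per-joint phase offsets phi_i
    phase_snapshot: np.ndarray | None = None  # phases at sharp-turn onset
    T_p0: float = np.nan  # pirouette initiation time
    T_omega0: float = np.nan
    T_omega1: float = np.nan
    T_omega2: float = np.nan
    T_omegaE: float = np.nan
    kappa_R: float = 0.0  # current random-walk curvature
    kappa_T_prev: float = 0.0  # previous random-walk target
    kappa_T: float = 0.0  # current random-walk target
    segment_start: float = 0.0  # start time of the current renewal interval


def weathervane_bias(params: BehaviorParams, d_s: float) -> float:
    """Curvature bias ``-C_w * d_s`` (rad); ``d_s`` is the lateral gradient in mM/mm."""
    return -params.C_w * d_s


def pirouette_rate(d_t: float, constants: tuple = PIROUETTE_RATE_CONSTANTS) -> float:
    """Pirouette initiation rate (events/s) as a function of the parallel gradient.

    Strictly decreasing in ``d_t``; saturates at ``a/b + c`` for strongly
    negative gradients and at ``c`` for strongly positive ones.  The
    exponential argument is clipped so extreme inputs saturate instead of
    overflowing.
    """
    a, b, gain, c = constants
    arg = min(gain * d_t, 700.0)
    return a / (b + np.exp(arg)) + c


def maybe_initiate_pirouette(f_p: float, dt: float, rng: np.random.Generator) -> bool:
    """Bernoulli initiation test with per-step probability ``f_p * dt``."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    return rng.random() < f_p * dt


def reversal_phase(omega: float, T_p0: float, phi_at_Tp0: np.ndarray) -> np.ndarray:
    """Phase map that reverses the travelling body wave, continuous at ``T_p0``.

    ``phi_i -> pi + 2*omega*T_p0 - phi_i(T_p0)``.  Applying it twice (with a
    later time) restores forward propagation.
    """
    return np.pi + 2.0 * omega * T_p0 - np.asarray(phi_at_Tp0, dtype=float)


def omega_turn_phase(
    params: BehaviorParams, state: BehaviorState, t: float, dt: float, phi_prev: np.ndarray
) -> np.ndarray:
    """Piecewise-linear phase manipulation of the sharp turn.

    Each joint's phase is ramped up at ``C_p / T_p1`` per unit time scaled by
    its position along the body (zero at the head joint, reaching the
    maximum delay ``C_p`` at the tail joint) on ``(T_omega0, T_omega1)``,
    held on ``(T_omega1, T_omega2)``, and ramped down at the same rate on
    ``(T_omega2, T_omegaE)``; the ramps cancel, so the phases rejoin their
    pre-turn trajectory when the turn ends.  The graded delay transiently
    shortens the body wavelength, coiling the posture S -> Omega -> S and
    reorienting the travelling direction (a uniform phase shift would only
    re-parametrise the same shape sequence and produce no turn).
    """
    if not (state.T_omega0 <= t < state.T_omegaE):
        raise ValueError("omega_turn_phase called outside the turn window")
    phi = np.asarray(phi_prev, dtype=float)
    n_j = len(phi)
    weights = np.arange(n_j) / max(n_j - 1, 1)  # 0 at head joint, 1 at tail joint
    rate = params.C_p / params.T_p1 * weights
    if t < state.T_omega1:
        return phi + rate * dt
    if t < state.T_omega2:
        return phi.copy()
    return phi - rate * dt


def turn_envelope(params: BehaviorParams, state: BehaviorState, t: float) -> float:
    """Trapezoidal 0 -> 1 -> 0 profile of the ventral bend over the sharp turn.

    The phase manipulation alone is a reciprocal shape sequence, which in an
    overdamped resistive medium produces no net reorientation; the actual
    turning comes from the deep ventral curvature bias
    ``kappa_turn * envelope`` applied while the body passes through the
    Omega posture.  The envelope ramps with the same segment durations as
    the phase delay, so the bias vanishes exactly at both ends of the turn.
    """
    if not (state.T_omega0 <= t < state.T_omegaE):
        return 0.0
    if t < state.T_omega1:
        return (t - state.T_omega0) / params.T_p1
    if t < state.T_omega2:
        return 1.0
    return (state.T_omegaE - t) / params.T_p3


def random_walk_update(params: BehaviorParams, state: BehaviorState, t: float, dt: float, rng: np.random.Generator) -> float:
    """Advance the random-walk curvature process; returns the current ``kappa_R``.

    A new target ``kappa_T ~ N(0, C_r)`` is drawn every ``Delta_T`` seconds;
    between renewals ``kappa_R`` interpolates linearly from the previous
    target to the current one (it equals the previous target exactly at each
    renewal boundary).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    while t - state.segment_start >= params.Delta_T:
        state.segment_start += params.Delta_T
        state.kappa_T_prev = state.kappa_T
        state.kappa_T = rng.normal(0.0, params.C_r) if params.C_r > 0 else 0.0
    frac = (t - state.segment_start) / params.Delta_T
    state.kappa_R = state.kappa_T_prev + (state.kappa_T - state.kappa_T_prev) * frac
    return state.kappa_R


def behavior_step(
    params: BehaviorParams,
    state: BehaviorState,
    y_p: float,
    y_w: float,
    t: float,
    dt: float,
    omega: float,
    rng: np.random.Generator,
    n_modules: int | None = None,
    psi: float = 0.125,
) -> tuple:
    """One step of the strategy layer.

    ``y_p`` (mM/s) gates pirouette initiation; ``y_w`` (mM/cm) sets the
    weathervane bias after conversion to mM/mm.  Returns
    ``(mode, phases, kappa, kappa_w, kappa_R)`` where ``phases`` are the
    per-joint phase offsets for the gait and ``kappa`` the curvature bias to
    apply this step (0 outside forward mode).
    """
    if state.phases is None:
        if n_modules is None:
            raise ValueError("n_modules required to initialise phases")
        state.phases = forward_phases(n_modules, psi)

    kappa_w = 0.0
    kappa_r_applied = 0.0

    if state.mode == REVERSAL and t >= state.T_p0 + params.T_b - 1e-9:
        # Reversal finished: flip the wave forward again and start the turn.
        state.phases = reversal_phase(omega, t, state.phases)
        state.phase_snapshot = state.phases.copy()
        state.mode = OMEGA_TURN
        state.T_omega0 = t
        state.T_omega1 = t + params.T_p1
        state.T_omega2 = t + params.T_p1 + params.T_p2
        state.T_omegaE = t + params.turn_duration
    elif state.mode == OMEGA_TURN and t >= state.T_omegaE - 1e-9:
        # The up/down ramps cancel; restore the snapshot so the cancellation
        # is exact regardless of floating-point boundary rounding.
        state.phases = state.phase_snapshot.copy()
        state.mode = FORWARD

    if state.mode == FORWARD:
        if maybe_initiate_pirouette(pirouette_rate(y_p, params.rate_constants), dt, rng):
            state.mode = REVERSAL
            state.T_p0 = t
            state.phases = reversal_phase(omega, t, state.phases)
        else:
            kappa_r_applied = random_walk_update(params, state, t, dt, rng)
            kappa_w = weathervane_bias(params, y_w * MM_PER_CM_TO_MM_PER_MM)
    kappa = kappa_w + kappa_r_applied
    if state.mode == OMEGA_TURN:
        state.phases = omega_turn_phase(params, state, t, dt, state.phases)
        kappa = params.kappa_turn * turn_envelope(params, state, t)
    return state.mode, state.phases, kappa, kappa_w, kappa_r_applied
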