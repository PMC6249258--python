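"""Multibody worm: prescribed sinusoidal gait and planar motion under anisotropic friction.

The body is a chain of ``L`` rigid modules.  Module ``i`` has a heading
angle ``theta_i``; adjacent centroids are exactly ``module_length`` apart
along the mean heading of the pair, so link lengths are conserved by
construction.  The posture is prescribed kinematically by the gait

    q_i(t) = q_max * sin(omega * t - phi_i(t)) + kappa(t)

with joint angles ``q_i = theta_i - theta_{i+1}`` (``q_0`` is the
head-bending angle) and forward-motion phases ``phi_i = -2*pi*psi*(i-1)``
(``psi`` sets the body wavelength).  The curvature bias ``kappa`` is shared
by all joints and is how the behaviour layer steers the worm.

Only the global rigid translation and rotation are dynamic.  In the default
overdamped mode - appropriate for crawling at ~0.12 mm/s, where inertia is
negligible - each step solves the linearised force/torque balance

    sum_j F_j = 0,   sum_j (x_j - x_g) x F_j = 0

where the friction on module ``j`` is viscous and anisotropic,
``F_j = -C_t (v.t)t - C_n (v.n)n`` with drag along the module axis ``C_t``
smaller than the normal drag ``C_n``.  Drag anisotropy is what turns the
undulation into propulsion (resistive-force mechanism).  An inertial mode
integrates the global Newton equations with module masses instead.

Gravity acts normal to the agar plane and therefore does not appear in the
planar equations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "BodyParams",
    "GaitParams",
    "BodyState",
    "forward_phases",
    "target_joint_angles",
    "shape_from_angles",
    "initial_state",
    "friction_forces",
    "step_dynamics",
    "nose_position",
    "body_centre",
]


@dataclass
class BodyParams:
    """Geometry, mass and friction of the multibody worm.

    Defaults give a 1 mm worm (12 modules); the friction anisotropy and gait
    amplitude are calibrated so the crawl speed matches the 0.12 mm/s
    measured on chemotaxis plates.
    """

    n_modules: int = 12
    module_length: float = 0.1 / 12  # cm; body length 1 mm
    module_mass: float = 1.0  # mass units (only ratios matter when overdamped)
    friction_tangential: float = 1.0  # drag per unit velocity, along the module axis
    friction_normal: float = 5.0  # drag per unit velocity, normal to the axis
    mode: Literal["overdamped", "inertial"] = "overdamped"

    def __post_init__(self) -> None:
        if self.n_modules < 2:
            raise ValueError("need at least two modules")
        if self.module_length <= 0 or self.module_mass <= 0:
            raise ValueError("module length and mass must be > 0")
        if self.friction_tangential < 0 or self.friction_normal < 0:
            raise ValueError("friction coefficients must be >= 0")
        if self.friction_normal < self.friction_tangential:
            raise ValueError("undulatory propulsion requires friction_normal >= friction_tangential")


@dataclass
class GaitParams:
    """Sinusoidal gait: amplitude, frequency, wavelength and curvature bias."""

    q_max: float = 0.5  # rad, maximum joint bend
    omega: float = np.pi  # rad/s (2 s undulation period; 3 cycles per 6 s reversal)
    psi: float = 0.125  # wavelength parameter: phase advance per joint / 2 pi
    kappa: float = 0.0  # current total curvature bias, rad
    phase_offsets: np.ndarray | None = None  # per-joint override; default from psi

    def __post_init__(self) -> None:
        if self.q_max <= 0 or self.omega <= 0:
            raise ValueError("q_max and omega must be > 0")
        if self.phase_offsets is not None:
            self.phase_offsets = np.asarray(self.phase_offsets, dtype=float)


@dataclass
class BodyState:
    """Full kinematic state: headings at centroids plus global pose."""

    positions: np.ndarray  # (L, 2) module centroids, cm
    headings: np.ndarray  # (L,) module heading angles, rad
    joint_angles: np.ndarray  # (L-1,) relative angles, q_0 = head bend
    velocities: np.ndarray  # (L, 2) centroid velocities, cm/s
    theta: float  # global body reference angle (= heading of module 0)
    t: float = 0.0

    def copy(self) -> "BodyState":
        return BodyState(
            self.positions.copy(), self.headings.copy(), self.joint_angles.copy(),
            self.velocities.copy(), self.theta, self.t,
        )


def forward_phases(n_modules: int, psi: float) -> np.ndarray:
    """Forward-motion phase offsets, ``2 pi psi`` of delay per joint toward the tail.

    The phase delay grows tailward so the bending wave travels head-to-tail,
    which under anisotropic drag propels the body nose-first (the sign of
    the per-joint offset is tied to this module-indexing convention).
    """
    return 2.0 * np.pi * psi * np.arange(n_modules - 1)


def target_joint_angles(gait: GaitParams, t: float, n_modules: int | None = None) -> np.ndarray:
    """Prescribed joint angles at time ``t`` (rad)."""
    phi = gait.phase_offsets
    if phi is None:
        if n_modules is None:
            raise ValueError("n_modules required when phase_offsets unset")
        phi = forward_phases(n_modules, gait.psi)
    return gait.q_max * np.sin(gait.omega * t - phi) + gait.kappa


def shape_from_angles(joint_angles: np.ndarray, module_length: float, theta0: float, head_position) -> tuple:
    """Build centroid positions and headings from joint angles and the head pose.

    ``theta_{i+1} = theta_i + q_i`` (the sign fixes which side of the body a
    positive bend is; it is chosen so a positive head bend swings the nose
    toward the side the lateral-gradient oracle calls positive); centroid
    ``i+1`` lies ``module_length`` behind centroid ``i`` along the mean
    heading of the pair.  Returns ``(positions (L,2), headings (L,))``.
    """
    q = np.asarray(joint_angles, dtype=float)
    headings = theta0 + np.concatenate(([0.0], np.cumsum(q)))
    mid = 0.5 * (headings[:-1] + headings[1:])
    steps = -module_length * np.stack([np.cos(mid), np.sin(mid)], axis=1)
    positions = np.concatenate(
        [np.zeros((1, 2)), np.cumsum(steps, axis=0)], axis=0
    ) + np.asarray(head_position, dtype=float)
    return positions, headings


def initial_state(params: BodyParams, gait: GaitParams, theta0: float = 0.0, centre=(0.0, 0.0), t: float = 0.0) -> BodyState:
    """Body at rest in the posture prescribed for time ``t``, centred at ``centre``."""
    q = target_joint_angles(gait, t, params.n_modules)
    positions, headings = shape_from_angles(q, params.module_length, theta0, (0.0, 0.0))
    positions += np.asarray(centre, dtype=float) - positions.mean(axis=0)
    return BodyState(
        positions=positions,
        headings=headings,
        joint_angles=q,
        velocities=np.zeros_like(positions),
        theta=theta0,
        t=t,
    )


def _friction_matrices(headings: np.ndarray, c_t: float, c_n: float) -> np.ndarray:
    """Per-module 2x2 anisotropic drag matrices ``C_t t t^T + C_n n n^T``."""
    c, s = np.cos(headings), np.sin(headings)
    m = np.empty((len(headings), 2, 2))
    m[:, 0, 0] = c_t * c * c + c_n * s * s
    m[:, 1, 1] = c_t * s * s + c_n * c * c
    m[:, 0, 1] = m[:, 1, 0] = (c_t - c_n) * c * s
    return m


def friction_forces(params: BodyParams, state: BodyState) -> np.ndarray:
    """Resistive anisotropic viscous force on each module, ``(L, 2)``."""
    m = _friction_matrices(state.headings, params.friction_tangential, params.friction_normal)
    return -np.einsum("lij,lj->li", m, state.velocities)


def body_centre(state: BodyState, params: BodyParams | None = None) -> np.ndarray:
    """Mass-weighted mean of module centroids (equal masses: arithmetic mean)."""
    return state.positions.mean(axis=0)


def nose_position(state: BodyState, params: BodyParams) -> np.ndarray:
    """Distal tip of the head module: centroid + half a module along the head heading."""
    half = 0.5 * params.module_length
    return state.positions[0] + half * np.array([np.cos(state.headings[0]), np.sin(state.headings[0])])


def step_dynamics(params: BodyParams, state: BodyState, target_q: np.ndarray, dt: float) -> BodyState:
    """Advance one step: prescribe the new posture, solve the global rigid motion.

    Overdamped mode solves the 3x3 linearised force/torque balance for the
    rigid translation and rotation; inertial mode integrates the global
    Newton equations semi-implicitly.  Link lengths are preserved exactly
    because the shape is rebuilt from the joint angles each step.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    target_q = np.asarray(target_q, dtype=float)
    if target_q.shape != (params.n_modules - 1,):
        raise ValueError("target_q must have length n_modules - 1")
    if params.friction_tangential == 0.0 and params.friction_normal == 0.0:
        raise ValueError("all friction coefficients zero: force balance is singular")

    x_c = state.positions.mean(axis=0)
    # Candidate placement: new shape with the previous global pose.
    cand_pos, cand_head = shape_from_angles(target_q, params.module_length, state.theta, (0.0, 0.0))
    cand_pos += x_c - cand_pos.mean(axis=0)

    m = _friction_matrices(cand_head, params.friction_tangential, params.friction_normal)
    r = cand_pos - x_c
    jr = np.stack([-r[:, 1], r[:, 0]], axis=1)  # 90 deg rotation of lever arms
    w = (cand_pos - state.positions) / dt  # shape-change velocity at zero rigid motion

    if params.mode == "overdamped":
        a_blk = m.sum(axis=0)
        b_blk = np.einsum("lij,lj->i", m, jr)
        e_blk = np.einsum("li,lij,lj->", jr, m, jr)
        rhs = -np.concatenate([np.einsum("lij,lj->i", m, w), [np.einsum("li,lij,lj->", jr, m, w)]])
        k = np.empty((3, 3))
        k[:2, :2] = a_blk
        k[:2, 2] = b_blk
        k[2, :2] = b_blk
        k[2, 2] = e_blk
        try:
            sol = np.linalg.solve(k, rhs)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
            raise ValueError("singular force-balance system") from exc
        v_lin, omega_rot = sol[:2], sol[2]
    else:  # inertial: rigid-DOF Newton with the current velocities
        mass = params.module_mass
        total_mass = mass * params.n_modules
        inertia = mass * (r ** 2).sum() + 1e-30
        v_body = state.velocities.mean(axis=0)
        rel = state.velocities - v_body
        omega_body = float(np.einsum("li,li->", jr, rel) / ((jr ** 2).sum() + 1e-30))
        vel = w + v_body + omega_body * jr
        forces = -np.einsum("lij,lj->li", m, vel)
        acc = forces.sum(axis=0) / total_mass
        ang_acc = float(np.einsum("li,li->", jr, forces)) / inertia
        v_lin = v_body + acc * dt
        omega_rot = omega_body + ang_acc * dt

    phi = omega_rot * dt
    c, s = np.cos(phi), np.sin(phi)
    rot = np.array([[c, -s], [s, c]])
    new_pos = x_c + r @ rot.T + v_lin * dt
    new_head = cand_head + phi
    return BodyState(
        positions=new_pos,
        headings=new_head,
        joint_angles=target_q.copy(),
        velocities=(new_pos - state.positions) / dt,
        theta=state.theta + phi,
        t=state.t + dt,
    )
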