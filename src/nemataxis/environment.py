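"""NaCl environment: diffusing point-source field and geometric gradient oracles.

The arena is a thin agar plate seeded with ``K`` NaCl point sources. After a
pre-run diffusion period the worm is released and the field keeps diffusing
while the simulation runs.  Concentration at position ``x`` (cm) and diffusion
time ``t`` (s) is

    c(x, t) = N0 * sum_k exp(-|x - x_k| / (r1 * D * t)) / (r2 * E * D * t)

with source concentration ``N0`` (mM), diffusion coefficient ``D`` (cm^2/s),
agar thickness ``E`` (cm) and dimensionless shape constants ``r1``, ``r2``.
The exponent uses the plain distance ``|x - x_k|``; an optional
``squared_distance`` switch provides the conventional Gaussian kernel instead
(the literal form is the default).

The module also provides the geometric "true gradient" oracles used to grade
the internal representations: the total time derivative of concentration
along the body-centre path (gradient parallel to the travelling direction)
and a central difference across two points displaced laterally from the path
(gradient perpendicular to the travelling direction).  Analytic fixture
fields (uniform, linear, Gaussian) allow the oracles themselves to be tested
against closed forms.

Units: positions cm, time s, concentration mM.  The perpendicular gradient is
reported in mM/cm; behaviour-level formulas that expect mM/mm apply the
explicit ``MM_PER_CM_TO_MM_PER_MM`` conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "EnvironmentParams",
    "TrueGradientParams",
    "DiffusionField",
    "UniformField",
    "LinearField",
    "GaussianField",
    "concentration",
    "fixture_field",
    "sensed_derivative",
    "true_parallel_gradient",
    "true_perpendicular_gradient",
    "parallel_gradient_series",
    "perpendicular_gradient_series",
    "lateral_offsets",
    "MM_PER_CM_TO_MM_PER_MM",
]

#: 1 mM/cm expressed in mM/mm (for the weathervane law, which takes mM/mm).
MM_PER_CM_TO_MM_PER_MM = 0.1

#: Rotation by -90 deg; maps the unit travelling direction onto the "ventral"
#: lateral offset direction.
ROTATION_TO_LATERAL = np.array([[0.0, 1.0], [-1.0, 0.0]])

_DEFAULT_PEAKS = ((1.1, 0.0), (0.0, 1.1), (-1.1, 0.0), (0.0, -1.1))


@dataclass
class EnvironmentParams:
    """Parameters of the diffusing NaCl field.

    Defaults place four sources symmetrically 1.6 cm from the plate centre.
    ``N0`` is calibrated so that, after the 3600 s pre-run, the concentration
    signal sensed by a worm crawling at ~0.12 mm/s has the same scale as the
    gradient statistics this simulator is validated against (peak
    concentrations of order 1e-3 mM).  All values are config-exposed; the
    verification statistics are correlation-based and therefore scale-free.
    """

    peaks: Sequence = _DEFAULT_PEAKS
    N0: float = 6.0e-3  # source concentration, mM
    D: float = 1.5e-5  # diffusion coefficient, cm^2/s
    E: float = 0.2  # agar thickness, cm
    r1: float = 18.0  # dimensionless kernel-width constant (decay length
    # r1*D*t ~ 1.0-1.3 cm over the run: localised peaks whose attraction
    # basins reach the release point at the plate centre)
    r2: float = 750.0  # dimensionless amplitude constant
    t_offset: float = 3600.0  # pre-run diffusion time, s
    squared_distance: bool = False

    def __post_init__(self) -> None:
        self.peaks = np.atleast_2d(np.asarray(self.peaks, dtype=float))
        if self.peaks.size == 0:
            self.peaks = np.zeros((0, 2))
        if self.peaks.shape[-1] != 2:
            raise ValueError("peaks must be 2-D coordinates")
        for name in ("N0", "D", "E", "r1", "r2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.t_offset < 0:
            raise ValueError("t_offset must be >= 0")

    @property
    def K(self) -> int:
        return len(self.peaks)


@dataclass
class TrueGradientParams:
    """Numerical parameters of the geometric oracles.

    delta: lateral displacement (cm) of the central difference; the lateral
    oracle converges to the analytic directional derivative as O(delta^2).
    dt: path sampling interval (s).
    """

    delta: float = 0.01
    dt: float = 0.01

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")


def concentration(params: EnvironmentParams, position, time) -> np.ndarray | float:
    """Concentration (mM) of the diffusing field at ``position`` and diffusion time ``time``.

    ``time`` is the total diffusion time (pre-run included) and must be > 0.
    ``position`` may be a single 2-vector or an ``(..., 2)`` array; ``time``
    may broadcast against the leading dimensions of ``position``.
    """
    time = np.asarray(time, dtype=float)
    if np.any(time <= 0):
        raise ValueError("diffusion time must be > 0 (division by zero in the kernel)")
    pos = np.asarray(position, dtype=float)
    scalar = pos.ndim == 1 and time.ndim == 0
    d = np.linalg.norm(pos[..., None, :] - params.peaks, axis=-1)  # (..., K)
    width = params.r1 * params.D * time  # (...,) or scalar
    arg = (d ** 2 if params.squared_distance else d) / width[..., None]
    amp = params.N0 / (params.r2 * params.E * params.D * time)
    out = amp * np.exp(-arg).sum(axis=-1)  # empty sum -> 0 when K == 0
    return float(out) if scalar else out


class DiffusionField:
    """Callable concentration field ``c(x, t_sim)`` with the pre-run offset applied.

    ``t_sim`` is simulation time; the kernel is evaluated at
    ``t_offset + t_sim``.  Non-negative everywhere by construction.
    """

    is_fixture = False

    def __init__(self, params: EnvironmentParams):
        self.params = params

    def __call__(self, position, t_sim):
        return concentration(self.params, position, np.asarray(t_sim, dtype=float) + self.params.t_offset)


class UniformField:
    """Constant fixture field (tests only)."""

    is_fixture = True

    def __init__(self, value: float = 1.0):
        self.value = value

    def __call__(self, position, t_sim):
        pos = np.asarray(position, dtype=float)
        out = np.full(pos.shape[:-1], self.value)
        return float(out) if out.ndim == 0 else out


class LinearField:
    """Static linear fixture field ``c = offset + g . x`` (may go negative)."""

    is_fixture = True

    def __init__(self, gradient, offset: float = 0.0):
        self.gradient = np.asarray(gradient, dtype=float)
        self.offset = offset

    def __call__(self, position, t_sim):
        pos = np.asarray(position, dtype=float)
        out = self.offset + pos @ self.gradient
        return float(out) if np.ndim(out) == 0 else out


class GaussianField:
    """Static isotropic Gaussian fixture field centred at ``centre``."""

    is_fixture = True

    def __init__(self, amplitude: float = 1.0, centre=(0.0, 0.0), sigma: float = 1.0):
        self.amplitude = amplitude
        self.centre = np.asarray(centre, dtype=float)
        self.sigma = sigma

    def __call__(self, position, t_sim):
        pos = np.asarray(position, dtype=float)
        d2 = ((pos - self.centre) ** 2).sum(axis=-1)
        out = self.amplitude * np.exp(-d2 / (2.0 * self.sigma ** 2))
        return float(out) if np.ndim(out) == 0 else out


def fixture_field(name: str, **params):
    """Analytic test field by name: ``uniform``, ``linear`` or ``gaussian``.

    Fixture fields may violate the non-negativity of the diffusion kernel;
    they exist for testing the oracles against closed forms.
    """
    registry = {"uniform": UniformField, "linear": LinearField, "gaussian": GaussianField}
    try:
        cls = registry[name]
    except KeyError:
        raise ValueError(f"unknown fixture field {name!r}; choose from {sorted(registry)}") from None
    return cls(**params)


def sensed_derivative(c_prev: float, c_curr: float, dt: float) -> float:
    """Backward difference of the nose-tip concentration, in mM/s."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    return (c_curr - c_prev) / dt


def true_parallel_gradient(field: Callable, centre_prev, centre_curr, t_prev: float, t_curr: float) -> float:
    """Total time derivative of concentration along the body-centre path (mM/s).

    Includes the field's own temporal decay; this is the quantity the
    parallel internal representation is graded against.
    """
    if not t_curr > t_prev:
        raise ValueError("t_curr must exceed t_prev")
    return (field(centre_curr, t_curr) - field(centre_prev, t_prev)) / (t_curr - t_prev)


def _lateral_unit(direction: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(direction)
    if norm <= 0:
        raise ValueError("travelling direction undefined (zero displacement)")
    return ROTATION_TO_LATERAL @ (direction / norm)


def true_perpendicular_gradient(
    field: Callable, centre_prev, centre_curr, t_curr: float, params: TrueGradientParams
) -> float:
    """Central-difference lateral gradient across the travelling direction (mM/cm).

    The two sample points sit ``delta`` cm to either side of the body centre,
    perpendicular to the displacement ``centre_curr - centre_prev``.  Raises
    if the displacement is zero; callers tracking a path should hold the last
    well-defined direction instead (see :func:`perpendicular_gradient_series`).
    """
    centre_prev = np.asarray(centre_prev, dtype=float)
    centre_curr = np.asarray(centre_curr, dtype=float)
    lat = _lateral_unit(centre_curr - centre_prev)
    dv = params.delta * lat
    return (field(centre_curr + dv, t_curr) - field(centre_curr - dv, t_curr)) / (2.0 * params.delta)


def lateral_offsets(directions: np.ndarray, delta: float) -> np.ndarray:
    """Ventral-side offset vectors ``delta * R(-90deg) u`` for unit directions ``u``."""
    return delta * directions @ ROTATION_TO_LATERAL.T


def _unit_directions(positions: np.ndarray, initial=(1.0, 0.0)) -> np.ndarray:
    """Unit travelling directions between consecutive positions.

    Degenerate steps (zero displacement, e.g. at a turn apex) reuse the last
    well-defined direction; if none exists yet, ``initial`` is used.
    """
    diffs = np.diff(positions, axis=0)
    norms = np.linalg.norm(diffs, axis=1)
    valid = norms > 1e-300
    units = np.empty_like(diffs)
    units[valid] = diffs[valid] / norms[valid, None]
    if not valid.all():
        idx = np.where(valid, np.arange(len(diffs)), -1)
        idx = np.maximum.accumulate(idx)
        units = np.where(
            (idx >= 0)[:, None],
            units[np.clip(idx, 0, None)],
            np.asarray(initial, dtype=float),
        )
    return units


def parallel_gradient_series(field: Callable, positions, times) -> np.ndarray:
    """Vectorised Eq-style parallel oracle along a sampled path.

    Returns ``len(positions) - 1`` values, one per consecutive pair.
    """
    positions = np.asarray(positions, dtype=float)
    times = np.asarray(times, dtype=float)
    c = field(positions, times)
    return np.diff(c) / np.diff(times)


def perpendicular_gradient_series(
    field: Callable, positions, times, params: TrueGradientParams, initial_direction=(1.0, 0.0)
) -> np.ndarray:
    """Vectorised lateral oracle along a sampled path (mM/cm).

    One value per consecutive pair of positions, evaluated at the later
    sample; degenerate displacements reuse the last well-defined direction.
    """
    positions = np.asarray(positions, dtype=float)
    times = np.asarray(times, dtype=float)
    units = _unit_directions(positions, initial_direction)
    dv = lateral_offsets(units, params.delta)
    cv = field(positions[1:] + dv, times[1:])
    cd = field(positions[1:] - dv, times[1:])
    return (cv - cd) / (2.0 * params.delta)
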