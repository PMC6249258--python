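"""Chemotaxis experiment orchestration.

Runs the closed-loop simulation (environment -> body -> sensing -> internal
gradient representations -> behaviour), computes the evaluation statistics
(chemotaxis index, correlations and RMSEs of the internal representations
against the geometric oracles, error-input dependencies), builds network
training datasets from recorded traces, and aggregates repeated runs.

The per-step procedure mirrors the experimental protocol: the worm starts at
the plate centre; each 0.01 s step evaluates the behaviour layer (pirouette
initiation, weathervane and random-walk biases), prescribes the gait
posture, advances the overdamped body dynamics, samples the NaCl
concentration at the nose tip of the moving body, and feeds its backward
difference into the two-ODE gradient model.  The field keeps diffusing
during the run.  Everything is reproducible from the seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import behavior as bhv
from . import body as bdy
from .environment import (
    DiffusionField,
    EnvironmentParams,
    TrueGradientParams,
    parallel_gradient_series,
    perpendicular_gradient_series,
)
from .gradient_model import GradientModelParams, GradientModelState, run_model
from .network import (
    NetworkParams,
    NetworkTopology,
    SensoryParams,
    TrainingConfig,
    asel_input,
    aser_input,
    default_topology,
    forward_trace,
    init_params,
    normalize_teacher,
    train,
)

__all__ = [
    "SimulationConfig",
    "SimulationTrace",
    "AnalysisParams",
    "ExperimentSummary",
    "run_simulation",
    "chemotaxis_index",
    "evaluate_gradient_model",
    "error_input_dependency",
    "evaluate_trace",
    "build_training_dataset",
    "run_full_experiment",
    "train_networks_on_traces",
]

TRACE_COLUMNS = (
    "t", "xg_x", "xg_y", "nose_x", "nose_y", "q0", "conc", "dcdt",
    "y_p", "y_w", "mode", "kappa_w", "kappa_R",
)


@dataclass
class SimulationConfig:
    """Everything needed to reproduce one chemotaxis run."""

    dt: float = 0.01  # s
    duration: float = 1200.0  # s
    seed: int = 0
    environment: EnvironmentParams = field(default_factory=EnvironmentParams)
    body: bdy.BodyParams = field(default_factory=bdy.BodyParams)
    gait: bdy.GaitParams = field(default_factory=bdy.GaitParams)
    behavior: bhv.BehaviorParams = field(default_factory=bhv.BehaviorParams)
    model: GradientModelParams = field(default_factory=GradientModelParams)
    sensory: SensoryParams = field(default_factory=SensoryParams)
    oracle: TrueGradientParams = field(default_factory=TrueGradientParams)
    start: tuple = (0.0, 0.0)
    initial_heading: float | None = None  # rad; None = drawn from the seed

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")
        n = self.duration / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration must be a multiple of dt")

    def digest(self) -> str:
        payload = repr(sorted(asdict(self).items(), key=lambda kv: kv[0]))
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class SimulationTrace:
    """Per-step records of one run plus provenance (seed, config digest)."""

    df: pd.DataFrame
    seed: int
    config_digest: str
    dt: float
    duration: float

    def to_csv(self, path, thin: int = 1) -> None:
        """Write the trace; full float precision so statistics round-trip exactly.

        ``thin`` keeps every thin-th record (disk economy); evaluation runs
        should use the full-rate trace (``thin=1``, the default).
        """
        if thin < 1:
            raise ValueError("thin must be >= 1")
        self.df.iloc[::thin].to_csv(path, index=False, float_format="%.17g")

    @staticmethod
    def from_csv(path, seed: int = -1, config_digest: str = "", dt: float | None = None) -> "SimulationTrace":
        df = pd.read_csv(path)
        if dt is None:
            dt = float(df["t"].iloc[1] - df["t"].iloc[0]) if len(df) > 1 else 0.01
        duration = float(df["t"].iloc[-1]) if len(df) else 0.0
        return SimulationTrace(df=df, seed=seed, config_digest=config_digest, dt=dt, duration=duration)


@dataclass
class AnalysisParams:
    """Evaluation constants: chemotaxis-index radius and oracle sampling.

    ``oracle_interval`` is the path-sampling interval of the geometric
    oracles.  The body centre wobbles at the undulation period, so
    consecutive-step displacement directions are dominated by gait jitter
    rather than travel; sampling the path once per undulation period
    (2 s with the default gait) and interpolating back onto the trace grid
    defines the travelling direction on the behavioural timescale.
    """

    ci_threshold: float = float(np.sqrt(2.0 / np.pi))  # cm
    delta: float = 0.01  # cm, lateral oracle displacement
    oracle_interval: float = 2.0  # s, path sampling interval of the oracles

    def __post_init__(self) -> None:
        if self.ci_threshold <= 0:
            raise ValueError("ci_threshold must be > 0")
        if self.oracle_interval <= 0:
            raise ValueError("oracle_interval must be > 0")


def run_simulation(config: SimulationConfig) -> SimulationTrace:
    """Execute one seeded chemotaxis run and return the full trace."""
    rng = np.random.default_rng(config.seed)
    theta0 = rng.uniform(0.0, 2.0 * np.pi) if config.initial_heading is None else float(config.initial_heading)
    fld = DiffusionField(config.environment)
    bp, gait, bep, gmp = config.body, config.gait, config.behavior, config.model
    L = bp.n_modules
    dt = config.dt
    n_steps = int(round(config.duration / dt))

    state = bdy.initial_state(bp, gait, theta0, centre=config.start, t=0.0)
    bstate = bhv.BehaviorState(phases=bdy.forward_phases(L, gait.psi))
    gm = GradientModelState()

    rec = np.empty((n_steps + 1, len(TRACE_COLUMNS) - 1))  # all but mode
    modes = np.empty(n_steps + 1, dtype=np.int8)

    nose = bdy.nose_position(state, bp)
    xg = state.positions.mean(axis=0)
    c_prev = fld(nose, 0.0)
    rec[0] = (0.0, xg[0], xg[1], nose[0], nose[1], state.joint_angles[0],
              c_prev, 0.0, 0.0, 0.0, 0.0, 0.0)
    modes[0] = bhv.FORWARD

    q_max, omega = gait.q_max, gait.omega
    for k in range(1, n_steps + 1):
        t_prev = (k - 1) * dt
        t_k = k * dt
        mode, phases, kappa, k_w, k_r = bhv.behavior_step(
            bep, bstate, gm.y_p, gm.y_w, t_prev, dt, omega, rng
        )
        target_q = q_max * np.sin(omega * t_k - phases) + kappa
        state = bdy.step_dynamics(bp, state, target_q, dt)
        nose = bdy.nose_position(state, bp)
        xg = state.positions.mean(axis=0)
        c = fld(nose, t_k)
        dcdt = (c - c_prev) / dt
        c_prev = c
        q0 = target_q[0]
        y_p = gm.y_p + dt * (-gmp.a_p * gm.y_p + gmp.b_p * gmp.scale_p * dcdt + gmp.eps_p)
        sgn = 1.0 if q0 > 0 else -1.0
        y_w = gm.y_w + dt * (-gmp.a_w * gm.y_w + sgn * gmp.b_w * gmp.scale_w * dcdt + gmp.eps_w)
        gm.y_p, gm.y_w = y_p, y_w
        rec[k] = (t_k, xg[0], xg[1], nose[0], nose[1], q0, c, dcdt, y_p, y_w, k_w, k_r)
        modes[k] = mode

    df = pd.DataFrame(rec, columns=[c for c in TRACE_COLUMNS if c != "mode"])
    df["mode"] = pd.Categorical.from_codes(modes, categories=[bhv.MODE_NAMES[i] for i in range(3)])
    df["mode"] = df["mode"].astype(str)
    df = df[list(TRACE_COLUMNS)]
    return SimulationTrace(
        df=df, seed=config.seed, config_digest=config.digest(), dt=dt, duration=config.duration
    )


def chemotaxis_index(trace: SimulationTrace, env: EnvironmentParams, params: AnalysisParams | None = None) -> float:
    """(T_in - T_out) / T_total with T_in the time spent within the threshold
    radius of any NaCl peak."""
    params = params or AnalysisParams()
    df = trace.df
    if len(df) == 0:
        raise ValueError("empty trace")
    pos = df[["xg_x", "xg_y"]].to_numpy()
    if env.K == 0:
        frac_in = 0.0
    else:
        d = np.linalg.norm(pos[:, None, :] - env.peaks[None, :, :], axis=-1).min(axis=1)
        frac_in = float((d <= params.ci_threshold).mean())
    return 2.0 * frac_in - 1.0


def _safe_corr(x: np.ndarray, y: np.ndarray):
    """Pearson r with p-value; (nan, nan) for zero-variance (degenerate) series."""
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _oracle_series(trace: SimulationTrace, env: EnvironmentParams, params: AnalysisParams):
    """True gradients along the recorded body-centre path (aligned to records 1..N).

    The path is sampled every ``oracle_interval`` seconds (at least one
    record) and the oracle values are linearly interpolated back onto the
    full record grid.
    """
    fld = DiffusionField(env)
    df = trace.df
    pos = df[["xg_x", "xg_y"]].to_numpy()
    times = df["t"].to_numpy()
    step = max(1, int(round(params.oracle_interval / trace.dt))) if trace.dt > 0 else 1
    tg = TrueGradientParams(delta=params.delta, dt=max(trace.dt, params.oracle_interval))
    p, t = pos[::step], times[::step]
    if len(t) < 2:
        p, t = pos, times
    y_p_c = parallel_gradient_series(fld, p, t)
    y_w_c = perpendicular_gradient_series(fld, p, t, tg)
    y_p_g = np.interp(times[1:], t[1:], y_p_c)
    y_w_g = np.interp(times[1:], t[1:], y_w_c)
    return y_p_g, y_w_g


def evaluate_gradient_model(trace: SimulationTrace, env: EnvironmentParams, params: AnalysisParams | None = None) -> dict:
    """Correlations and RMSEs of the internal representations vs the oracles.

    Returns r_p, r_w (with p-values) and RMSE_p (mM/s), RMSE_w (mM/cm),
    computed over the whole trace (records after the first, where the
    travelling direction is defined).
    """
    params = params or AnalysisParams()
    if len(trace.df) < 2:
        raise ValueError("trace needs at least 2 records")
    y_p_g, y_w_g = _oracle_series(trace, env, params)
    y_p = trace.df["y_p"].to_numpy()[1:]
    y_w = trace.df["y_w"].to_numpy()[1:]
    r_p, p_p = _safe_corr(y_p, y_p_g)
    r_w, p_w = _safe_corr(y_w, y_w_g)
    return {
        "r_p": r_p, "p_p": p_p, "r_w": r_w, "p_w": p_w,
        "rmse_p": float(np.sqrt(np.mean((y_p - y_p_g) ** 2))),
        "rmse_w": float(np.sqrt(np.mean((y_w - y_w_g) ** 2))),
    }


def error_input_dependency(trace: SimulationTrace, env: EnvironmentParams, params: AnalysisParams | None = None) -> dict:
    """Correlations between the model inputs and the representation errors.

    ``e_p = y_p^G - y_p`` and ``e_w = y_w^G - y_w``; returns the four
    correlations of (q0, dcdt) with (e_p, e_w).  Zero-variance error series
    yield NaN (degenerate, not an error).
    """
    params = params or AnalysisParams()
    y_p_g, y_w_g = _oracle_series(trace, env, params)
    df = trace.df
    e_p = y_p_g - df["y_p"].to_numpy()[1:]
    e_w = y_w_g - df["y_w"].to_numpy()[1:]
    q0 = df["q0"].to_numpy()[1:]
    dcdt = df["dcdt"].to_numpy()[1:]
    return {
        "q0_e_p": _safe_corr(q0, e_p)[0],
        "dcdt_e_p": _safe_corr(dcdt, e_p)[0],
        "q0_e_w": _safe_corr(q0, e_w)[0],
        "dcdt_e_w": _safe_corr(dcdt, e_w)[0],
    }


def evaluate_trace(trace: SimulationTrace, env: EnvironmentParams, params: AnalysisParams | None = None) -> dict:
    """All per-trace statistics: CI, speed, model fidelity and error dependencies."""
    params = params or AnalysisParams()
    out = {"ci": chemotaxis_index(trace, env, params)}
    pos = trace.df[["xg_x", "xg_y"]].to_numpy()
    path_len = float(np.linalg.norm(np.diff(pos, axis=0), axis=1).sum())  # cm
    total_t = float(trace.df["t"].iloc[-1] - trace.df["t"].iloc[0]) or np.nan
    out["speed_mm_s"] = 10.0 * path_len / total_t
    out.update(evaluate_gradient_model(trace, env, params))
    out.update(error_input_dependency(trace, env, params))
    return out


def build_training_dataset(
    trace: SimulationTrace,
    env: EnvironmentParams,
    sensory: SensoryParams,
    topology: NetworkTopology,
    config: TrainingConfig,
    analysis: AnalysisParams | None = None,
) -> dict:
    """Network inputs and normalised true-gradient teachers from a trace.

    Uses the first 600 s (training window 0-300 s, validation 300-600 s),
    downsampled by ``config.downsample``.  Teachers are min-max normalised
    over the full 600 s window.  Returns a mapping with ``inputs`` (T, m),
    ``teachers`` (T, n), ``times`` (T,) plus the raw teacher series.
    """
    analysis = analysis or AnalysisParams()
    span = config.validation_window[1]
    if trace.duration < span:
        raise ValueError(f"trace shorter than {span} s")
    y_p_g, y_w_g = _oracle_series(trace, env, analysis)
    df = trace.df
    times = df["t"].to_numpy()[1:]
    keep = times <= span
    times, y_p_g, y_w_g = times[keep], y_p_g[keep], y_w_g[keep]
    dcdt = df["dcdt"].to_numpy()[1:][keep]
    q0 = df["q0"].to_numpy()[1:][keep]
    y_p_m = df["y_p"].to_numpy()[1:][keep]
    y_w_m = df["y_w"].to_numpy()[1:][keep]
    sl = slice(None, None, config.downsample)
    times, y_p_g, y_w_g = times[sl], y_p_g[sl], y_w_g[sl]
    dcdt, q0, y_p_m, y_w_m = dcdt[sl], q0[sl], y_p_m[sl], y_w_m[sl]
    inputs = np.column_stack([asel_input(sensory, dcdt), aser_input(sensory, dcdt), q0])
    d_par = normalize_teacher(y_p_g)
    d_perp = normalize_teacher(y_w_g)
    teachers = np.zeros((len(times), topology.n))
    for nm in topology.output_assignment.get("parallel", ()):
        teachers[:, topology.neuron_names.index(nm)] = d_par
    for nm in topology.output_assignment.get("perpendicular", ()):
        teachers[:, topology.neuron_names.index(nm)] = d_perp
    return {
        "inputs": inputs,
        "teachers": teachers,
        "times": times,
        "teacher_parallel": d_par,
        "teacher_perpendicular": d_perp,
        "dcdt": dcdt,
        "q0": q0,
        "y_p_model": y_p_m,
        "y_w_model": y_w_m,
    }


@dataclass
class ExperimentSummary:
    """Per-run statistics and their mean +- SD over the run set."""

    per_run: pd.DataFrame
    mean: pd.Series
    sd: pd.Series | None
    n: int

    @staticmethod
    def from_records(records: Sequence[Mapping]) -> "ExperimentSummary":
        df = pd.DataFrame(list(records))
        mean = df.mean(numeric_only=True)
        sd = df.std(numeric_only=True, ddof=1) if len(df) > 1 else None
        return ExperimentSummary(per_run=df, mean=mean, sd=sd, n=len(df))


def run_full_experiment(
    config: SimulationConfig,
    n_runs: int = 10,
    seeds: Sequence[int] | None = None,
    keep_traces: bool = False,
):
    """Repeat the chemotaxis simulation and aggregate all statistics.

    Seeds default to ``seed*1000 + run`` so runs are independent but fully
    reproducible from the base config.  Returns the summary, or
    ``(summary, traces)`` when ``keep_traces``.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if seeds is None:
        seeds = [(config.seed * 1000 + i) % (2 ** 31) for i in range(n_runs)]
    records = []
    traces = []
    for run_idx, seed in enumerate(seeds):
        cfg = SimulationConfig(**{**asdict_shallow(config), "seed": int(seed)})
        try:
            trace = run_simulation(cfg)
            stats_ = evaluate_trace(trace, cfg.environment)
        except Exception as exc:
            raise RuntimeError(f"run {run_idx} (seed {seed}) failed: {exc}") from exc
        stats_["seed"] = seed
        records.append(stats_)
        if keep_traces:
            traces.append(trace)
    summary = ExperimentSummary.from_records(records)
    return (summary, traces) if keep_traces else summary


def asdict_shallow(config: SimulationConfig) -> dict:
    """Shallow field dict of a config (keeps parameter objects intact)."""
    return {name: getattr(config, name) for name in config.__dataclass_fields__}


def train_networks_on_traces(
    traces: Sequence[SimulationTrace],
    env: EnvironmentParams,
    sensory: SensoryParams,
    model: GradientModelParams,
    config: TrainingConfig,
    topology: NetworkTopology | None = None,
) -> dict:
    """Train one network per trace and evaluate all network-level statistics.

    Returns per-trace and mean train/validation correlations for both
    gradient outputs, plus the agreement between the trained network outputs
    and the two-ODE computational model run on the same inputs.
    """
    topology = topology or default_topology()
    datasets = [
        build_training_dataset(tr, env, sensory, topology, config) for tr in traces
    ]
    rng = np.random.default_rng(config.seed)
    T_s = traces[0].dt * config.downsample
    params0 = [
        init_params(
            topology,
            np.random.default_rng(rng.integers(2 ** 31)),
            T_s=T_s,
            weight_scale=config.init_weight_scale,
            gap_init=config.init_gap,
            tau_init=config.init_tau,
        )
        for _ in datasets
    ]
    trained, history = _train_with_backoff(topology, params0, datasets, config)
    times = datasets[0]["times"]
    train_mask = (times >= config.train_window[0]) & (times < config.train_window[1])
    val_mask = (times >= config.validation_window[0]) & (times < config.validation_window[1])
    per_trace = []
    for ds, pr, tr in zip(datasets, trained, traces):
        U = forward_trace(topology, pr, ds["inputs"])
        rec = {}
        for wname, mask in (("train", train_mask), ("validation", val_mask)):
            for key in ("parallel", "perpendicular"):
                rs = []
                for nm in topology.output_assignment[key]:
                    i = topology.neuron_names.index(nm)
                    rs.append(_safe_corr(U[mask][:, i], ds["teachers"][mask][:, i])[0])
                rec[f"r_{key}_{wname}"] = float(np.nanmean(rs))
        # Agreement with the two-ODE computational model run on the same trace.
        y_p, y_w = ds["y_p_model"], ds["y_w_model"]
        agree = []
        for key, ref in (("parallel", y_p), ("perpendicular", y_w)):
            for nm in topology.output_assignment[key]:
                i = topology.neuron_names.index(nm)
                r, _ = _safe_corr(U[:, i], ref)
                agree.append(r)
        rec["r_model_agreement"] = float(np.nanmean(agree))
        per_trace.append(rec)
    df = pd.DataFrame(per_trace)
    return {
        "per_trace": df,
        "mean": df.mean(),
        "sd": df.std(ddof=1) if len(df) > 1 else None,
        "history": history,
        "trained": trained,
        "topology": topology,
    }


def trace_dt(trace: SimulationTrace) -> float:
    return trace.dt


def _train_with_backoff(topology, params0, datasets, config, chunk: int = 600, max_retries: int = 8):
    """Run the full epoch budget in chunks; on divergence, rerun the failed
    chunk from the last checkpoint with the diverged networks' learning
    rates halved.

    Plain gradient descent on this recurrence sits close to its stability
    boundary; the per-network backoff keeps long runs finite without
    changing the update rule and without slowing the networks that were
    stable.  Chunk histories are concatenated (diverged chunks are
    discarded).
    """
    from dataclasses import replace as dc_replace

    from .network import TrainingDiverged

    params_list = list(params0)
    B = len(datasets)
    scale = np.ones(B)
    remaining = config.epochs
    retries = 0
    hist_train, hist_val = [], []
    while remaining > 0:
        epochs = int(min(chunk, remaining))
        chunk_cfg = dc_replace(config, epochs=epochs)
        try:
            params_list, hist = train(topology, params_list, datasets, chunk_cfg, eta_scale=scale)
        except TrainingDiverged as exc:
            retries += 1
            if retries > max_retries:
                break
            bad = exc.bad_members if exc.bad_members is not None else np.ones(B, dtype=bool)
            scale = scale.copy()
            scale[bad] *= 0.5
            continue
        hist_train.append(hist["train"])
        hist_val.append(hist["validation"])
        remaining -= epochs
    if not hist_train:
        raise FloatingPointError("training diverged at every attempted learning rate")
    return params_list, {
        "train": np.concatenate(hist_train, axis=0),
        "validation": np.concatenate(hist_val, axis=0),
    }
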