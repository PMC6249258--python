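"""Shared fixtures: the default-condition experiment, computed once per session."""

import numpy as np
import pytest

from nemataxis.pipeline import SimulationConfig, run_full_experiment


@pytest.fixture(scope="session")
def default_experiment():
    """Ten seeded 1200 s chemotaxis runs with shipped defaults, plus their statistics.

    Uses the package's own repeated-experiment entry point (and therefore its
    seed-derivation convention), exactly as the reproduction script does.
    Shared by every statistical acceptance test so the expensive simulations
    run once.
    """
    cfg = SimulationConfig(seed=1)
    summary, traces = run_full_experiment(cfg, n_runs=10, keep_traces=True)
    stats = summary.per_run.to_dict("records")
    cfgs = [SimulationConfig(seed=int(s["seed"])) for s in stats]
    return {"traces": list(zip(traces, cfgs)), "stats": stats, "summary": summary}


def mean_stat(experiment, key):
    return float(np.mean([s[key] for s in experiment["stats"]]))
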