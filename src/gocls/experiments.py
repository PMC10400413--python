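"""Reproducible experiment runners.

Each runner regenerates its inputs from seeds, executes the relevant module
operations at paper-scale defaults (with scaled-down presets for quick runs),
and returns tidy DataFrames; ``run_experiment`` additionally writes CSV
results plus the fully resolved configuration and a content hash.

The α-sweep compares three learning systems as a function of the normalized
data quantity α = P/N:

* batch (student + notebook): notebook-replayed gradient descent, reported
  both trained to convergence (standard consolidation) and oracle-stopped
  (Go-CLS);
* online (student only): single-pass SGD with a risk-optimal learning-rate
  schedule, evaluated through the deterministic expected-risk recursion;
* nearest-neighbor (notebook only): 1-NN regression on the stored examples.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import child_seed
from .consolidation import (TrainConfig, _run_training, estimate_snr_mle,
                            estimate_snr_learning_speed, oracle_early_stop,
                            validation_early_stop)
from .notebook import Notebook, nearest_neighbor_errors
from .scores import LesionExperiment, amnesia_curve
from .student import (closed_form_generalization_error,
                      expected_online_errors, min_norm_solution,
                      optimal_online_schedule)
from .teachers import (make_linear_teacher, make_partial_obs_teacher,
                       make_sine_teacher, sample_examples, sine_scale_for_snr)

__all__ = [
    "ExperimentConfig",
    "SweepResult",
    "run_alpha_sweep",
    "run_experiment",
    "make_fixtures",
    "EXPERIMENT_IDS",
]

EXPERIMENT_IDS = ("fig2_dynamics", "fig2_regulation", "fig3_amnesia",
                  "fig4_sweep", "fig5_teachers")


@dataclass
class ExperimentConfig:
    """Identifier, parameter overrides, seeds and output directory of a run."""

    experiment: str
    params: dict = field(default_factory=dict)
    seeds: tuple = (0, 1, 2)
    outdir: str | Path | None = None
    scale: str = "full"          # "full" or "small"

    def __post_init__(self):
        if self.experiment not in EXPERIMENT_IDS:
            raise ValueError(f"unknown experiment {self.experiment!r}; "
                             f"choose from {EXPERIMENT_IDS}")
        if self.scale not in ("full", "small"):
            raise ValueError("scale must be 'full' or 'small'")


@dataclass
class SweepResult:
    """Per-(α, seed) generalization errors of the three learning systems."""

    snr: float
    n: int
    alpha_grid: np.ndarray
    table: pd.DataFrame      # columns: alpha, seed, system, gen_error

    def mean_frame(self) -> pd.DataFrame:
        return (self.table.groupby(["alpha", "system"])["gen_error"]
                .mean().unstack("system").reset_index())

    def argmax_alpha(self, system: str = "batch_converged") -> float:
        m = self.mean_frame()
        return float(m.alpha[int(np.argmax(m[system].to_numpy()))])

    def argmax_gap(self) -> float:
        """α with the worst overfitting: largest standard-vs-Go-CLS error gap."""
        m = self.mean_frame()
        gap = m["batch_converged"].to_numpy() - m["batch_gocls"].to_numpy()
        return float(m.alpha[int(np.argmax(gap))])


def run_alpha_sweep(snr: float, alpha_grid=None, n: int = 100, seeds=range(10), *,
                    epochs: int = 3000, learnrate: float = 0.015,
                    p_test: int = 1000) -> SweepResult:
    """Sweep α = P/N and evaluate all three learning systems at each cell.

    Batch-system errors use the closed-form generalization error; the
    converged value is evaluated at the gradient-descent fixed point
    (minimum-norm least squares) and the Go-CLS value is the minimum over the
    training trajectory and its limit.  The online value is the final error
    of the expected-risk recursion under the greedy-optimal schedule.
    """
    alpha_grid = np.asarray([0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 2.0] if alpha_grid is None
                            else alpha_grid, dtype=float)
    rows = []
    for alpha in alpha_grid:
        p = int(round(alpha * n))
        online = expected_online_errors(snr, n, p, optimal_online_schedule(snr, n, p))[-1]
        for seed in seeds:
            teacher = make_linear_teacher(snr, n, seed=child_seed(seed, "sweep-teacher"))
            data = sample_examples(teacher, p, seed=child_seed(seed, "sweep-data"))
            w_inf = min_norm_solution(data.inputs, data.outputs)
            converged = closed_form_generalization_error(w_inf, teacher)
            cfg = TrainConfig(epochs=epochs, learnrate=learnrate, replay="full",
                              gen_error="closed", track_notebook=False,
                              keep_weights=False, seed=child_seed(seed, "sweep-train"))
            trace = _run_training(teacher, data, cfg)
            gocls = min(float(trace.student_gen_error.min()), converged)
            _, nn_gen = nearest_neighbor_errors(data, teacher, p_test=p_test,
                                                seed=child_seed(seed, "sweep-nn"))
            rows += [
                {"alpha": alpha, "seed": seed, "system": "batch_converged", "gen_error": converged},
                {"alpha": alpha, "seed": seed, "system": "batch_gocls", "gen_error": gocls},
                {"alpha": alpha, "seed": seed, "system": "online", "gen_error": float(online)},
                {"alpha": alpha, "seed": seed, "system": "nearest_neighbor", "gen_error": nn_gen},
            ]
    return SweepResult(snr, n, alpha_grid, pd.DataFrame(rows))


# -- individual figure-style experiments ----------------------------------

_SMALL = {
    "fig2_dynamics": {"n": 50, "p": 50, "m": 500, "epochs": 200},
    "fig2_regulation": {"n": 50, "p": 50, "epochs": 200},
    "fig3_amnesia": {"n": 50, "p": 50, "m": 500, "epochs": 200, "prior_epochs": 200},
    "fig4_sweep": {"n": 50, "epochs": 500},
    "fig5_teachers": {"n": 50, "p": 50, "epochs": 200},
}


def _fig2_dynamics(params, seeds):
    p = {"snr": 4.0, "n": 100, "p": 100, "m": 2000, "sparsity": 0.05,
         "epochs": 1000, "learnrate": 0.015, "replay": "resample",
         "gen_error": "mc", "p_test": 1000, **params}
    frames = []
    for seed in seeds:
        teacher = make_linear_teacher(p["snr"], p["n"], seed=child_seed(seed, "teacher"))
        data = sample_examples(teacher, p["p"], seed=child_seed(seed, "data"))
        nb = Notebook(p["m"], p["sparsity"], p["n"], seed=child_seed(seed, "notebook"))
        nb.encode(data)
        cfg = TrainConfig(epochs=p["epochs"], learnrate=p["learnrate"],
                          replay=p["replay"], gen_error=p["gen_error"],
                          p_test=p["p_test"], keep_weights=False,
                          seed=child_seed(seed, "train"))
        frame = _run_training(teacher, data, cfg, notebook=nb).to_frame()
        frame.insert(0, "seed", seed)
        frames.append(frame)
    return {"trace": pd.concat(frames, ignore_index=True)}, p


def _fig2_regulation(params, seeds):
    p = {"snr": 4.0, "n": 100, "p": 100, "epochs": 1000, "learnrate": 0.015,
         "val_fraction": 0.1, **params}
    rows = []
    for seed in seeds:
        teacher = make_linear_teacher(p["snr"], p["n"], seed=child_seed(seed, "teacher"))
        data = sample_examples(teacher, p["p"], seed=child_seed(seed, "data"))
        cfg = TrainConfig(epochs=p["epochs"], learnrate=p["learnrate"], replay="resample",
                          gen_error="closed", track_notebook=False,
                          seed=child_seed(seed, "train"))
        stop_val, _, trace = validation_early_stop(data, p["val_fraction"], cfg)
        stop_opt = oracle_early_stop(trace)
        rows.append({
            "seed": seed,
            "stop_validation": stop_val,
            "stop_oracle": stop_opt,
            "gen_at_validation_stop": trace.student_gen_error[stop_val],
            "gen_at_oracle_stop": trace.student_gen_error[stop_opt],
            "snr_mle": estimate_snr_mle(data),
            "snr_learning_speed": estimate_snr_learning_speed(data),
        })
    return {"regulation": pd.DataFrame(rows)}, p


def _fig3_amnesia(params, seeds):
    p = {"snr_list": (0.01, 0.1, 0.3, 1.0, 8.0), "prior_snr": 50.0,
         "prior_epochs": 2000, "n": 100, "p": 100, "prior_p": 300, "m": 5000,
         "sparsity": 0.05, "learnrate": 0.005, "epochs": 2000,
         "lesion_grid": 20, **params}
    rows = []
    for seed in seeds:
        conditions = [(s, 0, p["p"]) for s in p["snr_list"]]
        conditions.append((p["prior_snr"], p["prior_epochs"], p["prior_p"]))
        for snr, prior, pp in conditions:
            exp = LesionExperiment(
                snr=snr, n=p["n"], p=pp, m=p["m"], sparsity=p["sparsity"],
                learnrate=p["learnrate"], epochs=p["epochs"], prior_epochs=prior,
                lesion_times=np.unique(np.linspace(0, p["epochs"], p["lesion_grid"]).astype(int)),
                seed=seed)
            curve = amnesia_curve(exp)
            f = curve.to_frame()
            f.insert(0, "classification", curve.classification)
            f.insert(0, "prior_epochs", prior)
            f.insert(0, "snr", snr)
            f.insert(0, "seed", seed)
            rows.append(f)
    return {"amnesia": pd.concat(rows, ignore_index=True)}, p


def _fig4_sweep(params, seeds):
    p = {"snr": 1000.0, "n": 100,
         "alpha_grid": (0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 2.0),
         "epochs": 3000, "learnrate": 0.015, **params}
    res = run_alpha_sweep(p["snr"], p["alpha_grid"], p["n"], seeds,
                          epochs=p["epochs"], learnrate=p["learnrate"])
    return {"sweep": res.table, "sweep_mean": res.mean_frame()}, p


def _fig5_teachers(params, seeds):
    p = {"target_snr": 4.0, "n": 100, "p": 100, "epochs": 1000,
         "learnrate": 0.015, "p_test": 1000, **params}
    n, target = p["n"], p["target_snr"]
    n_teacher = int(round(n * (1.0 + 1.0 / target)))
    s = sine_scale_for_snr(target)

    def teachers_for(seed):
        return {
            "linear": make_linear_teacher(target, n, seed=child_seed(seed, "lin"),
                                          fixed_norm=True),
            "sine": make_sine_teacher(s, n, seed=child_seed(seed, "sine")),
            "partial_obs": make_partial_obs_teacher(n, n_teacher,
                                                    seed=child_seed(seed, "pobs")),
        }

    curves = {}
    for name in ("linear", "sine", "partial_obs"):
        acc = np.zeros(p["epochs"] + 1)
        for seed in seeds:
            teacher = teachers_for(seed)[name]
            data = sample_examples(teacher, p["p"], seed=child_seed(seed, "f5-data"))
            cfg = TrainConfig(epochs=p["epochs"], learnrate=p["learnrate"],
                              replay="full", gen_error="mc", p_test=p["p_test"],
                              track_notebook=False, keep_weights=False,
                              seed=child_seed(seed, "f5-train"))
            acc += _run_training(teacher, data, cfg).student_gen_error
        curves[name] = acc / len(list(seeds))
    frame = pd.DataFrame({"epoch": np.arange(p["epochs"] + 1), **curves})
    return {"trajectories": frame}, p


_RUNNERS = {
    "fig2_dynamics": _fig2_dynamics,
    "fig2_regulation": _fig2_regulation,
    "fig3_amnesia": _fig3_amnesia,
    "fig4_sweep": _fig4_sweep,
    "fig5_teachers": _fig5_teachers,
}


def run_experiment(config: ExperimentConfig) -> dict:
    """Dispatch an experiment, optionally writing CSV/JSON artifacts.

    Returns ``{"results": {name: DataFrame}, "params": resolved, "hash": sha1}``.
    Identical (config, seeds) produce byte-identical outputs.
    """
    params = dict(_SMALL[config.experiment]) if config.scale == "small" else {}
    params.update(config.params)
    seeds = tuple(config.seeds)
    results, resolved = _RUNNERS[config.experiment](params, seeds)
    resolved = {"experiment": config.experiment, "seeds": list(seeds),
                "scale": config.scale, **{k: (list(v) if isinstance(v, tuple) else v)
                                          for k, v in resolved.items()}}
    digest = hashlib.sha1(json.dumps(resolved, sort_keys=True).encode()).hexdigest()
    if config.outdir is not None:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(json.dumps({**resolved, "hash": digest}, indent=2))
        for name, frame in results.items():
            frame.to_csv(out / f"{config.experiment}_{name}.csv", index=False,
                         float_format="%.17g")
    return {"results": results, "params": resolved, "hash": digest}


def make_fixtures(seed: int = 0, outdir: str | Path | None = None) -> dict:
    """Small deterministic fixture bundle used by the test suite.

    Contains a printed-value teacher (SNR=4 → σ_w² = 0.8), a tiny example set,
    a tiny encoded notebook verified to store every index as a fixed point,
    and a synthetic U-shaped error trace with its minimum planted at epoch 17.
    """
    teacher = make_linear_teacher(4.0, 10, seed=child_seed(seed, "fx-teacher"))
    data = sample_examples(teacher, 10, seed=child_seed(seed, "fx-data"))
    nb = Notebook(200, 0.05, 10, seed=child_seed(seed, "fx-notebook"))
    nb.encode(data)
    if nb.fixed_point_fraction() < 1.0:
        raise AssertionError("fixture notebook failed the fixed-point check")
    t = np.arange(61)
    u_trace = 0.5 + (t - 17.0) ** 2 / 400.0
    fixtures = {"teacher": teacher, "data": data, "notebook": nb,
                "u_trace": u_trace, "u_argmin": 17}
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "teacher.json").write_text(teacher.to_json())
        np.savetxt(out / "u_trace.csv", u_trace, fmt="%.17g", delimiter=",")
        from .notebook import save_notebook
        from .teachers import save_examples
        save_examples(data, out / "examples")
        save_notebook(nb, out / "notebook")
    return fixtures
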