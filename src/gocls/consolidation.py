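"""Systems-consolidation loop and the policies that regulate it.

Consolidation is modeled as notebook-driven student training: each epoch the
notebook replays a batch of stored experiences (by Hopfield attractor
retrieval, or bypassing the dynamics for deterministic variants) and the
student takes one gradient step on it.  Standard systems consolidation trains
to convergence (full memory transfer); generalization-optimized consolidation
(Go-CLS) halts at the epoch where further training would harm generalization.

Because the true generalization error is not observable, several regulation
policies estimate the stopping point:

* ``oracle_early_stop`` — argmin of the true generalization-error trace
  (the normative reference);
* ``validation_early_stop`` — hold out a fraction of the stored examples and
  stop at the minimum of the validation error;
* ``estimate_snr_mle`` — maximum-likelihood estimate of the teacher's
  predictability from the marginal Gaussian likelihood of the outputs;
* ``estimate_snr_learning_speed`` — map the initial training-error drop onto
  predictability through a simulated calibration curve;
* ``predicted_stop_from_snr`` — convert an SNR estimate into a stopping time
  via a matched simulation.

The statsmodels-style entry point is :class:`SystemsConsolidation` (model)
whose ``fit`` returns a :class:`ConsolidationResults`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._rng import child_rng, child_seed
from .notebook import Notebook
from .student import (StudentState, closed_form_generalization_error,
                      gradient_update, memorization_error)
from .teachers import ExampleSet, TeacherSpec, make_linear_teacher, sample_examples

__all__ = [
    "TrainConfig",
    "TrainTrace",
    "RegulationPolicy",
    "SystemsConsolidation",
    "ConsolidationResults",
    "consolidate",
    "oracle_early_stop",
    "validation_early_stop",
    "estimate_snr_mle",
    "default_snr_grid",
    "measure_learning_speed",
    "learning_speed_calibration",
    "estimate_snr_learning_speed",
    "predicted_stop_from_snr",
]


@dataclass(frozen=True)
class TrainConfig:
    """Knobs of one consolidation run.

    ``replay`` selects how each epoch's batch is produced:
    ``"hopfield"`` — random-initialization attractor retrieval through the
    notebook (the full model); ``"resample"`` — sample stored (x, y) pairs
    directly, bypassing the Hopfield dynamics; ``"full"`` — deterministic
    full-batch replay of every stored pair.
    """

    epochs: int = 1000
    reactivations_per_epoch: int = 100
    learnrate: float = 0.015
    replay: str = "hopfield"
    p_test: int = 1000
    gen_error: str = "mc"            # "mc" or "closed"
    p_test_notebook: int = 200       # sample size for the (constant) notebook errors
    track_notebook: bool = True
    keep_weights: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.reactivations_per_epoch < 1:
            raise ValueError("epochs and reactivations_per_epoch must be >= 1")
        if self.replay not in ("hopfield", "resample", "full"):
            raise ValueError(f"unknown replay mode {self.replay!r}")
        if self.gen_error not in ("mc", "closed"):
            raise ValueError("gen_error must be 'mc' or 'closed'")

    @property
    def deterministic_replay(self) -> bool:
        return self.replay in ("resample", "full")


@dataclass(frozen=True)
class RegulationPolicy:
    """How much consolidation to perform.

    kinds: ``none`` (train to the horizon — standard systems consolidation),
    ``oracle_early_stop``, ``validation_early_stop``, ``snr_mle_stop``,
    ``learning_speed_stop``.
    """

    kind: str = "none"
    val_fraction: float = 0.1
    snr_grid: np.ndarray | None = None
    patience: int | None = None

    def __post_init__(self):
        kinds = ("none", "oracle_early_stop", "validation_early_stop",
                 "snr_mle_stop", "learning_speed_stop")
        if self.kind not in kinds:
            raise ValueError(f"policy kind must be one of {kinds}")
        if not 0 < self.val_fraction < 0.5:
            raise ValueError("val_fraction must be in (0, 0.5)")


@dataclass
class TrainTrace:
    """Per-epoch error trajectories (length epochs+1; epoch 0 = pre-training)."""

    student_mem_error: np.ndarray
    student_gen_error: np.ndarray
    notebook_mem_error: np.ndarray
    notebook_gen_error: np.ndarray
    config: TrainConfig
    teacher: TeacherSpec
    weights: np.ndarray | None = None   # (epochs+1, N) checkpoints

    @property
    def epochs(self) -> int:
        return len(self.student_gen_error) - 1

    def weights_at(self, epoch: int) -> np.ndarray:
        if self.weights is None:
            raise ValueError("weight checkpoints were not kept")
        return self.weights[epoch]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": np.arange(self.epochs + 1),
            "student_mem_error": self.student_mem_error,
            "student_gen_error": self.student_gen_error,
            "notebook_mem_error": self.notebook_mem_error,
            "notebook_gen_error": self.notebook_gen_error,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


class ConsolidationDiverged(RuntimeError):
    pass


def _run_training(teacher: TeacherSpec, data: ExampleSet, config: TrainConfig,
                  student: StudentState | None = None,
                  notebook: Notebook | None = None) -> TrainTrace:
    """Run the consolidation loop for the full horizon and record the trace."""
    n = data.inputs.shape[0]
    student = student if student is not None else StudentState.zeros(n, config.learnrate)
    if student.learnrate != config.learnrate:
        student = StudentState(student.weights, config.learnrate)
    if config.replay == "hopfield" and notebook is None:
        raise ValueError("hopfield replay requires a notebook")

    rng = child_rng(config.seed, "replay")
    epochs = config.epochs

    # generalization-error estimator (test set fixed across epochs)
    if config.gen_error == "closed":
        if teacher.kind != "linear_noisy":
            raise ValueError("closed-form errors need a linear_noisy teacher")
        def gen_err(w):
            return closed_form_generalization_error(w, teacher)
    else:
        test = sample_examples(teacher, config.p_test, seed=child_seed(config.seed, "test-set"))
        def gen_err(w):
            return float(np.mean((test.outputs - w @ test.inputs) ** 2))

    # notebook errors are constant during consolidation (encoding is one-shot)
    nb_mem = nb_gen = math.nan
    if notebook is not None and config.track_notebook and notebook.p > 0:
        nb_mem, nb_gen = notebook.errors(data, teacher, p_test=config.p_test_notebook,
                                         seed=child_seed(config.seed, "nb-errors"))

    mem = np.empty(epochs + 1)
    gen = np.empty(epochs + 1)
    whist = np.empty((epochs + 1, n)) if config.keep_weights else None
    b = config.reactivations_per_epoch

    w = student
    for epoch in range(epochs + 1):
        mem[epoch] = memorization_error(w, data)
        gen[epoch] = gen_err(w.weights)
        if whist is not None:
            whist[epoch] = w.weights
        if mem[epoch] > 1e6 or not np.isfinite(mem[epoch]):
            raise ConsolidationDiverged(
                f"training error {mem[epoch]:.3g} at epoch {epoch} "
                f"(learnrate {config.learnrate} likely too large)")
        if epoch == epochs:
            break
        if config.replay == "full":
            xb, yb = data.inputs, data.outputs
        elif config.replay == "resample":
            idx = rng.integers(0, data.p, size=b)
            xb, yb = data.inputs[:, idx], data.outputs[idx]
        else:
            xb, yb = notebook.sample_reactivations(b, seed=int(rng.integers(2**31)))
        w = gradient_update(w, xb, yb)

    return TrainTrace(mem, gen, np.full(epochs + 1, nb_mem), np.full(epochs + 1, nb_gen),
                      config, teacher, whist)


def oracle_early_stop(trace: TrainTrace | np.ndarray) -> int:
    """Epoch minimizing the student generalization error (first min on ties)."""
    errs = trace.student_gen_error if isinstance(trace, TrainTrace) else np.asarray(trace)
    return int(np.argmin(errs))


def validation_early_stop(data: ExampleSet, val_fraction: float,
                          config: TrainConfig, *, patience: int | None = None,
                          teacher: TeacherSpec | None = None,
                          notebook: Notebook | None = None):
    """Hold-out regulation of consolidation.

    A seeded random ``val_fraction`` of the stored examples is withheld from
    training; the per-epoch validation MSE estimates the generalization error.
    The stop epoch is its global minimum within the horizon, or the first
    minimum that survives ``patience`` epochs without improvement (streaming
    variant).  Returns ``(stop_epoch, val_errors, trace)`` where ``trace`` is
    the training run on the retained examples.
    """
    if not 0 < val_fraction < 0.5:
        raise ValueError("val_fraction must be in (0, 0.5)")
    teacher = teacher or data.teacher
    n_val = int(round(val_fraction * data.p))
    if n_val < 2:
        raise ValueError("validation set must contain at least 2 examples")
    perm = child_rng(config.seed, "val-split").permutation(data.p)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    train = replace(data, inputs=data.inputs[:, tr_idx], outputs=data.outputs[tr_idx],
                    hidden_inputs=None)
    xv, yv = data.inputs[:, val_idx], data.outputs[val_idx]

    cfg = replace(config, keep_weights=True)
    trace = _run_training(teacher, train, cfg, notebook=notebook)
    val = np.mean((yv[None, :] - trace.weights @ xv) ** 2, axis=1)
    if patience is None:
        stop = int(np.argmin(val))
    else:
        best, stop = math.inf, 0
        for t, v in enumerate(val):
            if v < best:
                best, stop = v, t
            elif t - stop >= patience:
                break
    return stop, val, trace


# -- predictability (SNR) estimation --------------------------------------

def default_snr_grid() -> np.ndarray:
    """41 log-spaced SNR values over 2^-8..2^8 plus the endpoints 0 and inf."""
    return np.concatenate([[0.0], 2.0 ** np.linspace(-8, 8, 41), [math.inf]])


def estimate_snr_mle(data: ExampleSet, snr_grid: np.ndarray | None = None) -> float:
    """Maximum-likelihood predictability estimate from teacher-generated data.

    Under the linear-noisy generative model with σ_w² + σ_ε² = 1, the outputs
    given the inputs are zero-mean Gaussian with covariance
    σ_w²·XᵀX + σ_ε²·I.  One eigendecomposition of the Gram matrix is reused
    across the SNR grid; the grid argmax of the log-likelihood is returned.
    """
    if data.p < 2:
        raise ValueError("need at least 2 examples")
    grid = default_snr_grid() if snr_grid is None else np.asarray(snr_grid, dtype=float)
    gram = data.inputs.T @ data.inputs
    d, v = np.linalg.eigh(gram)
    d = np.clip(d, 0.0, None)
    z2 = (v.T @ data.outputs) ** 2
    best, best_ll = grid[0], -math.inf
    for s in grid:
        sw2 = 1.0 if math.isinf(s) else s / (1.0 + s)
        lam = sw2 * d + (1.0 - sw2) + 1e-12
        ll = -0.5 * float(np.sum(np.log(lam) + z2 / lam))
        if ll > best_ll:
            best, best_ll = s, ll
    return float(best)


def measure_learning_speed(data: ExampleSet, *, epochs: int = 5,
                           learnrate: float = 0.02) -> float:
    """Initial learning speed: relative training-error drop over the first
    ``epochs`` full-batch gradient steps at a fixed probe learning rate."""
    x, y = data.inputs, data.outputs
    a = x @ x.T          # precomputed batch matrices: one step is w @ a
    b = y @ x.T
    w = np.zeros(x.shape[0])
    e0 = float(np.mean(y**2))
    for _ in range(epochs):
        w = w + learnrate * (b - w @ a)
    e = float(np.mean((y - w @ x) ** 2))
    return (e0 - e) / e0


_SPEED_CAL_CACHE: dict = {}


def learning_speed_calibration(p: int, n: int, *, snr_grid: np.ndarray | None = None,
                               n_seeds: int = 5, epochs: int = 5,
                               learnrate: float = 0.02, base_seed: int = 12345):
    """Seed-averaged speed at each grid SNR for matched (P, N).

    Returns ``(snr_grid, mean_speeds)``; cached per parameter set.  The curve
    is monotonically increasing in SNR, which is what makes initial learning
    speed a usable predictability feature.
    """
    grid = 2.0 ** np.linspace(-4, 4, 9) if snr_grid is None else np.asarray(snr_grid, float)
    key = (p, n, tuple(grid), n_seeds, epochs, learnrate, base_seed)
    if key not in _SPEED_CAL_CACHE:
        speeds = np.empty((len(grid), n_seeds))
        for i, s in enumerate(grid):
            for j in range(n_seeds):
                t = make_linear_teacher(s, n, seed=child_seed(base_seed, "speed-cal", i, j))
                d = sample_examples(t, p, seed=child_seed(base_seed, "speed-cal-data", i, j))
                speeds[i, j] = measure_learning_speed(d, epochs=epochs, learnrate=learnrate)
        _SPEED_CAL_CACHE[key] = (grid, speeds.mean(axis=1))
    return _SPEED_CAL_CACHE[key]


def estimate_snr_learning_speed(data: ExampleSet, *, snr_grid: np.ndarray | None = None,
                                n_seeds: int = 5, epochs: int = 5,
                                learnrate: float = 0.02, base_seed: int = 12345) -> float:
    """Predictability estimate from initial learning speed.

    The measured speed is mapped through the simulated calibration curve for
    matched (P, N) by monotone interpolation in log-SNR; speeds outside the
    calibrated range are clamped to the grid endpoints with a warning.
    """
    grid, cal = learning_speed_calibration(data.p, data.inputs.shape[0],
                                           snr_grid=snr_grid, n_seeds=n_seeds,
                                           epochs=epochs, learnrate=learnrate,
                                           base_seed=base_seed)
    speed = measure_learning_speed(data, epochs=epochs, learnrate=learnrate)
    order = np.argsort(cal)
    cal_sorted, log_snr_sorted = cal[order], np.log2(grid[order])
    if speed < cal_sorted[0] or speed > cal_sorted[-1]:
        warnings.warn("measured learning speed outside calibration range; clamping",
                      stacklevel=2)
    return float(2.0 ** np.interp(speed, cal_sorted, log_snr_sorted))


def predicted_stop_from_snr(snr_hat: float, p: int, n: int,
                            config: TrainConfig | None = None) -> int:
    """Stopping epoch predicted from an SNR estimate via a matched simulation.

    Runs a deterministic-replay consolidation of a teacher at ``snr_hat`` with
    matched (P, N) and closed-form errors, and returns its oracle stop epoch.
    Infinite SNR never stops early; zero SNR stops immediately.
    """
    if snr_hat < 0:
        raise ValueError("snr_hat must be nonnegative")
    config = config or TrainConfig(replay="full", gen_error="closed", keep_weights=False)
    if math.isinf(snr_hat):
        return config.epochs
    if snr_hat == 0:
        return 0
    cfg = replace(config, replay="full", gen_error="closed", keep_weights=False,
                  track_notebook=False)
    teacher = make_linear_teacher(snr_hat, n, seed=child_seed(cfg.seed, "matched-teacher"))
    data = sample_examples(teacher, p, seed=child_seed(cfg.seed, "matched-data"))
    trace = _run_training(teacher, data, cfg)
    return oracle_early_stop(trace)


# -- spec-style functional entry point ------------------------------------

def consolidate(teacher: TeacherSpec, data: ExampleSet, notebook: Notebook | None,
                student: StudentState | None, config: TrainConfig,
                policy: RegulationPolicy | None = None):
    """Run consolidation under a regulation policy.

    Returns ``(trace, final_student, stop_epoch)``: the full-horizon trace,
    the student frozen at the policy's stopping epoch, and that epoch.  The
    notebook remains usable after the stop (only student plasticity halts).
    """
    policy = policy or RegulationPolicy("none")
    if notebook is not None and notebook.p == 0:
        notebook.encode(data)

    if policy.kind == "validation_early_stop":
        stop, _, trace = validation_early_stop(data, policy.val_fraction, config,
                                               patience=policy.patience,
                                               teacher=teacher, notebook=notebook)
    else:
        trace = _run_training(teacher, data, config, student=student, notebook=notebook)
        if policy.kind == "none":
            stop = config.epochs
        elif policy.kind == "oracle_early_stop":
            stop = oracle_early_stop(trace)
        else:
            if policy.kind == "snr_mle_stop":
                snr_hat = estimate_snr_mle(data, policy.snr_grid)
            else:
                snr_hat = estimate_snr_learning_speed(data, snr_grid=policy.snr_grid)
            stop = min(predicted_stop_from_snr(snr_hat, data.p, data.inputs.shape[0], config),
                       config.epochs)

    final = StudentState(trace.weights_at(stop), config.learnrate)
    return trace, final, stop


# -- statsmodels-style model / results ------------------------------------

class SystemsConsolidation:
    """Teacher–student–notebook consolidation model.

    Parameters
    ----------
    data : ExampleSet
        The experiences to encode and consolidate.
    teacher : TeacherSpec, optional
        Defaults to the teacher that generated ``data``.
    notebook : Notebook or None
        Pass an (empty or pre-encoded) notebook, or None with
        ``m``/``sparsity`` to have one built; ``notebook=False`` runs a
        student-only model (deterministic replay required).
    config : TrainConfig
    policy : RegulationPolicy

    Examples
    --------
    >>> model = SystemsConsolidation.from_teacher(snr=4.0, n=100, p=100, seed=7)
    >>> res = model.fit()
    >>> res.stop_epoch, round(res.gen_error_at_stop, 3)  # doctest: +SKIP
    """

    def __init__(self, data: ExampleSet, teacher: TeacherSpec | None = None, *,
                 notebook: Notebook | None | bool = None, m: int = 2000,
                 sparsity: float = 0.05, config: TrainConfig | None = None,
                 policy: RegulationPolicy | None = None):
        self.data = data
        self.teacher = teacher or data.teacher
        self.config = config or TrainConfig()
        self.policy = policy or RegulationPolicy("none")
        if notebook is False:
            self.notebook = None
            if self.config.replay == "hopfield":
                raise ValueError("student-only model cannot use hopfield replay")
        elif notebook is None:
            self.notebook = Notebook(m, sparsity, data.inputs.shape[0],
                                     seed=child_seed(self.config.seed, "notebook"))
        else:
            self.notebook = notebook

    @classmethod
    def from_teacher(cls, snr: float = 4.0, n: int = 100, p: int = 100,
                     seed: int = 0, *, m: int = 2000, sparsity: float = 0.05,
                     config: TrainConfig | None = None,
                     policy: RegulationPolicy | None = None) -> "SystemsConsolidation":
        """Build teacher, examples and notebook from high-level parameters."""
        teacher = make_linear_teacher(snr, n, seed=child_seed(seed, "teacher"))
        data = sample_examples(teacher, p, seed=child_seed(seed, "data"))
        config = config or TrainConfig(seed=seed)
        return cls(data, teacher, m=m, sparsity=sparsity, config=config, policy=policy)

    def fit(self, policy: RegulationPolicy | None = None) -> "ConsolidationResults":
        policy = policy or self.policy
        trace, final, stop = consolidate(self.teacher, self.data, self.notebook,
                                         None, self.config, policy)
        return ConsolidationResults(self, trace, final, stop, policy)


class ConsolidationResults:
    """Fitted consolidation run: trace, stopped student, diagnostics."""

    def __init__(self, model: SystemsConsolidation, trace: TrainTrace,
                 student: StudentState, stop_epoch: int, policy: RegulationPolicy):
        self.model = model
        self.trace = trace
        self.student = student
        self.stop_epoch = stop_epoch
        self.policy = policy

    @property
    def params(self) -> np.ndarray:
        """Student weights at the stopping epoch."""
        return self.student.weights

    @property
    def gen_error_at_stop(self) -> float:
        return float(self.trace.student_gen_error[self.stop_epoch])

    @property
    def mem_error_at_stop(self) -> float:
        return float(self.trace.student_mem_error[self.stop_epoch])

    def scores(self, lesion_time: int | None = None):
        """Combined-system memory/generalization score curves (see scores module)."""
        from .scores import combined_scores
        return combined_scores(self.trace, lesion_time=lesion_time,
                               stop_epoch=self.stop_epoch)

    def summary(self) -> str:
        t, m = self.trace, self.model
        lines = [
            "        Systems Consolidation Results",
            "=" * 46,
            f"teacher kind:       {m.teacher.kind:>12}",
            f"SNR:                {m.teacher.snr:>12.4g}",
            f"N (student dim):    {m.teacher.n_observed:>12d}",
            f"P (examples):       {m.data.p:>12d}",
            f"notebook M, a:      {(f'{m.notebook.m}, {m.notebook.a}' if m.notebook else 'none'):>12}",
            f"replay mode:        {t.config.replay:>12}",
            f"learnrate:          {t.config.learnrate:>12.4g}",
            f"policy:             {self.policy.kind:>12}",
            f"horizon (epochs):   {t.config.epochs:>12d}",
            f"stop epoch:         {self.stop_epoch:>12d}",
            "-" * 46,
            f"gen error @ stop:   {self.gen_error_at_stop:>12.4f}",
            f"mem error @ stop:   {self.mem_error_at_stop:>12.4f}",
            f"gen error @ end:    {t.student_gen_error[-1]:>12.4f}",
            f"mem error @ end:    {t.student_mem_error[-1]:>12.4f}",
            f"notebook mem error: {t.notebook_mem_error[0]:>12.4f}",
            f"notebook gen error: {t.notebook_gen_error[0]:>12.4f}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot the four error trajectories (requires matplotlib)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        f = self.trace.to_frame()
        ax.plot(f.epoch, f.student_gen_error, "r-", label="student gen")
        ax.plot(f.epoch, f.student_mem_error, "b-", label="student mem")
        ax.plot(f.epoch, f.notebook_gen_error, "r--", label="notebook gen")
        ax.plot(f.epoch, f.notebook_mem_error, "b--", label="notebook mem")
        ax.axvline(self.stop_epoch, color="k", ls=":", label="stop")
        ax.set_xlabel("epoch"); ax.set_ylabel("error"); ax.legend()
        return ax
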