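"""Linear "student" learner modeling the neocortex.

The student is a bias-free linear map ŷ = w·x with weights initialized to
zero (tabula rasa) and trained by gradient descent on replayed examples.  The
batch update is

    w ← w + learnrate · (Ỹ X̃ᵀ − w X̃ X̃ᵀ)

with X̃, Ỹ the column-stacked batch — the exact gradient step of the summed
squared-error loss ½‖Ỹ − wX̃‖².  For a linear noisy teacher the generalization
error has the closed form E_g = (1/N)‖w − w̄‖² + σ_ε² (test noise included).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
import numpy as np

from ._rng import child_seed
from .teachers import ExampleSet, TeacherSpec, sample_examples

__all__ = [
    "StudentState",
    "predict",
    "memorization_error",
    "generalization_error",
    "closed_form_generalization_error",
    "gradient_update",
    "train_to_convergence",
    "min_norm_solution",
    "online_learn",
    "optimal_online_schedule",
    "expected_online_errors",
]


@dataclass(frozen=True)
class StudentState:
    """Weight vector and step size of the linear student."""

    weights: np.ndarray
    learnrate: float = 0.015

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1:
            raise ValueError("weights must be a vector")
        if not 0 < self.learnrate:
            raise ValueError("learnrate must be positive")
        object.__setattr__(self, "weights", w)

    @classmethod
    def zeros(cls, n: int, learnrate: float = 0.015) -> "StudentState":
        return cls(np.zeros(n), learnrate)

    def to_json(self) -> str:
        return json.dumps({"weights": self.weights.tolist(), "learnrate": self.learnrate})

    @classmethod
    def from_json(cls, s: str) -> "StudentState":
        d = json.loads(s)
        return cls(np.asarray(d["weights"]), d["learnrate"])


def predict(student: StudentState, inputs: np.ndarray) -> np.ndarray:
    """Student predictions w·x, one per input column."""
    inputs = np.asarray(inputs)
    if inputs.shape[0] != student.weights.shape[0]:
        raise ValueError(f"input dimension {inputs.shape[0]} != weight length "
                         f"{student.weights.shape[0]}")
    return student.weights @ inputs


def memorization_error(student: StudentState, data: ExampleSet) -> float:
    """Mean squared error over the stored training examples."""
    if data.p < 1:
        raise ValueError("empty example set")
    resid = data.outputs - predict(student, data.inputs)
    return float(np.mean(resid**2))


def closed_form_generalization_error(weights: np.ndarray, teacher: TeacherSpec,
                                     include_noise: bool = True) -> float:
    """Exact generalization error (1/N)‖w − w̄‖² + σ_ε² for a linear teacher."""
    if teacher.kind != "linear_noisy":
        raise ValueError("closed form only applies to linear_noisy teachers")
    err = float(np.sum((weights - teacher.teacher_weights) ** 2)) / teacher.n_teacher
    return err + (teacher.sigma_eps2 if include_noise else 0.0)


def generalization_error(student: StudentState, teacher: TeacherSpec,
                         p_test: int = 1000, seed: int = 0, *,
                         method: str = "mc", include_noise: bool = True) -> float:
    """Expected squared error on fresh teacher-generated examples.

    ``method="mc"`` estimates it on ``p_test`` fresh samples (test outputs
    carry the teacher's noise); ``method="closed"`` uses the linear-teacher
    closed form.  ``include_noise=False`` subtracts the σ_ε² floor (analysis
    variant; Monte-Carlo mode then scores against noiseless targets).
    """
    if method == "closed":
        return closed_form_generalization_error(student.weights, teacher, include_noise)
    if p_test < 1:
        raise ValueError("p_test must be >= 1")
    test = sample_examples(teacher, p_test, seed=child_seed(seed, "gen-test"))
    y = test.outputs
    if not include_noise and teacher.sigma_eps2 > 0:
        # rebuild noiseless targets from the teacher mapping
        full = test.inputs if test.hidden_inputs is None else np.vstack([test.inputs, test.hidden_inputs])
        y = teacher._output_fn(teacher.teacher_weights @ full)
    resid = y - predict(student, test.inputs)
    return float(np.mean(resid**2))


def gradient_update(student: StudentState, x_batch: np.ndarray, y_batch: np.ndarray) -> StudentState:
    """One batch gradient step; returns a new state (pure function)."""
    x_batch = np.atleast_2d(np.asarray(x_batch, dtype=float))
    y_batch = np.atleast_1d(np.asarray(y_batch, dtype=float))
    if x_batch.shape[0] != student.weights.shape[0] or x_batch.shape[1] != y_batch.shape[0]:
        raise ValueError("batch shapes inconsistent with student weights")
    w = student.weights
    dw = student.learnrate * (y_batch @ x_batch.T - w @ (x_batch @ x_batch.T))
    return StudentState(w + dw, student.learnrate)


def min_norm_solution(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Minimum-norm least-squares weights — the fixed point that full-batch
    gradient descent from zero initialization converges to."""
    w, *_ = np.linalg.lstsq(np.asarray(x).T, np.asarray(y), rcond=None)
    return w


def train_to_convergence(student: StudentState, x: np.ndarray, y: np.ndarray, *,
                         tol: float = 1e-13, max_epochs: int = 5_000_000,
                         learnrate: float | None = None) -> tuple[StudentState, int]:
    """Iterate full-batch gradient steps until the weight change stalls.

    ``learnrate=None`` picks 1.9/λ_max(X̃X̃ᵀ), just inside the stability limit.
    Returns the final state and the number of epochs run.  The per-step
    matrices are precomputed, so each epoch is a single N×N product.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    a = x @ x.T
    b = y @ x.T
    if learnrate is None:
        lam_max = float(np.linalg.eigvalsh(a)[-1])
        learnrate = 1.9 / lam_max
    w = student.weights.copy()
    scale = max(1.0, float(np.linalg.norm(b)))
    for epoch in range(1, max_epochs + 1):
        dw = learnrate * (b - w @ a)
        w = w + dw
        if epoch % 200 == 0 and float(np.max(np.abs(dw))) < tol * scale * learnrate:
            break
    return StudentState(w, learnrate), epoch


# -- student-only online baseline ----------------------------------------

def online_learn(teacher: TeacherSpec, p_stream: int, schedule, seed: int = 0) -> dict:
    """Single-pass stochastic gradient descent over a stream of examples.

    Each teacher-generated example is used for one update
    ``w ← w + η_t (y − w·x) x`` and then discarded.  ``schedule`` is a scalar
    (constant rate) or a length-``p_stream`` sequence.  Returns a dict with the
    final state and the closed-form generalization-error trajectory (length
    p_stream + 1, entry 0 before any update) for linear teachers, or a
    Monte-Carlo trajectory otherwise.
    """
    etas = np.broadcast_to(np.asarray(schedule, dtype=float), (p_stream,))
    data = sample_examples(teacher, p_stream, seed=child_seed(seed, "online-stream"))
    n = teacher.n_observed
    w = np.zeros(n)
    linear = teacher.kind == "linear_noisy"
    errs = np.empty(p_stream + 1)

    def gen_err(wv):
        if linear:
            return closed_form_generalization_error(wv, teacher)
        return generalization_error(StudentState(wv, 1.0), teacher, 1000, seed=child_seed(seed, "online-test"))

    errs[0] = gen_err(w)
    for t in range(p_stream):
        x = data.inputs[:, t]
        w = w + etas[t] * (data.outputs[t] - w @ x) * x
        errs[t + 1] = gen_err(w)
    final_lr = float(etas[-1]) if p_stream and etas[-1] > 0 else 1.0
    return {"student": StudentState(w, final_lr),
            "gen_errors": errs, "schedule": np.array(etas)}


def expected_online_errors(snr: float, n: int, p_stream: int, schedule) -> np.ndarray:
    """Deterministic expected generalization-error recursion for the online
    linear-Gaussian stream.

    With r_t = E‖w_t − w̄‖², a step with rate η gives
        r_{t+1} = r_t (1 − 2η/N + η²(N+2)/N²) + η²σ_ε²
    and E_g(t) = r_t/N + σ_ε².  Returns the length p_stream+1 error trajectory.
    """
    sw2 = 1.0 if math.isinf(snr) else snr / (1.0 + snr)
    se2 = 1.0 - sw2
    etas = np.broadcast_to(np.asarray(schedule, dtype=float), (p_stream,))
    r = n * sw2
    errs = np.empty(p_stream + 1)
    errs[0] = r / n + se2
    for t, eta in enumerate(etas):
        r = r * (1.0 - 2.0 * eta / n + eta * eta * (n + 2.0) / n**2) + eta * eta * se2
        errs[t + 1] = r / n + se2
    return errs


def optimal_online_schedule(snr: float, n: int, p_stream: int) -> np.ndarray:
    """Greedy risk-optimal learning-rate schedule for the online baseline.

    Minimizing the one-step expected risk r_{t+1}(η) (a quadratic in η) gives
    η*_t = (r_t/N) / ((N+2) r_t/N² + σ_ε²); since the expected risk depends on
    the weights only through the scalar r_t and is monotone in it, the greedy
    schedule is globally optimal for this recursion.
    """
    sw2 = 1.0 if math.isinf(snr) else snr / (1.0 + snr)
    se2 = 1.0 - sw2
    r = n * sw2
    etas = np.empty(p_stream)
    for t in range(p_stream):
        denom = (n + 2.0) * r / n**2 + se2
        eta = (r / n) / denom if denom > 0 else 0.0
        etas[t] = eta
        r = r * (1.0 - 2.0 * eta / n + eta * eta * (n + 2.0) / n**2) + eta * eta * se2
    return etas
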