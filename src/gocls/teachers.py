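"""Generative "teacher" environments with a controllable degree of predictability.

A teacher is a fixed shallow network that maps an input pattern ``x`` (components
i.i.d. N(0, 1/N), N the teacher's input dimension) to a scalar output ``y``.
Three kinds are supported:

``linear_noisy``
    y = w̄·x + ε with w̄ ~ N(0, σ_w²) componentwise and ε ~ N(0, σ_ε²).
    The constraint σ_w² + σ_ε² = 1 gives unit-variance outputs, so the
    signal-to-noise ratio SNR = σ_w²/σ_ε² fully parameterizes predictability.

``nonlinear``
    y = c·sin(w̄·x): a deterministic mapping that a linear learner cannot
    fully model; the unmodellable (non-linear) part of the sine acts like
    noise.  ``c`` rescales the output to unit variance by default.

``partial_obs``
    y = w̄·x over all N teacher coordinates, but the learner only observes
    the first ``n_observed`` of them; the hidden coordinates' contribution is
    unpredictable from the learner's viewpoint.

Any teacher reduces to an *equivalent SNR*: the ratio of the variance of the
best linear prediction of y from the observed inputs to the residual variance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from ._rng import child_rng

__all__ = [
    "TeacherSpec",
    "ExampleSet",
    "make_linear_teacher",
    "make_sine_teacher",
    "make_partial_obs_teacher",
    "sample_examples",
    "equivalent_snr",
    "sine_equivalent_snr",
    "sine_scale_for_snr",
    "partial_obs_equivalent_snr",
    "save_examples",
    "load_examples",
]


@dataclass(frozen=True)
class TeacherSpec:
    """Frozen description of a generative environment.

    Attributes
    ----------
    kind : {"linear_noisy", "nonlinear", "partial_obs"}
    n_teacher : int
        Teacher input dimension N (may exceed ``n_observed`` for partial_obs).
    n_observed : int
        Number of input coordinates exposed to the learner.
    sigma_w2, sigma_eps2 : float
        Variance of teacher weight components and of the additive output noise.
    teacher_weights : ndarray, shape (n_teacher,)
    nonlinearity : str or None
        ``"sine"`` for the nonlinear teacher, None for identity.
    output_scale : float
        Multiplier applied to the (possibly nonlinear) output, used to
        normalize the sine teacher to unit output variance.
    seed : int
    """

    kind: str
    n_teacher: int
    n_observed: int
    sigma_w2: float
    sigma_eps2: float
    teacher_weights: np.ndarray = field(repr=False)
    nonlinearity: str | None = None
    output_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("linear_noisy", "nonlinear", "partial_obs"):
            raise ValueError(f"unknown teacher kind {self.kind!r}")
        if self.n_teacher < 1 or not (1 <= self.n_observed <= self.n_teacher):
            raise ValueError("invalid teacher dimensions")
        if self.sigma_w2 < 0 or self.sigma_eps2 < 0:
            raise ValueError("variances must be nonnegative")
        if self.kind == "linear_noisy" and abs(self.sigma_w2 + self.sigma_eps2 - 1.0) > 1e-12:
            raise ValueError("linear_noisy teacher requires sigma_w2 + sigma_eps2 = 1")
        if self.kind == "partial_obs" and (self.nonlinearity is not None or self.sigma_eps2 != 0):
            raise ValueError("partial_obs teacher must be noiseless and linear")
        w = np.asarray(self.teacher_weights, dtype=float)
        if w.shape != (self.n_teacher,):
            raise ValueError("teacher_weights must have shape (n_teacher,)")
        object.__setattr__(self, "teacher_weights", w)

    @property
    def snr(self) -> float:
        """Construction SNR σ_w²/σ_ε² (inf when noiseless)."""
        if self.sigma_eps2 == 0:
            return math.inf
        return self.sigma_w2 / self.sigma_eps2

    def _output_fn(self, preact: np.ndarray) -> np.ndarray:
        if self.nonlinearity is None:
            return self.output_scale * preact
        if self.nonlinearity == "sine":
            return self.output_scale * np.sin(preact)
        raise ValueError(f"unknown nonlinearity {self.nonlinearity!r}")

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        d = {
            "kind": self.kind,
            "n_teacher": self.n_teacher,
            "n_observed": self.n_observed,
            "sigma_w2": self.sigma_w2,
            "sigma_eps2": self.sigma_eps2,
            "nonlinearity": self.nonlinearity,
            "output_scale": self.output_scale,
            "seed": self.seed,
            "teacher_weights": self.teacher_weights.tolist(),
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "TeacherSpec":
        d = json.loads(s)
        d["teacher_weights"] = np.asarray(d["teacher_weights"], dtype=float)
        return cls(**d)


@dataclass(frozen=True)
class ExampleSet:
    """A batch of P teacher-generated input–output pairs.

    ``inputs`` holds one example per column (n_observed × P), as seen by the
    learner; for partially observable teachers ``hidden_inputs`` carries the
    unobserved coordinates.
    """

    inputs: np.ndarray
    outputs: np.ndarray
    teacher: TeacherSpec
    seed: int
    hidden_inputs: np.ndarray | None = None

    def __post_init__(self):
        if self.inputs.ndim != 2 or self.inputs.shape[1] != self.outputs.shape[0]:
            raise ValueError("inputs must be (n_observed, P) matching outputs length P")

    @property
    def p(self) -> int:
        return self.outputs.shape[0]

    def split(self, n_first: int) -> tuple["ExampleSet", "ExampleSet"]:
        """Deterministically split off the first ``n_first`` examples."""
        if not 0 < n_first < self.p:
            raise ValueError("split size out of range")
        h = self.hidden_inputs
        a = replace(self, inputs=self.inputs[:, :n_first], outputs=self.outputs[:n_first],
                    hidden_inputs=None if h is None else h[:, :n_first])
        b = replace(self, inputs=self.inputs[:, n_first:], outputs=self.outputs[n_first:],
                    hidden_inputs=None if h is None else h[:, n_first:])
        return a, b


def _snr_to_variances(snr: float) -> tuple[float, float]:
    if snr < 0:
        raise ValueError("snr must be nonnegative")
    if math.isinf(snr):
        return 1.0, 0.0
    return snr / (1.0 + snr), 1.0 / (1.0 + snr)


def _draw_weights(rng, n: int, sigma_w2: float, fixed_norm: bool) -> np.ndarray:
    w = rng.standard_normal(n) * math.sqrt(sigma_w2)
    if fixed_norm and sigma_w2 > 0:
        # random direction, deterministic length: ||w|| = sqrt(n * sigma_w2)
        w *= math.sqrt(n * sigma_w2) / np.linalg.norm(w)
    return w


def make_linear_teacher(snr: float, n: int, seed: int = 0, *, fixed_norm: bool = False) -> TeacherSpec:
    """Linear noisy teacher with unit output variance.

    ``sigma_w2 = snr/(1+snr)``, ``sigma_eps2 = 1/(1+snr)`` (infinite SNR gives
    the noiseless teacher).  Weight components are i.i.d. N(0, σ_w²); with
    ``fixed_norm`` the weight vector is rescaled to its expected norm so the
    realized signal variance equals σ_w² exactly.
    """
    sw2, se2 = _snr_to_variances(snr)
    rng = child_rng(seed, "teacher-weights")
    w = _draw_weights(rng, n, sw2, fixed_norm)
    return TeacherSpec("linear_noisy", n, n, sw2, se2, w, seed=seed)


def make_sine_teacher(weight_scale: float, n: int, seed: int = 0, *,
                      normalize_output: bool = True, fixed_norm: bool = True) -> TeacherSpec:
    """Deterministic sine teacher y = c·sin(w̄·x) with preactivation scale s.

    ``weight_scale`` is s, the standard deviation of w̄·x (σ_w² = s²).  By
    default the weight norm is fixed so the realized preactivation scale is
    exactly s, and c normalizes the output to unit variance
    (Var sin(z) = (1 − e^{−2s²})/2 for z ~ N(0, s²)).
    """
    if weight_scale <= 0:
        raise ValueError("weight_scale must be positive")
    s2 = weight_scale**2
    rng = child_rng(seed, "teacher-weights")
    w = _draw_weights(rng, n, s2, fixed_norm)
    scale = 1.0 / math.sqrt((1.0 - math.exp(-2.0 * s2)) / 2.0) if normalize_output else 1.0
    return TeacherSpec("nonlinear", n, n, s2, 0.0, w, nonlinearity="sine",
                       output_scale=scale, seed=seed)


def make_partial_obs_teacher(n_observed: int, n_teacher: int, seed: int = 0, *,
                             fixed_norm: bool = True) -> TeacherSpec:
    """Noiseless linear teacher of which only ``n_observed`` inputs are visible.

    σ_w² = 1 so total output variance is ≈ 1; the hidden coordinates carry a
    fraction (n_teacher − n_observed)/n_teacher of it, giving equivalent SNR
    n_observed/(n_teacher − n_observed).  With ``fixed_norm`` the observed and
    hidden weight blocks are each rescaled to their expected norms.
    """
    if not 1 <= n_observed < n_teacher:
        raise ValueError("need 1 <= n_observed < n_teacher")
    rng = child_rng(seed, "teacher-weights")
    if fixed_norm:
        w = np.concatenate([
            _draw_weights(rng, n_observed, 1.0, True),
            _draw_weights(rng, n_teacher - n_observed, 1.0, True),
        ])
    else:
        w = _draw_weights(rng, n_teacher, 1.0, False)
    return TeacherSpec("partial_obs", n_teacher, n_observed, 1.0, 0.0, w, seed=seed)


def sample_examples(teacher: TeacherSpec, p: int, seed: int = 0) -> ExampleSet:
    """Draw P input–output pairs: y = f(w̄·x) + ε, x components i.i.d. N(0, 1/N).

    The 1/N input scaling always uses the *teacher's* dimension, so output
    variance is comparable across observability conditions.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    rng = child_rng(seed, "examples")
    n = teacher.n_teacher
    x = rng.standard_normal((n, p)) / math.sqrt(n)
    y = teacher._output_fn(teacher.teacher_weights @ x)
    if teacher.sigma_eps2 > 0:
        y = y + rng.standard_normal(p) * math.sqrt(teacher.sigma_eps2)
    nobs = teacher.n_observed
    hidden = x[nobs:] if nobs < n else None
    return ExampleSet(np.ascontiguousarray(x[:nobs]), y, teacher, seed, hidden)


def equivalent_snr(teacher: TeacherSpec, n_mc: int = 100_000, seed: int = 0) -> float:
    """Equivalent SNR: modellable over unmodellable output variance.

    The population-optimal linear predictor of y from the observed inputs is
    estimated by ordinary least squares on ``n_mc`` Monte-Carlo samples; the
    returned ratio is Var(ŷ)/Var(y − ŷ).  Returns ``inf`` when the residual
    variance is numerically zero.
    """
    data = sample_examples(teacher, n_mc, seed=seed)
    X = data.inputs.T  # (n_mc, n_obs)
    beta, *_ = np.linalg.lstsq(X, data.outputs, rcond=None)
    pred = X @ beta
    resid_var = float(np.var(data.outputs - pred))
    signal_var = float(np.var(pred))
    if resid_var < 1e-12 * max(signal_var, 1.0):
        return math.inf
    return signal_var / resid_var


def sine_equivalent_snr(s: float) -> float:
    """Closed-form equivalent SNR of y = sin(z), z ~ N(0, s²).

    From the Hermite expansion of sine under a Gaussian: the linearly
    modellable variance is s²e^{−s²} and the total variance (1 − e^{−2s²})/2.
    """
    s2 = s * s
    total = -math.expm1(-2.0 * s2) / 2.0
    signal = s2 * math.exp(-s2)
    return signal / (total - signal)


def sine_scale_for_snr(snr: float) -> float:
    """Preactivation scale s at which the sine teacher has the given equivalent SNR."""
    if not 0 < snr < math.inf:
        raise ValueError("snr must be positive and finite")
    if snr > sine_equivalent_snr(0.05):
        raise ValueError("requested equivalent SNR beyond the resolvable range")
    # eq SNR decreases monotonically with s (~6/s^4 for small s)
    return brentq(lambda s: sine_equivalent_snr(s) - snr, 0.05, 20.0, xtol=1e-12)


def partial_obs_equivalent_snr(n_observed: int, n_teacher: int) -> float:
    """Expected equivalent SNR of the partially observable teacher."""
    return n_observed / (n_teacher - n_observed)


# -- serialization -------------------------------------------------------

def save_examples(data: ExampleSet, prefix: str | Path) -> None:
    """Write ``<prefix>.csv`` (columns x1..xN, y) and ``<prefix>.json`` metadata.

    Floats are written with 17 significant digits, so the round-trip is exact.
    """
    prefix = Path(prefix)
    table = np.column_stack([data.inputs.T, data.outputs])
    header = ",".join([f"x{i+1}" for i in range(data.inputs.shape[0])] + ["y"])
    np.savetxt(prefix.with_suffix(".csv"), table, fmt="%.17g", delimiter=",",
               header=header, comments="")
    meta = {"teacher": json.loads(data.teacher.to_json()), "seed": data.seed,
            "hidden_inputs": None if data.hidden_inputs is None else data.hidden_inputs.tolist()}
    prefix.with_suffix(".json").write_text(json.dumps(meta))


def load_examples(prefix: str | Path) -> ExampleSet:
    prefix = Path(prefix)
    table = np.loadtxt(prefix.with_suffix(".csv"), delimiter=",", skiprows=1, ndmin=2)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    teacher = TeacherSpec.from_json(json.dumps(meta["teacher"]))
    hidden = meta["hidden_inputs"]
    return ExampleSet(np.ascontiguousarray(table[:, :-1].T), table[:, -1], teacher,
                      meta["seed"], None if hidden is None else np.asarray(hidden))
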