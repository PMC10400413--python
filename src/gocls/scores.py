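"""Behavioral scores, combined-system selection, lesions and amnesia curves.

Mean squared errors are translated into behavioral scores by

    score = (E_0 − E_t) / E_0

where E_0 is the error of the untrained (zero-weight) student — chance
performance — so 0 means chance, 1 perfect, and negative worse than chance.
The combined student–notebook system predicts with whichever subsystem has
the lower error at each time.  A notebook lesion at time t removes the
notebook from the selection AND freezes the student (consolidation requires
notebook replay), so post-lesion performance is the student's at the lesion
time.  Sweeping the lesion time maps out retrograde amnesia curves, which are
classified as flat, graded or absent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import child_seed
from .consolidation import (TrainConfig, TrainTrace, _run_training,
                            oracle_early_stop)
from .notebook import Notebook
from .student import StudentState
from .teachers import make_linear_teacher, sample_examples

__all__ = [
    "score",
    "ScoreCurve",
    "combined_scores",
    "LesionExperiment",
    "AmnesiaCurve",
    "amnesia_curve",
    "classify_amnesia",
    "memory_generalization_correlation",
]


def score(e0: float, et: float) -> float:
    """Behavioral score (E0 − Et)/E0; E0 must be positive, Et nonnegative."""
    if e0 <= 0:
        raise ValueError("baseline error e0 must be positive")
    if et < 0:
        raise ValueError("error must be nonnegative")
    return (e0 - et) / e0


@dataclass
class ScoreCurve:
    """Memory and generalization score trajectories for one condition."""

    times: np.ndarray
    memory_score: np.ndarray
    generalization_score: np.ndarray
    snr: float = math.nan
    lesion_time: int | None = None
    stop_epoch: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch": self.times, "memory_score": self.memory_score,
                             "generalization_score": self.generalization_score})


def _effective_student_errors(trace: TrainTrace, stop_epoch: int | None) -> tuple[np.ndarray, np.ndarray]:
    """Student errors with weights frozen from ``stop_epoch`` onward."""
    mem = trace.student_mem_error.copy()
    gen = trace.student_gen_error.copy()
    if stop_epoch is not None and stop_epoch < trace.epochs:
        mem[stop_epoch:] = mem[stop_epoch]
        gen[stop_epoch:] = gen[stop_epoch]
    return mem, gen


def combined_scores(trace: TrainTrace, lesion_time: int | None = None,
                    stop_epoch: int | None = None) -> ScoreCurve:
    """Score curves of the combined system, optionally with a notebook lesion.

    At each epoch the memory (generalization) error is the minimum of the
    student's and the notebook's; after ``lesion_time`` the notebook is
    excluded and the student is frozen at its lesion-time weights.
    """
    if lesion_time is not None and not 0 <= lesion_time <= trace.epochs:
        raise ValueError("lesion_time outside the training horizon")
    s_mem, s_gen = _effective_student_errors(trace, stop_epoch)
    e0_mem = trace.student_mem_error[0]
    e0_gen = trace.student_gen_error[0]
    nb_mem, nb_gen = trace.notebook_mem_error, trace.notebook_gen_error
    have_nb = np.isfinite(nb_mem[0])

    mem = np.minimum(s_mem, nb_mem) if have_nb else s_mem.copy()
    gen = np.minimum(s_gen, nb_gen) if have_nb else s_gen.copy()
    if lesion_time is not None:
        mem[lesion_time:] = s_mem[lesion_time]
        gen[lesion_time:] = s_gen[lesion_time]
    t = np.arange(trace.epochs + 1)
    return ScoreCurve(t, (e0_mem - mem) / e0_mem, (e0_gen - gen) / e0_gen,
                      snr=trace.teacher.snr, lesion_time=lesion_time,
                      stop_epoch=stop_epoch)


@dataclass
class LesionExperiment:
    """Configuration of a retrograde-amnesia simulation.

    ``prior_epochs`` pretrains the student on an independent example set from
    the same teacher before the tested experiences are encoded, modeling
    consolidation of earlier schema-consistent experience.  ``lesion_times``
    defaults to 20 evenly spaced epochs across the horizon; each lesioned run
    is paired with the same-seed intact control.
    """

    snr: float = 8.0
    n: int = 100
    p: int = 100
    m: int = 5000
    sparsity: float = 0.05
    learnrate: float = 0.005
    epochs: int = 2000
    prior_epochs: int = 0
    prior_p: int | None = None
    lesion_times: np.ndarray | None = None
    policy: str = "oracle_early_stop"
    replay: str = "full"
    gen_error: str = "closed"
    use_notebook: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.lesion_times is None:
            self.lesion_times = np.unique(np.linspace(0, self.epochs, 20).astype(int))
        self.lesion_times = np.asarray(self.lesion_times, dtype=int)
        if self.lesion_times.max() > self.epochs or self.lesion_times.min() < 0:
            raise ValueError("lesion_times must lie within the training horizon")


@dataclass
class AmnesiaCurve:
    lesion_times: np.ndarray
    control_scores: np.ndarray
    lesioned_scores: np.ndarray
    deficits: np.ndarray
    classification: str
    stop_epoch: int
    experiment: LesionExperiment

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "lesion_time": self.lesion_times,
            "control_score": self.control_scores,
            "lesioned_score": self.lesioned_scores,
            "deficit": self.deficits,
        })


def classify_amnesia(deficits: np.ndarray, *, none_threshold: float = 0.05,
                     flat_threshold: float = 0.25) -> str:
    """Taxonomy of a retrograde amnesia curve.

    ``none`` when the worst deficit is below ``none_threshold``; ``flat`` when
    deficits are substantial but nearly level (range/mean below
    ``flat_threshold``); otherwise ``graded``.
    """
    deficits = np.asarray(deficits, dtype=float)
    if deficits.max() < none_threshold:
        return "none"
    mean = deficits.mean()
    if mean > 0 and (deficits.max() - deficits.min()) / mean < flat_threshold:
        return "flat"
    return "graded"


def amnesia_curve(exp: LesionExperiment) -> AmnesiaCurve:
    """Simulate notebook lesions at each lesion time and classify the curve.

    For each lesion time t the memory deficit is the paired difference between
    the intact (control) combined-system memory score at t and the
    student-only score at t (student frozen at min(t, stop epoch)).
    """
    teacher = make_linear_teacher(exp.snr, exp.n, seed=child_seed(exp.seed, "teacher"))
    data = sample_examples(teacher, exp.p, seed=child_seed(exp.seed, "data"))
    cfg = TrainConfig(epochs=exp.epochs, learnrate=exp.learnrate, replay=exp.replay,
                      gen_error=exp.gen_error, seed=child_seed(exp.seed, "train"),
                      track_notebook=exp.use_notebook)

    student = None
    if exp.prior_epochs > 0:
        prior = sample_examples(teacher, exp.prior_p or exp.p,
                                seed=child_seed(exp.seed, "prior-data"))
        pcfg = TrainConfig(epochs=exp.prior_epochs, learnrate=exp.learnrate,
                           replay="full", gen_error=exp.gen_error,
                           track_notebook=False, keep_weights=True,
                           seed=child_seed(exp.seed, "prior-train"))
        ptrace = _run_training(teacher, prior, pcfg)
        student = StudentState(ptrace.weights[-1], exp.learnrate)

    notebook = None
    if exp.use_notebook:
        notebook = Notebook(exp.m, exp.sparsity, exp.n,
                            seed=child_seed(exp.seed, "notebook"))
        notebook.encode(data)

    trace = _run_training(teacher, data, cfg, student=student, notebook=notebook)
    stop = oracle_early_stop(trace) if exp.policy == "oracle_early_stop" else exp.epochs

    control = combined_scores(trace, stop_epoch=stop)
    s_mem, _ = _effective_student_errors(trace, stop)
    e0 = trace.student_mem_error[0]

    lt = exp.lesion_times
    control_scores = control.memory_score[lt]
    lesioned_scores = (e0 - s_mem[lt]) / e0
    deficits = control_scores - lesioned_scores
    return AmnesiaCurve(lt, control_scores, lesioned_scores, deficits,
                        classify_amnesia(deficits), stop, exp)


def memory_generalization_correlation(snr_grid, config: TrainConfig | None = None, *,
                                      lesion_fraction: float = 0.8, p: int = 100,
                                      n: int = 100, seeds=(0,),
                                      policy: str = "oracle_early_stop") -> float:
    """Pearson correlation of post-lesion memory vs generalization scores
    across predictability conditions.

    Each SNR condition is consolidated under the given policy, the notebook is
    lesioned at a fixed remote time (``lesion_fraction`` of the horizon), and
    the student-only memory and generalization scores at that time are
    correlated across conditions (seed-averaged per condition).
    """
    snr_grid = np.asarray(snr_grid, dtype=float)
    if snr_grid.size < 3:
        raise ValueError("need at least 3 SNR conditions for a correlation")
    cfg = config or TrainConfig(epochs=2000, learnrate=0.005, replay="full",
                                gen_error="closed", track_notebook=False)
    lesion = int(round(lesion_fraction * cfg.epochs))
    mem_scores, gen_scores = [], []
    for s in snr_grid:
        ms, gs = [], []
        for seed in seeds:
            teacher = make_linear_teacher(s, n, seed=child_seed(seed, "corr-teacher"))
            data = sample_examples(teacher, p, seed=child_seed(seed, "corr-data"))
            trace = _run_training(teacher, data, cfg)
            stop = oracle_early_stop(trace) if policy == "oracle_early_stop" else cfg.epochs
            t = min(lesion, trace.epochs)
            s_mem, s_gen = _effective_student_errors(trace, stop)
            ms.append(score(trace.student_mem_error[0], s_mem[t]))
            gs.append(score(trace.student_gen_error[0], s_gen[t]))
        mem_scores.append(np.mean(ms))
        gen_scores.append(np.mean(gs))
    return float(np.corrcoef(mem_scores, gen_scores)[0, 1])
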