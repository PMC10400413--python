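"""Scores, combined-system selection, lesions and amnesia taxonomy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gocls._rng import child_seed
from gocls.consolidation import TrainConfig, _run_training, oracle_early_stop
from gocls.scores import (LesionExperiment, amnesia_curve,
                          classify_amnesia, combined_scores,
                          memory_generalization_correlation, score)
from gocls.teachers import make_linear_teacher, sample_examples


@pytest.mark.parametrize("e0,et,expect", [(1.0, 1.0, 0.0), (1.0, 0.0, 1.0),
                                          (0.5, 1.0, -1.0), (2.0, 1.0, 0.5)])
def test_score_values(e0, et, expect):
    assert score(e0, et) == pytest.approx(expect)


def test_score_domain_errors():
    with pytest.raises(ValueError):
        score(0.0, 1.0)
    with pytest.raises(ValueError):
        score(-1.0, 1.0)


@settings(deadline=None, max_examples=50)
@given(e0=st.floats(0.01, 100, allow_nan=False), et=st.floats(0, 100, allow_nan=False))
def test_score_bounded_above_and_monotone(e0, et):
    s = score(e0, et)
    assert s <= 1.0
    assert score(e0, et + 1.0) < s


def _trace(snr=4.0, n=50, p=50, epochs=400, seed=0, nb_mem=0.02, nb_gen=1.8):
    t = make_linear_teacher(snr, n, seed=child_seed(seed, "t"), fixed_norm=True)
    d = sample_examples(t, p, seed=child_seed(seed, "d"))
    cfg = TrainConfig(epochs=epochs, replay="full", gen_error="closed",
                      track_notebook=False, seed=seed)
    tr = _run_training(t, d, cfg)
    tr.notebook_mem_error[:] = nb_mem
    tr.notebook_gen_error[:] = nb_gen
    return tr


def test_combined_memory_score_near_ceiling_pre_lesion():
    tr = _trace()
    sc = combined_scores(tr)
    assert np.all(sc.memory_score >= 0.95)  # notebook dominates memory recall


def test_combined_errors_never_worse_than_subsystems():
    tr = _trace()
    sc = combined_scores(tr)
    e0m, e0g = tr.student_mem_error[0], tr.student_gen_error[0]
    mem_err = e0m * (1 - sc.memory_score)
    gen_err = e0g * (1 - sc.generalization_score)
    assert np.all(mem_err <= tr.student_mem_error + 1e-12)
    assert np.all(mem_err <= tr.notebook_mem_error + 1e-12)
    assert np.all(gen_err <= tr.student_gen_error + 1e-12)


def test_lesion_at_zero_gives_chance_memory():
    tr = _trace()
    sc = combined_scores(tr, lesion_time=0)
    assert sc.memory_score[0] == pytest.approx(0.0)
    assert np.all(sc.memory_score == sc.memory_score[0])  # frozen student


def test_lesion_does_not_change_pre_lesion_scores():
    tr = _trace()
    intact = combined_scores(tr)
    lesioned = combined_scores(tr, lesion_time=200)
    assert np.array_equal(intact.memory_score[:200], lesioned.memory_score[:200])


def test_late_lesion_after_noiseless_consolidation_preserves_memory():
    tr = _trace(snr=np.inf, epochs=2000)
    sc = combined_scores(tr, lesion_time=2000)
    assert sc.memory_score[-1] > 0.9  # memory fully transferred to the student


def test_lesion_beyond_horizon_rejected():
    tr = _trace()
    with pytest.raises(ValueError):
        combined_scores(tr, lesion_time=10_000)


def test_generalization_score_bounded_by_noise_floor():
    tr = _trace(snr=4.0)
    sc = combined_scores(tr, stop_epoch=oracle_early_stop(tr))
    e0 = tr.student_gen_error[0]
    bound = 1 - tr.teacher.sigma_eps2 / e0
    assert np.all(sc.generalization_score <= bound + 1e-9)


class TestClassification:
    def test_thresholds(self):
        assert classify_amnesia([0.01, 0.02, 0.03]) == "none"
        assert classify_amnesia([0.9, 0.92, 0.88]) == "flat"
        assert classify_amnesia([0.9, 0.5, 0.1]) == "graded"

    @pytest.mark.parametrize("snr,prior,p,expect", [
        (0.01, 0, 100, "flat"),
        (8.0, 0, 100, "graded"),
        (50.0, 2000, 300, "none"),
    ])
    def test_methods_parameter_sets(self, snr, prior, p, expect):
        exp = LesionExperiment(snr=snr, prior_epochs=prior, p=p, prior_p=300,
                               m=2000, seed=1)
        assert amnesia_curve(exp).classification == expect

    def test_graded_deficit_decreases_with_memory_age(self):
        exp = LesionExperiment(snr=8.0, m=2000, seed=2)
        c = amnesia_curve(exp)
        assert c.deficits[0] > c.deficits[-1] + 0.2


def test_standard_consolidation_always_graded_even_at_low_snr():
    """Training to convergence transfers every memory, so lesions spare
    remote memories regardless of predictability."""
    exp = LesionExperiment(snr=0.3, m=2000, policy="none", epochs=4000,
                           learnrate=0.02, seed=3)
    c = amnesia_curve(exp)
    assert c.classification == "graded"


def test_correlation_across_predictability():
    snrs = 2.0 ** np.arange(-4, 5)
    r = memory_generalization_correlation(snrs, seeds=(0, 1))
    assert r > 0.8


def test_correlation_requires_three_conditions():
    with pytest.raises(ValueError):
        memory_generalization_correlation([1.0, 2.0])


def test_standard_policy_breaks_correlation_sign():
    """Under standard consolidation at low SNR the post-lesion generalization
    score goes negative while memory score is high — the Go-CLS coupling of
    memory transfer and generalization does not hold."""
    t = make_linear_teacher(0.05, 100, seed=child_seed(7, "t"), fixed_norm=True)
    d = sample_examples(t, 100, seed=child_seed(7, "d"))
    cfg = TrainConfig(epochs=4000, learnrate=0.02, replay="full",
                      gen_error="closed", track_notebook=False)
    tr = _run_training(t, d, cfg)
    mem_s = score(tr.student_mem_error[0], tr.student_mem_error[-1])
    gen_s = score(tr.student_gen_error[0], tr.student_gen_error[-1])
    assert mem_s > 0.5 and gen_s < 0.0


def test_amnesia_classification_stable_across_seeds():
    labels = [amnesia_curve(LesionExperiment(snr=0.01, m=2000, seed=s)).classification
              for s in range(5)]
    assert labels.count("flat") >= 4


def test_lesion_leaves_student_weights_untouched(snr4_data, encoded_notebook):
    """Notebook and student state are disjoint: encoding then excluding the
    notebook changes nothing about the student's parameters."""
    tr = _trace()
    sc = combined_scores(tr, lesion_time=100)
    assert np.array_equal(tr.weights[0], np.zeros(50))  # student started tabula rasa
    assert sc.lesion_time == 100
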