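"""Exit heads, joint loss, entropy, and the threshold-gated cascade."""

import numpy as np
import pytest

from rfcottnet.models import (ExitHead, ExitPolicy, StagePrediction,
                              attach_exit_heads, build_backbone,
                              dynamic_inference, entropy, exit_statistics,
                              joint_loss, tiny_config)
from rfcottnet.nn import Tensor, no_grad
from rfcottnet.nn.autograd import cross_entropy


# -- entropy ----------------------------------------------------------------

def test_entropy_closed_forms():
    assert entropy(np.array([1.0, 0, 0])) == 0.0
    assert entropy(np.full(11, 1 / 11)) == pytest.approx(np.log(11), abs=1e-12)
    assert np.log(11) == pytest.approx(2.3979, abs=5e-5)
    assert entropy(np.array([0.7, 0.2, 0.1])) == pytest.approx(0.8018, abs=5e-5)


def test_entropy_rejects_invalid():
    with pytest.raises(ValueError):
        entropy(np.array([0.5, 0.6]))
    with pytest.raises(ValueError):
        entropy(np.array([1.2, -0.2]))


# -- heads ------------------------------------------------------------------

def test_head_parameter_count_matches_hand_sum(rng):
    head = ExitHead(96, 128, 11, rng=rng)
    assert head.num_parameters() == 96 * 128 + 128 + 128 * 11 + 11 == 13_835


def test_attach_heads_arity(rng):
    model = attach_exit_heads(build_backbone(tiny_config(), seed=0),
                              head_width=16, seed=1)
    model.eval()
    with no_grad():
        outs = model(Tensor(rng.normal(size=(3, 3, 64, 64)).astype(np.float32)))
    assert len(outs) == 4 and all(o.shape == (3, 11) for o in outs)


def test_attach_heads_requires_tap_points():
    class NoTaps:
        tap_channels = []
    with pytest.raises(ValueError, match="tap"):
        from rfcottnet.models.multi_exit import MultiExitModel
        MultiExitModel(NoTaps())  # type: ignore[arg-type]


# -- joint loss -------------------------------------------------------------

def _logits_for_probs(probs):
    return np.log(np.asarray(probs, dtype=np.float64))


def test_joint_loss_zero_when_certain_and_correct():
    z = Tensor(_logits_for_probs([[1 - 2e-9, 1e-9, 1e-9]]))
    report = joint_loss([z, z], np.array([0]))
    assert report.total.item() == pytest.approx(0.0, abs=1e-6)


def test_joint_loss_uniform_is_log_c_per_stage():
    z = Tensor(np.zeros((4, 11)))
    report = joint_loss([z, z, z, z], np.array([0, 3, 7, 10]))
    for l in report.values():
        assert l == pytest.approx(np.log(11), abs=1e-6)
    assert report.total.item() == pytest.approx(4 * np.log(11), abs=1e-5)


def test_joint_loss_matches_hand_arithmetic():
    """2 samples, 2 stages with hand-written probabilities."""
    s1 = _logits_for_probs([[0.7, 0.2, 0.1], [0.1, 0.8, 0.1]])   # labels 0, 1
    s2 = _logits_for_probs([[0.5, 0.25, 0.25], [0.2, 0.6, 0.2]])
    labels = np.array([0, 1])
    report = joint_loss([Tensor(s1), Tensor(s2)], labels, weights=(1.0, 2.0))
    l1 = -(np.log(0.7) + np.log(0.8)) / 2
    l2 = -(np.log(0.5) + np.log(0.6)) / 2
    assert report.values()[0] == pytest.approx(l1, abs=1e-9)
    assert report.values()[1] == pytest.approx(l2, abs=1e-9)
    assert report.total.item() == pytest.approx(l1 + 2 * l2, abs=1e-9)


def test_joint_loss_validates_labels_and_weights():
    z = Tensor(np.zeros((2, 3)))
    with pytest.raises(ValueError):
        joint_loss([z], np.array([0, 3]))
    with pytest.raises(ValueError):
        joint_loss([z, z], np.array([0, 1]), weights=(1.0,))


# -- exit policy / dynamic inference ----------------------------------------

def _pred(stage, conf, C=4):
    rest = (1 - conf) / (C - 1)
    probs = np.full(C, rest)
    probs[0] = conf
    return StagePrediction(stage, np.log(probs), probs, entropy(probs), conf)


def test_policy_first_crossing_scan():
    """Confidences (0.55, 0.72, 0.5) vs thresholds (0.6, 0.7, 0.8) -> stage 2."""
    policy = ExitPolicy(mode="confidence", thresholds=(0.6, 0.7, 0.8))
    confs = (0.55, 0.72, 0.5)
    exit_stage = 4
    for i, c in enumerate(confs, start=1):
        if policy.passes(_pred(i, c)):
            exit_stage = i
            break
    assert exit_stage == 2


def test_policy_strict_inequality_tie_does_not_exit():
    policy = ExitPolicy(mode="confidence", thresholds=(0.6, 0.7, 0.8))
    assert not policy.passes(_pred(1, 0.6))
    assert policy.passes(_pred(1, 0.6 + 1e-9))


def test_policy_final_stage_always_exits():
    policy = ExitPolicy(mode="entropy", thresholds=(0.0, 0.0, 0.0))
    assert policy.passes(_pred(4, 0.25))


def test_policy_validation():
    with pytest.raises(ValueError):
        ExitPolicy(mode="magic")
    with pytest.raises(ValueError):
        ExitPolicy(thresholds=(0.5, 0.5))  # wrong arity for 4 stages
    with pytest.raises(ValueError):
        ExitPolicy(mode="entropy", thresholds=(-1.0, 0.1, 0.1))


def test_one_hot_exits_at_stage_one_in_both_modes():
    p = _pred(1, 1.0 - 1e-12)
    assert ExitPolicy(mode="confidence").passes(p)
    assert ExitPolicy(mode="entropy", thresholds=(0.5, 0.5, 0.5)).passes(p)


# -- cascade on a real (trained) model --------------------------------------

def test_disabled_exits_equal_plain_final_forward(trained_tiny, corpus_arrays):
    """Thresholds above 1 never trigger: output equals the final-head pass."""
    _, _, xte, _ = corpus_arrays
    x = xte[:16]
    policy = ExitPolicy(mode="confidence", thresholds=(1.1, 1.1, 1.1))
    preds = dynamic_inference(x, trained_tiny, policy)
    with no_grad():
        ref = trained_tiny.final_logits(Tensor(x)).data
    assert all(p.stage_index == 4 for p in preds)
    for i, p in enumerate(preds):
        np.testing.assert_array_equal(p.logits, ref[i])


def test_entropy_zero_threshold_never_exits_early(trained_tiny, corpus_arrays):
    _, _, xte, _ = corpus_arrays
    preds = dynamic_inference(xte[:8], trained_tiny,
                              ExitPolicy(mode="entropy", thresholds=(0.0, 0.0, 0.0)))
    assert all(p.stage_index == 4 for p in preds)


def test_threshold_monotonicity(trained_tiny, corpus_arrays):
    """Lowering confidence thresholds never pushes a sample to a later exit."""
    _, _, xte, _ = corpus_arrays
    x = xte[:24]
    loose = dynamic_inference(x, trained_tiny,
                              ExitPolicy(thresholds=(0.3, 0.4, 0.5)))
    tight = dynamic_inference(x, trained_tiny,
                              ExitPolicy(thresholds=(0.6, 0.7, 0.8)))
    for lo, hi in zip(loose, tight):
        assert lo.stage_index <= hi.stage_index


def test_exit_totality_and_eval_counter(trained_tiny, corpus_arrays):
    """Each sample exits exactly once; post-exit stages are not computed."""
    _, _, xte, _ = corpus_arrays
    x = xte[:12]
    trained_tiny.stage_eval_count = 0
    preds = dynamic_inference(x, trained_tiny,
                              ExitPolicy(thresholds=(0.0 + 1e-9,) * 3))
    # a near-zero threshold exits everything at stage 1: only 1 stage evaluated
    assert all(p is not None for p in preds)
    assert trained_tiny.stage_eval_count == 1
    trained_tiny.stage_eval_count = 0
    dynamic_inference(x, trained_tiny, ExitPolicy(thresholds=(1.1, 1.1, 1.1)))
    assert trained_tiny.stage_eval_count == 4


def test_dynamic_inference_rejects_mismatched_policy(trained_tiny, corpus_arrays):
    _, _, xte, _ = corpus_arrays
    with pytest.raises(ValueError):
        dynamic_inference(xte[:2], trained_tiny,
                          ExitPolicy(thresholds=(0.5,), n_stages=2))


# -- exit statistics --------------------------------------------------------

def test_exit_statistics_all_stage_one():
    preds = [_pred(1, 0.9) for _ in range(5)]
    stats = exit_statistics(preds, n_stages=4)
    np.testing.assert_allclose(stats["fractions"], [1, 0, 0, 0])
    assert stats["mean_stage"] == 1.0


def test_exit_statistics_mixed():
    preds = [_pred(s, 0.9) for s in (1, 4, 4, 4)]
    stats = exit_statistics(preds, n_stages=4)
    np.testing.assert_allclose(stats["fractions"], [0.25, 0, 0, 0.75])
    assert stats["mean_stage"] == pytest.approx(3.25)


def test_exit_statistics_rejects_empty():
    with pytest.raises(ValueError):
        exit_statistics([])


# -- gradient coverage ------------------------------------------------------

def test_all_parameters_receive_gradient(rng):
    """With unit stage weights every trainable parameter gets a gradient.

    Run at 128 x 128 so every attention layer sees more than one token per
    group (with a single token the softmax is constant and the score branch
    has a structurally zero gradient).
    """
    model = attach_exit_heads(build_backbone(tiny_config(image_size=128), seed=2),
                              head_width=16, seed=3)
    model.train()
    x = Tensor(rng.normal(0.5, 0.2, size=(4, 3, 128, 128)).astype(np.float32))
    outs = model(x)
    report = joint_loss(outs, np.array([0, 1, 2, 3]))
    report.total.backward()
    missing = [n for n, p in model.named_parameters()
               if p.grad is None or not np.any(p.grad)]
    assert missing == []
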