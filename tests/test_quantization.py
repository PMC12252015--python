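"""Quantize/dequantize laws, fake-quant insertion, QAT, and INT8 export."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rfcottnet.models import (ExitPolicy, attach_exit_heads, build_backbone,
                              dynamic_inference, tiny_config)
from rfcottnet.nn import Tensor, no_grad
from rfcottnet.nn.modules import Linear
from rfcottnet.quant import (QuantSpec, calibrate, dequantize_tensor,
                             export_int8, freeze_quantization,
                             insert_fake_quant, is_frozen, load_int8,
                             qat_finetune, quantize_tensor, QuantLinear)
from rfcottnet.training import accuracy


# -- quantize_tensor --------------------------------------------------------

def test_zeros_map_to_zero_point():
    spec = QuantSpec(scale=0.1, zero_point=3)
    q = quantize_tensor(np.zeros(5), spec)
    assert (q == 3).all()
    np.testing.assert_allclose(dequantize_tensor(q, spec), 0.0)


def test_half_even_rounding_at_symmetric_midpoint():
    """scale 1/127 (range [-1, 1]); 0.5/scale = 63.5 rounds to 64 (even)."""
    spec = QuantSpec(scale=1 / 127, zero_point=0)
    assert quantize_tensor(np.array([0.5]), spec, symmetric=True)[0] == 64
    # and 0.492125... = 62.5/127 rounds down to 62 (even), not 63
    assert quantize_tensor(np.array([62.5 / 127]), spec, symmetric=True)[0] == 62


def test_round_trip_error_bounded_by_half_scale():
    rng = np.random.default_rng(0)
    spec = QuantSpec(scale=2 / 255, zero_point=-1)
    # representable dequant range is [(qmin-zp)*s, (qmax-zp)*s] = [-0.996, 1.004]
    x = rng.uniform(-0.99, 1.0, 500)
    back = dequantize_tensor(quantize_tensor(x, spec), spec)
    assert np.abs(back - x).max() <= spec.scale / 2 + 1e-9


@given(st.lists(st.floats(-3, 3), min_size=2, max_size=50))
@settings(max_examples=100, deadline=None)
def test_quantization_is_order_preserving(values):
    spec = QuantSpec(scale=0.05, zero_point=7)
    x = np.sort(np.asarray(values))
    q = quantize_tensor(x, spec)
    assert (np.diff(q.astype(int)) >= 0).all()


def test_quantize_rejects_bad_inputs():
    with pytest.raises(ValueError):
        quantize_tensor(np.ones(3), QuantSpec(scale=None))
    with pytest.raises(ValueError):
        quantize_tensor(np.array([np.inf]), QuantSpec(scale=0.1))


# -- fake-quant insertion ---------------------------------------------------

def _tiny_model(seed=11, head_width=16):
    return attach_exit_heads(build_backbone(tiny_config(), seed=seed),
                             head_width=head_width, seed=seed + 1)


def test_high_bitwidth_sentinel_is_lossless(rng):
    """At a 40-bit sentinel the quantization step degenerates to the
    identity: wrapped model matches FP32 to 1e-6 (in fact exactly)."""
    model = _tiny_model()
    model.eval()
    x = Tensor(rng.normal(0.5, 0.2, size=(2, 3, 64, 64)).astype(np.float32))
    with no_grad():
        ref = [o.data.copy() for o in model(x)]
    insert_fake_quant(model, QuantSpec(bitwidth=40))
    model.eval()
    with no_grad():
        out = model(x)
    for a, b in zip(ref, out):
        np.testing.assert_allclose(a, b.data, atol=1e-6)


def test_single_linear_fake_quant_matches_hand_arithmetic(rng):
    layer = Linear(4, 3, rng=rng)
    spec = QuantSpec()
    q = QuantLinear(layer, spec)
    q.eval()
    x = rng.normal(size=(5, 4)).astype(np.float32)
    out = q(Tensor(x)).data
    # hand path: per-column symmetric quant-dequant of W, then x@W + b
    w = layer.weight.data
    scales = np.maximum(np.abs(w).max(axis=0), 1e-7) / 127
    scales = scales.astype(np.float16).astype(np.float32)
    wq = (np.clip(np.round(w.astype(np.float64) / scales), -127, 127)
          * scales).astype(np.float32)
    np.testing.assert_allclose(out, x @ wq + layer.bias.data, atol=1e-6)


def test_exit_heads_stay_functional_after_insertion(rng):
    model = _tiny_model()
    insert_fake_quant(model, QuantSpec())
    model.eval()
    with no_grad():
        outs = model(Tensor(rng.normal(0.5, 0.2, (2, 3, 64, 64)).astype(np.float32)))
    assert len(outs) == 4 and all(np.isfinite(o.data).all() for o in outs)


# -- QAT fine-tuning --------------------------------------------------------

def test_qat_finetune_freezes_finite_scales(qat_tiny):
    from rfcottnet.quant import iter_quant_modules
    assert is_frozen(qat_tiny)
    for _, mod in iter_quant_modules(qat_tiny):
        scale, zp = mod.observer.qparams()
        assert np.isfinite(scale) and scale > 0
        assert -128 <= zp <= 127


def test_frozen_model_is_deterministic(qat_tiny, corpus_arrays):
    _, _, xte, _ = corpus_arrays
    x = Tensor(xte[:4])
    with no_grad():
        a = qat_tiny(x)
        b = qat_tiny(x)
    for u, v in zip(a, b):
        np.testing.assert_array_equal(u.data, v.data)


def test_qat_requires_nodes_and_positive_epochs(corpus_arrays):
    xtr, ytr, _, _ = corpus_arrays
    model = _tiny_model()
    with pytest.raises(ValueError, match="fake-quant"):
        qat_finetune(model, xtr[:8], ytr[:8], epochs=1)
    insert_fake_quant(model)
    with pytest.raises(ValueError, match="epochs"):
        qat_finetune(model, xtr[:8], ytr[:8], epochs=0)


def test_int8_accuracy_within_two_points_of_fp32(trained_tiny, qat_tiny,
                                                 corpus_arrays):
    """Quantization parity: INT8 test accuracy within 2 points of FP32."""
    _, _, xte, yte = corpus_arrays
    fp32 = accuracy(trained_tiny, xte, yte)
    int8 = accuracy(qat_tiny, xte, yte)
    assert fp32 >= 0.90
    assert abs(fp32 - int8) <= 0.02


# -- export -----------------------------------------------------------------

def test_export_requires_frozen_ranges(tmp_path):
    model = _tiny_model()
    insert_fake_quant(model)
    with pytest.raises(RuntimeError, match="frozen"):
        export_int8(model, tmp_path / "m.npz")


def test_export_size_law_and_param_count(qat_tiny, tmp_path):
    report = export_int8(qat_tiny, tmp_path / "m.npz")
    assert report.params == qat_tiny.num_parameters()
    # ~1 byte per parameter plus metadata
    assert report.bytes <= 1.05 * (report.params + 200_000)


def test_export_load_reexport_round_trip(qat_tiny, corpus_arrays, tmp_path):
    _, _, xte, _ = corpus_arrays
    p1, p2 = tmp_path / "a.npz", tmp_path / "b.npz"
    export_int8(qat_tiny, p1)
    loaded = load_int8(p1)
    with no_grad():
        ref = qat_tiny(Tensor(xte[:6]))
        out = loaded(Tensor(xte[:6]))
    for a, b in zip(ref, out):
        np.testing.assert_array_equal(a.data, b.data)
    export_int8(loaded, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_int8_exit_decisions_match_fake_quant(qat_tiny, tmp_path, rng):
    """On 100 seeded synthetic inputs the INT8 model exits where the
    fake-quant model exits."""
    path = tmp_path / "m.npz"
    export_int8(qat_tiny, path)
    loaded = load_int8(path)
    x = rng.normal(0.5, 0.25, size=(100, 3, 64, 64)).astype(np.float32).clip(0, 1)
    policy = ExitPolicy()
    a = dynamic_inference(x, qat_tiny, policy)
    b = dynamic_inference(x, loaded, policy)
    assert [p.stage_index for p in a] == [p.stage_index for p in b]
    assert [p.label_index for p in a] == [p.label_index for p in b]


def test_export_size_scales_linearly_with_params(tmp_path, corpus_arrays):
    """Across two widths, file bytes per parameter stay near one."""
    from rfcottnet.models.backbone import BackboneConfig
    sizes = []
    for wm, hw in ((0.125, 16), (0.25, 32)):
        cfg = BackboneConfig(width_multiplier=wm, image_size=64)
        model = attach_exit_heads(build_backbone(cfg, seed=0),
                                  head_width=hw, seed=1)
        insert_fake_quant(model)
        xtr, _, _, _ = corpus_arrays
        calibrate(model, xtr[:8])
        freeze_quantization(model)
        rep = export_int8(model, tmp_path / f"m{wm}.npz")
        sizes.append((rep.params, rep.bytes))
    ratio = [b / p for p, b in sizes]
    assert 0.9 < ratio[0] < 1.4 and 0.9 < ratio[1] < 1.4
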