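"""Confusion-module fusion, FACM semantics, and the prompt paths."""

import numpy as np
import pytest

from agsam.autodiff import Tensor, no_grad
from agsam.profiles import FULL, MINI
from agsam.prompts import (ConfusionModule, DensePromptPath, Facm,
                           FacmConfig, PromptPathConfig, SparsePromptPath,
                           draw_suppression)

rng = np.random.default_rng(0)


# -- FacmConfig / draw semantics ----------------------------------------------


def test_facm_config_invariants_enforced():
    with pytest.raises(ValueError):
        FacmConfig(p_zero=0.6, p_activate=0.5)
    with pytest.raises(ValueError):
        FacmConfig(alpha_range=(0.0, 1.0))
    with pytest.raises(ValueError):
        FacmConfig(status="MAYBE")


def test_alpha_draws_bounded_and_mean_contracts_to_0625():
    """alpha ~ U(0.25, 1): all draws within the range, empirical mean within
    three standard errors of 5/8."""
    cfg = FacmConfig(p_zero=0.0, p_activate=1.0, seed=123)
    alphas = np.array([draw_suppression(cfg, i)[1] for i in range(10_000)])
    assert (alphas >= 0.25).all() and (alphas <= 1.0).all()
    se = (0.75 / np.sqrt(12)) / np.sqrt(len(alphas))
    assert abs(alphas.mean() - 0.625) <= 3 * se


def test_beta_draws_are_zero_mean_in_range():
    cfg = FacmConfig(p_zero=0.0, p_activate=1.0, seed=321)
    betas = np.array([draw_suppression(cfg, i)[2] for i in range(10_000)])
    assert (np.abs(betas) <= 10.0).all()
    se = (20 / np.sqrt(12)) / np.sqrt(len(betas))
    assert abs(betas.mean()) <= 3 * se


def test_zero_mode_frequency_matches_p_zero():
    cfg = FacmConfig(p_zero=0.05, p_activate=0.5, seed=7)
    modes = [draw_suppression(cfg, i)[0] for i in range(10_000)]
    assert abs(modes.count("zero") / 10_000 - 0.05) < 0.01
    assert abs(modes.count("suppress") / 10_000 - 0.45) < 0.02


# -- Facm layer ---------------------------------------------------------------


def _facm(status, stride=1, cin=3, cout=5):
    cfg = FacmConfig(status=status, stride=stride, seed=0)
    return Facm(cin, cout, cfg, np.random.default_rng(1)), cfg


def test_off_state_is_bitwise_a_single_conv():
    layer, _ = _facm("OFF")
    x = Tensor(rng.normal(size=(2, 3, 8, 8)).astype(np.float32))
    with no_grad():
        out = layer(x, rng_draw=0)
        ref = layer.conv(x)
    assert np.array_equal(out.data, ref.data)


def test_on_with_identity_suppression_equals_off():
    layer, _ = _facm("ON")
    x = Tensor(rng.normal(size=(1, 3, 8, 8)).astype(np.float32))
    with no_grad():
        forced = layer(x, forced=(1.0, 0.0))
        plain = layer.conv(x)
    assert np.allclose(forced.data, plain.data)


def test_forced_suppression_arithmetic_on_constant_map():
    """conv output rigged to the constant 10; alpha=0.5, beta=2 gives 7."""
    layer, _ = _facm("ON")
    layer.conv.weight.data *= 0.0
    layer.conv.bias.data[:] = 10.0
    x = Tensor(rng.normal(size=(1, 3, 8, 8)).astype(np.float32))
    with no_grad():
        out = layer(x, forced=(0.5, 2.0))
    assert np.allclose(out.data, 7.0, atol=1e-6)


def test_on_at_inference_behaves_as_off():
    layer, _ = _facm("ON")
    layer.eval()
    x = Tensor(rng.normal(size=(1, 3, 8, 8)).astype(np.float32))
    with no_grad():
        a = layer(x, rng_draw=5)
        layer2, _ = _facm("OFF")
        layer2.conv.load_state_dict(layer.conv.state_dict())
        b = layer2(x, rng_draw=5)
    assert np.array_equal(a.data, b.data)


def test_zero_draw_zeroes_the_feature_map():
    cfg = FacmConfig(status="ON", p_zero=1.0, p_activate=1.0, seed=0)
    layer = Facm(3, 4, cfg, np.random.default_rng(2))
    x = Tensor(rng.normal(size=(1, 3, 8, 8)).astype(np.float32))
    with no_grad():
        out = layer(x, rng_draw=0)
    assert (out.data == 0).all()


# -- fusion -------------------------------------------------------------------


def test_fuse_mini_and_full_contracts():
    fuse = ConfusionModule(MINI, seed=0)
    fa = Tensor(rng.normal(size=(1, 32, 8, 8)).astype(np.float32))
    fs = Tensor(rng.normal(size=(1, 16, 4, 4)).astype(np.float32))
    with no_grad():
        out = fuse(fa, fs)
    assert out.shape == (1, 32, 8, 8)

    fuse_full = ConfusionModule(FULL, seed=0)
    fa = Tensor(np.zeros((1, 2048, 32, 32), dtype=np.float32))
    fs = Tensor(np.zeros((1, 256, 16, 16), dtype=np.float32))
    with no_grad():
        out = fuse_full(fa, fs)
    assert out.shape == (1, 2048, 32, 32)


def test_fuse_grid_mismatch_rejected():
    fuse = ConfusionModule(MINI, seed=0)
    with pytest.raises(ValueError):
        fuse(Tensor(np.zeros((1, 32, 6, 6), dtype=np.float32)),
             Tensor(np.zeros((1, 16, 4, 4), dtype=np.float32)))


def test_fuse_with_identity_agent_half_passes_agent_through():
    """Rig the 1x1 squeeze to the identity on the agent half and zero on the
    aligned half: with f_sam = 0 the fused feature equals f_agent."""
    fuse = ConfusionModule(MINI, seed=0)
    d = MINI.agent_dim
    w = np.zeros((d, 2 * d, 1, 1), dtype=np.float32)
    for i in range(d):
        w[i, i, 0, 0] = 1.0
    fuse.squeeze.weight.data = w
    fuse.squeeze.bias.data[:] = 0.0
    fa = Tensor(rng.normal(size=(1, d, 8, 8)).astype(np.float32))
    fs = Tensor(np.zeros((1, 16, 4, 4), dtype=np.float32))
    with no_grad():
        out = fuse(fa, fs)
    assert np.allclose(out.data, fa.data, atol=1e-5)


# -- prompt paths -------------------------------------------------------------


def test_sparse_path_mini_token_contract():
    path = SparsePromptPath(MINI, PromptPathConfig(hidden=16), FacmConfig(),
                            seed=0)
    mask = Tensor(rng.uniform(size=(2, 4, 64, 64)).astype(np.float32))
    with no_grad():
        tok = path(mask)
    assert tok.shape == (2, 4, 16)


def test_sparse_path_full_grid_is_sixteenth_of_input():
    path = SparsePromptPath(FULL, PromptPathConfig(hidden=32), FacmConfig(),
                            seed=0)
    mask = Tensor(np.zeros((1, 4, 256, 256), dtype=np.float32))
    with no_grad():
        y = path.stack(mask)
    assert y.shape[2:] == (16, 16)          # 256 / 16


def test_total_downsampling_invariant_checked_by_config():
    with pytest.raises(ValueError):
        PromptPathConfig(stride2_count=2)    # 2 * 2^2 != 16


def test_dense_path_contracts():
    path = DensePromptPath(MINI, PromptPathConfig(hidden=16), FacmConfig(),
                           seed=0)
    f = Tensor(rng.normal(size=(1, 32, 8, 8)).astype(np.float32))
    with no_grad():
        out = path(f)
    assert out.shape == (1, 16, 4, 4)


def test_prompt_paths_deterministic_with_all_facm_off():
    cfg = PromptPathConfig(hidden=16).all_off()
    sp = SparsePromptPath(MINI, cfg, FacmConfig(), seed=0)
    dp = DensePromptPath(MINI, cfg, FacmConfig(), seed=0)
    mask = Tensor(rng.uniform(size=(1, 4, 64, 64)).astype(np.float32))
    f = Tensor(rng.normal(size=(1, 32, 8, 8)).astype(np.float32))
    with no_grad():
        assert np.array_equal(sp(mask, 0).data, sp(mask, 99).data)
        assert np.array_equal(dp(f, 0).data, dp(f, 99).data)


def test_dense_path_is_homogeneous_linear_in_rigged_configuration():
    """All FACMs OFF, no inter-layer nonlinearity, biases zeroed: doubling
    the fused feature doubles the dense prompt."""
    cfg = PromptPathConfig(hidden=16, nonlinearity=False).all_off()
    dp = DensePromptPath(MINI, cfg, FacmConfig(), seed=0)
    for name, p in dp.named_parameters():
        if name.endswith("bias_"):
            p.data *= 0.0
    f = Tensor(rng.normal(size=(1, 32, 8, 8)).astype(np.float32))
    with no_grad():
        y1 = dp(f).data
        y2 = dp(f * 2.0).data
    assert np.allclose(y2, 2.0 * y1, rtol=1e-4, atol=1e-5)
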