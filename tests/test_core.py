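"""Assembled model: mask fusion identities, dual Dice loss, training-step
semantics, schedule, determinism, and ablation equivalences."""

import numpy as np
import pytest

from agsam.autodiff import Tensor, no_grad
from agsam.backbone import AgentDecoder, AgentEncoder, normalize_images
from agsam.core import (Agsam, TrainConfig, dice_loss, fit, lr_at_epoch,
                        train_step)
from agsam.data import AugmentConfig
from agsam.nn import AdamW, checksum_state
from agsam.phantom import PhantomSpec, generate_phantom
from agsam.profiles import MINI


def _model(pair, **kw):
    cfg = TrainConfig(seed=0, epochs=2, batch_size=2, **kw)
    return Agsam(MINI, pair, cfg), cfg


# -- mask fusion --------------------------------------------------------------


def test_fusion_alpha_zero_returns_decoder_mask(pretrained_pair,
                                                phantom_batch):
    images, _ = phantom_batch
    model, _ = _model(pretrained_pair, fusion_alpha=0.0)
    model.eval()
    with no_grad():
        ma, ms, mp = model.forward(normalize_images(images[:1]))
    assert np.allclose(mp.data, ms.data, atol=1e-7)


def test_fusion_alpha_one_returns_agent_mask(pretrained_pair, phantom_batch):
    images, _ = phantom_batch
    model, _ = _model(pretrained_pair, fusion_alpha=1.0)
    model.eval()
    with no_grad():
        ma, ms, mp = model.forward(normalize_images(images[:1]))
    assert np.allclose(mp.data, ma.data, atol=1e-7)


def test_fusion_worked_pixel_example():
    sam = Tensor(np.array([0.8], dtype=np.float32))
    agent = Tensor(np.array([0.4], dtype=np.float32))
    fused = sam * (1 - 0.25) + agent * 0.25
    assert np.isclose(fused.data[0], 0.7, atol=1e-7)


def test_fused_mask_is_convex_combination_per_pixel(pretrained_pair,
                                                    phantom_batch):
    images, _ = phantom_batch
    for alpha in (0.1, 0.25, 0.5, 0.9):
        model, _ = _model(pretrained_pair, fusion_alpha=alpha)
        model.eval()
        with no_grad():
            ma, ms, mp = model.forward(normalize_images(images[:1]))
        lo = np.minimum(ma.data, ms.data) - 1e-6
        hi = np.maximum(ma.data, ms.data) + 1e-6
        assert (mp.data >= lo).all() and (mp.data <= hi).all()
        assert np.allclose(mp.data.sum(axis=1), 1.0, atol=1e-5)


# -- dice loss ----------------------------------------------------------------


def test_dice_loss_zero_for_exact_one_hot():
    target = np.array([[0, 1], [1, 0]])
    onehot = (target[None] == np.arange(2)[:, None, None]).astype(np.float32)
    loss = dice_loss(Tensor(onehot[None]), target)
    assert float(loss.data) < 1e-5


def test_dice_loss_uniform_half_and_half_is_half():
    """Two classes, 4 pixels each; uniform prediction 1/2 per channel gives
    per-channel dice (2*(0.5*4))/(4+4)=0.5 and loss 0.5."""
    target = np.array([[0, 0, 0, 0], [1, 1, 1, 1]])
    pred = Tensor(np.full((1, 2, 2, 4), 0.5, dtype=np.float32))
    assert np.isclose(float(dice_loss(pred, target).data), 0.5, atol=1e-6)


def test_dice_loss_monotone_as_mass_moves_to_target():
    target = np.array([[1]])
    losses = []
    for p in np.linspace(0.05, 0.95, 10):
        pred = Tensor(np.array([[[[1 - p]], [[p]]]], dtype=np.float32))
        losses.append(float(dice_loss(pred, target).data))
    assert all(a > b for a, b in zip(losses, losses[1:]))


# -- training steps -----------------------------------------------------------


def test_loss_breakdown_additivity(pretrained_pair, phantom_batch):
    images, masks = phantom_batch
    model, _ = _model(pretrained_pair)
    opt = AdamW(model.parameters(), lr=1e-4)
    lb = train_step((images[:2], masks[:2]), model, opt)
    assert lb.l_all == pytest.approx(lb.l_agent + lb.l_pred, abs=1e-6)
    assert lb.l_agent >= 0 and lb.l_pred >= 0


def test_zero_learning_rate_leaves_parameters_unchanged(pretrained_pair,
                                                        phantom_batch):
    images, masks = phantom_batch
    model, _ = _model(pretrained_pair)
    before = checksum_state(model)
    opt = AdamW(model.parameters(), lr=0.0, weight_decay=0.0)
    train_step((images[:2], masks[:2]), model, opt)
    assert checksum_state(model) == before


def test_optimization_reduces_loss_on_single_phantom(pretrained_pair):
    s = generate_phantom(PhantomSpec(style="cardiac", image_side=64,
                                     seed=77), 0)
    batch = (s.image[None], s.mask[None])
    model, _ = _model(pretrained_pair)
    opt = AdamW(model.parameters(), lr=1e-3)
    losses = [train_step(batch, model, opt, rng_draw=i).l_all
              for i in range(50)]
    assert min(losses) < losses[0]


def test_frozen_foundation_untouched_by_training(pretrained_pair,
                                                 phantom_batch):
    images, masks = phantom_batch
    before = pretrained_pair.checksum()
    model, _ = _model(pretrained_pair)
    opt = AdamW(model.parameters(), lr=1e-3)
    for i in range(3):
        train_step((images[:2], masks[:2]), model, opt, rng_draw=i)
    assert pretrained_pair.checksum() == before


# -- schedule / config --------------------------------------------------------


def test_default_schedule_matches_training_protocol():
    cfg = TrainConfig()
    assert cfg.epochs == 50 and cfg.batch_size == 8
    assert lr_at_epoch(cfg, 0) == pytest.approx(1e-4)     # epoch 1
    assert lr_at_epoch(cfg, 24) == pytest.approx(1e-4)    # epoch 25
    assert lr_at_epoch(cfg, 25) == pytest.approx(1e-5)    # epoch 26
    assert lr_at_epoch(cfg, 29) == pytest.approx(1e-5)    # epoch 30


def test_config_invariants():
    with pytest.raises(ValueError):
        TrainConfig(fusion_alpha=1.5)
    with pytest.raises(ValueError):
        TrainConfig(epochs=5, decay_epoch=7)
    with pytest.raises(ValueError):
        TrainConfig(use_foundation_encoder=False,
                    use_foundation_decoder=True)


# -- fit ----------------------------------------------------------------------


def _tiny_fit(pair, seed=0):
    spec = PhantomSpec(style="cardiac", image_side=64, seed=50)
    train = [generate_phantom(spec, i) for i in range(2)]
    val = [generate_phantom(spec, i) for i in range(2, 4)]
    cfg = TrainConfig(seed=seed, epochs=2, batch_size=4, lr_initial=1e-3,
                      lr_decayed=1e-4, decay_epoch=2)
    model = Agsam(MINI, pair, cfg)
    res = fit(model, train, val, cfg, AugmentConfig(replicate_to=8, seed=seed))
    return model, res


def test_fit_history_and_best_epoch(pretrained_pair):
    _, res = _tiny_fit(pretrained_pair)
    assert len(res.history) == 2
    assert res.best_epoch in (0, 1)
    assert res.history[0]["lr"] == pytest.approx(1e-3)
    assert res.history[1]["lr"] == pytest.approx(1e-4)
    for h in res.history:
        for la, lp, lall in h["steps"]:
            assert lall == pytest.approx(la + lp, abs=1e-6)


def test_fit_is_deterministic_in_seed(pretrained_pair):
    _, r1 = _tiny_fit(pretrained_pair, seed=3)
    _, r2 = _tiny_fit(pretrained_pair, seed=3)
    assert r1.history == r2.history


# -- ablation semantics -------------------------------------------------------


def test_all_off_flags_reproduce_standalone_agent(phantom_batch):
    """FE=MD=FACM=off is exactly the agent baseline: identical outputs to the
    encoder/decoder pair run standalone with the same weights."""
    images, _ = phantom_batch
    cfg = TrainConfig(seed=5, epochs=2, use_foundation_encoder=False,
                      use_foundation_decoder=False, use_facm=False)
    model = Agsam(MINI, None, cfg)
    model.eval()
    enc = AgentEncoder(MINI, variant="tiny", seed=5)
    dec = AgentDecoder(MINI, seed=5)
    enc.eval(); dec.eval()
    x = normalize_images(images[:2])
    with no_grad():
        ma, ms, mp = model.forward(x)
        ref = dec(enc(x))
    assert ms is None
    assert np.array_equal(mp.data, ma.data)
    assert np.array_equal(ma.data, ref.data)


def test_md_without_fe_rejected():
    with pytest.raises(ValueError, match="MD requires FE"):
        TrainConfig(use_foundation_encoder=False,
                    use_foundation_decoder=True)
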