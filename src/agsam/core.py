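"""Model assembly, dual Dice loss, training loop and ablation protocol.

The assembled model runs: agent encode -> (optionally) fuse with the frozen
foundation embedding -> agent decode -> generate sparse/dense prompts ->
frozen foundation decode -> weighted mask fusion

    mask_pred = (1 - alpha) * mask_sam + alpha * mask_agent

applied to probability maps channel-wise, so the prediction stays a convex
combination (and rows still sum to 1).  Training minimises

    L_all = L_agent + L_pred

with Dice losses against the same annotation; gradients flow through the
frozen decoder to the prompt paths without ever mutating frozen weights.

Ablation switches reproduce the module grid: FE (foundation encoder fused
into the agent), MD (foundation mask decoder driven by generated prompts),
FACM (stochastic suppression in the first prompt layer).  With all three
off the model is exactly the agent baseline.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .autodiff import Tensor, no_grad
from .backbone import AgentDecoder, AgentEncoder, normalize_images
from .data import AugmentConfig, ImageSample, Manifest, replicate_training_set
from .foundation import FoundationPair, PromptPair
from .nn import AdamW, Module
from .profiles import ScaleProfile
from .prompts import (ConfusionModule, DensePromptPath, FacmConfig,
                      PromptPathConfig, SparsePromptPath)

__all__ = ["TrainConfig", "LossBreakdown", "Agsam", "dice_loss",
           "train_step", "fit", "run_ablation", "mean_foreground_dice",
           "lr_at_epoch", "ABLATION_GRID"]


@dataclass(frozen=True)
class TrainConfig:
    """Training settings.

    Defaults follow the reference protocol: 512 augmented copies, 50 epochs,
    batch size 8, AdamW at 1e-4 decaying to 1e-5 from epoch 26, Dice loss.
    ``fusion_alpha`` is the agent weight in the mask fusion (the strong
    setting 0.25 is the default; 0.1/0.3/0.5 are common sweep values).
    """

    fusion_alpha: float = 0.25
    epochs: int = 50
    batch_size: int = 8
    lr_initial: float = 1e-4
    lr_decayed: float = 1e-5
    decay_epoch: int | None = None   # default: min(26, epochs)
    weight_decay: float = 0.01
    seed: int = 0
    use_foundation_encoder: bool = True
    use_foundation_decoder: bool = True
    use_facm: bool = True

    def __post_init__(self):
        if not 0.0 <= self.fusion_alpha <= 1.0:
            raise ValueError("fusion_alpha must lie in [0, 1]")
        if self.decay_epoch is None:
            object.__setattr__(self, "decay_epoch", min(26, self.epochs))
        if self.decay_epoch > self.epochs:
            raise ValueError("decay_epoch must not exceed epochs")
        if self.use_foundation_decoder and not self.use_foundation_encoder:
            raise ValueError("the mask-decoder stage requires the "
                             "foundation-encoder stage (MD requires FE)")


@dataclass(frozen=True)
class LossBreakdown:
    l_agent: float
    l_pred: float
    l_all: float


class Agsam(Module):
    """The assembled agent-guided model.

    The frozen foundation pair is held by reference and is *not* part of the
    trainable state; ``state_dict()`` covers only the agent, fusion and
    prompt-path weights.
    """

    def __init__(self, profile: ScaleProfile, foundation: FoundationPair | None,
                 cfg: TrainConfig, variant: str = "tiny",
                 path_cfg: PromptPathConfig | None = None,
                 facm_cfg: FacmConfig | None = None, seed: int | None = None):
        super().__init__()
        seed = cfg.seed if seed is None else seed
        self.profile = profile
        self.cfg = cfg
        self.foundation = foundation
        if (cfg.use_foundation_encoder or cfg.use_foundation_decoder) \
                and foundation is None:
            raise ValueError("ablation flags require a foundation pair")

        self.encoder = AgentEncoder(profile, variant=variant, seed=seed)
        self.decoder = AgentDecoder(profile, seed=seed)

        path_cfg = path_cfg or PromptPathConfig(
            hidden=16 if profile.input_side < 256 else 64)
        if not cfg.use_facm:
            path_cfg = path_cfg.all_off()
        facm_cfg = facm_cfg or FacmConfig(seed=seed)
        self.path_cfg, self.facm_cfg = path_cfg, facm_cfg

        if cfg.use_foundation_encoder:
            self.fuse = ConfusionModule(profile, seed=seed)
        if cfg.use_foundation_decoder:
            self.sparse_path = SparsePromptPath(profile, path_cfg, facm_cfg,
                                                seed=seed)
            self.dense_path = DensePromptPath(profile, path_cfg, facm_cfg,
                                              seed=seed)

    # -- forward --------------------------------------------------------------

    def forward(self, x: Tensor, rng_draw: int = 0):
        """Return ``(mask_agent, mask_sam, mask_pred)``; ``mask_sam`` is None
        when the foundation decoder stage is ablated."""
        cfg = self.cfg
        f_agent = self.encoder(x)

        if cfg.use_foundation_encoder:
            emb = self.foundation.encode(x)
            f_fused = self.fuse(f_agent, emb)
        else:
            emb, f_fused = None, f_agent

        mask_agent = self.decoder(f_fused)

        if not cfg.use_foundation_decoder:
            return mask_agent, None, mask_agent

        sparse = self.sparse_path(mask_agent, rng_draw=rng_draw)
        dense = self.dense_path(f_fused, rng_draw=rng_draw)
        mask_sam = self.foundation.decode(emb, PromptPair(sparse, dense))
        a = cfg.fusion_alpha
        mask_pred = mask_sam * (1.0 - a) + mask_agent * a
        return mask_agent, mask_sam, mask_pred

    def predict(self, images: np.ndarray, rng_draw: int = 0) -> np.ndarray:
        """Class-label prediction (argmax of the fused probability map)."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                _, _, pred = self.forward(normalize_images(images),
                                          rng_draw=rng_draw)
        finally:
            self.train(was_training)
        return np.argmax(pred.data, axis=1)

    def predict_probs(self, images: np.ndarray) -> np.ndarray:
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                _, _, pred = self.forward(normalize_images(images))
        finally:
            self.train(was_training)
        return pred.data


def dice_loss(pred: Tensor, target: np.ndarray, eps: float = 1e-6) -> Tensor:
    """Soft Dice loss: ``1 - mean_channels (2 sum(p*g) + eps) /
    (sum(p) + sum(g) + eps)`` with one-hot targets; lies in [0, 1]."""
    target = np.asarray(target)
    if target.ndim == 2:
        target = target[None]
    n, k = pred.shape[0], pred.shape[1]
    onehot = (target[:, None] == np.arange(k)[None, :, None, None])
    g = Tensor(onehot.astype(np.float32))
    inter = (pred * g).sum(axis=(2, 3))
    denom = pred.sum(axis=(2, 3)) + g.data.sum(axis=(2, 3))
    dice = (inter * 2.0 + eps) / (denom + eps)
    return 1.0 - dice.mean()


def train_step(batch: tuple[np.ndarray, np.ndarray], model: Agsam,
               opt: AdamW, rng_draw: int = 0) -> LossBreakdown:
    """One optimisation step on a batch ``(images, masks)``; returns the
    loss breakdown with ``l_all = l_agent + l_pred`` exactly."""
    images, masks = batch
    x = normalize_images(images)
    mask_agent, _, mask_pred = model.forward(x, rng_draw=rng_draw)
    l_agent = dice_loss(mask_agent, masks)
    l_pred = dice_loss(mask_pred, masks)
    l_all = l_agent + l_pred
    if not np.isfinite(l_all.data):
        raise FloatingPointError(
            f"training diverged: l_agent={float(l_agent.data)}, "
            f"l_pred={float(l_pred.data)}")
    opt.zero_grad()
    l_all.backward()
    opt.step()
    return LossBreakdown(l_agent=float(l_agent.data),
                         l_pred=float(l_pred.data),
                         l_all=float(l_all.data))


def mean_foreground_dice(pred_labels: np.ndarray, gt: np.ndarray,
                         n_classes: int) -> float:
    """Mean Dice over foreground classes (both-empty classes count 1)."""
    from .metrics import dice
    vals = [dice(pred_labels, gt, c) for c in range(1, n_classes + 1)]
    return float(np.mean(vals))


def lr_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    """Stepped schedule: ``lr_initial`` before ``decay_epoch`` (1-based),
    ``lr_decayed`` from it onward."""
    return cfg.lr_initial if (epoch + 1) < cfg.decay_epoch else cfg.lr_decayed


@dataclass
class FitResult:
    history: list[dict]
    best_epoch: int
    best_val_dice: float


def _val_dice(model: Agsam, samples: list[ImageSample]) -> float:
    scores = []
    for s in samples:
        labels = model.predict(s.image)[0]
        scores.append(mean_foreground_dice(labels, s.mask,
                                           model.profile.n_classes))
    return float(np.mean(scores))


def fit(model: Agsam, train: Manifest | list[ImageSample],
        val: Manifest | list[ImageSample], cfg: TrainConfig | None = None,
        augment: AugmentConfig | None = None) -> FitResult:
    """Full training protocol: replicate the few-shot set by augmentation,
    train with the stepped learning-rate schedule, track validation mean
    foreground Dice per epoch, and restore the best-epoch weights."""
    cfg = cfg or model.cfg
    augment = augment or AugmentConfig(seed=cfg.seed)
    val_samples = val.load_all() if isinstance(val, Manifest) else list(val)
    if (isinstance(train, Manifest) and len(train) == 0) or not val_samples:
        raise ValueError("train and val sets must be nonempty")

    pool = replicate_training_set(train, augment)
    images = np.stack([s.image for s in pool])
    masks = np.stack([s.mask for s in pool])

    frozen_before = model.foundation.checksum() if model.foundation else None
    opt = AdamW(model.parameters(), lr=cfg.lr_initial,
                weight_decay=cfg.weight_decay)
    history: list[dict] = []
    best = (-1.0, -1, None)          # (val dice, epoch, state)
    step_counter = 0
    model.train()

    for epoch in range(cfg.epochs):
        opt.lr = lr_at_epoch(cfg, epoch)
        order = np.random.default_rng([int(cfg.seed), 40 + epoch]) \
            .permutation(len(pool))
        steps = []
        for start in range(0, len(pool), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            lb = train_step((images[idx], masks[idx]), model, opt,
                            rng_draw=step_counter)
            steps.append(lb)
            step_counter += 1
        vd = _val_dice(model, val_samples)
        model.train()
        history.append(dict(
            epoch=epoch, lr=opt.lr, val_dice=vd,
            l_agent=float(np.mean([s.l_agent for s in steps])),
            l_pred=float(np.mean([s.l_pred for s in steps])),
            l_all=float(np.mean([s.l_all for s in steps])),
            steps=[(s.l_agent, s.l_pred, s.l_all) for s in steps]))
        if vd > best[0]:
            best = (vd, epoch, copy.deepcopy(model.state_dict()))

    if best[2] is not None:
        model.load_state_dict(best[2])
    model.eval()

    if frozen_before is not None:
        frozen_after = model.foundation.checksum()
        if frozen_after != frozen_before:
            raise RuntimeError("frozen foundation weights changed during "
                               "fit(); freezing invariant violated")
    return FitResult(history=history, best_epoch=best[1],
                     best_val_dice=best[0])


ABLATION_GRID = (
    (False, False, False),
    (True, False, False),
    (True, True, False),
    (True, True, True),
)


def run_ablation(train: Manifest | list[ImageSample],
                 val: Manifest | list[ImageSample],
                 test: Manifest | list[ImageSample],
                 profile: ScaleProfile, foundation: FoundationPair,
                 base_cfg: TrainConfig, augment: AugmentConfig | None = None,
                 variant: str = "tiny",
                 grid=ABLATION_GRID) -> list[dict]:
    """Train and evaluate one model per (FE, MD, FACM) flag combination.

    MD without FE is rejected.  Returns one row per combination with held-out
    mean foreground Dice and Hausdorff distance.
    """
    from .metrics import evaluate_samples

    test_samples = test.load_all() if isinstance(test, Manifest) else list(test)
    rows = []
    for fe, md, facm in grid:
        if md and not fe:
            raise ValueError("MD requires FE")
        cfg = replace(base_cfg, use_foundation_encoder=fe,
                      use_foundation_decoder=md, use_facm=facm)
        model = Agsam(profile, foundation if fe else None, cfg,
                      variant=variant)
        fit(model, train, val, cfg, augment)
        table = evaluate_samples(model, test_samples, profile.n_classes)
        fg = table[table["cls"] > 0]
        rows.append(dict(FE=fe, MD=md, FACM=facm,
                         mean_dice=float(fg["dice"].mean()),
                         mean_hd=float(fg["hd"].mean())))
    return rows
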