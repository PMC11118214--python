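"""The frozen pre-trained encoder/decoder pair and its seeded surrogate.

The contract mirrors a promptable foundation segmenter: an image encoder
producing an embedding ``[sam_dim, S/16, S/16]`` and a mask decoder that
consumes the embedding plus sparse/dense prompt embeddings and emits a
joint ``(n_classes+1)``-channel probability map.  Real external checkpoints
would attach behind the same interface (see ``ExternalCheckpointAdapter``);
the package ships a surrogate that is small enough to pre-train on synthetic
phantoms in seconds and then freeze.

Freezing stops weight updates but *not* gradient flow: prompt tensors
receive gradients through the frozen decoder, which is what makes automatic
prompt learning possible.

At full scale the encoder reproduces the ViT-b shape pipeline (16x16
patchify, 12 transformer blocks of width 768 with 12 heads, then two convs
down to 256 channels).  At mini scale a strided conv stack with one
attention layer keeps the same shape contract at a CPU-friendly size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, no_grad
from .nn import (AdamW, Conv2d, ConvTranspose2d, GroupNorm2d, LayerNorm,
                 Linear, Module, MultiHeadAttention, ReLU, Sequential,
                 checksum_state)
from .profiles import ScaleProfile

__all__ = ["PromptPair", "FoundationPair", "build_surrogate",
           "oracle_prompts", "ExternalCheckpointAdapter"]


@dataclass
class PromptPair:
    """Sparse token embeddings + dense spatial embeddings for the decoder."""

    sparse: Tensor     # [N, n_classes+1, prompt_dim]
    dense: Tensor      # [N, prompt_dim, sam_grid, sam_grid]


class _TransformerBlock(Module):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator,
                 mlp_ratio: int = 4):
        super().__init__()
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadAttention(dim, heads, rng)
        self.ln2 = LayerNorm(dim)
        self.fc1 = Linear(dim, dim * mlp_ratio, rng)
        self.fc2 = Linear(dim * mlp_ratio, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.ln1(x)
        x = x + self.attn(h, h, h)
        h = self.ln2(x)
        return x + self.fc2(self.fc1(h).relu())


class VitEncoder(Module):
    """ViT-b-shaped image encoder: patchify, 12 transformer layers of width
    768 with 12 heads, then two convolutions down to ``sam_dim``."""

    def __init__(self, profile: ScaleProfile, rng: np.random.Generator,
                 depth: int = 12, width: int = 768, heads: int = 12):
        super().__init__()
        self.profile = profile
        g = profile.input_side // 16
        self.grid = g
        self.patch = Conv2d(3, width, 16, rng, stride=16, padding=0)
        pos = rng.normal(0.0, 0.02, (g * g, width))
        self.register("pos_embed", Tensor(pos, requires_grad=True))
        self.blocks = Sequential(*[_TransformerBlock(width, heads, rng)
                                   for _ in range(depth)])
        self.neck1 = Conv2d(width, profile.sam_dim, 1, rng, bias=False)
        self.neck2 = Conv2d(profile.sam_dim, profile.sam_dim, 3, rng,
                            bias=False)
        self.width = width

    def forward(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        g, w = self.grid, self.width
        tok = self.patch(x).reshape(n, w, g * g).transpose(0, 2, 1)
        tok = tok + self.pos_embed
        tok = self.blocks(tok)
        fmap = tok.transpose(0, 2, 1).reshape(n, w, g, g)
        return self.neck2(self.neck1(fmap))


class ConvEncoder(Module):
    """Mini-scale frozen encoder: strided convs to the /16 grid plus one
    attention layer over grid tokens."""

    def __init__(self, profile: ScaleProfile, rng: np.random.Generator):
        super().__init__()
        self.profile = profile
        d = profile.sam_dim
        c1 = max(d // 2, 8)
        self.net = Sequential(
            Conv2d(3, c1, 3, rng, stride=2, bias=False),
            GroupNorm2d(c1), ReLU(),
            Conv2d(c1, c1, 3, rng, stride=2, bias=False),
            GroupNorm2d(c1), ReLU(),
            Conv2d(c1, d, 3, rng, stride=2, bias=False),
            GroupNorm2d(d), ReLU(),
            Conv2d(d, d, 3, rng, stride=2, bias=False),
        )
        heads = max(1, d // 8)
        while d % heads:
            heads -= 1
        self.attn = MultiHeadAttention(d, heads, rng)
        self.ln = LayerNorm(d)

    def forward(self, x: Tensor) -> Tensor:
        p = self.profile
        f = self.net(x)                                  # [N, d, g, g]
        n, d, g, _ = f.shape
        tok = f.reshape(n, d, g * g).transpose(0, 2, 1)
        h = self.ln(tok)
        tok = tok + self.attn(h, h, h)
        return tok.transpose(0, 2, 1).reshape(n, d, g, g)


class _TwoWayBlock(Module):
    """Cross-attention block: tokens attend themselves and the image;
    the image attends the tokens back.

    Residual branches (attention output projections and the MLP's second
    layer) start at zero, so the block is the identity at initialisation.
    This keeps the class information carried by the prompt tokens intact at
    the start of pre-training and makes short optimisation runs converge
    reliably instead of collapsing to the background class.
    """

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        super().__init__()
        self.self_attn = MultiHeadAttention(dim, heads, rng)
        self.ln1 = LayerNorm(dim)
        self.t2i = MultiHeadAttention(dim, heads, rng)
        self.ln2 = LayerNorm(dim)
        self.fc1 = Linear(dim, dim * 2, rng)
        self.fc2 = Linear(dim * 2, dim, rng)
        self.ln3 = LayerNorm(dim)
        self.i2t = MultiHeadAttention(dim, heads, rng)
        self.ln4 = LayerNorm(dim)
        for att in (self.self_attn, self.t2i, self.i2t):
            att.out.weight.data *= 0.0
        self.fc2.weight.data *= 0.0

    def forward(self, tokens: Tensor, img: Tensor):
        tokens = self.ln1(tokens + self.self_attn(tokens, tokens, tokens))
        tokens = self.ln2(tokens + self.t2i(tokens, img, img))
        tokens = self.ln3(tokens + self.fc2(self.fc1(tokens).relu()))
        img = self.ln4(img + self.i2t(img, tokens, tokens))
        return tokens, img


class MaskDecoder(Module):
    """Prompt-conditioned mask decoder.

    The dense prompt is added to the image embedding; sparse tokens interact
    with the image tokens through two two-way cross-attention blocks; the
    image tokens are upscaled by two transposed convolutions and each class
    token is turned into a per-pixel linear classifier over the upscaled
    feature (a hypernetwork head), followed by a channel softmax.
    """

    def __init__(self, profile: ScaleProfile, rng: np.random.Generator):
        super().__init__()
        self.profile = profile
        d = profile.prompt_dim
        if d != profile.sam_dim:
            raise ValueError("prompt_dim must equal sam_dim for additive "
                             "dense-prompt fusion")
        heads = max(1, d // 8)
        while d % heads:
            heads -= 1
        self.block1 = _TwoWayBlock(d, heads, rng)
        self.block2 = _TwoWayBlock(d, heads, rng)
        c_up = max(d // 2, 8)
        self.up1 = ConvTranspose2d(d, c_up, 2, rng, stride=2)
        self.n1 = GroupNorm2d(c_up)
        self.up2 = ConvTranspose2d(c_up, c_up, 2, rng, stride=2)
        self.hyper = Linear(d, c_up, rng)
        self.c_up = c_up

    def forward(self, embedding: Tensor, prompts: PromptPair) -> Tensor:
        p = self.profile
        n, d, g, _ = embedding.shape
        n_tok = prompts.sparse.shape[1]
        if n_tok != p.n_classes + 1:
            raise ValueError(f"expected {p.n_classes + 1} sparse tokens, "
                             f"got {n_tok}")
        if prompts.dense.shape[1:] != (d, g, g):
            raise ValueError("dense prompt does not match embedding grid")
        src = embedding + prompts.dense
        img = src.reshape(n, d, g * g).transpose(0, 2, 1)
        tokens = prompts.sparse
        tokens, img = self.block1(tokens, img)
        tokens, img = self.block2(tokens, img)
        fmap = img.transpose(0, 2, 1).reshape(n, d, g, g)
        feat = self.n1(self.up1(fmap)).relu()
        feat = self.up2(feat).relu()                     # [N, c_up, 4g, 4g]
        feat = feat.resize_bilinear(p.input_side, p.input_side)
        w = self.hyper(tokens)                           # [N, n_tok, c_up]
        s = p.input_side
        logits = (w @ feat.reshape(n, self.c_up, s * s)).reshape(
            n, n_tok, s, s)
        return logits.softmax(axis=1)


@dataclass
class FoundationPair:
    """A frozen encoder/decoder pair plus the fixed projection matrices used
    to render oracle prompts from ground-truth masks during surrogate
    pre-training."""

    encoder: Module
    decoder: Module
    profile: ScaleProfile
    provenance: str
    oracle_class_proj: np.ndarray   # [n_classes+1, prompt_dim]
    oracle_stat_proj: np.ndarray    # [3, prompt_dim]
    oracle_dense_proj: np.ndarray   # [n_classes+1, prompt_dim]
    frozen: bool = True

    def encode(self, images: Tensor) -> Tensor:
        p = self.profile
        emb = self.encoder(images)
        expected = (p.sam_dim, p.sam_grid, p.sam_grid)
        if emb.shape[1:] != expected:
            raise RuntimeError(f"embedding shape {emb.shape[1:]} != "
                               f"{expected}")
        return emb

    def decode(self, embedding: Tensor, prompts: PromptPair) -> Tensor:
        return self.decoder(embedding, prompts)

    def checksum(self) -> str:
        return checksum_state(self.encoder) + checksum_state(self.decoder)


def oracle_prompts(pair: FoundationPair, masks: np.ndarray) -> PromptPair:
    """Render prompts directly from ground-truth masks (agent-free).

    Sparse token k = fixed class embedding + (area, centroid row/col of
    class k) through a fixed projection; dense prompt = one-hot mask
    average-pooled to the embedding grid, projected to ``prompt_dim``.
    Used only for surrogate pre-training; the trained pipeline generates
    prompts from the agent instead.
    """
    p = pair.profile
    masks = np.asarray(masks)
    if masks.ndim == 2:
        masks = masks[None]
    n, s, _ = masks.shape
    k = p.n_classes + 1
    onehot = (masks[:, None] == np.arange(k)[None, :, None, None])
    onehot = onehot.astype(np.float32)

    rows = (np.arange(s, dtype=np.float32) + 0.5) / s
    area = onehot.mean(axis=(2, 3))                                # [N, K]
    tot = np.maximum(onehot.sum(axis=(2, 3)), 1.0)
    cr = (onehot * rows[None, None, :, None]).sum(axis=(2, 3)) / tot
    cc = (onehot * rows[None, None, None, :]).sum(axis=(2, 3)) / tot
    stats = np.stack([area, cr, cc], axis=-1)                      # [N, K, 3]
    sparse = pair.oracle_class_proj[None] + stats @ pair.oracle_stat_proj

    g = p.sam_grid
    f = s // g
    pooled = onehot.reshape(n, k, g, f, g, f).mean(axis=(3, 5))    # [N,K,g,g]
    dense = np.einsum("nkhw,kd->ndhw", pooled, pair.oracle_dense_proj)
    return PromptPair(sparse=Tensor(sparse), dense=Tensor(dense))


def _dice_loss_np(pred: Tensor, masks: np.ndarray, k: int) -> Tensor:
    # local import keeps foundation importable without the training module
    from .core import dice_loss
    return dice_loss(pred, masks)


def build_surrogate(profile: ScaleProfile, seed: int = 0,
                    pretrain_steps: int = 0, style: str = "cardiac",
                    batch_size: int = 8, lr: float = 3e-3) -> FoundationPair:
    """Construct (and optionally pre-train on phantoms, then freeze) a
    surrogate foundation pair.  Identical arguments give checksum-identical
    weights."""
    rng = np.random.default_rng([int(seed), 31])
    if profile.input_side >= 256:
        encoder: Module = VitEncoder(profile, rng)
    else:
        encoder = ConvEncoder(profile, rng)
    decoder = MaskDecoder(profile, rng)
    k = profile.n_classes + 1
    pair = FoundationPair(
        encoder=encoder, decoder=decoder, profile=profile,
        provenance=f"surrogate_seed_{seed}",
        oracle_class_proj=rng.normal(0.0, 1.0, (k, profile.prompt_dim))
        .astype(np.float32),
        oracle_stat_proj=rng.normal(0.0, 1.0, (3, profile.prompt_dim))
        .astype(np.float32),
        oracle_dense_proj=rng.normal(0.0, 1.0, (k, profile.prompt_dim))
        .astype(np.float32),
    )

    if pretrain_steps > 0:
        from .backbone import normalize_images
        from .phantom import PhantomSpec, generate_phantom

        spec = PhantomSpec(style=style, image_side=profile.input_side,
                           seed=int(seed) + 5000)
        params = encoder.parameters() + decoder.parameters()
        opt = AdamW(params, lr=lr)
        order = np.random.default_rng([int(seed), 32])
        n_pool = 64
        samples = [generate_phantom(spec, i) for i in range(n_pool)]
        for step in range(pretrain_steps):
            idx = order.integers(0, n_pool, size=batch_size)
            imgs = np.stack([samples[i].image for i in idx])
            msks = np.stack([samples[i].mask for i in idx])
            x = normalize_images(imgs)
            prompts = oracle_prompts(pair, msks)
            # Promptable segmenters are trained with imperfect prompts; the
            # surrogate mirrors that so decoding degrades gracefully when
            # learned (initially off-distribution) prompts drive it later.
            if order.uniform() < 0.3:
                prompts = PromptPair(
                    sparse=Tensor(prompts.sparse.data
                                  + order.normal(0.0, 1.0,
                                                 prompts.sparse.shape)
                                  .astype(np.float32)),
                    dense=Tensor(prompts.dense.data
                                 + order.normal(0.0, 1.0,
                                                prompts.dense.shape)
                                 .astype(np.float32)))
            pred = pair.decode(pair.encode(x), prompts)
            loss = _dice_loss_np(pred, msks, k)
            opt.zero_grad()
            loss.backward()
            opt.step()

    encoder.freeze()
    decoder.freeze()
    encoder.eval()
    decoder.eval()
    return pair


class ExternalCheckpointAdapter:
    """Declared mounting point for real pre-trained foundation weights.

    Loading actual ViT-b checkpoints is intentionally not implemented; the
    table documents the tensor-name mapping an adapter would need so that an
    external encoder/decoder can stand behind :class:`FoundationPair`.

    ==========================  =========================================
    package parameter            external checkpoint tensor
    ==========================  =========================================
    encoder.patch.weight         image_encoder.patch_embed.proj.weight
    encoder.pos_embed            image_encoder.pos_embed
    encoder.blocks.{i}.*         image_encoder.blocks.{i}.*
    encoder.neck1/neck2.weight   image_encoder.neck.0/2.weight
    decoder.block{1,2}.*         mask_decoder.transformer.layers.{0,1}.*
    decoder.up1/up2.weight       mask_decoder.output_upscaling.0/3.weight
    decoder.hyper.*              mask_decoder.output_hypernetworks_mlps.*
    ==========================  =========================================
    """

    def __init__(self, checkpoint_path):
        raise NotImplementedError(
            "external checkpoint loading is a documented interface only; "
            "use build_surrogate() for a self-contained foundation pair")
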