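"""Walk a 3x256x256 image through the full-scale architecture and print
every intermediate tensor shape.

No training happens here; this demonstrates that the paper-scale
instantiation (ResNet-50-shaped agent trunk, ViT-b-shaped frozen encoder,
prompt paths with 1/16 downsampling) satisfies its dimension contracts on
one CPU.
"""

import numpy as np

from agsam.autodiff import Tensor, no_grad
from agsam.backbone import AgentEncoder, normalize_images
from agsam.foundation import PromptPair, build_surrogate
from agsam.profiles import FULL
from agsam.prompts import (ConfusionModule, DensePromptPath, FacmConfig,
                           PromptPathConfig, SparsePromptPath)

x = normalize_images(np.zeros((1, 3, 256, 256), dtype=np.uint8))
print("input:", tuple(x.shape))

with no_grad():
    f_agent = AgentEncoder(FULL, variant="fcn", seed=0)(x)
print("agent feature:", tuple(f_agent.shape))          # (1, 2048, 32, 32)

pair = build_surrogate(FULL, seed=0, pretrain_steps=0)
with no_grad():
    emb = pair.encode(x)
print("foundation embedding:", tuple(emb.shape))       # (1, 256, 16, 16)

with no_grad():
    fused = ConfusionModule(FULL, seed=0)(f_agent, emb)
print("fused feature:", tuple(fused.shape))            # (1, 2048, 32, 32)

pc = PromptPathConfig(hidden=32)
mask = Tensor(np.full((1, 4, 256, 256), 0.25, dtype=np.float32))
with no_grad():
    tokens = SparsePromptPath(FULL, pc, FacmConfig(), seed=0)(mask)
    dense = DensePromptPath(FULL, pc, FacmConfig(), seed=0)(fused)
    out = pair.decode(emb, PromptPair(tokens, dense))
print("sparse tokens:", tuple(tokens.shape))           # (1, 4, 256)
print("dense prompt:", tuple(dense.shape))             # (1, 256, 16, 16)
print("decoded probability map:", tuple(out.shape))    # (1, 4, 256, 256)
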