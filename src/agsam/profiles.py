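"""Architecture scale profiles.

All tensor dimensions of the pipeline live in one place so the full-scale
instantiation (256-px inputs, ViT-shaped foundation encoder, ResNet-50-shaped
agent trunk) and the mini instantiation (64-px, small dims, CPU-trainable)
share a single code path.
"""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass(frozen=True)
class ScaleProfile:
    """Dimensions shared by every stage of the pipeline.

    Attributes
    ----------
    input_side : image side in pixels after pre-processing.
    sam_dim : channel dim of the foundation image embedding.
    sam_grid : spatial side of that embedding; fixed at input_side / 16.
    agent_dim : channel dim of the agent encoder feature.
    agent_stride : total downsampling of the agent encoder (output stride).
    prompt_dim : channel dim of sparse tokens and dense prompt maps.
    n_classes : number of foreground classes (background is channel 0).
    """

    input_side: int = 256
    sam_dim: int = 256
    sam_grid: int = 16
    agent_dim: int = 2048
    agent_stride: int = 8
    prompt_dim: int = 256
    n_classes: int = 3

    def __post_init__(self):
        if self.input_side % self.agent_stride:
            raise ValueError("input_side must divide by agent_stride")
        if self.sam_grid != self.input_side // 16:
            raise ValueError("sam_grid must equal input_side / 16")
        for f in ("input_side", "sam_dim", "sam_grid", "agent_dim",
                  "agent_stride", "prompt_dim", "n_classes"):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be >= 1")

    @property
    def agent_grid(self) -> int:
        return self.input_side // self.agent_stride

    def with_classes(self, n_classes: int) -> "ScaleProfile":
        return replace(self, n_classes=n_classes)


#: Paper-scale dimensions: 3x256x256 input, 256x16x16 foundation embedding,
#: 2048x32x32 agent feature.
FULL = ScaleProfile()

#: Reduced dimensions for CPU training and tests.
MINI = ScaleProfile(input_side=64, sam_dim=16, sam_grid=4, agent_dim=32,
                    agent_stride=8, prompt_dim=16, n_classes=3)
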