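"""Pre-packaged experiment protocols.

``few_shot_comparison`` is the package's headline experiment: at mini scale,
with a 200-step pre-trained frozen surrogate, train the full agent-guided
model and an identically budgeted agent-only baseline on n = 2 phantoms and
compare held-out mean foreground Dice across independent replicate seeds.
"""

from __future__ import annotations

import numpy as np

from .core import Agsam, TrainConfig, fit, mean_foreground_dice
from .data import AugmentConfig
from .foundation import build_surrogate
from .phantom import PhantomSpec, generate_phantom
from .profiles import MINI, ScaleProfile

__all__ = ["few_shot_comparison"]


def _heldout_dice(model: Agsam, test) -> float:
    return float(np.mean([
        mean_foreground_dice(model.predict(s.image)[0], s.mask,
                             model.profile.n_classes) for s in test]))


def few_shot_comparison(seed: int, n_seeds: int = 10, n_train: int = 2,
                        pretrain_steps: int = 200, epochs: int = 8,
                        replicate_to: int = 32,
                        profile: ScaleProfile = MINI) -> dict:
    """Run the paired few-shot comparison over ``n_seeds`` replicates.

    Each replicate builds its own frozen surrogate and phantom stream from
    ``seed + k``, then trains the full model and the agent-only baseline
    under the same optimisation budget.  Returns per-replicate scores and
    the win fraction of the full model.
    """
    rows = []
    for k in range(n_seeds):
        rep = int(seed) + k
        pair = build_surrogate(profile, seed=rep,
                               pretrain_steps=pretrain_steps)
        spec = PhantomSpec(style="cardiac", image_side=profile.input_side,
                           seed=10_000 + rep)
        train = [generate_phantom(spec, i) for i in range(n_train)]
        val = [generate_phantom(spec, i) for i in range(n_train, n_train + 3)]
        test = [generate_phantom(spec, i)
                for i in range(n_train + 3, n_train + 11)]
        aug = AugmentConfig(replicate_to=replicate_to, seed=rep)
        scores = {}
        for name, flags in (
                ("agsam", dict()),
                ("baseline", dict(use_foundation_encoder=False,
                                  use_foundation_decoder=False,
                                  use_facm=False))):
            cfg = TrainConfig(seed=rep, epochs=epochs, batch_size=4,
                              lr_initial=1e-3, lr_decayed=1e-4,
                              decay_epoch=max(1, epochs - 1), **flags)
            model = Agsam(profile, pair if name == "agsam" else None, cfg)
            fit(model, train, val, cfg, aug)
            scores[name] = _heldout_dice(model, test)
        rows.append(scores)
    wins = sum(r["agsam"] > r["baseline"] for r in rows)
    return dict(
        rows=rows,
        wins=wins,
        n_seeds=n_seeds,
        win_fraction=wins / n_seeds,
        agsam_mean_dice=float(np.mean([r["agsam"] for r in rows])),
        baseline_mean_dice=float(np.mean([r["baseline"] for r in rows])),
    )
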