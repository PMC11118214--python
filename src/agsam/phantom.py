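"""Synthetic segmentation phantoms with nested anatomical structure.

Two styles are provided:

* ``cardiac`` -- emulates apical-view echocardiography topology: an
  endocardial blood pool (class 1) enclosed by a myocardial ring
  (class 2, the region between two confocal rotated ellipses), with a
  separate atrial-wall blob (class 3) below the ventricle.  Appearance is a
  piecewise-smooth grayscale template with multiplicative Rayleigh-like
  speckle.
* ``fundus`` -- emulates retinal colour photographs: a bright optic disc
  (class 1) containing a strictly nested optic cup (class 2), on a warm
  background with a radial vignette and additive Gaussian noise.

All randomness is a pure function of ``(spec.seed, index)``, so a given
phantom is bit-identical across calls, machines and processes.  The phantoms
are deliberately simple: they exercise the geometry and class statistics the
segmentation pipeline cares about without modelling imaging physics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .data import ImageSample, Manifest, ManifestEntry

__all__ = ["PhantomSpec", "generate_phantom", "generate_dataset",
           "phantom_geometry"]

_STYLES = ("cardiac", "fundus")


@dataclass(frozen=True)
class PhantomSpec:
    """Configuration of the phantom generator.

    ``shape_jitter`` entries are fractional ranges applied per phantom:
    position (fraction of the image side), scale (relative), rotation
    (degrees).  ``speckle_var`` is the relative variance of the multiplicative
    speckle (cardiac) or the std of the additive noise in [0,1] intensity
    units (fundus).
    """

    style: str = "cardiac"
    image_side: int = 64
    n_classes: int | None = None          # default: 3 cardiac / 2 fundus
    jitter_pos: float = 0.02
    jitter_scale: float = 0.08
    jitter_rot_deg: float = 10.0
    speckle_var: float = 0.05
    background: float = 0.20
    vignette: float = 0.35
    seed: int = 0

    def __post_init__(self):
        if self.style not in _STYLES:
            raise ValueError(f"unknown phantom style {self.style!r}; "
                             f"expected one of {_STYLES}")
        if self.image_side < 32:
            raise ValueError("image_side must be >= 32")
        n = self.n_classes
        if n is None:
            object.__setattr__(self, "n_classes",
                               3 if self.style == "cardiac" else 2)
        elif n not in (2, 3):
            raise ValueError("n_classes must be 2 or 3")


def _rng(spec: PhantomSpec, index: int) -> np.random.Generator:
    return np.random.default_rng([int(spec.seed), int(index)])


def _ellipse_mask(side: int, cr: float, cc: float, ar: float, ac: float,
                  theta_deg: float) -> np.ndarray:
    """Boolean mask of a rotated ellipse; coordinates are fractions of side,
    evaluated at pixel centres."""
    coords = (np.arange(side) + 0.5) / side
    rr, cc_ = np.meshgrid(coords, coords, indexing="ij")
    th = math.radians(theta_deg)
    dr, dc = rr - cr, cc_ - cc
    u = dr * math.cos(th) + dc * math.sin(th)
    v = -dr * math.sin(th) + dc * math.cos(th)
    return (u / ar) ** 2 + (v / ac) ** 2 <= 1.0


def phantom_geometry(spec: PhantomSpec, index: int) -> dict:
    """Analytic ellipse parameters (fractions of the image side) for a given
    phantom, before rasterisation.  Exposed so tests can compare pixel counts
    against exact ellipse areas."""
    rng = _rng(spec, index)
    jp, js = spec.jitter_pos, spec.jitter_scale
    rot = rng.uniform(-spec.jitter_rot_deg, spec.jitter_rot_deg)
    dpos = rng.uniform(-jp, jp, size=2)
    scale = 1.0 + rng.uniform(-js, js)

    if spec.style == "cardiac":
        cr, cc = 0.40 + dpos[0], 0.50 + dpos[1]
        inner = (0.22 * scale, 0.13 * scale)
        outer = (inner[0] * 1.40, inner[1] * 1.40)
        a_dpos = rng.uniform(-0.015, 0.015, size=2)
        a_scale = 1.0 + rng.uniform(-js, js)
        a_rot = rng.uniform(-spec.jitter_rot_deg, spec.jitter_rot_deg)
        atr = dict(center=(0.875 + a_dpos[0], 0.52 + a_dpos[1]),
                   axes=(0.075 * a_scale, 0.13 * a_scale), rot=a_rot)
        return dict(style="cardiac", center=(cr, cc), rot=rot,
                    inner_axes=inner, outer_axes=outer, atrium=atr)

    # fundus: disc with strictly nested cup
    cr, cc = 0.50 + dpos[0], 0.52 + dpos[1]
    disc = (0.20 * scale, 0.22 * scale)
    cup_scale = rng.uniform(0.40, 0.55)
    cup = (disc[0] * cup_scale, disc[1] * cup_scale)
    # offset small enough that cup + offset stays inside the disc
    max_off = min(disc) * (1.0 - cup_scale) * 0.5
    cup_dpos = rng.uniform(-max_off, max_off, size=2)
    return dict(style="fundus", center=(cr, cc), rot=rot, disc_axes=disc,
                cup_center=(cr + cup_dpos[0], cc + cup_dpos[1]),
                cup_axes=cup)


def _cardiac(spec: PhantomSpec, index: int, rng: np.random.Generator):
    side = spec.image_side
    g = phantom_geometry(spec, index)
    cr, cc = g["center"]
    outer = _ellipse_mask(side, cr, cc, *g["outer_axes"], g["rot"])
    inner = _ellipse_mask(side, cr, cc, *g["inner_axes"], g["rot"])
    atr = _ellipse_mask(side, *g["atrium"]["center"], *g["atrium"]["axes"],
                        g["atrium"]["rot"])
    mask = np.zeros((side, side), dtype=np.uint8)
    mask[outer] = 2
    mask[inner] = 1
    mask[atr & (mask == 0)] = 3          # atrial wall never overwrites LV

    tpl = np.full((side, side), spec.background, dtype=np.float64)
    tpl[mask == 2] = 0.65                # myocardium: echogenic
    tpl[mask == 1] = 0.10                # blood pool: anechoic
    tpl[mask == 3] = 0.58
    return tpl, mask


def _fundus(spec: PhantomSpec, index: int, rng: np.random.Generator):
    side = spec.image_side
    g = phantom_geometry(spec, index)
    disc = _ellipse_mask(side, *g["center"], *g["disc_axes"], g["rot"])
    cup = _ellipse_mask(side, *g["cup_center"], *g["cup_axes"], g["rot"])
    cup &= disc                          # nesting is enforced, not assumed
    mask = np.zeros((side, side), dtype=np.uint8)
    mask[disc] = 1
    mask[cup] = 2

    tpl = np.full((side, side), 0.45, dtype=np.float64)
    tpl[disc] = 0.80
    tpl[cup] = 0.95
    return tpl, mask


def generate_phantom(spec: PhantomSpec, index: int) -> ImageSample:
    """Render one phantom image + mask; bit-identical for a fixed
    ``(spec, index)``."""
    if index < 0:
        raise ValueError("index must be >= 0")
    rng = _rng(spec, index)
    side = spec.image_side

    if spec.style == "cardiac":
        tpl, mask = _cardiac(spec, index, rng)
        if spec.speckle_var > 0:
            # Rayleigh field normalised to unit mean, rescaled to the
            # requested relative variance -- first-order speckle appearance.
            ray = rng.rayleigh(scale=1.0, size=(side, side))
            ray /= math.sqrt(math.pi / 2.0)
            ray_std = math.sqrt((4.0 - math.pi) / math.pi)
            factor = 1.0 + math.sqrt(spec.speckle_var) * (ray - 1.0) / ray_std
            img1 = tpl * np.clip(factor, 0.0, None)
        else:
            img1 = tpl
        img1 = np.clip(img1, 0.0, 1.0)
        chans = np.stack([img1, img1, img1])
    else:
        tpl, mask = _fundus(spec, index, rng)
        coords = (np.arange(side) + 0.5) / side
        rr, cc = np.meshgrid(coords, coords, indexing="ij")
        d2 = (rr - 0.5) ** 2 + (cc - 0.5) ** 2
        vig = 1.0 - spec.vignette * d2 / 0.5
        img1 = tpl * vig
        if spec.speckle_var > 0:
            img1 = img1 + rng.normal(0.0, math.sqrt(spec.speckle_var),
                                     size=(side, side))
        img1 = np.clip(img1, 0.0, 1.0)
        # warm colour cast typical of fundus photographs
        chans = np.stack([img1, img1 * 0.55, img1 * 0.25])

    image = np.rint(chans * 255.0).astype(np.uint8)
    return ImageSample(image=image, mask=mask.astype(np.int64),
                       id=f"{spec.style}-{spec.seed}-{index:04d}")


def generate_dataset(spec: PhantomSpec, n: int, out_dir,
                     split: str = "train") -> Manifest:
    """Write ``n`` phantom image/mask PNG pairs plus a JSON-lines manifest.

    Returns the loaded manifest; paths inside it are relative to
    ``out_dir``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for i in range(n):
        s = generate_phantom(spec, i)
        img_name, mask_name = f"img_{i:04d}.png", f"mask_{i:04d}.png"
        Image.fromarray(s.image.transpose(1, 2, 0)).save(out / img_name)
        Image.fromarray(s.mask.astype(np.uint8), mode="L").save(out / mask_name)
        entries.append(ManifestEntry(image=img_name, mask=mask_name,
                                     split=split))
    manifest_path = out / "manifest.jsonl"
    with open(manifest_path, "w") as f:
        for e in entries:
            f.write(json.dumps({"image": e.image, "mask": e.mask,
                                "split": e.split}) + "\n")
    return Manifest(entries=entries, n_classes=spec.n_classes, root=out)
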