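"""Phantom generator: determinism, anatomical nesting, noiseless-template
exactness against the analytic ellipse-area oracle, and dataset round-trips."""

import hashlib
import math

import numpy as np
import pytest
from scipy import ndimage
from scipy.spatial import ConvexHull, Delaunay

from agsam.data import load_manifest
from agsam.phantom import (PhantomSpec, generate_dataset, generate_phantom,
                           phantom_geometry)


def checksum(sample):
    h = hashlib.sha256()
    h.update(sample.image.tobytes())
    h.update(sample.mask.tobytes())
    return h.hexdigest()


def test_identical_spec_seed_index_is_bit_identical(cardiac_spec):
    a = generate_phantom(cardiac_spec, 0)
    b = generate_phantom(cardiac_spec, 0)
    assert checksum(a) == checksum(b)


def test_distinct_seeds_give_distinct_images():
    sums = set()
    for seed in range(10):
        spec = PhantomSpec(style="cardiac", image_side=64, seed=seed)
        sums.add(checksum(generate_phantom(spec, 0)))
    assert len(sums) == 10


@pytest.mark.parametrize("style,n_classes", [("cardiac", 3), ("fundus", 2)])
def test_mask_values_within_class_range(style, n_classes):
    spec = PhantomSpec(style=style, image_side=64, seed=1)
    for i in range(5):
        s = generate_phantom(spec, i)
        assert set(np.unique(s.mask)) <= set(range(n_classes + 1))
        assert s.image.shape == (3, 64, 64)


def test_cardiac_nesting_endocardium_enclosed_by_epicardium(cardiac_spec):
    """Every pixel bordering the endocardium (class 1) from outside must be
    epicardial ring (class 2); the atrial blob (3) never touches class 1."""
    for i in range(5):
        s = generate_phantom(cardiac_spec, i)
        inner = s.mask == 1
        ring = ndimage.binary_dilation(inner) & ~inner
        assert inner.any() and ring.any()
        assert set(np.unique(s.mask[ring])) <= {2}


def test_fundus_cup_inside_disc_hull(fundus_spec):
    for i in range(5):
        s = generate_phantom(fundus_spec, i)
        union = np.argwhere(s.mask > 0)
        cup = np.argwhere(s.mask == 2)
        assert len(cup) > 0
        hull = Delaunay(union[ConvexHull(union).vertices])
        assert (hull.find_simplex(cup) >= 0).all()


def test_zero_noise_image_equals_template_and_analytic_areas():
    """With speckle variance 0 the cardiac image is the deterministic
    template, and per-class pixel counts match the exact ellipse areas to
    within one perimeter's worth of rasterisation error."""
    spec = PhantomSpec(style="cardiac", image_side=96, seed=2,
                       speckle_var=0.0)
    a = generate_phantom(spec, 0)
    b = generate_phantom(spec, 0)
    assert np.array_equal(a.image, b.image)
    assert (a.image[0] == a.image[1]).all()      # grayscale replicated

    g = phantom_geometry(spec, 0)
    side = spec.image_side

    def ell_area(axes):
        return math.pi * axes[0] * axes[1] * side * side

    def ell_perimeter(axes):
        aa, bb = axes[0] * side, axes[1] * side
        # Ramanujan approximation is ample for a tolerance bound
        h = ((aa - bb) / (aa + bb)) ** 2
        return math.pi * (aa + bb) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))

    counts = {c: int((a.mask == c).sum()) for c in (1, 2, 3)}
    expected = {
        1: ell_area(g["inner_axes"]),
        2: ell_area(g["outer_axes"]) - ell_area(g["inner_axes"]),
        3: ell_area(g["atrium"]["axes"]),
    }
    tolerances = {
        1: ell_perimeter(g["inner_axes"]),
        2: ell_perimeter(g["outer_axes"]) + ell_perimeter(g["inner_axes"]),
        3: ell_perimeter(g["atrium"]["axes"]),
    }
    for c in (1, 2, 3):
        assert abs(counts[c] - expected[c]) <= tolerances[c], \
            f"class {c}: {counts[c]} vs {expected[c]:.1f}"


def test_class_frequency_stability_over_100_phantoms():
    spec = PhantomSpec(style="cardiac", image_side=64, seed=11)
    total = 64 * 64
    for i in range(100):
        m = generate_phantom(spec, i).mask
        for c in (1, 2, 3):
            frac = (m == c).sum() / total
            assert 0.005 < frac < 0.40, f"phantom {i} class {c}: {frac:.4f}"


def test_unknown_style_rejected():
    with pytest.raises(ValueError, match="style"):
        PhantomSpec(style="xray")
    with pytest.raises(ValueError):
        PhantomSpec(image_side=16)


def test_negative_index_rejected(cardiac_spec):
    with pytest.raises(ValueError):
        generate_phantom(cardiac_spec, -1)


def test_generate_dataset_roundtrip_and_determinism(tmp_path, cardiac_spec):
    m = generate_dataset(cardiac_spec, 4, tmp_path / "a")
    assert len(m) == 4
    files = list((tmp_path / "a").glob("*.png"))
    assert len(files) == 8

    loaded = load_manifest(tmp_path / "a" / "manifest.jsonl", n_classes=3)
    assert len(loaded) == 4
    s_disk = loaded.load_sample(0)
    s_mem = generate_phantom(cardiac_spec, 0)
    assert np.array_equal(s_disk.image, s_mem.image)
    assert np.array_equal(s_disk.mask, s_mem.mask)

    generate_dataset(cardiac_spec, 4, tmp_path / "b")
    for name in ("img_0002.png", "mask_0003.png"):
        assert (tmp_path / "a" / name).read_bytes() == \
            (tmp_path / "b" / name).read_bytes()


def test_single_sample_dataset_is_valid_one_shot_set(tmp_path, cardiac_spec):
    m = generate_dataset(cardiac_spec, 1, tmp_path)
    assert len(m) == 1
    assert m.load_sample(0).mask.shape == (64, 64)
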