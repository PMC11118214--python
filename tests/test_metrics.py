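"""Evaluation metrics against independent oracles: brute-force Hausdorff,
pair-counting AUC, closed-form paired t statistic."""

import numpy as np
import pytest
from scipy import stats as sstats

from agsam.metrics import (compare_paired, dice, evaluate_samples,
                           hausdorff, prob_metrics, summarize)


# -- dice ---------------------------------------------------------------------


def test_dice_identical_nonempty_masks():
    m = np.zeros((8, 8), dtype=int)
    m[2:5, 2:5] = 1
    assert dice(m, m, 1) == 1.0


def test_dice_half_overlap_counting_oracle():
    p = np.zeros((4, 4), dtype=int)
    g = np.zeros((4, 4), dtype=int)
    p[0, :4] = 1          # |P| = 4
    g[0, 2:4] = 1         # overlap 2
    g[1, 2:4] = 1         # |G| = 4
    assert dice(p, g, 1) == pytest.approx(0.5)


def test_dice_disjoint_and_empty_conventions():
    p = np.zeros((4, 4), dtype=int)
    g = np.zeros((4, 4), dtype=int)
    p[0, 0] = 1
    g[3, 3] = 1
    assert dice(p, g, 1) == 0.0
    assert dice(np.zeros((4, 4), int), np.zeros((4, 4), int), 1) == 1.0


def test_dice_symmetric_and_translation_invariant():
    rng = np.random.default_rng(0)
    for _ in range(20):
        p = rng.integers(0, 2, (10, 10))
        g = rng.integers(0, 2, (10, 10))
        assert dice(p, g, 1) == pytest.approx(dice(g, p, 1))
        pt = np.roll(np.roll(np.pad(p, 3), 2, 0), 1, 1)
        gt = np.roll(np.roll(np.pad(g, 3), 2, 0), 1, 1)
        assert dice(pt, gt, 1) == pytest.approx(dice(p, g, 1))


# -- hausdorff ----------------------------------------------------------------


def brute_force_hausdorff(p, g):
    """O(n^2) max-min distance over boundary pixels."""
    from scipy import ndimage

    def boundary(m):
        return np.argwhere(m & ~ndimage.binary_erosion(m, border_value=0))

    bp, bg = boundary(p), boundary(g)
    d = np.sqrt(((bp[:, None, :] - bg[None, :, :]) ** 2).sum(-1))
    return max(d.min(axis=1).max(), d.min(axis=0).max())


def test_hausdorff_identical_masks_is_zero():
    m = np.zeros((8, 8), dtype=bool)
    m[2:5, 2:6] = True
    hd, degen = hausdorff(m.astype(int), m.astype(int), 1)
    assert hd == 0.0 and not degen


def test_hausdorff_single_pixels_euclidean():
    p = np.zeros((8, 8), dtype=int)
    g = np.zeros((8, 8), dtype=int)
    p[0, 0] = 1
    g[3, 4] = 1
    hd, _ = hausdorff(p, g, 1)
    assert hd == pytest.approx(5.0)


def test_hausdorff_matches_brute_force_on_random_masks():
    rng = np.random.default_rng(42)
    for _ in range(50):
        p = rng.uniform(size=(12, 12)) < 0.3
        g = rng.uniform(size=(12, 12)) < 0.3
        if not p.any() or not g.any():
            continue
        hd, _ = hausdorff(p.astype(int), g.astype(int), 1)
        assert hd == pytest.approx(brute_force_hausdorff(p, g))


def test_hausdorff_empty_side_conventions():
    p = np.zeros((6, 8), dtype=int)
    g = np.zeros((6, 8), dtype=int)
    g[2, 2] = 1
    hd, degen = hausdorff(p, g, 1)
    assert degen and hd == pytest.approx(np.hypot(6, 8))
    hd, degen = hausdorff(p, p, 1)
    assert hd == 0.0 and not degen


def test_dice_one_iff_hausdorff_zero_for_nonempty():
    rng = np.random.default_rng(3)
    for _ in range(20):
        p = rng.uniform(size=(10, 10)) < 0.4
        g = rng.uniform(size=(10, 10)) < 0.4
        if not p.any() or not g.any():
            continue
        d = dice(p.astype(int), g.astype(int), 1)
        hd, _ = hausdorff(p.astype(int), g.astype(int), 1)
        assert (d == 1.0) == (hd == 0.0)


# -- probability metrics ------------------------------------------------------


def test_perfect_separation_all_ones():
    gt = np.array([[1, 1], [0, 0]])
    probs = np.stack([1.0 - gt, gt]).astype(float)
    pm = prob_metrics(probs, gt, 1)
    assert (pm.sensitivity, pm.specificity, pm.auc, pm.aupr) == (1, 1, 1, 1)


def test_constant_probability_gives_auc_half():
    gt = np.array([[1, 0], [0, 1]])
    probs = np.full((2, 2, 2), 0.5)
    pm = prob_metrics(probs, gt, 1)
    assert pm.auc == pytest.approx(0.5)


def test_auc_hand_example_eight_ninths():
    """probs [.9,.8,.7,.4,.3,.1] vs gt [1,1,0,1,0,0]: 8 of 9 pos/neg pairs
    are concordant."""
    gt = np.array([[1, 1, 0, 1, 0, 0]])
    p1 = np.array([[0.9, 0.8, 0.7, 0.4, 0.3, 0.1]])
    probs = np.stack([1 - p1, p1])
    pm = prob_metrics(probs, gt, 1)
    assert pm.auc == pytest.approx(8 / 9)


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(0)
    gt = (rng.uniform(size=(6, 6)) < 0.4).astype(int)
    p1 = rng.uniform(size=(6, 6))
    a1 = prob_metrics(np.stack([1 - p1, p1]), gt, 1).auc
    p2 = p1 ** 3        # strictly monotone
    a2 = prob_metrics(np.stack([1 - p2, p2]), gt, 1).auc
    assert a1 == pytest.approx(a2)


def test_absent_class_reported_as_missing():
    gt = np.zeros((4, 4), dtype=int)
    probs = np.full((2, 4, 4), 0.5)
    pm = prob_metrics(probs, gt, 1)
    assert np.isnan(pm.sensitivity) and np.isnan(pm.auc)


# -- paired comparison --------------------------------------------------------


def test_equal_scores_give_p_one():
    r = compare_paired([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
    assert r.p == 1.0 and r.stars == "ns"


def test_constant_nonzero_difference_flagged_degenerate():
    r = compare_paired([1, 1, 1, 1], [0, 0, 0, 0])
    assert r.degenerate and r.p == 0.0


def test_five_pair_example_matches_closed_form():
    a = np.array([12.0, 14.0, 11.0, 13.0, 15.0])
    b = np.array([10.0, 13.0, 11.5, 12.0, 13.0])
    d = a - b
    t_expected = d.mean() / (d.std(ddof=1) / np.sqrt(5))
    p_expected = 2 * sstats.t.sf(abs(t_expected), df=4)
    r = compare_paired(a, b)
    assert r.t == pytest.approx(t_expected)
    assert r.p == pytest.approx(p_expected)


def test_compare_paired_input_validation():
    with pytest.raises(ValueError):
        compare_paired([1.0], [2.0])


# -- table evaluation ---------------------------------------------------------


class _OracleModel:
    """Returns the ground truth as a crisp probability map."""

    def __init__(self, samples):
        self._lookup = {s.image.tobytes(): s.mask for s in samples}

    def predict_probs(self, image):
        mask = self._lookup[np.asarray(image).tobytes()]
        k = int(mask.max()) + 1
        onehot = (mask[None] == np.arange(max(k, 4))[:, None, None])
        return onehot.astype(float)[None]


def test_oracle_model_scores_perfectly(cardiac_spec):
    from agsam.phantom import generate_phantom

    samples = [generate_phantom(cardiac_spec, i) for i in range(3)]
    table = evaluate_samples(_OracleModel(samples), samples, 3)
    assert len(table) == 3 * 3
    assert (table["dice"] == 1.0).all()
    assert (table["hd"] == 0.0).all()
    s = summarize(table)
    assert s["mean"]["dice"] == 1.0 and s["mean"]["hd"] == 0.0


def test_empty_evaluation_set_rejected():
    with pytest.raises(ValueError):
        evaluate_samples(None, [], 3)
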