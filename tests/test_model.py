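"""Network contracts: gating, fusion, losses, prediction rules, checkpoints."""

import numpy as np
import pytest

from pasivision.core import Region
from pasivision.model import (
    CheckpointError,
    EncoderFeatures,
    ModelConfig,
    SeverityNet,
    attention_gate,
    cross_teacher_loss,
    fuse_multiview,
    predict_region,
    smooth_l1,
)


@pytest.fixture(scope="module")
def small_net():
    return SeverityNet(ModelConfig(image_size=(32, 40)), seed=5)


def random_images(rng, n, size=(32, 40)):
    return [rng.integers(0, 256, (*size, 3)).astype(np.uint8) for _ in range(n)]


# -- encoder ----------------------------------------------------------------

def test_encoder_attention_in_unit_interval_and_grids_match(small_net, rng):
    img = rng.integers(0, 256, (32, 40, 3)).astype(np.uint8)
    feats = small_net.encode(small_net.preprocess_image(img))
    assert feats.attention_map.min() >= 0 and feats.attention_map.max() <= 1
    assert feats.visual_map.shape[1:] == feats.attention_map.shape[1:]


def test_encoder_deterministic_and_per_sample_independent(small_net, rng):
    imgs = np.stack([small_net.preprocess_image(im) for im in random_images(rng, 2)])
    single = small_net.forward(imgs[None], np.array([0]))
    double = small_net.forward(imgs[None].repeat(2, axis=0), np.array([0, 0]))
    assert np.allclose(single["reg"].data[0], double["reg"].data[0])
    assert np.allclose(double["reg"].data[0], double["reg"].data[1])


def test_encoder_rejects_wrong_size(small_net, rng):
    with pytest.raises(ValueError, match="does not match"):
        small_net.encode(rng.random((3, 64, 80)))


# -- attention gate / fusion (hand arithmetic) ------------------------------

def test_attention_gate_identity_and_suppression():
    visual = np.arange(8, dtype=float).reshape(2, 2, 2)
    ones = EncoderFeatures(visual, np.ones((1, 2, 2)))
    zeros = EncoderFeatures(visual, np.zeros((1, 2, 2)))
    assert np.allclose(attention_gate(ones), visual.mean(axis=(1, 2)))
    assert np.allclose(attention_gate(zeros), 0)


def test_attention_gate_hand_example():
    visual = np.array([[[1.0, 2.0], [3.0, 4.0]]])
    attn = np.array([[[1.0, 0.0], [0.0, 1.0]]])
    assert attention_gate(EncoderFeatures(visual, attn)) == pytest.approx([1.25])


def test_fuse_multiview_hand_example_and_symmetry(rng):
    v1, v2 = np.array([1.0, 0.0]), np.array([3.0, 2.0])
    assert np.allclose(fuse_multiview([v1, v2]), [3, 2, 2, 1])
    assert np.allclose(fuse_multiview([v2, v1]), fuse_multiview([v1, v2]))
    assert np.allclose(fuse_multiview([v1]), [1, 0, 1, 0])  # max == mean
    assert np.allclose(fuse_multiview([v1, v2], "max"), [3, 2])
    assert np.allclose(fuse_multiview([v1, v2], "mean"), [2, 1])
    with pytest.raises(ValueError):
        fuse_multiview([])


# -- loss functions vs brute force -----------------------------------------

def brute_smooth_l1(pred, target):
    d = abs(pred - target)
    return 0.5 * d * d if d < 1 else d - 0.5


def brute_cross_teacher(reg, logits):
    p = np.exp(logits - logits.max())
    p = p / p.sum()
    mu = sum(k * p[k] for k in range(len(p)))
    lbl = int(np.clip(np.floor(abs(reg) + 0.5) * np.sign(reg), 0, len(p) - 1))
    return brute_smooth_l1(reg, mu) - np.log(p[lbl])


@pytest.mark.parametrize("d,expect", [(0.0, 0.0), (0.5, 0.125), (2.0, 1.5), (-2.0, 1.5)])
def test_smooth_l1_examples(d, expect):
    assert smooth_l1(d, 0.0) == pytest.approx(expect)


def test_smooth_l1_matches_brute_force_on_random_inputs(rng):
    for _ in range(200):
        p, t = rng.uniform(-5, 5, 2)
        assert smooth_l1(p, t) == pytest.approx(brute_smooth_l1(p, t), abs=1e-6)


def test_cross_teacher_uniform_logits_worked_example():
    val = cross_teacher_loss(2.0, np.zeros(5))
    assert val == pytest.approx(-np.log(0.2), abs=1e-9)  # mu = 2, sl1 = 0


def test_cross_teacher_self_consistent_heads_approach_ce_floor():
    logits = np.array([0.0, 0.0, 20.0, 0.0, 0.0])
    val = cross_teacher_loss(2.0, logits)
    # mu ~= 2 and p_max ~= 1 -> loss ~= -log p_max ~= 0
    assert val == pytest.approx(0.0, abs=1e-6)


def test_cross_teacher_matches_brute_force_and_nonnegative(rng):
    for _ in range(200):
        k = int(rng.choice([5, 7]))
        reg = float(rng.uniform(-1, k))
        logits = rng.standard_normal(k)
        val = cross_teacher_loss(reg, logits)
        assert val >= 0
        assert val == pytest.approx(brute_cross_teacher(reg, logits), abs=1e-6)


def test_loss_bundle_total_is_weighted_sum(small_net, rng):
    imgs = np.stack(
        [np.stack([small_net.preprocess_image(im) for im in random_images(rng, 2)])]
    )
    out = small_net.forward(imgs, np.array([1]))
    heats = rng.random((2, 1, *small_net.encode(imgs[0, 0]).attention_map.shape[1:]))
    weights = (1.0, 0.5, 2.0, 0.25)
    total, bundle = small_net.compute_losses(
        out, np.array([[3, 2, 1, 0]]), heats, loss_weights=weights
    )
    expect = (
        bundle.l_reg * 1.0 + bundle.l_cls * 0.5
        + bundle.l_attn * 2.0 + bundle.l_cross * 0.25
    )
    assert bundle.total == pytest.approx(expect)
    assert min(bundle.l_reg, bundle.l_cls, bundle.l_attn, bundle.l_cross) >= 0


# -- prediction rules -------------------------------------------------------

def test_prediction_clamps_and_rounds_regression(small_net):
    from pasivision.model import RegionOutputs

    out = RegionOutputs(
        regression={"area": 3.5, "erythema": -0.3, "induration": 4.7, "desquamation": 1.49},
        class_logits={}, attention_maps=[],
    )
    a = out.to_assessment(Region.TRUNK)
    assert a.as_tuple() == (4, 0, 4, 1)


def test_predict_region_invariant_to_image_permutation(small_net, rng):
    images = random_images(rng, 3)
    _, a1 = predict_region(images, small_net, Region.HEAD)
    _, a2 = predict_region(images[::-1], small_net, Region.HEAD)
    _, a3 = predict_region([images[1], images[0], images[2]], small_net, Region.HEAD)
    assert a1.as_tuple() == a2.as_tuple() == a3.as_tuple()


def test_mean_fusion_invariant_to_duplicating_every_image(rng):
    net = SeverityNet(ModelConfig(image_size=(32, 40), fusion="mean"), seed=2)
    images = random_images(rng, 2)
    o1, _ = predict_region(images, net)
    o2, _ = predict_region(images + images, net)
    for m in o1.regression:
        assert o1.regression[m] == pytest.approx(o2.regression[m], abs=1e-9)


def test_max_fusion_invariant_to_adding_a_duplicate(rng):
    net = SeverityNet(ModelConfig(image_size=(32, 40), fusion="max"), seed=2)
    images = random_images(rng, 2)
    o1, _ = predict_region(images, net)
    o2, _ = predict_region(images + [images[0]], net)
    for m in o1.regression:
        assert o1.regression[m] == pytest.approx(o2.regression[m], abs=1e-9)


def test_region_embedding_differentiates_regions(small_net, rng):
    images = random_images(rng, 2)
    o_head, _ = predict_region(images, small_net, Region.HEAD)
    o_lower, _ = predict_region(images, small_net, Region.LOWER_LIMB)
    assert any(
        o_head.regression[m] != pytest.approx(o_lower.regression[m])
        for m in o_head.regression
    )


# -- checkpointing ----------------------------------------------------------

def test_checkpoint_round_trip_preserves_predictions(small_net, tmp_path, rng):
    images = random_images(rng, 2)
    o1, _ = predict_region(images, small_net)
    path = tmp_path / "ckpt.npz"
    small_net.save(path)
    restored = SeverityNet.load(path)
    o2, _ = predict_region(images, restored)
    for m in o1.regression:
        assert o1.regression[m] == pytest.approx(o2.regression[m], abs=1e-12)
    assert restored.config == small_net.config


def test_missing_checkpoint_is_explicit_error(tmp_path, rng):
    with pytest.raises(CheckpointError, match="not found"):
        predict_region(random_images(rng, 1), tmp_path / "nope.npz")
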