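"""Similarity-transform fitting, application, idempotence, synthetic round trip."""

import numpy as np
import pytest

from larvapose.annotations import Keypoint, KeypointSet
from larvapose.errors import ConfigurationError, DegenerateGeometryError
from larvapose.normalize import (CanonicalSpec, SimilarityTransform,
                                 apply_to_image, apply_to_points,
                                 fit_normalization, normalize_image)
from larvapose.synthetic import (LarvaShapeParams, canonical_keypoints,
                                 generate_larva)

SPEC = CanonicalSpec(96, 72, 0.7)


def _anchors(xy1, xy4, xy5):
    return Keypoint(1, *xy1), Keypoint(4, *xy4), Keypoint(5, *xy5)


class TestFit:
    def test_canonical_triple_gives_identity(self):
        L = SPEC.target_length_fraction * SPEC.width
        p1, p4, p5 = _anchors((48 - L / 2, 36), (48 + L / 2, 36), (70, 40))
        t = fit_normalization(p1, p4, p5, SPEC)
        assert not t.flip_vertical
        assert t.rotation == pytest.approx(0.0, abs=1e-9)
        assert t.scale == pytest.approx(1.0, rel=1e-9)
        assert np.allclose(t.translation, (0, 0), atol=1e-6)

    @pytest.mark.parametrize("seed", range(8))
    def test_postconditions_random_triples(self, seed):
        rng = np.random.default_rng(seed)
        a1, a4 = rng.uniform(5, 90, 2), rng.uniform(5, 90, 2)
        a5 = rng.uniform(5, 70, 2)
        p1, p4, p5 = _anchors(a1, a4, a5)
        t = fit_normalization(p1, p4, p5, SPEC)
        q = t.apply(np.array([a1, a4, a5]))
        assert abs(q[0, 1] - 36.0) < 1e-6 and abs(q[1, 1] - 36.0) < 1e-6
        assert np.allclose((q[0] + q[1]) / 2, (48, 36), atol=1e-6)
        assert np.hypot(*(q[1] - q[0])) == pytest.approx(0.7 * 96, rel=1e-9)
        assert q[2, 1] >= 36.0 - 1e-9  # point 5 below (or on) the axis

    def test_fit_inverts_applied_perturbation(self):
        # compose-then-fit oracle: perturb a canonical triple, refit, compare
        rng = np.random.default_rng(4)
        L = 0.7 * 96
        base = np.array([[48 - L / 2, 36], [48 + L / 2, 36], [60, 45]])
        for _ in range(10):
            pert = SimilarityTransform(rng.uniform(-2, 2), rng.uniform(0.5, 2),
                                       tuple(rng.uniform(-10, 10, 2)),
                                       bool(rng.random() < 0.5))
            moved = pert.apply(base)
            t = fit_normalization(*_anchors(*moved), SPEC)
            np.testing.assert_allclose(t.apply(moved), base, atol=1e-6)

    def test_coincident_anchors_rejected(self):
        p1, p4, p5 = _anchors((10, 10), (10, 10), (5, 5))
        with pytest.raises(DegenerateGeometryError):
            fit_normalization(p1, p4, p5, SPEC)

    def test_bad_length_fraction_rejected(self):
        with pytest.raises(ConfigurationError):
            CanonicalSpec(96, 72, 0.0)


class TestApplyToPoints:
    def test_identity_unchanged(self, random_keypoints):
        t = SimilarityTransform()
        out = apply_to_points(t, random_keypoints)
        np.testing.assert_allclose(out.to_array(), random_keypoints.to_array())

    def test_pure_translation(self, random_keypoints):
        t = SimilarityTransform(translation=(10.0, 0.0))
        out = apply_to_points(t, random_keypoints)
        np.testing.assert_allclose(out.to_array()[:, 0],
                                   random_keypoints.to_array()[:, 0] + 10.0)

    def test_pairwise_distance_ratios_preserved(self, random_keypoints):
        t = SimilarityTransform(0.7, 1.9, (5.0, -3.0), True)
        a = random_keypoints.to_array()
        b = apply_to_points(t, random_keypoints).to_array()
        da = np.linalg.norm(a[None] - a[:, None], axis=-1)
        db = np.linalg.norm(b[None] - b[:, None], axis=-1)
        mask = da > 1e-9
        np.testing.assert_allclose(db[mask] / da[mask], 1.9, rtol=1e-5)

    def test_inverse_composes_to_identity(self, random_keypoints):
        t = SimilarityTransform(0.4, 2.2, (7.0, 1.0), True)
        a = random_keypoints.to_array()
        h = np.hstack([t.apply(a), np.ones((26, 1))])
        back = (t.inverse_matrix() @ h.T).T[:, :2]
        np.testing.assert_allclose(back, a, atol=1e-9)


class TestApplyToImage:
    def test_identity_is_pixel_identical(self, canonical_larva):
        out = apply_to_image(SimilarityTransform(), canonical_larva, SPEC)
        np.testing.assert_array_equal(out.pixels, canonical_larva.pixels)

    def test_idempotent_on_keypoints(self):
        img = generate_larva(LarvaShapeParams(rotation=0.4, scale=0.9, seed=11), (96, 72))
        once = normalize_image(img, SPEC)
        twice = normalize_image(once, SPEC)
        np.testing.assert_allclose(twice.keypoints.to_array(),
                                   once.keypoints.to_array(), atol=1e-3)

    @pytest.mark.parametrize("flip", [False, True])
    def test_synthetic_round_trip(self, flip):
        params = LarvaShapeParams(rotation=-0.5, scale=1.1, translation=(4.0, -3.0),
                                  flip=flip, seed=21)
        img = generate_larva(params, (96, 72))
        norm = normalize_image(img, SPEC)
        canon = canonical_keypoints(params, (96, 72))
        err = np.abs(norm.keypoints.to_array() - canon.to_array()).max()
        assert err < 0.5

    def test_raster_follows_keypoints(self):
        # a dark organ under a keypoint stays dark under it after warping
        params = LarvaShapeParams(rotation=0.3, scale=1.0, seed=5, noise_sd=0.0)
        img = generate_larva(params, (96, 72))
        norm = normalize_image(img, SPEC)
        eye_center = norm.keypoints.to_array()[12:16].mean(axis=0)  # eye extrema
        x, y = np.round(eye_center).astype(int)
        patch = norm.pixels[y - 1:y + 2, x - 1:x + 2, 0].astype(float).mean()
        background = float(np.median(norm.pixels[:5, :, 0]))
        assert patch < background - 30  # eye is much darker than background


def test_predict_anchors_rejects_wrong_head(canonical_larva):
    from larvapose.model import build_network, tiny_network_spec
    from larvapose.normalize import predict_anchors

    model = build_network(tiny_network_spec("csht", 26, 1))
    with pytest.raises(ConfigurationError):
        predict_anchors(canonical_larva, model)


def test_trained_anchor_model_localizes_anchors():
    """A 3-channel configuration of the main network, trained on easy
    synthetic larvae, predicts anchors 1/4/5 to < 3 px on held-out images."""
    from larvapose.annotations import AnnotatedImage
    from larvapose.model import build_network, tiny_network_spec
    from larvapose.normalize import predict_anchors
    from larvapose.synthetic import generate_dataset
    from larvapose.train import TrainConfig, train

    images, index = generate_dataset(130, (96, 72), seed=23, easy=True)

    def anchors_only(im):
        xy = im.keypoints.to_array()[[0, 3, 4]]
        return AnnotatedImage(im.image_id, im.width, im.height, im.pixels,
                              KeypointSet.from_array(xy))

    imgs3 = [anchors_only(im) for im in images]
    net = build_network(tiny_network_spec("csht", 3, 1), seed=2)
    cfg = TrainConfig(batch_size=24, epochs=60, base_lr=1e-3,
                      lr_drops={40: 1e-4, 52: 1e-5}, input_size=(96, 72),
                      seed=2, head_mode="csht")
    train(net, imgs3, index, cfg)
    by = {im.image_id: im for im in imgs3}
    errs = []
    for image_id in index.ids("test"):
        im = by[image_id]
        bare = AnnotatedImage(im.image_id, im.width, im.height, im.pixels, None)
        p1, p4, p5 = predict_anchors(bare, net)
        assert (p1.index, p4.index, p5.index) == (1, 4, 5)
        pred = np.array([[p.x, p.y] for p in (p1, p4, p5)])
        errs.append(np.linalg.norm(pred - im.keypoints.to_array(), axis=1).mean())
    assert np.mean(errs) < 3.0
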