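"""Dual-branch patch model: losses, patches, training, inference."""

import math

import numpy as np
import pytest

from nsseg.dualnet import (
    IGNORE,
    NEG,
    POS,
    PatchNet,
    TrainConfig,
    TrainingSample,
    TriStateMask,
    classification_loss,
    extract_patches,
    forward,
    masked_pixel_loss,
    patch_label,
    predict_exam,
    train,
)
from nsseg.metrics import roc_auc
from nsseg.phantom import DomainSpec, make_exam


class TestTriStateMask:
    def test_reference_mask_roundtrip(self):
        m = TriStateMask.from_binary(np.array([[0, 1], [1, 0]]))
        assert set(np.unique(m.grid)) <= {NEG, POS}

    def test_invalid_state_rejected(self):
        with pytest.raises(ValueError):
            TriStateMask(np.array([[0, 7]]))


class TestPatchLabel:
    def test_all_negative(self):
        assert patch_label(np.zeros((4, 4), np.int8)) == 0

    def test_single_positive_pixel(self):
        m = np.zeros((4, 4), np.int8)
        m[2, 2] = POS
        assert patch_label(m) == 1

    def test_all_ignore_counts_as_negative(self):
        m = np.full((4, 4), IGNORE, np.int8)
        assert patch_label(m) == 0


class TestExtractPatches:
    def test_full_size_crop_is_identity(self, rng):
        img = rng.random((16, 16))
        msk = np.zeros((16, 16), np.int8)
        patches = extract_patches(img, msk, 16, "grid")
        assert len(patches) == 1
        assert np.array_equal(patches[0][0], img)

    def test_grid_tiling_count(self, rng):
        img = rng.random((64, 64))
        patches = extract_patches(img, np.zeros((64, 64), np.int8), 32, "grid")
        assert len(patches) == 4

    def test_labels_match_recount(self, rng):
        img = rng.random((64, 64))
        msk = (rng.random((64, 64)) < 0.01).astype(np.int8)
        for _, mp, lab in extract_patches(img, msk, 16, "random", rng, n_patches=20):
            assert lab == int((mp == POS).any())

    def test_oversize_crop_rejected(self, rng):
        with pytest.raises(ValueError):
            extract_patches(rng.random((8, 8)), np.zeros((8, 8)), 16, "grid")


class TestForward:
    def test_untrained_outputs_half(self, rng):
        model = PatchNet.init(rng)
        cp, pm = forward(model, rng.random((32, 32)))
        assert cp == 0.5
        assert np.all(pm == 0.5)

    def test_outputs_bounded_and_finite(self, rng):
        model = PatchNet.init(rng)
        model.params["w3"] += rng.normal(0, 1, model.params["w3"].shape)
        model.params["w4"] += rng.normal(0, 1, model.params["w4"].shape)
        cp, pm = forward(model, rng.random((32, 32)))
        assert 0.0 <= cp <= 1.0
        assert np.isfinite(pm).all() and pm.min() >= 0 and pm.max() <= 1

    def test_eval_determinism(self, rng):
        model = PatchNet.init(rng)
        patch = rng.random((32, 32))
        out1 = forward(model, patch)
        out2 = forward(model, patch)
        assert out1[0] == out2[0]
        assert np.array_equal(out1[1], out2[1])

    def test_odd_shape_rejected(self, rng):
        with pytest.raises(ValueError):
            forward(PatchNet.init(rng), rng.random((31, 31)))


class TestLosses:
    def test_perfect_prediction_near_zero(self):
        tri = np.array([[POS, NEG], [NEG, NEG]], np.int8)
        probs = np.array([[1.0, 0.0], [0.0, 0.0]])
        assert masked_pixel_loss(probs, tri) <= 1e-6

    def test_ignore_pixels_generate_no_loss(self, rng):
        tri = np.array([[POS, IGNORE], [IGNORE, NEG]], np.int8)
        base = np.array([[0.8, 0.1], [0.9, 0.2]])
        flipped = base.copy()
        flipped[0, 1] = 0.99  # prob at an IGNORE position
        flipped[1, 0] = 0.01
        assert masked_pixel_loss(base, tri) == masked_pixel_loss(flipped, tri)

    def test_all_ignore_is_zero(self):
        tri = np.full((3, 3), IGNORE, np.int8)
        assert masked_pixel_loss(np.full((3, 3), 0.4), tri) == 0.0

    def test_half_half_at_chance_is_ln2(self):
        tri = np.array([[POS, POS], [NEG, NEG]], np.int8)
        loss = masked_pixel_loss(np.full((2, 2), 0.5), tri)
        assert loss == pytest.approx(math.log(2), abs=1e-9)

    def test_classification_closed_forms(self):
        assert classification_loss(0.5, 1) == pytest.approx(math.log(2))
        assert classification_loss(1.0, 1) <= 1e-6
        assert classification_loss(0.3, 1) == pytest.approx(classification_loss(0.7, 0))


class TestGradients:
    def test_backward_matches_finite_differences(self, rng):
        """Analytic gradients of the combined objective vs central differences."""
        from nsseg.dualnet import _batch_objective, _prepare_patch

        model = PatchNet.init(rng, c1=3, c2=4)
        for k in ("w3", "w4"):
            model.params[k] += rng.normal(0, 0.3, model.params[k].shape)
        img = rng.random((8, 8))
        tri = rng.integers(0, 3, (8, 8)).astype(np.int8)
        sample = TrainingSample(image=img, mask=tri)
        prepared = [(img, tri, patch_label(tri), sample)]
        _, grads, _ = _batch_objective(model, prepared, lambda_cls=1.0)

        eps = 1e-6
        for name in ("W1", "W2", "w3", "b3", "w4", "b4"):
            flat = model.params[name].reshape(-1)
            idx = int(rng.integers(0, flat.size))
            for sign in (+1, -1):
                flat[idx] += sign * eps
                loss, _, _ = _batch_objective(model, prepared, 1.0)
                flat[idx] -= sign * eps
                if sign > 0:
                    up = loss
                else:
                    down = loss
            numeric = (up - down) / (2 * eps)
            analytic = grads[name].reshape(-1)[idx]
            assert analytic == pytest.approx(numeric, rel=1e-4, abs=1e-7)


def toy_pool(n_pos=8, n_neg=8, seed=0):
    """Linearly separable corpus: bright discs vs empty heads."""
    spec = DomainSpec(image_size=32, lesion_radius_range=(3.0, 5.0), noise_sd=0.02)
    rng = np.random.default_rng(seed)
    samples, exams = [], []
    for i in range(n_pos + n_neg):
        exam = make_exam(spec, 1, positive=i < n_pos, rng=rng, exam_id=f"t{i}")
        samples.append(TrainingSample(image=exam.images[0], mask=exam.masks[0].astype(np.int8)))
        exams.append(exam)
    return samples, exams


class TestTrain:
    def test_loss_decreases_on_fixed_corpus(self):
        samples, _ = toy_pool()
        cfg = TrainConfig(epochs=6, steps_per_epoch=10, crop_size=16, learning_rate=0.02, seed=0)
        hist = {}
        train(None, samples, None, cfg, rng=np.random.default_rng(0), history=hist)
        assert hist["epoch_loss"][-1] < hist["epoch_loss"][0]

    def test_seeded_training_reproducible(self):
        samples, exams = toy_pool()
        cfg = TrainConfig(epochs=2, steps_per_epoch=5, crop_size=16, seed=0)
        s1 = train(None, samples, None, cfg, rng=np.random.default_rng(0))
        s2 = train(None, samples, None, cfg, rng=np.random.default_rng(0))
        for k in s1:
            assert np.array_equal(s1[k], s2[k])
        p1 = predict_exam(PatchNet.from_state(s1), exams[0], crop_size=16)
        p2 = predict_exam(PatchNet.from_state(s2), exams[0], crop_size=16)
        assert p1.exam_score == p2.exam_score

    def test_mixing_ratio_one_never_samples_pseudo(self):
        samples, _ = toy_pool(4, 4)
        pseudo = [TrainingSample(image=s.image, mask=s.mask, source="pseudo") for s in samples]
        cfg = TrainConfig(epochs=1, steps_per_epoch=8, crop_size=16, mixing_ratio=1.0, seed=0)
        hist = {}
        train(None, samples, pseudo, cfg, rng=np.random.default_rng(0), history=hist)
        assert hist["drawn"].get("pseudo", 0) == 0

    def test_empty_labeled_source_rejected(self):
        with pytest.raises(ValueError):
            train(None, [], None, TrainConfig(epochs=1), rng=np.random.default_rng(0))

    def test_init_weights_not_mutated(self):
        samples, _ = toy_pool(4, 4)
        cfg = TrainConfig(epochs=1, steps_per_epoch=4, crop_size=16, seed=0)
        init = train(None, samples, None, cfg, rng=np.random.default_rng(0))
        frozen = {k: v.copy() for k, v in init.items()}
        train(init, samples, None, cfg, rng=np.random.default_rng(1))
        for k in init:
            assert np.array_equal(init[k], frozen[k])

    def test_ignore_positions_cannot_influence_objective(self):
        """The combined objective (masked pixel BCE + classification BCE)
        is exactly invariant to the model's output at IGNORE positions."""
        rng = np.random.default_rng(3)
        tri = rng.integers(0, 3, (16, 16)).astype(np.int8)
        assert (tri == IGNORE).any()
        probs = rng.random((16, 16))
        perturbed = probs.copy()
        perturbed[tri == IGNORE] = rng.random(int((tri == IGNORE).sum()))
        label = patch_label(tri)

        obj_a = masked_pixel_loss(probs, tri) + classification_loss(0.42, label)
        obj_b = masked_pixel_loss(perturbed, tri) + classification_loss(0.42, label)
        assert obj_a == obj_b
        # and the label itself never counts IGNORE as positive evidence
        all_ignore = np.full_like(tri, IGNORE)
        assert patch_label(all_ignore) == 0

    def test_learning_sanity_separable_corpus(self):
        """Exam AUC >= 0.95 on held-in data for bright-disc vs empty-head."""
        samples, exams = toy_pool(10, 10)
        cfg = TrainConfig(
            epochs=12, steps_per_epoch=15, crop_size=16, learning_rate=0.03, seed=0
        )
        state = train(None, samples, None, cfg, rng=np.random.default_rng(0))
        model = PatchNet.from_state(state)
        scores = [predict_exam(model, e, crop_size=16).exam_score for e in exams]
        labels = [int(e.exam_label) for e in exams]
        assert roc_auc(scores, labels) >= 0.95


class TestPredictExam:
    def test_identical_images_identical_probs(self, rng):
        spec = DomainSpec(image_size=32)
        exam = make_exam(spec, 1, True, np.random.default_rng(0))
        exam.images = [exam.images[0], exam.images[0].copy()]
        exam.masks = [exam.masks[0], exam.masks[0].copy()]
        model = PatchNet.init(rng)
        model.params["w3"] += rng.normal(0, 0.5, model.params["w3"].shape)
        pred = predict_exam(model, exam, crop_size=16)
        assert pred.image_probs[0] == pred.image_probs[1]

    def test_exam_score_is_max_over_images(self, rng):
        spec = DomainSpec(image_size=32)
        exam = make_exam(spec, 4, True, np.random.default_rng(1))
        model = PatchNet.init(rng)
        model.params["w4"] += rng.normal(0, 0.5, model.params["w4"].shape)
        pred = predict_exam(model, exam, crop_size=16)
        assert pred.exam_score == max(pred.image_probs)

    def test_stitched_map_in_unit_interval(self, rng):
        spec = DomainSpec(image_size=48)
        exam = make_exam(spec, 2, True, np.random.default_rng(2))
        model = PatchNet.init(rng)
        model.params["w3"] += rng.normal(0, 1.0, model.params["w3"].shape)
        pred = predict_exam(model, exam, crop_size=32)
        for pm in pred.prob_maps:
            assert pm.shape == exam.images[0].shape
            assert pm.min() >= 0.0 and pm.max() <= 1.0
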