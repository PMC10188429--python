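"""Transformer tests: gradients vs finite differences, training sanity,
attention normalisation, determinism, parameter accounting."""

import numpy as np
import pytest

from eegvit.vit import (
    ViTConfig,
    _backward,
    count_parameters,
    forward,
    init_params,
    patchify,
    predict,
    train,
    unpatchify,
)

TINY = ViTConfig(image_side=16, patch_side=8, embed_dim=8, depth=2, heads=2,
                 mlp_ratio=2, batch_size=4, seed=0)
DESK = ViTConfig.desk()


def _toy_task(rng, n_per_class=10, side=64):
    """Trivially separable: uniformly bright vs uniformly dark images."""
    bright = rng.uniform(0.7, 1.0, (n_per_class, side, side))
    dark = rng.uniform(0.0, 0.3, (n_per_class, side, side))
    x = np.concatenate([bright, dark])
    y = np.array([1] * n_per_class + [0] * n_per_class)
    return x, y


class TestConfig:
    def test_clinical_preset_carries_standard_hyperparameters(self):
        cfg = ViTConfig.clinical()
        assert (cfg.image_side, cfg.patch_side, cfg.depth, cfg.heads) == (224, 16, 12, 8)
        assert (cfg.batch_size, cfg.learning_rate, cfg.epochs) == (64, 1e-3, 5)

    def test_invalid_divisibility_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            ViTConfig(image_side=50, patch_side=16)
        with pytest.raises(ValueError, match="divisible"):
            ViTConfig(embed_dim=100, heads=8)


class TestPatchify:
    @pytest.mark.parametrize(
        "cfg,n_patches,patch_len",
        [(ViTConfig.clinical(), 196, 256), (DESK, 64, 64)],
    )
    def test_patch_counts(self, cfg, n_patches, patch_len, rng):
        img = rng.normal(0, 1, (cfg.image_side, cfg.image_side))
        patches = patchify(img, cfg)
        assert patches.shape == (n_patches, patch_len)

    def test_reassembly_is_exact(self, rng):
        img = rng.normal(0, 1, (64, 64))
        assert np.array_equal(unpatchify(patchify(img, DESK), DESK), img)

    def test_side_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="image_side"):
            patchify(rng.normal(0, 1, (32, 32)), DESK)


class TestGradients:
    def test_backward_matches_finite_differences(self, rng):
        """The strongest correctness check: analytic gradients of every
        parameter tensor agree with central differences."""
        params = init_params(TINY, rng)
        # move off the (zero-head) init so every gradient path is exercised
        for k in params:
            params[k] = params[k] + rng.normal(0, 0.1, params[k].shape)
        x = rng.normal(0, 1, (3, 16, 16))
        y = np.array([0, 1, 1])
        _, grads, _ = _backward(params, x, y, TINY)
        eps = 1e-6
        for key in params:
            flat = params[key].ravel()
            g = grads[key].ravel()
            for i in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp, _, _ = _backward(params, x, y, TINY)
                flat[i] = orig - eps
                lm, _, _ = _backward(params, x, y, TINY)
                flat[i] = orig
                numeric = (lp - lm) / (2 * eps)
                assert abs(numeric - g[i]) <= 1e-5 * max(1.0, abs(numeric)), key

    def test_initial_loss_near_ln2(self, rng):
        params = init_params(DESK, rng)
        x, y = _toy_task(rng)
        loss, _, _ = _backward(params, x, y, DESK)
        assert abs(loss - np.log(2)) < 0.1 * np.log(2)


class TestForward:
    def test_probabilities_normalised_and_bounded(self, rng):
        params = init_params(DESK, rng)
        params["head_w"] = rng.normal(0, 0.2, params["head_w"].shape)
        probs = forward(params, rng.uniform(0, 1, (5, 64, 64)), DESK)
        assert probs.shape == (5, 2)
        assert np.all(probs >= 0) and np.all(probs <= 1)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_attention_rows_sum_to_one(self, rng):
        params = init_params(DESK, rng)
        _, attention = forward(params, rng.uniform(0, 1, (2, 64, 64)), DESK,
                               collect_attention=True)
        assert len(attention) == DESK.depth
        for a in attention:
            assert np.allclose(a.sum(axis=-1), 1.0, atol=1e-6)

    def test_inference_is_deterministic(self, rng):
        params = init_params(DESK, rng)
        x = rng.uniform(0, 1, (4, 64, 64))
        assert np.array_equal(forward(params, x, DESK), forward(params, x, DESK))

    def test_without_positional_embeddings_patch_permutation_is_invisible(self, rng):
        """Equivariance probe: zeroing positions makes the class output
        invariant to patch order, so position handling is real."""
        params = init_params(DESK, rng)
        params["head_w"] = rng.normal(0, 0.2, params["head_w"].shape)
        params["pos"] = np.zeros_like(params["pos"])
        img = rng.uniform(0, 1, (64, 64))
        patches = patchify(img, DESK)
        perm = rng.permutation(patches.shape[0])
        img_perm = unpatchify(patches[perm], DESK)
        p1 = forward(params, img[None], DESK)
        p2 = forward(params, img_perm[None], DESK)
        assert np.allclose(p1, p2, atol=1e-9)
        # with positions restored the permutation must matter
        params2 = init_params(DESK, rng)
        params2["head_w"] = rng.normal(0, 0.2, params2["head_w"].shape)
        q1 = forward(params2, img[None], DESK)
        q2 = forward(params2, img_perm[None], DESK)
        assert not np.allclose(q1, q2, atol=1e-9)


class TestTrain:
    def test_separable_toy_task_fit_exactly_within_five_epochs(self, rng):
        x, y = _toy_task(rng)
        params, trace = train(x, y, DESK)
        assert trace[-1].accuracy == 1.0
        preds, _, _ = predict(params, x, DESK)
        assert np.array_equal(preds, y)

    def test_same_seed_same_data_identical_parameters(self, rng):
        x, y = _toy_task(rng, n_per_class=4)
        cfg = ViTConfig.desk(epochs=2)
        p1, _ = train(x, y, cfg)
        p2, _ = train(x, y, cfg)
        assert p1.keys() == p2.keys()
        for k in p1:
            assert np.array_equal(p1[k], p2[k]), k

    def test_single_class_training_rejected(self, rng):
        x = rng.uniform(0, 1, (6, 64, 64))
        with pytest.raises(ValueError, match="single class"):
            train(x, np.ones(6, dtype=int), DESK)

    def test_parameter_count_closed_form(self, rng):
        # hand-derived for the desk preset:
        #   patch 64*64+64, cls 64, pos 65*64, 2 blocks of
        #   (128 + 12480 + 4160 + 128 + 8320 + 8256), final LN 128, head 130
        assert count_parameters(DESK) == 75586
        params = init_params(DESK, rng)
        assert sum(v.size for v in params.values()) == count_parameters(DESK)


class TestPredict:
    def test_argmax_and_tie_rule(self, rng):
        params = init_params(DESK, rng)
        # zero head => exactly equal logits => tie broken toward control
        params["head_w"] = np.zeros_like(params["head_w"])
        params["head_b"] = np.zeros_like(params["head_b"])
        preds, probs, ties = predict(params, rng.uniform(0, 1, (3, 64, 64)), DESK)
        assert np.all(preds == 0) and np.all(ties)
        assert np.allclose(probs, 0.5)

    def test_shape_mismatch_rejected(self, rng):
        params = init_params(DESK, rng)
        with pytest.raises(ValueError, match="image"):
            predict(params, rng.uniform(0, 1, (2, 32, 32)), DESK)


def test_model_roundtrip_through_disk(tmp_path, rng):
    from eegvit.vit import load_model, save_model

    x, y = _toy_task(rng, n_per_class=3)
    cfg = ViTConfig.desk(epochs=1)
    params, trace = train(x, y, cfg)
    save_model(tmp_path / "model.npz", params, cfg, trace)
    loaded, cfg2 = load_model(tmp_path / "model.npz")
    assert cfg2 == cfg
    for k in params:
        assert np.array_equal(params[k], loaded[k])
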