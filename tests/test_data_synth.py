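"""Synthetic scenes, augmentation ops, dataset building and splitting."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage.measure import label

from pestseg.augment import (AugmentSpec, augment, cutmix, enhance, hflip,
                             mixup, rotate, shift, vflip)
from pestseg.synth import (SceneSpec, SynthDataset, generate_dataset,
                           generate_scene, split_indices)


class TestSceneGeneration:
    def test_no_pests_means_empty_mask(self):
        img, mask = generate_scene(SceneSpec(n_pests=0), seed=1)
        assert mask.sum() == 0
        assert img.shape == (64, 64, 3) and img.dtype == np.uint8

    def test_nonoverlapping_pests_form_distinct_components(self):
        spec = SceneSpec(n_pests=3, non_overlap=True)
        for seed in range(5):
            _, mask = generate_scene(spec, seed=seed)
            n = label(mask, connectivity=2).max()
            assert n == 3

    def test_same_seed_bit_identical(self):
        spec = SceneSpec()
        a_img, a_mask = generate_scene(spec, seed=9)
        b_img, b_mask = generate_scene(spec, seed=9)
        assert np.array_equal(a_img, b_img)
        assert np.array_equal(a_mask, b_mask)

    def test_mask_codes_and_image_range(self):
        for seed in range(3):
            img, mask = generate_scene(SceneSpec(n_pests=4), seed=seed)
            assert set(np.unique(mask)) <= {0, 1}
            assert img.dtype == np.uint8

    def test_pests_darker_than_background(self):
        img, mask = generate_scene(SceneSpec(contrast=0.6), seed=2)
        assert img[mask == 1].mean() < img[mask == 0].mean()

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SceneSpec(n_pests=-1)
        with pytest.raises(ValueError):
            SceneSpec(scale_range=(0.1, 0.9))


class TestDatasetBuilding:
    def test_rebalance_tops_up_rare_categories(self, tmp_path):
        ds = generate_dataset(class_profile={"A": 10, "B": 2},
                              rebalance_floor=5, seed=0)
        m = ds.manifest
        assert len(ds) == 15
        b_aug = m[(m.category == "B") & (m.provenance == "augmented")]
        assert len(b_aug) == 3
        assert (m[m.category == "A"].provenance == "original").all()

    def test_zero_floor_adds_nothing(self):
        ds = generate_dataset(class_profile={"A": 3, "B": 2}, seed=0)
        assert (ds.manifest.provenance == "original").all()
        assert len(ds) == 5

    def test_provenance_counts_conserve_size(self):
        ds = generate_dataset(class_profile={"A": 4, "B": 1, "C": 2},
                              rebalance_floor=3, seed=1)
        counts = ds.manifest.provenance.value_counts()
        assert counts.get("original", 0) + counts.get("augmented", 0) == len(ds)

    def test_save_and_reload_roundtrip(self, tmp_path):
        from pestseg.data import load_directory

        ds = generate_dataset(n_images=3, seed=5, out_dir=tmp_path)
        images, masks, manifest = load_directory(tmp_path)
        assert np.array_equal(images, ds.images)
        assert np.array_equal(masks, ds.masks)
        assert list(manifest.filename) == list(ds.manifest.filename)


class TestAugmentOps:
    @pytest.fixture
    def pair(self):
        return generate_scene(SceneSpec(n_pests=2), seed=4)

    def test_flip_involutions(self, pair):
        img, mask = pair
        for op in (hflip, vflip):
            i2, m2 = op(*op(img, mask))
            assert np.array_equal(i2, img)
            assert np.array_equal(m2, mask)

    def test_zero_rotation_and_shift_are_identity(self, pair):
        img, mask = pair
        i2, m2 = rotate(img, mask, 0.0)
        assert np.array_equal(i2, img) and np.array_equal(m2, mask)
        i3, m3 = shift(img, mask, 0, 0)
        assert np.array_equal(i3, img) and np.array_equal(m3, mask)

    def test_right_angle_rotation_preserves_pest_pixel_count(self, pair):
        """90-degree rotation of a square scene is a lossless permutation."""
        img, mask = pair
        _, m2 = rotate(img, mask, 90.0)
        assert m2.sum() == mask.sum()
        assert np.array_equal(m2, np.rot90(mask))

    def test_arbitrary_rotation_keeps_binary_codes(self, pair):
        img, mask = pair
        _, m2 = rotate(img, mask, 17.3)
        assert set(np.unique(m2)) <= {0, 1}

    def test_enhance_touches_image_only(self, pair):
        img, mask = pair
        bright = enhance(img, 1.2, 1.0)
        assert bright.dtype == img.dtype
        assert bright.mean() >= img.mean()

    def test_augment_pipeline_preserves_pairing(self, pair):
        img, mask = pair
        spec = AugmentSpec(prob=1.0)
        i2, m2 = augment(img, mask, spec, rng=3)
        assert i2.shape == img.shape and m2.shape == mask.shape
        assert set(np.unique(m2)) <= {0, 1}

    def test_shape_mismatch_rejected(self, pair):
        img, mask = pair
        with pytest.raises(ValueError):
            hflip(img, mask[:10])


class TestMixup:
    def test_endpoint_returns_first_pair(self, rng):
        p1 = generate_scene(SceneSpec(), seed=1)
        p2 = generate_scene(SceneSpec(), seed=2)
        img, soft = mixup(p1, p2, lam=1.0)
        assert np.array_equal(img, p1[0])
        assert np.array_equal(np.argmax(soft, -1), p1[1])

    def test_midpoint_of_black_and_white(self):
        white = np.full((8, 8, 3), 255, np.uint8), np.zeros((8, 8), np.uint8)
        black = np.zeros((8, 8, 3), np.uint8), np.zeros((8, 8), np.uint8)
        img, _ = mixup(white, black, lam=0.5)
        assert np.all(np.abs(img.astype(int) - 128) <= 1)

    def test_soft_mask_rows_sum_to_one(self):
        p1 = generate_scene(SceneSpec(), seed=1)
        p2 = generate_scene(SceneSpec(), seed=2)
        _, soft = mixup(p1, p2, lam=0.3)
        assert np.allclose(soft.sum(-1), 1.0)
        assert soft.min() >= 0.0

    def test_invalid_lambda_rejected(self):
        p = generate_scene(SceneSpec(), seed=1)
        with pytest.raises(ValueError):
            mixup(p, p, lam=1.5)


class TestCutMix:
    def test_near_full_area_returns_second_content(self):
        p1 = generate_scene(SceneSpec(), seed=1)
        p2 = generate_scene(SceneSpec(), seed=2)
        img, mask, _ = cutmix(p1, p2, area_frac=0.999999, rng=0)
        assert np.array_equal(img, p2[0])
        assert np.array_equal(mask, p2[1])

    def test_pixel_set_arithmetic(self):
        """Pest pixels = pair1 outside the box plus pair2 inside the box."""
        p1 = generate_scene(SceneSpec(n_pests=2), seed=3)
        p2 = generate_scene(SceneSpec(n_pests=3), seed=4)
        img, mask, (top, left, bh, bw) = cutmix(p1, p2, 0.3, rng=5)
        inside = np.zeros_like(mask, dtype=bool)
        inside[top:top + bh, left:left + bw] = True
        assert np.array_equal(mask[inside], p2[1][inside])
        assert np.array_equal(mask[~inside], p1[1][~inside])
        assert mask.sum() == p1[1][~inside].sum() + p2[1][inside].sum()

    def test_same_seed_same_box(self):
        p1 = generate_scene(SceneSpec(), seed=1)
        p2 = generate_scene(SceneSpec(), seed=2)
        a = cutmix(p1, p2, 0.4, rng=7)
        b = cutmix(p1, p2, 0.4, rng=7)
        assert a[2] == b[2]
        assert np.array_equal(a[0], b[0])


class TestSplitting:
    def test_exact_sizes_for_ten_items(self):
        sp = split_indices(10, seed=0)
        assert (len(sp.train), len(sp.val), len(sp.test)) == (6, 2, 2)

    def test_published_dataset_size_splits(self):
        # the 9,314-image augmented corpus at 6:2:2
        sp = split_indices(9314, seed=0)
        assert (len(sp.train), len(sp.val), len(sp.test)) == (5588, 1863, 1863)

    @given(n=st.integers(3, 300), seed=st.integers(0, 10_000))
    @settings(max_examples=150, deadline=None)
    def test_partition_for_any_size_and_seed(self, n, seed):
        sp = split_indices(n, seed=seed)
        all_idx = np.concatenate([sp.train, sp.val, sp.test])
        assert len(all_idx) == n
        assert set(all_idx.tolist()) == set(range(n))

    @given(seed=st.integers(0, 200))
    @settings(max_examples=120, deadline=None)
    def test_augmented_items_never_leak_into_val_or_test(self, seed):
        prov = np.array(["original"] * 20 + ["augmented"] * 10)
        sp = split_indices(30, seed=seed, provenance=prov)
        assert set(np.concatenate([sp.val, sp.test]).tolist()) <= set(range(20))
        assert set(sp.train.tolist()) >= set(range(20, 30))

    def test_too_small_dataset_rejected(self):
        with pytest.raises(ValueError):
            split_indices(2)

    def test_insufficient_originals_rejected(self):
        prov = np.array(["original"] * 2 + ["augmented"] * 8)
        with pytest.raises(ValueError, match="original"):
            split_indices(10, seed=0, provenance=prov)


class TestBatchMixer:
    def test_soft_targets_remain_probabilities(self):
        from pestseg.augment import make_batch_mixer

        rng = np.random.default_rng(0)
        imgs = rng.random((4, 16, 16, 3))
        masks = rng.integers(0, 2, (4, 16, 16))
        mixer = make_batch_mixer(mixup_prob=1.0, cutmix_prob=0.0)
        mi, soft = mixer(imgs, masks, np.random.default_rng(1))
        assert soft.shape == (4, 16, 16, 2)
        assert np.allclose(soft.sum(-1), 1.0)
        assert soft.min() >= 0.0
        assert mi.shape == imgs.shape

    def test_cutmix_mode_keeps_hard_labels(self):
        from pestseg.augment import make_batch_mixer

        rng = np.random.default_rng(0)
        imgs = rng.random((4, 16, 16, 3))
        masks = rng.integers(0, 2, (4, 16, 16))
        mixer = make_batch_mixer(mixup_prob=0.0, cutmix_prob=1.0)
        _, soft = mixer(imgs, masks, np.random.default_rng(2))
        assert set(np.unique(soft)) <= {0.0, 1.0}

    def test_disabled_mixing_returns_one_hot(self):
        from pestseg.augment import make_batch_mixer

        imgs = np.zeros((2, 8, 8, 3))
        masks = np.ones((2, 8, 8), dtype=int)
        mixer = make_batch_mixer(mixup_prob=0.0, cutmix_prob=0.0)
        mi, soft = mixer(imgs, masks, np.random.default_rng(0))
        assert np.array_equal(mi, imgs)
        assert np.all(soft[..., 1] == 1.0)

    def test_training_accepts_mixed_batches(self, tiny_scenes):
        from pestseg.augment import make_batch_mixer
        from pestseg.data import images_to_float
        from pestseg.network import ModelConfig, PestSegNet
        from pestseg.training import TrainConfig, train

        imgs, masks = tiny_scenes
        net = PestSegNet(ModelConfig(base_channels=16,
                                     encoder_depths=(1, 1, 1, 1),
                                     decoder_depths=(1, 1, 1, 1),
                                     state_size=4, seed=0))
        _, _, _, losses = train(
            net, images_to_float(imgs[:4]), masks[:4],
            train_config=TrainConfig(iterations=2, batch_size=4, eval_every=2),
            batch_augment=make_batch_mixer(mixup_prob=1.0, cutmix_prob=0.0))
        assert len(losses) == 2 and all(np.isfinite(losses))


class TestSSMState:
    def test_zero_initialisation_and_validation(self):
        from pestseg.ssm import SSMState

        st = SSMState.zeros(3, 4)
        assert st.h.shape == (3, 4) and not st.h.any()
        with pytest.raises(ValueError):
            SSMState(np.full((2, 2), np.nan))
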