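"""Generator contracts: determinism, downsampling consistency, mixture
structure, dataset round trips, and the designed multi-scale learnability split."""

import numpy as np
import pytest

from mcvit.io import load_patch_arrays, read_manifest, read_manifest_seed
from mcvit.synthetic import (
    DEFAULT_TYPE_COMPOSITION,
    SynthConfig,
    area_downsample,
    generate_wsi_bag,
    make_triplet,
    radial_power_spectrum,
    render_scene,
    render_template,
    sample_patch_labels,
    synthetic_patch_embeddings,
    write_dataset,
)


class TestRenderScene:
    def test_deterministic_given_label_and_seed(self, small_synth_config):
        a = render_scene(3, np.random.default_rng(7), small_synth_config)
        b = render_scene(3, np.random.default_rng(7), small_synth_config)
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("label", range(10))
    def test_intensities_in_unit_interval(self, label, small_synth_config, rng):
        img = render_scene(label, rng, small_synth_config)
        assert img.shape == (64, 64, 3)
        assert img.min() >= 0.0 and img.max() <= 1.0

    def test_unknown_label_rejected(self, small_synth_config, rng):
        with pytest.raises(ValueError, match="0..9"):
            render_scene(10, rng, small_synth_config)
        with pytest.raises(ValueError, match="0..9"):
            render_scene(-1, rng, small_synth_config)

    def test_noiseless_render_equals_template(self):
        cfg = SynthConfig(scene_size=64, noise_sd=0.0, jitter_frac=0.0,
                          clutter_pairs_per_block=0)
        img = render_scene(4, np.random.default_rng(42), cfg)
        assert np.array_equal(img, render_template(4, 64))

    def test_different_seeds_same_class_share_spectra(self, small_synth_config):
        """Renders differ across seeds but their radial power spectra are a
        class signature: two disjoint seed-group means agree closely."""
        def group_spectrum(seeds):
            specs = [radial_power_spectrum(
                render_scene(0, np.random.default_rng(s), small_synth_config))
                for s in seeds]
            return np.mean(specs, axis=0)

        a = group_spectrum(range(0, 50))
        b = group_spectrum(range(50, 100))
        img_a = render_scene(0, np.random.default_rng(1), small_synth_config)
        img_b = render_scene(0, np.random.default_rng(2), small_synth_config)
        assert not np.array_equal(img_a, img_b)
        nonzero = a > 1e-12
        assert np.abs(a[nonzero] - b[nonzero]).max() / a[nonzero].max() < 0.15


class TestMakeTriplet:
    def test_constant_scene_constant_at_all_scales(self):
        t = make_triplet(np.full((64, 64, 3), 0.5), 0)
        for img in (t.img10, t.img20, t.img40):
            assert np.allclose(img, 0.5)

    def test_checkerboard_period_two_averages_to_mean(self):
        scene = np.zeros((64, 64, 3))
        scene[::2, ::2] = 1.0
        scene[1::2, 1::2] = 1.0
        t = make_triplet(scene, 0)
        assert np.allclose(t.img20, 0.5)

    def test_published_triplet_shapes(self):
        t = make_triplet(np.random.default_rng(0).random((256, 256, 3)), 0)
        assert t.img10.shape == (64, 64, 3)
        assert t.img20.shape == (128, 128, 3)
        assert t.img40.shape == (256, 256, 3)

    def test_mean_conserved_across_scales(self, small_synth_config, rng):
        for label in (0, 4, 9):
            t = make_triplet(render_scene(label, rng, small_synth_config), label)
            assert abs(t.img40.mean() - t.img20.mean()) < 1e-6
            assert abs(t.img40.mean() - t.img10.mean()) < 1e-6

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError, match="scene"):
            make_triplet(np.zeros((64, 32, 3)), 0)

    def test_area_downsample_is_block_mean(self, rng):
        img = rng.random((8, 8, 3))
        down = area_downsample(img, 4)
        assert np.allclose(down[0, 0], img[:4, :4].mean(axis=(0, 1)))


class TestBags:
    def test_configured_patch_count(self, small_synth_config, rng):
        bag = generate_wsi_bag(2, small_synth_config, rng)
        assert len(bag.triplets) == small_synth_config.patches_per_wsi
        assert abs(bag.composition.sum() - 1.0) < 1e-9

    def test_default_composition_rows_stochastic(self):
        assert DEFAULT_TYPE_COMPOSITION.shape == (8, 10)
        assert np.allclose(DEFAULT_TYPE_COMPOSITION.sum(axis=1), 1.0)

    def test_one_hot_composition_degenerates(self, rng):
        comp = np.zeros((8, 10))
        comp[:, 5] = 1.0
        cfg = SynthConfig(scene_size=64, patches_per_wsi=8, type_composition=comp)
        bag = generate_wsi_bag(0, cfg, rng)
        assert all(t.patho_label == 5 for t in bag.triplets)

    def test_empirical_frequencies_within_three_se(self, rng):
        """10,000 label draws from the type-A mixture match the sampled
        composition within 3 multinomial standard errors per class."""
        cfg = SynthConfig(scene_size=64)
        comp, labels = sample_patch_labels(0, 10_000, cfg, rng)
        freq = np.bincount(labels, minlength=10) / 10_000
        se = np.sqrt(comp * (1 - comp) / 10_000)
        assert np.all(np.abs(freq - comp) <= 3 * se + 1e-12)

    def test_invalid_type_rejected(self, small_synth_config, rng):
        with pytest.raises(ValueError, match="0..7"):
            generate_wsi_bag(8, small_synth_config, rng)

    def test_mixed_type_rows_average_components(self):
        assert np.allclose(DEFAULT_TYPE_COMPOSITION[3],
                           (DEFAULT_TYPE_COMPOSITION[2] + DEFAULT_TYPE_COMPOSITION[4]) / 2)


class TestWriteDataset:
    def test_round_trip_and_counts(self, tmp_path, rng):
        cfg = SynthConfig(scene_size=64, patches_per_wsi=10, n_wsis_per_type=1)
        bags = [generate_wsi_bag(t, cfg, rng, wsi_id=f"w{t}") for t in (0, 1)]
        manifest = write_dataset(bags, tmp_path, cfg)
        df = read_manifest(manifest)
        assert len(df) == 20
        assert read_manifest_seed(manifest) == cfg.seed
        # field-identical round trip
        row = df.iloc[0]
        assert row["wsi_id"] == "w0"
        assert row["patho_label"] == bags[0].triplets[0].patho_label
        assert row["thymoma_type"] == 0
        # pixel round trip within PNG quantisation
        arrays = load_patch_arrays(df.iloc[:2], tmp_path)
        assert np.abs(arrays["img40"][0] - bags[0].triplets[0].img40).max() <= 1 / 255 + 1e-12

    def test_no_wsi_in_both_splits(self, tmp_path, rng):
        cfg = SynthConfig(scene_size=64, patches_per_wsi=4, n_wsis_per_type=4)
        bags = [generate_wsi_bag(t // 4, cfg, rng, wsi_id=f"w{t}") for t in range(8)]
        manifest = write_dataset(bags, tmp_path, cfg)
        df = read_manifest(manifest)
        per_wsi = df.groupby("wsi_id")["split"].nunique()
        assert (per_wsi == 1).all()
        assert set(df["split"]) == {"train", "test"}

    def test_byte_identical_given_seed(self, tmp_path):
        cfg = SynthConfig(scene_size=64, patches_per_wsi=4, n_wsis_per_type=1, seed=5)
        trees = []
        for sub in ("a", "b"):
            rng = np.random.default_rng(cfg.seed)
            bags = [generate_wsi_bag(0, cfg, rng, wsi_id="w0")]
            write_dataset(bags, tmp_path / sub, cfg)
            files = sorted((tmp_path / sub).rglob("*"))
            trees.append({f.relative_to(tmp_path / sub): f.read_bytes()
                          for f in files if f.is_file()})
        assert trees[0] == trees[1]


class TestLearnabilitySplit:
    """The designed scale split: the coarse-only pair is separable from the
    10x view but not (at fixed budget) from the cluttered 40x view; the
    fine-only pair is the reverse. Reference classifier: logistic regression
    on raw pixels, 60 training fields per class."""

    @staticmethod
    def _pair_accuracies(pair, n_train=60, n_test=60):
        from sklearn.linear_model import LogisticRegression

        cfg = SynthConfig(scene_size=64)

        def build(n, seed):
            r = np.random.default_rng(seed)
            X40, X10, y = [], [], []
            for _ in range(n):
                for ci, lab in enumerate(pair):
                    t = make_triplet(render_scene(lab, r, cfg), lab)
                    X40.append(t.img40.ravel())
                    X10.append(t.img10.ravel())
                    y.append(ci)
            return np.array(X40), np.array(X10), np.array(y)

        X40tr, X10tr, ytr = build(n_train, 0)
        X40te, X10te, yte = build(n_test, 1)
        acc = {}
        for name, Xtr, Xte in (("40x", X40tr, X40te), ("10x", X10tr, X10te)):
            clf = LogisticRegression(max_iter=500).fit(Xtr, ytr)
            acc[name] = clf.score(Xte, yte)
        return acc

    def test_coarse_pair_needs_low_magnification(self):
        acc = self._pair_accuracies((4, 7))
        assert acc["10x"] - acc["40x"] >= 0.15
        assert acc["40x"] <= 0.85   # below ceiling at the fine scale

    def test_fine_pair_needs_high_magnification(self):
        acc = self._pair_accuracies((2, 3))
        assert acc["40x"] - acc["10x"] >= 0.15


def test_synthetic_embeddings_cluster_by_label(rng):
    labels = rng.integers(0, 10, 200)
    emb = synthetic_patch_embeddings(labels, rng)
    assert emb.shape == (200, 768)
    same = emb[labels == 3][:, 3].mean()
    other = emb[labels != 3][:, 3].mean()
    assert same > other + 0.5
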