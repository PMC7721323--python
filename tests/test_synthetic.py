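"""Synthetic rosette scenes: determinism, ground truth, state statistics."""

import math

import numpy as np
import pytest
from scipy import stats

from rosettephen import (
    SceneParams,
    channel_means,
    generate_rosette,
    generate_time_series,
    process_image,
    write_dataset,
)


class TestGenerateRosette:
    def test_same_seed_and_index_reproduce_the_scene(self):
        params = SceneParams(seed=3, state_probabilities=(0.5, 0.3, 0.2))
        a, b = generate_rosette(params, index=4), generate_rosette(params, index=4)
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.truth.labels, b.truth.labels)

    def test_different_index_changes_the_scene(self):
        params = SceneParams(seed=3)
        a, b = generate_rosette(params, index=0), generate_rosette(params, index=1)
        assert (a.image != b.image).any()

    def test_zero_leaves_is_pure_background(self):
        scene = generate_rosette(SceneParams(leaf_count=0, seed=1))
        assert scene.class_counts["background"] == scene.truth.labels.size
        assert (scene.truth.labels == 0).all()

    def test_degenerate_state_mix_yields_only_norm(self):
        scene = generate_rosette(
            SceneParams(seed=2, state_probabilities=(1.0, 0.0, 0.0))
        )
        assert scene.class_counts["class_antho"] == 0
        assert scene.class_counts["class_senesc"] == 0
        assert scene.class_counts["class_norm"] > 0

    def test_counts_match_mask_tallies(self, mixed_scene):
        assert mixed_scene.class_counts == mixed_scene.truth.class_counts()

    def test_oversized_leaves_are_clipped_not_an_error(self):
        scene = generate_rosette(
            SceneParams(size=(48, 48), leaf_length=(200.0, 1.0), seed=1)
        )
        assert scene.truth.labels.shape == (48, 48)

    @pytest.mark.parametrize(
        "background", ["solid", "blue_mesh", "soil", "soil_with_algae"]
    )
    def test_backgrounds_render(self, background):
        scene = generate_rosette(SceneParams(seed=1, background=background))
        assert scene.image.dtype == np.uint8

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SceneParams(state_probabilities=(0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            SceneParams(background="lawn")
        with pytest.raises(ValueError):
            SceneParams(leaf_count=-1)

    def test_state_pixel_fractions_match_probabilities(self):
        # Monte-Carlo: leaf states are drawn per leaf, so the pixel fraction
        # of each state over many scenes should sit within 3 binomial SEs
        # (on the leaf count) of its probability.
        p = (0.5, 0.3, 0.2)
        params = SceneParams(seed=77, state_probabilities=p, leaf_count=8)
        totals = np.zeros(3)
        n_leaves = 0
        for i in range(200):
            counts = generate_rosette(params, index=i).class_counts
            totals += (
                counts["class_norm"], counts["class_antho"], counts["class_senesc"],
            )
            n_leaves += params.leaf_count
        fractions = totals / totals.sum()
        for frac, prob in zip(fractions, p):
            se = math.sqrt(prob * (1 - prob) / n_leaves)
            assert abs(frac - prob) < 3 * se

    def test_channel_means_recover_state_colors_at_zero_spread(self):
        scene = generate_rosette(
            SceneParams(seed=8, color_spread=0.0,
                        state_probabilities=(1.0, 0.0, 0.0))
        )
        m = channel_means(scene.image, scene.truth, "class_norm")
        assert (m.n_red, m.n_green, m.n_blue) == scene.true_colors["class_norm"]

    def test_process_image_areas_equal_generator_counts(self, mixed_scene):
        row = process_image(mixed_scene.image, mixed_scene.truth, "s")
        for cls in ("class_norm", "class_antho", "class_senesc"):
            assert row[f"{cls}_area"] == mixed_scene.class_counts[cls]
        assert row["background_area"] == mixed_scene.class_counts["background"]


class TestTimeSeries:
    @staticmethod
    def linear_senescence(age):
        # linear ramp to complete senescence at age 9, as rosettes at the
        # end of a long growth experiment approach fully senescent canopies
        p_sen = min(1.0, age / 9)
        p_antho = 0.05 * (1 - p_sen)
        return (1.0 - p_sen - p_antho, p_antho, p_sen)

    def test_non_monotone_ages_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            generate_time_series(
                SceneParams(), [0, 2, 1], self.linear_senescence
            )

    def test_reproducible_per_replicate(self):
        base = SceneParams(seed=5)
        s1 = generate_time_series(base, [0, 1, 2], self.linear_senescence, replicate=3)
        s2 = generate_time_series(base, [0, 1, 2], self.linear_senescence, replicate=3)
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.image, b.image)

    def test_leaf_count_grows_with_age(self):
        scenes = generate_time_series(
            SceneParams(seed=5, leaf_count=4), [0, 1, 2, 3],
            self.linear_senescence,
        )
        assert [s.params.leaf_count for s in scenes] == [4, 5, 6, 7]

    def test_constant_mapping_gives_flat_state_fractions(self):
        scenes = [
            s
            for rep in range(10)
            for s in generate_time_series(
                SceneParams(seed=6, leaf_count=8),
                list(range(8)),
                lambda age: (0.6, 0.2, 0.2),
                replicate=rep,
            )
        ]
        ages = [s.index % 100003 for s in scenes]
        fracs = [
            s.class_counts["class_senesc"]
            / max(1, s.truth.labels.size - s.class_counts["background"])
            for s in scenes
        ]
        rho, _ = stats.spearmanr(ages, fracs)
        assert abs(rho) < 0.35

    def test_increasing_senescence_recovered_by_rank_correlation(self):
        ages = list(range(10))
        all_ages, all_fracs = [], []
        for rep in range(20):
            for scene, age in zip(
                generate_time_series(
                    SceneParams(seed=41, leaf_count=6), ages,
                    self.linear_senescence, replicate=rep,
                ),
                ages,
            ):
                plant = scene.truth.labels.size - scene.class_counts["background"]
                all_ages.append(age)
                all_fracs.append(scene.class_counts["class_senesc"] / max(1, plant))
        rho, _ = stats.spearmanr(all_ages, all_fracs)
        assert rho > 0.9


class TestWriteDataset:
    def test_writes_images_masks_and_truth(self, tmp_path):
        truth = write_dataset(tmp_path, n=3, seed=1, preset="mixed")
        assert truth.exists()
        assert len(list((tmp_path / "images").glob("*.png"))) == 3
        assert len(list((tmp_path / "masks").glob("*.png"))) == 3
        header = truth.read_text().splitlines()[0]
        assert header.startswith("image_id,")

    def test_timeseries_preset(self, tmp_path):
        write_dataset(tmp_path, n=4, seed=1, preset="timeseries")
        assert len(list((tmp_path / "images").glob("*.png"))) == 4
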