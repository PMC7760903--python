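"""Rank-test machinery and the pattern matrices."""

import itertools

import numpy as np
import pytest

import thermopattern as tp
from thermopattern.io import DatasetError, PixelSample


def exact_mww_p(x, y, direction):
    """Independent oracle: enumerate all rank assignments of the pooled data.

    For samples without ties, every split of the pooled values into the
    two groups is equally likely under the null; the one-sided p-value
    is the fraction of splits whose U statistic is at least as extreme
    as the observed one (in the stated direction).
    """
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)

    def u_stat(first, second):
        return sum(1 for a in first for b in second if a > b)

    observed = u_stat(x, y) if direction == "x_greater" else u_stat(y, x)
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        first = [pooled[i] for i in idx]
        second = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_stat(first, second) if direction == "x_greater" else u_stat(second, first)
        count += u >= observed
        total += 1
    return count / total


class TestDrawSamples:
    def test_sizes_equalised_to_smaller(self):
        rng = np.random.default_rng(0)
        a = PixelSample(np.arange(50.0), "a")
        b = PixelSample(np.arange(200.0), "b")
        x, y = tp.draw_test_samples(a, b, rng)
        assert len(x) == len(y) == 50

    def test_equal_sizes_returned_whole(self):
        rng = np.random.default_rng(0)
        a = PixelSample(np.arange(30.0), "a")
        b = PixelSample(np.arange(30.0, 60.0), "b")
        x, y = tp.draw_test_samples(a, b, rng)
        np.testing.assert_array_equal(x, a.values)
        np.testing.assert_array_equal(y, b.values)

    def test_subsample_is_without_replacement_and_unbiased(self):
        rng = np.random.default_rng(1)
        a = PixelSample(np.zeros(10), "a")
        b_values = np.random.default_rng(2).normal(5.0, 1.0, size=1000)
        b = PixelSample(b_values, "b")
        means = []
        for _ in range(1000):
            _, y = tp.draw_test_samples(a, b, rng)
            assert len(np.unique(y)) == len(y)  # continuous values: no repeats
            means.append(y.mean())
        # Monte-Carlo average of subsample means converges to the population mean
        assert abs(np.mean(means) - b_values.mean()) < 4 * b_values.std() / np.sqrt(10 * 1000)

    def test_empty_sample_names_its_source(self):
        rng = np.random.default_rng(0)
        with pytest.raises(DatasetError, match="H.3/roi2"):
            tp.draw_test_samples(
                PixelSample(np.empty(0), "H.3/roi2"), PixelSample(np.ones(3), "b"), rng
            )

    def test_subsample_both_rule_draws_both_sides(self):
        rng = np.random.default_rng(3)
        a = PixelSample(np.arange(30.0), "a")
        b = PixelSample(np.arange(100.0, 160.0), "b")
        x, y = tp.draw_test_samples(a, b, rng, n_rule="subsample_both")
        assert len(x) == len(y) == 30


class TestMWW:
    def test_textbook_extreme_case(self):
        """x={1,2}, y={3,4}: the observed split is the most extreme of C(4,2)=6."""
        result = tp.mww_one_sided([1, 2], [3, 4], "y_greater")
        assert result.p_value == pytest.approx(1 / 6, abs=1e-12)
        assert result.direction == "second_greater"

    @pytest.mark.parametrize("n1,n2", [(1, 3), (2, 2), (3, 4), (4, 4), (5, 6), (6, 6), (2, 9)])
    @pytest.mark.parametrize("direction", ["x_greater", "y_greater"])
    def test_small_sample_p_matches_exact_enumeration(self, n1, n2, direction):
        rng = np.random.default_rng(n1 * 100 + n2)
        for _ in range(5):
            pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))  # distinct -> no ties
            x, y = pooled[:n1], pooled[n1:]
            ours = tp.mww_one_sided(x, y, direction).p_value
            oracle = exact_mww_p(x, y, direction)
            assert ours == pytest.approx(oracle, rel=1e-10)

    def test_identical_samples_give_no_evidence(self):
        values = [1.0, 2.0, 3.0, 4.0]
        for direction in ("x_greater", "y_greater"):
            assert tp.mww_one_sided(values, values, direction).p_value >= 0.5

    def test_all_tied_input_is_flagged(self):
        result = tp.mww_one_sided([5.0] * 10, [5.0] * 8, "x_greater")
        assert result.p_value == 1.0
        assert result.direction == "tie"

    def test_species_level_separation_is_detected(self):
        rng = np.random.default_rng(4)
        x = rng.normal(22.72, 2.46, 500)
        y = rng.normal(18.88, 2.30, 500)
        assert tp.mww_one_sided(x, y, "x_greater").p_value < 0.001

    def test_n_used_is_min_size(self):
        result = tp.mww_one_sided(np.arange(7.0), np.arange(12.0) + 0.5, "x_greater")
        assert result.n_used == 7


class TestDifferenceMatrix:
    def test_antisymmetric_with_zero_diagonal(self, study_dataset):
        for species in ("horse", "donkey"):
            diff = tp.difference_matrix(study_dataset, species)
            np.testing.assert_array_equal(diff.deltas + diff.deltas.T, np.zeros((10, 10)))
            np.testing.assert_array_equal(np.diag(diff.deltas), np.zeros(10))

    def test_rump_neck_contrast_matches_designed_profile(self, study_dataset):
        """Horse Rump minus Neck is designed at -2.12 °C."""
        diff = tp.difference_matrix(study_dataset, "horse")
        pixel_se = 3 * 2.46 / np.sqrt(16 * 2 * 324)  # generous pooled bound
        assert diff.deltas[4, 0] == pytest.approx(-2.12, abs=max(0.05, 3 * pixel_se))

    def test_gor_delta_matches_brute_force_means(self, tiny_dataset):
        gors = tp.default_gors()
        diff = tp.difference_matrix(tiny_dataset, "horse")
        pooled = [
            np.concatenate(
                [tp.gor_pixels(r, g).values for r in tiny_dataset.animals("horse")]
            )
            for g in gors
        ]
        for i, j in ((0, 1), (4, 0), (2, 9)):
            expected = pooled[i].mean() - pooled[j].mean()
            assert diff.deltas[i, j] == pytest.approx(expected, abs=1e-12)


class TestGlobalSignificance:
    def test_flags_symmetric_false_diagonal(self, study_matrices):
        for diff, _ in study_matrices.values():
            np.testing.assert_array_equal(diff.significant, diff.significant.T)
            assert not diff.significant.diagonal().any()

    def test_horse_exceptions_are_the_five_designed_pairs(self, study_matrices):
        diff, _ = study_matrices["horse"]
        assert set(diff.nonsignificant_pairs()) == {
            (1, 2), (3, 7), (3, 8), (7, 8), (5, 10),
        }

    def test_donkey_exceptions_are_the_two_designed_pairs(self, study_matrices):
        diff, _ = study_matrices["donkey"]
        assert set(diff.nonsignificant_pairs()) == {(3, 9), (7, 8)}


class TestLocalCounts:
    def test_counts_symmetric_and_bounded(self, study_matrices):
        for _, local in study_matrices.values():
            np.testing.assert_array_equal(local.counts, local.counts.T)
            assert local.counts.min() >= 0
            assert local.counts.max() <= local.n_animals
            assert not local.counts.diagonal().any()

    def test_strong_contrast_is_supported_by_every_animal(self, study_matrices):
        """Rump vs Neck (|delta| > 2 °C at low pixel noise) counts all 16."""
        _, local = study_matrices["horse"]
        assert local.counts[4, 0] == local.n_animals

    def test_monotone_in_effect_size(self, tiny_layout):
        counts = []
        for separation in (0.0, 0.6, 3.0):
            offsets = [0.0] * 15
            offsets[0] = offsets[1] = offsets[2] = separation  # lift all of Neck
            cfg = tp.SpeciesConfig(
                name="horse", n_animals=4, global_mean=20.0, roi_offsets=tuple(offsets),
                animal_sd=0.5, pixel_sd=1.0,
            )
            other = tp.SpeciesConfig(**{**cfg.__dict__, "name": "donkey", "n_animals": 1})
            dataset = tp.generate_dataset(cfg, other, layout=tiny_layout, rng_seed=5)
            local = tp.local_count_matrix(dataset, "horse", config=tp.TestConfig(rng_seed=5))
            counts.append(local.counts[0, 7])  # Neck vs Abdomen (disjoint ROIs)
        assert counts == sorted(counts)
        assert counts[-1] == 4

    def test_animal_with_empty_gor_is_skipped_and_logged(self, tiny_layout):
        horse, donkey = tp.study_like_species_configs()
        horse = tp.SpeciesConfig(**{**horse.__dict__, "n_animals": 2})
        donkey = tp.SpeciesConfig(**{**donkey.__dict__, "n_animals": 1})
        dataset = tp.generate_dataset(horse, donkey, layout=tiny_layout, rng_seed=6)
        record = dataset.get("H.1")
        record.class_map.grid[record.class_map.grid == 11] = 0  # empty Abdomen
        local = tp.local_count_matrix(dataset, "horse", config=tp.TestConfig(rng_seed=6))
        assert ("H.1", 8) in local.skipped
        assert local.counts[7, :].max() <= 1  # H.1 cannot support Abdomen pairs


class TestStablePatterns:
    def test_stable_requires_global_flag_and_full_support(self, study_matrices):
        diff, local = study_matrices["horse"]
        stable = tp.stable_patterns(diff, local)
        for gi, gj in stable:
            i, j = gi - 1, gj - 1
            assert diff.significant[i, j]
            assert local.counts[i, j] == local.n_animals
        # non-significant pairs can never be stable
        assert not stable & set(diff.nonsignificant_pairs())

    def test_zero_counts_give_empty_set(self, study_matrices):
        diff, local = study_matrices["horse"]
        empty = tp.LocalCountMatrix(
            counts=np.zeros_like(local.counts),
            n_animals=local.n_animals,
            species=local.species,
            gor_set=local.gor_set,
        )
        assert tp.stable_patterns(diff, empty) == set()


class TestSpeciesComparisons:
    def test_roi_comparison_reports_horse_minus_donkey(self, study_dataset, study_config):
        result = tp.species_roi_comparison(study_dataset, 7, study_config)
        pooled_h = tp.pooled_roi_pixels(study_dataset, "horse", 7).mean()
        pooled_d = tp.pooled_roi_pixels(study_dataset, "donkey", 7).mean()
        assert result.mean_diff == pytest.approx(pooled_h - pooled_d, abs=1e-12)
        assert result.p_value < 0.001  # designed largest separation (5.26 °C)

    def test_every_roi_significantly_warmer_in_horses(self, study_dataset, study_config):
        for roi in range(1, 16):
            result = tp.species_roi_comparison(study_dataset, roi, study_config)
            assert result.mean_diff > 0
            assert result.p_value < 0.001

    def test_missing_roi_in_one_species_is_an_error(self, tiny_dataset):
        for record in tiny_dataset.animals("donkey"):
            record.class_map.grid[record.class_map.grid == 4] = 0
        with pytest.raises(DatasetError, match="ROI 4"):
            tp.species_roi_comparison(tiny_dataset, 4)


class TestMetadata:
    def test_hair_coat_longer_in_donkeys(self, study_dataset, study_config):
        out = tp.compare_metadata(study_dataset, "hair_coat_length_cm", study_config)
        assert out["donkey_mean"] > out["horse_mean"]
        assert out["significant"]  # p < 1e-4 at the configured separation

    def test_sf_skin_thicker_in_donkeys(self, study_dataset, study_config):
        out = tp.compare_metadata(study_dataset, "sf_skin_mm", study_config)
        assert out["donkey_mean"] > out["horse_mean"]
        assert out["test"].p_value < 1e-4

    def test_missing_field_lists_animals(self, tiny_dataset):
        tiny_dataset.records[0].metadata.sf_skin_mm = None
        with pytest.raises(DatasetError, match="H.1"):
            tp.compare_metadata(tiny_dataset, "sf_skin_mm")

    def test_single_animal_species_is_an_error(self, tiny_layout):
        horse, donkey = tp.study_like_species_configs()
        horse = tp.SpeciesConfig(**{**horse.__dict__, "n_animals": 1})
        donkey = tp.SpeciesConfig(**{**donkey.__dict__, "n_animals": 2})
        dataset = tp.generate_dataset(horse, donkey, layout=tiny_layout, rng_seed=8)
        with pytest.raises(DatasetError, match="horse"):
            tp.compare_metadata(dataset, "hair_coat_length_cm")


class TestConfigContract:
    def test_alpha_bounds(self):
        with pytest.raises(ValueError):
            tp.TestConfig(alpha=0.0)
        with pytest.raises(ValueError):
            tp.TestConfig(alpha=1.5)

    def test_unknown_n_rule(self):
        with pytest.raises(ValueError):
            tp.TestConfig(n_rule="bootstrap")
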