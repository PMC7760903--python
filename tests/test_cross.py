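"""Cross-species taxonomy and compliance scoring."""

import numpy as np
import pytest

import thermopattern as tp
from thermopattern.cross import PATTERN_CLASSES
from thermopattern.io import DatasetError


@pytest.fixture(scope="module")
def classes(study_matrices):
    return tp.classify_patterns(
        study_matrices["horse"][0],
        study_matrices["donkey"][0],
        study_matrices["horse"][1],
        study_matrices["donkey"][1],
    )


def two_gor_set():
    """Minimal custom set: two singleton groups on disjoint ROIs."""
    return tp.GORSet(
        [
            tp.GORDefinition(1, "A", frozenset({1})),
            tp.GORDefinition(2, "B", frozenset({2})),
        ]
    )


def contrast_dataset(tiny_layout, horse_delta, donkey_delta, seed=9):
    """Two species whose ROI1-ROI2 contrast is set independently."""

    def offsets(delta):
        out = [0.0] * 15
        out[0], out[1] = delta / 2, -delta / 2
        return tuple(out)

    horse = tp.SpeciesConfig(
        name="horse", n_animals=4, global_mean=22.0,
        roi_offsets=offsets(horse_delta), animal_sd=0.3, pixel_sd=1.0,
    )
    donkey = tp.SpeciesConfig(
        name="donkey", n_animals=4, global_mean=19.0,
        roi_offsets=offsets(donkey_delta), animal_sd=0.3, pixel_sd=1.0,
    )
    return tp.generate_dataset(horse, donkey, layout=tiny_layout, rng_seed=seed)


class TestClassification:
    def test_classes_symmetric_with_empty_diagonal(self, classes):
        np.testing.assert_array_equal(classes.classes, classes.classes.T)
        assert all(classes.classes[i, i] == "" for i in range(10))

    def test_study_taxonomy_matches_designed_structure(self, classes):
        """35 same-sign-significant pairs, 4 opposite-significant, 6 other."""
        summary = tp.taxonomy_summary(classes)
        assert summary["SPS"] == pytest.approx(35 / 45)
        assert summary["HWS"] + summary["HCS"] == pytest.approx(4 / 45)

    def test_fractions_sum_to_one(self, classes):
        assert sum(tp.taxonomy_summary(classes).values()) == pytest.approx(1.0)
        assert set(tp.taxonomy_summary(classes)) == set(PATTERN_CLASSES)

    def test_min_shared_is_min_of_local_counts(self, classes, study_matrices):
        horse_local = study_matrices["horse"][1].counts
        donkey_local = study_matrices["donkey"][1].counts
        for i, j in classes.gor_set.pairs():
            if classes.classes[i, j] in ("SPS", "HWS", "HCS"):
                assert classes.min_shared[i, j] == min(
                    horse_local[i, j], donkey_local[i, j]
                )
            else:
                assert classes.min_shared[i, j] == -1

    def test_min_shared_bounded_by_species_sizes(self, classes):
        defined = classes.min_shared[classes.min_shared >= 0]
        assert defined.max() <= min(classes.n_horses, classes.n_donkeys)

    def test_rump_neck_is_shared_and_significant(self, classes):
        """Both species have a colder rump than neck: SPS with high support."""
        assert classes.classes[4, 0] == "SPS"
        assert classes.min_shared[4, 0] >= 15

    def test_opposite_contrast_yields_horse_warmer_class(self, tiny_layout):
        dataset = contrast_dataset(tiny_layout, horse_delta=3.0, donkey_delta=-3.0)
        gors = two_gor_set()
        config = tp.TestConfig(rng_seed=9)
        matrices = {}
        for species in ("horse", "donkey"):
            diff = tp.global_significance(dataset, species, gors, config)
            local = tp.local_count_matrix(dataset, species, gors, config, reference=diff)
            matrices[species] = (diff, local)
        result = tp.classify_patterns(
            matrices["horse"][0], matrices["donkey"][0],
            matrices["horse"][1], matrices["donkey"][1],
        )
        assert result.classes[0, 1] == "HWS"
        assert result.min_shared[0, 1] == 4

    def test_non_significant_opposite_contrast_is_not_s_class(self, tiny_layout):
        dataset = contrast_dataset(tiny_layout, horse_delta=3.0, donkey_delta=0.0)
        gors = two_gor_set()
        config = tp.TestConfig(rng_seed=9)
        matrices = {}
        for species in ("horse", "donkey"):
            diff = tp.global_significance(dataset, species, gors, config)
            local = tp.local_count_matrix(dataset, species, gors, config, reference=diff)
            matrices[species] = (diff, local)
        result = tp.classify_patterns(
            matrices["horse"][0], matrices["donkey"][0],
            matrices["horse"][1], matrices["donkey"][1],
        )
        assert result.classes[0, 1] in ("SP", "HW", "HC")

    def test_mismatched_gor_sets_rejected(self, study_matrices, tiny_layout):
        dataset = contrast_dataset(tiny_layout, 1.0, 1.0)
        gors = two_gor_set()
        small_diff = tp.difference_matrix(dataset, "horse", gors)
        with pytest.raises(DatasetError, match="GOR sets"):
            tp.classify_patterns(
                study_matrices["horse"][0], small_diff,
                study_matrices["horse"][1], study_matrices["donkey"][1],
            )


class TestCompliance:
    def test_typical_animal_is_mostly_compliant(self, study_dataset, study_config):
        reference_records = [
            r for r in study_dataset.animals("donkey") if r.animal_id != "D.1"
        ]
        reference = tp.difference_matrix(tp.Dataset(records=reference_records), "donkey")
        compliance = tp.compliance_matrix(
            study_dataset.get("D.1"), reference, config=study_config
        )
        assert tp.ns_count(compliance) <= 5

    def test_entries_symmetric_with_empty_diagonal(self, study_dataset, study_config):
        reference = tp.difference_matrix(study_dataset, "donkey")
        compliance = tp.compliance_matrix(
            study_dataset.get("H.1"), reference, config=study_config
        )
        np.testing.assert_array_equal(compliance.entries, compliance.entries.T)
        assert all(compliance.entries[i, i] == "" for i in range(10))

    def test_self_consistent_animal_is_all_s(self, tiny_layout):
        """An animal scored against siblings with huge shared contrasts."""
        dataset = contrast_dataset(tiny_layout, horse_delta=4.0, donkey_delta=4.0)
        gors = two_gor_set()
        reference = tp.difference_matrix(dataset, "horse", gors)
        compliance = tp.compliance_matrix(
            dataset.get("H.1"), reference, gors, tp.TestConfig(rng_seed=9)
        )
        assert compliance.entries[0, 1] == "S"
        assert tp.ns_count(compliance) == 0

    def test_warm_patch_animal_less_compliant_than_control(
        self, study_dataset, study_config
    ):
        """Hair-loss hot spots break the species pattern; a matched healthy
        donkey from the same draw stays close to it."""
        donkeys = study_dataset.animals("donkey")
        counts = {}
        for animal_id in ("D.1", "D.18"):
            reference = tp.difference_matrix(
                tp.Dataset(records=[r for r in donkeys if r.animal_id != animal_id]),
                "donkey",
            )
            compliance = tp.compliance_matrix(
                study_dataset.get(animal_id), reference, config=study_config
            )
            counts[animal_id] = tp.ns_count(compliance)
        assert counts["D.18"] > counts["D.1"]

    def test_empty_gor_scores_ns_with_reason(self, study_dataset, study_config):
        import copy

        animal = copy.deepcopy(study_dataset.get("D.2"))
        animal.class_map.grid[animal.class_map.grid == 11] = 0  # no Abdomen pixels
        reference = tp.difference_matrix(study_dataset, "donkey")
        compliance = tp.compliance_matrix(animal, reference, config=study_config)
        abdomen = 7  # index of GOR 8
        assert all(
            compliance.entries[abdomen, j] == "NS" for j in range(10) if j != abdomen
        )
        assert (3, 8) in compliance.empty_pairs
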