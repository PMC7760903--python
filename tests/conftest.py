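import numpy as np
import pytest

import thermopattern as tp

#: reduced geometry for fast statistical tests (18x18 px per ROI block)
SMALL_LAYOUT = tp.LayoutSpec(height=60, width=100, margin=1, min_pixels=150)
#: minimal geometry for unit tests (8x8 px per ROI block)
TINY_LAYOUT = tp.LayoutSpec(height=30, width=50, margin=1, min_pixels=24)


@pytest.fixture(scope="session")
def small_layout() -> tp.LayoutSpec:
    return SMALL_LAYOUT


@pytest.fixture(scope="session")
def tiny_layout() -> tp.LayoutSpec:
    return TINY_LAYOUT


@pytest.fixture(scope="session")
def study_dataset() -> tp.Dataset:
    """Study-like preset with both outlier donkeys, at reduced geometry."""
    return tp.study_like_dataset(rng_seed=7, with_outliers=True, layout=SMALL_LAYOUT)


@pytest.fixture(scope="session")
def study_config() -> tp.TestConfig:
    return tp.TestConfig(rng_seed=7)


@pytest.fixture(scope="session")
def study_matrices(study_dataset, study_config):
    """Global difference + local count matrices for both species."""
    out = {}
    for species in ("horse", "donkey"):
        diff = tp.global_significance(study_dataset, species, config=study_config)
        local = tp.local_count_matrix(
            study_dataset, species, config=study_config, reference=diff
        )
        out[species] = (diff, local)
    return out


@pytest.fixture()
def tiny_dataset(tiny_layout) -> tp.Dataset:
    """2 + 2 animals with mild structure, for I/O and CLI tests."""
    horse, donkey = tp.study_like_species_configs()
    horse = tp.SpeciesConfig(**{**horse.__dict__, "n_animals": 2})
    donkey = tp.SpeciesConfig(**{**donkey.__dict__, "n_animals": 2})
    return tp.generate_dataset(horse, donkey, layout=tiny_layout, rng_seed=11)


def constant_record(value: float = 20.0, layout: tp.LayoutSpec = TINY_LAYOUT,
                    animal_id: str = "H.1", species: str = "horse") -> tp.AnimalRecord:
    labels = layout.class_map()
    grid = np.zeros(labels.shape)
    grid[labels > 0] = value
    return tp.AnimalRecord(
        tp.AnimalMetadata(animal_id=animal_id, species=species),
        tp.ThermalImage(grid),
        tp.ClassMap(labels),
    )
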