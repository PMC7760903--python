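"""The 15-ROI vocabulary and the 10 groups of ROIs (GORs).

Thermal phenomena on an equid's body surface usually span several of the
annotated muscle regions, so the analysis unit is a *group of ROIs*: a
named union of ROI labels treated as one pixel population. The default
set contains ten anatomically motivated groups (Neck, Front quarter,
Trunk, Hindquarter, Rump, Dorsal aspect, Ventral aspect, Abdomen,
Groins, Legs). Groups intentionally overlap -- e.g. ROI 9 (crus region)
belongs to Hindquarter, Rump, Ventral aspect and Legs -- and a shared
pixel contributes to every group containing it; no deduplication is
performed anywhere.

Custom group sets can be supplied through a YAML config with a ``gors:``
section mapping group names to ROI id lists, enabling more granular
segmentations without touching the defaults.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .io import AnimalRecord, Dataset, DatasetError, N_ROIS, PixelSample, extract_roi_pixels

__all__ = [
    "GORDefinition",
    "GORSet",
    "default_gors",
    "gors_from_config",
    "gor_pixels",
    "pooled_gor_pixels",
    "pooled_roi_pixels",
]

#: (gor_id, name, member ROI ids) -- the ten default groups
DEFAULT_GOR_TABLE: tuple[tuple[int, str, frozenset[int]], ...] = (
    (1, "Neck", frozenset({1, 2, 3})),
    (2, "Front quarter", frozenset({1, 2, 3, 4, 14, 15})),
    (3, "Trunk", frozenset({5, 11})),
    (4, "Hindquarter", frozenset({6, 7, 8, 9, 10})),
    (5, "Rump", frozenset({8, 9})),
    (6, "Dorsal aspect", frozenset({3, 4, 5, 6})),
    (7, "Ventral aspect", frozenset({9, 10, 11, 12, 13})),
    (8, "Abdomen", frozenset({11})),
    (9, "Groins", frozenset({10, 12})),
    (10, "Legs", frozenset({9, 13})),
)


@dataclass(frozen=True)
class GORDefinition:
    gor_id: int
    name: str
    roi_ids: frozenset[int]

    def __post_init__(self) -> None:
        if not self.roi_ids:
            raise DatasetError(f"GOR {self.gor_id} ({self.name}): empty ROI set")
        bad = [r for r in self.roi_ids if not 1 <= r <= N_ROIS]
        if bad:
            raise DatasetError(f"GOR {self.gor_id} ({self.name}): ROI ids {bad} outside 1..{N_ROIS}")


class GORSet:
    """Ordered collection of GOR definitions with unique ids."""

    def __init__(self, definitions: list[GORDefinition] | tuple[GORDefinition, ...]):
        definitions = list(definitions)
        ids = [d.gor_id for d in definitions]
        if len(ids) != len(set(ids)):
            raise DatasetError("duplicate gor_id in GOR set")
        self.definitions = definitions

    def __len__(self) -> int:
        return len(self.definitions)

    def __iter__(self):
        return iter(self.definitions)

    def __getitem__(self, index: int) -> GORDefinition:
        return self.definitions[index]

    def by_id(self, gor_id: int) -> GORDefinition:
        for d in self.definitions:
            if d.gor_id == gor_id:
                return d
        raise KeyError(gor_id)

    def by_name(self, name: str) -> GORDefinition:
        for d in self.definitions:
            if d.name == name:
                return d
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.definitions]

    def pairs(self) -> list[tuple[int, int]]:
        """Unordered index pairs (i < j) over the set; 45 for the default ten."""
        n = len(self.definitions)
        return [(i, j) for i in range(n) for j in range(i + 1, n)]


def default_gors() -> GORSet:
    """The ten standard groups of ROIs (pure constant, stable across runs)."""
    return GORSet([GORDefinition(g, name, rois) for g, name, rois in DEFAULT_GOR_TABLE])


def gors_from_config(config: str | Path | dict) -> GORSet:
    """Build a GOR set from a YAML config; absent ``gors:`` section -> defaults.

    Config shape::

        gors:
          Neck: [1, 2, 3]
          Whole trunk: [5, 11, 12]
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text()) or {}
    section = config.get("gors")
    if not section:
        return default_gors()
    return GORSet(
        [
            GORDefinition(i + 1, str(name), frozenset(int(r) for r in rois))
            for i, (name, rois) in enumerate(section.items())
        ]
    )


def gor_pixels(record: AnimalRecord, gor: GORDefinition) -> PixelSample:
    """All of one animal's pixels belonging to a group.

    Multiset concatenation of the member-ROI samples, so the group size
    equals the sum of member sizes; a pixel in an ROI shared by several
    groups contributes to each of them.
    """
    parts = [extract_roi_pixels(record, roi).values for roi in sorted(gor.roi_ids)]
    values = np.concatenate(parts) if parts else np.empty(0)
    return PixelSample(values, source=f"{record.animal_id}/gor{gor.gor_id}")


def pooled_gor_pixels(
    dataset: Dataset,
    species: str,
    gor: GORDefinition,
    include_excluded: bool = False,
) -> PixelSample:
    """Union over all (non-excluded) animals of a species for one group.

    Animals contribute proportionally to their pixel counts; there is no
    per-animal reweighting, mirroring the pooled "union of sets" the
    global tests operate on.
    """
    records = dataset.animals(species=species, include_excluded=include_excluded)
    if not records:
        raise DatasetError(f"no {species} records available for pooling")
    parts = [gor_pixels(r, gor).values for r in records]
    return PixelSample(np.concatenate(parts), source=f"{species}/gor{gor.gor_id}/pooled")


def pooled_roi_pixels(
    dataset: Dataset,
    species: str,
    roi_id: int,
    include_excluded: bool = False,
) -> PixelSample:
    """Union over all (non-excluded) animals of a species for one ROI."""
    records = dataset.animals(species=species, include_excluded=include_excluded)
    if not records:
        raise DatasetError(f"no {species} records available for pooling")
    parts = [extract_roi_pixels(r, roi_id).values for r in records]
    return PixelSample(np.concatenate(parts), source=f"{species}/roi{roi_id}/pooled")
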