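"""Reading, validation and writing of thermogram datasets.

A dataset is a collection of per-animal records, each pairing a thermal
image (a 2-D grid of surface temperatures in °C, natively 240 rows by
320 columns) with a class map of identical shape whose integer labels
assign every pixel to one of 15 regions of interest (ROIs, labels 1-15)
or to background (label 0, unannotated).

The on-disk portable format is deliberately plain text so that datasets
round-trip exactly and remain inspectable:

* temperature grid  -- one row per line, comma-separated decimals;
* class map         -- same layout, integer values 0-15;
* manifest          -- a YAML document listing, per animal: ``animal_id``,
  ``species``, ``image``, ``class_map`` (paths relative to the manifest),
  and optionally ``hair_coat_length_cm``, ``sf_skin_mm`` and ``excluded``.

Pixel coordinates are row-major, 0-based, origin at the top-left corner;
all extraction orders derive from that convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "DatasetError",
    "ThermalImage",
    "ClassMap",
    "AnimalMetadata",
    "AnimalRecord",
    "Dataset",
    "PixelSample",
    "load_dataset",
    "save_dataset",
    "extract_roi_pixels",
    "validate_record",
]

#: native sensor raster (rows, columns)
NATIVE_SHAPE = (240, 320)
#: sanity window for annotated surface temperatures, °C
TEMP_WINDOW = (-20.0, 60.0)
N_ROIS = 15
SPECIES = ("horse", "donkey")


class DatasetError(ValueError):
    """Fatal dataset problem (missing file, broken invariant)."""


@dataclass
class ThermalImage:
    """2-D grid of per-pixel surface temperatures in °C."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise DatasetError("thermal image must be a 2-D grid")

    @property
    def height(self) -> int:
        return self.grid.shape[0]

    @property
    def width(self) -> int:
        return self.grid.shape[1]


@dataclass
class ClassMap:
    """Integer ROI-label grid; 0 marks unannotated pixels."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 2:
            raise DatasetError("class map must be a 2-D grid")
        if not np.issubdtype(grid.dtype, np.integer):
            as_int = grid.astype(int)
            if not np.array_equal(as_int, grid):
                raise DatasetError("class map labels must be integers")
            grid = as_int
        self.grid = grid

    @property
    def roi_ids_present(self) -> set[int]:
        return set(int(v) for v in np.unique(self.grid) if v != 0)

    @property
    def n_annotated(self) -> int:
        return int(np.count_nonzero(self.grid))


@dataclass
class AnimalMetadata:
    animal_id: str
    species: str
    hair_coat_length_cm: float | None = None
    sf_skin_mm: float | None = None
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise DatasetError(
                f"{self.animal_id}: unknown species {self.species!r}; expected one of {SPECIES}"
            )
        for name in ("hair_coat_length_cm", "sf_skin_mm"):
            value = getattr(self, name)
            if value is not None and not value > 0:
                raise DatasetError(f"{self.animal_id}: {name} must be positive, got {value}")


@dataclass
class AnimalRecord:
    """One animal: metadata plus its thermal image and ROI class map."""

    metadata: AnimalMetadata
    image: ThermalImage
    class_map: ClassMap

    def __post_init__(self) -> None:
        if self.image.grid.shape != self.class_map.grid.shape:
            raise DatasetError(
                f"{self.metadata.animal_id}: image shape {self.image.grid.shape} does not "
                f"match class-map shape {self.class_map.grid.shape}"
            )

    @property
    def animal_id(self) -> str:
        return self.metadata.animal_id

    @property
    def species(self) -> str:
        return self.metadata.species

    def annotated_values(self) -> np.ndarray:
        """All annotated temperatures, row-major order."""
        return self.image.grid[self.class_map.grid > 0]


@dataclass
class PixelSample:
    """Multiset of temperatures extracted for an (animal, ROI-or-GOR) pair.

    ``source`` is a human-readable descriptor such as ``"H.1/roi3"`` or
    ``"horse/gor5/pooled"``; it is also used to derive per-comparison
    random streams, so it must be stable across runs.
    """

    values: np.ndarray
    source: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()

    @property
    def size(self) -> int:
        return self.values.size

    @property
    def is_empty(self) -> bool:
        return self.values.size == 0

    def mean(self) -> float:
        if self.is_empty:
            raise DatasetError(f"mean undefined for empty sample {self.source}")
        return float(self.values.mean())


@dataclass
class Dataset:
    records: list[AnimalRecord] = field(default_factory=list)
    manifest_path: Path | None = None
    #: per-animal list of non-fatal validation findings
    validation: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.animal_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DatasetError(f"duplicate animal ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, animal_id: str) -> AnimalRecord:
        for record in self.records:
            if record.animal_id == animal_id:
                return record
        raise KeyError(animal_id)

    def animals(self, species: str | None = None, include_excluded: bool = False) -> list[AnimalRecord]:
        """Records for formal analysis: excluded animals are omitted by default."""
        out = []
        for record in self.records:
            if species is not None and record.species != species:
                continue
            if record.metadata.excluded and not include_excluded:
                continue
            out.append(record)
        return out

    def species_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for record in self.records:
            counts[record.species] = counts.get(record.species, 0) + 1
        return counts


def validate_record(record: AnimalRecord) -> list[str]:
    """Check invariants of one record.

    Raises :class:`DatasetError` for fatal findings (shape mismatch is
    already impossible by construction; out-of-range labels and
    non-finite or insane annotated temperatures are fatal here) and
    returns a list of non-fatal warnings (non-native shape, empty ROIs).
    """
    warnings: list[str] = []
    aid = record.animal_id
    labels = record.class_map.grid
    if labels.min() < 0 or labels.max() > N_ROIS:
        raise DatasetError(
            f"{aid}: class-map labels outside 0..{N_ROIS} "
            f"(found range {labels.min()}..{labels.max()})"
        )
    annotated = record.annotated_values()
    if annotated.size and not np.all(np.isfinite(annotated)):
        raise DatasetError(f"{aid}: non-finite annotated temperatures")
    if annotated.size:
        lo, hi = float(annotated.min()), float(annotated.max())
        if lo < TEMP_WINDOW[0] or hi > TEMP_WINDOW[1]:
            raise DatasetError(
                f"{aid}: annotated temperatures {lo:.2f}..{hi:.2f} °C outside "
                f"sanity window {TEMP_WINDOW}"
            )
    else:
        warnings.append("no annotated pixels")
    if record.image.grid.shape != NATIVE_SHAPE:
        warnings.append(f"non-native shape {record.image.grid.shape}, expected {NATIVE_SHAPE}")
    missing = sorted(set(range(1, N_ROIS + 1)) - record.class_map.roi_ids_present)
    if missing:
        warnings.append(f"empty ROIs: {missing}")
    return warnings


def extract_roi_pixels(record: AnimalRecord, roi_id: int) -> PixelSample:
    """Temperatures at pixels labelled ``roi_id``, in row-major order.

    An empty sample is a valid, flagged result (the ROI may be missing
    from a given annotation), never an error.
    """
    if not 1 <= int(roi_id) <= N_ROIS:
        raise DatasetError(f"roi_id must be in 1..{N_ROIS}, got {roi_id}")
    mask = record.class_map.grid == int(roi_id)
    return PixelSample(record.image.grid[mask], source=f"{record.animal_id}/roi{int(roi_id)}")


def _load_grid(path: Path, dtype: str) -> np.ndarray:
    if not path.exists():
        raise DatasetError(f"missing file: {path}")
    grid = np.loadtxt(path, delimiter=",", dtype=float, ndmin=2)
    if dtype == "int":
        as_int = grid.astype(int)
        if not np.array_equal(as_int, grid):
            raise DatasetError(f"{path}: expected integer class-map values")
        return as_int
    return grid


def load_dataset(manifest: str | Path) -> Dataset:
    """Load a portable-format dataset from its manifest.

    Records are returned in manifest order; every record is validated
    and per-record warnings are collected on ``Dataset.validation``.
    A missing file, an image/class-map shape mismatch or an out-of-range
    label is fatal and names the offending animal or path.
    """
    manifest = Path(manifest)
    if not manifest.exists():
        raise DatasetError(f"missing manifest: {manifest}")
    doc = yaml.safe_load(manifest.read_text())
    entries = (doc or {}).get("animals", [])
    root = manifest.parent
    records: list[AnimalRecord] = []
    validation: dict[str, list[str]] = {}
    for entry in entries:
        meta = AnimalMetadata(
            animal_id=str(entry["animal_id"]),
            species=str(entry["species"]),
            hair_coat_length_cm=entry.get("hair_coat_length_cm"),
            sf_skin_mm=entry.get("sf_skin_mm"),
            excluded=bool(entry.get("excluded", False)),
        )
        image = ThermalImage(_load_grid(root / entry["image"], "float"))
        class_map = ClassMap(_load_grid(root / entry["class_map"], "int"))
        record = AnimalRecord(meta, image, class_map)
        validation[meta.animal_id] = validate_record(record)
        records.append(record)
    return Dataset(records=records, manifest_path=manifest, validation=validation)


def save_dataset(dataset: Dataset, directory: str | Path) -> Path:
    """Write a dataset in the portable text format; returns the manifest path.

    Temperatures are stored with six decimal places, so a reload agrees
    with the in-memory grids to well below 1e-6 °C; class maps
    round-trip bit-exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for record in dataset.records:
        aid = record.animal_id
        safe = aid.replace("/", "_")
        image_name = f"{safe}_temp.csv"
        map_name = f"{safe}_classmap.csv"
        np.savetxt(directory / image_name, record.image.grid, fmt="%.6f", delimiter=",")
        np.savetxt(directory / map_name, record.class_map.grid, fmt="%d", delimiter=",")
        entry: dict = {
            "animal_id": aid,
            "species": record.species,
            "image": image_name,
            "class_map": map_name,
        }
        if record.metadata.hair_coat_length_cm is not None:
            entry["hair_coat_length_cm"] = float(record.metadata.hair_coat_length_cm)
        if record.metadata.sf_skin_mm is not None:
            entry["sf_skin_mm"] = float(record.metadata.sf_skin_mm)
        if record.metadata.excluded:
            entry["excluded"] = True
        entries.append(entry)
    manifest = directory / "manifest.yaml"
    manifest.write_text(yaml.safe_dump({"animals": entries}, sort_keys=False))
    return manifest
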