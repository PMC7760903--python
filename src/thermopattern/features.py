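"""Per-animal ROI feature vectors and 2-D embedding.

Each animal is summarised by one statistic (mean, standard deviation,
excess kurtosis or skewness) computed per ROI, giving a 15-dimensional
vector ordered ROI 1..15. Optionally pixels are first centred by the
animal's global annotated mean, which removes between-animal level
differences and leaves only the within-animal pattern.

The embedding uses t-SNE with a small perplexity (default 5, suited to
a few dozen animals). t-SNE output has no absolute meaning: only the
neighbourhood structure is interpretable, and a fixed seed makes a run
reproducible rather than "correct".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.manifold import TSNE

from .io import AnimalRecord, Dataset, DatasetError, N_ROIS, extract_roi_pixels

__all__ = ["FeatureVector", "EmbedConfig", "extract_features", "feature_table", "embed_2d"]

STATISTICS = ("mean", "sd", "kurtosis", "skewness")
#: minimum pixels per ROI for each statistic to be defined
_MIN_PIXELS = {"mean": 1, "sd": 2, "skewness": 3, "kurtosis": 4}


@dataclass
class FeatureVector:
    animal_id: str
    species: str
    statistic: str
    normalized: bool
    values: np.ndarray  # length 15, NaN where missing
    missing: list[int]  # ROI ids with too few pixels

    @property
    def complete(self) -> bool:
        return not self.missing


@dataclass
class EmbedConfig:
    perplexity: float = 5.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.perplexity <= 0:
            raise ValueError("perplexity must be positive")


def _statistic(values: np.ndarray, statistic: str) -> float:
    if statistic == "mean":
        return float(values.mean())
    if statistic == "sd":
        return float(values.std(ddof=1))
    if statistic == "kurtosis":
        return float(sps.kurtosis(values, fisher=True, bias=False))
    if statistic == "skewness":
        return float(sps.skew(values, bias=False))
    raise DatasetError(f"unknown statistic {statistic!r}; expected one of {STATISTICS}")


def extract_features(
    record: AnimalRecord, statistic: str = "mean", normalized: bool = False
) -> FeatureVector:
    """One statistic per ROI for one animal (deterministic, no RNG).

    With ``normalized=True`` the animal's global annotated-pixel mean is
    subtracted from every pixel first, so the transformed annotated
    pixels average exactly zero. ROIs with too few pixels for the
    statistic are flagged missing (NaN).
    """
    if statistic not in STATISTICS:
        raise DatasetError(f"unknown statistic {statistic!r}; expected one of {STATISTICS}")
    annotated = record.annotated_values()
    if annotated.size == 0:
        raise DatasetError(f"{record.animal_id}: no annotated pixels")
    offset = annotated.mean() if normalized else 0.0
    values = np.full(N_ROIS, np.nan)
    missing: list[int] = []
    for roi in range(1, N_ROIS + 1):
        pixels = extract_roi_pixels(record, roi).values
        if pixels.size < _MIN_PIXELS[statistic]:
            missing.append(roi)
            continue
        values[roi - 1] = _statistic(pixels - offset, statistic)
    return FeatureVector(
        animal_id=record.animal_id,
        species=record.species,
        statistic=statistic,
        normalized=normalized,
        values=values,
        missing=missing,
    )


def feature_table(
    dataset: Dataset,
    statistic: str = "mean",
    normalized: bool = False,
    include_excluded: bool = False,
) -> list[FeatureVector]:
    """Feature vectors for every (by default non-excluded) animal."""
    return [
        extract_features(r, statistic, normalized)
        for r in dataset.animals(include_excluded=include_excluded)
    ]


def embed_2d(vectors: list[FeatureVector], config: EmbedConfig | None = None) -> pd.DataFrame:
    """t-SNE embedding of feature vectors into two dimensions.

    Vectors with missing entries are rejected by name rather than
    imputed. Returns a frame with columns animal_id, species, x, y;
    reruns with the same seed give identical coordinates.
    """
    config = config or EmbedConfig()
    incomplete = [v.animal_id for v in vectors if not v.complete]
    if incomplete:
        raise DatasetError(f"vectors with missing ROI entries cannot be embedded: {incomplete}")
    if len(vectors) <= config.perplexity:
        raise DatasetError(
            f"need more than perplexity={config.perplexity} points, got {len(vectors)}; "
            "use a smaller perplexity"
        )
    matrix = np.vstack([v.values for v in vectors])
    tsne = TSNE(
        n_components=2,
        perplexity=config.perplexity,
        random_state=int(config.rng_seed),
        init="pca",
    )
    coords = tsne.fit_transform(matrix)
    return pd.DataFrame(
        {
            "animal_id": [v.animal_id for v in vectors],
            "species": [v.species for v in vectors],
            "x": coords[:, 0],
            "y": coords[:, 1],
        }
    )
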