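"""Visualization conventions: thermal maps, histograms, boxplot statistics.

Thermal maps use a violet-to-red colour ramp over a fixed temperature
window (defaults 8.8 to 30.65 °C, the extreme annotated temperatures of
the study population), clamped at the ends; unannotated pixels render
black. Per-animal mode instead stretches the ramp over the animal's own
annotated range to highlight individual structure.

Histogram heights follow the counts/total convention (they sum to one);
a true density (counts / (total * bin width)) is available via a flag.
Boxplot quartiles use linear interpolation between order statistics;
whiskers sit at q1 - 1.5*IQR and q3 + 1.5*IQR clipped to observed data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.colors import hsv_to_rgb

from .io import AnimalRecord, DatasetError, PixelSample

__all__ = [
    "RenderConfig",
    "BoxplotStats",
    "spectrum_lut",
    "render_thermal_map",
    "histogram",
    "boxplot_stats",
]

#: common colour range, °C (extreme annotated values across the study animals)
T_LOW_DEFAULT = 8.8
T_HIGH_DEFAULT = 30.65


@dataclass
class RenderConfig:
    t_low: float = T_LOW_DEFAULT
    t_high: float = T_HIGH_DEFAULT
    mode: str = "common_range"  # or 'per_animal'
    background: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        if self.mode not in ("common_range", "per_animal"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.t_low < self.t_high:
            raise ValueError("t_low must be below t_high")


@dataclass
class BoxplotStats:
    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray


def spectrum_lut(n: int = 256) -> np.ndarray:
    """Violet-to-red lookup table, shape (n, 3) uint8.

    Hue runs linearly from 0.75 (violet) down to 0 (red) at full
    saturation and value -- an idealised visible-spectrum ramp that
    approximates the published figures without claiming pixel parity.
    """
    hue = np.linspace(0.75, 0.0, n)
    hsv = np.stack([hue, np.ones(n), np.ones(n)], axis=1)
    return (hsv_to_rgb(hsv) * 255).round().astype(np.uint8)


def render_thermal_map(record: AnimalRecord, config: RenderConfig | None = None) -> np.ndarray:
    """Rasterise one record to an RGB image (uint8, H x W x 3).

    Annotated temperatures map monotonically onto the ramp, clamped to
    the endpoint colours outside the range; unannotated pixels take the
    background colour.
    """
    config = config or RenderConfig()
    lut = spectrum_lut()
    mask = record.class_map.grid > 0
    t_low, t_high = config.t_low, config.t_high
    if config.mode == "per_animal":
        annotated = record.annotated_values()
        if annotated.size == 0:
            raise DatasetError(f"{record.animal_id}: nothing to render in per_animal mode")
        t_low, t_high = float(annotated.min()), float(annotated.max())
        if t_low == t_high:
            t_high = t_low + 1e-9
    scaled = (record.image.grid - t_low) / (t_high - t_low)
    idx = np.clip((scaled * (len(lut) - 1)).round(), 0, len(lut) - 1).astype(int)
    out = np.empty(record.image.grid.shape + (3,), dtype=np.uint8)
    out[:] = np.asarray(config.background, dtype=np.uint8)
    out[mask] = lut[idx[mask]]
    return out


def histogram(
    sample: PixelSample,
    bins: int = 20,
    value_range: tuple[float, float] | None = None,
    true_density: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram heights and bin edges for a pixel sample.

    Default heights are bin counts divided by the total count and sum
    to one; ``true_density=True`` divides additionally by bin width.
    """
    if sample.is_empty:
        raise DatasetError(f"cannot histogram empty sample {sample.source}")
    if bins < 1:
        raise DatasetError("bins must be >= 1")
    counts, edges = np.histogram(sample.values, bins=bins, range=value_range)
    heights = counts / counts.sum()
    if true_density:
        heights = heights / np.diff(edges)
    return heights, edges


def boxplot_stats(sample: PixelSample) -> BoxplotStats:
    """Quartiles, whiskers and outliers under the standard Tukey rule."""
    if sample.is_empty:
        raise DatasetError(f"cannot summarise empty sample {sample.source}")
    values = sample.values
    q1, median, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    low_fence, high_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= low_fence) & (values <= high_fence)]
    # whiskers clip to the most extreme observations inside the fences
    whisker_low = float(inside.min()) if inside.size else float(q1)
    whisker_high = float(inside.max()) if inside.size else float(q3)
    outliers = np.sort(values[(values < low_fence) | (values > high_fence)])
    return BoxplotStats(
        q1=float(q1),
        median=float(median),
        q3=float(q3),
        whisker_low=whisker_low,
        whisker_high=whisker_high,
        outliers=outliers,
    )
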