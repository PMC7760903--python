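"""Sampled one-sided rank tests and the thermal-pattern matrices.

The statistical machinery works on pixel populations, which differ in
size between regions and animals. Every comparison therefore equalises
the two sides first: with the default ``min_whole`` rule the smaller
sample is used whole and the larger is subsampled uniformly without
replacement down to the smaller size (``subsample_both`` draws both
sides, for sensitivity checks). The equalised pair then enters a
one-sided Mann-Whitney-Wilcoxon (MWW) test whose direction is fixed by
the observed mean difference -- the direction is "known" in the sense
that the hypothesis being scored is the observed ordering itself.

Two scopes of testing build the pattern matrices for a species:

* *global*  -- pixels pooled over all animals; a significant pair of
  groups (p < alpha, default 0.001) is a **thermal pattern** and sets a
  flag in the difference matrix ``M_delta``;
* *local*   -- the same test per animal; the count matrix ``M_L``
  records how many animals individually support the global direction.
  A pattern supported by every animal is **stable**.

No multiple-testing correction is applied across the 45 group pairs;
the fixed threshold p < 0.001 is the decision rule throughout, which is
deliberate and should be kept in mind when interpreting borderline
flags.

Reproducibility: each comparison draws its subsample from an RNG stream
derived by stable hashing of (seed, comparison descriptor), so results
are bit-identical for a fixed seed regardless of evaluation order.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import mannwhitneyu

from .gors import GORSet, default_gors, gor_pixels, pooled_gor_pixels, pooled_roi_pixels
from .io import Dataset, DatasetError, PixelSample

__all__ = [
    "TestConfig",
    "TestResult",
    "DifferenceMatrix",
    "LocalCountMatrix",
    "comparison_rng",
    "draw_test_samples",
    "mww_one_sided",
    "difference_matrix",
    "global_significance",
    "local_count_matrix",
    "stable_patterns",
    "species_roi_comparison",
    "compare_metadata",
]


@dataclass
class TestConfig:
    """Knobs of the testing scheme.

    alpha            significance threshold for pattern tests (0.001)
    alpha_metadata   reporting threshold for metadata comparisons (1e-4)
    rng_seed         root seed for all subsampling streams
    n_rule           'min_whole' (default) or 'subsample_both'
    exact_threshold  combined sample size up to which the exact MWW
                     null distribution is enumerated (no-ties only)
    """

    alpha: float = 0.001
    rng_seed: int = 0
    n_rule: str = "min_whole"
    alpha_metadata: float = 1e-4
    exact_threshold: int = 12

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n_rule not in ("min_whole", "subsample_both"):
            raise ValueError(f"unknown n_rule {self.n_rule!r}")


@dataclass
class TestResult:
    p_value: float
    direction: str  # 'first_greater' | 'second_greater' | 'tie'
    n_used: int
    mean_diff: float  # mean(first) - mean(second), °C

    def significant(self, alpha: float) -> bool:
        return self.direction != "tie" and self.p_value < alpha


@dataclass
class DifferenceMatrix:
    """Signed mean-temperature differences between group pairs, M_delta.

    ``deltas[i, j] = mean(GOR i) - mean(GOR j)`` over the pooled species
    pixels, hence exactly antisymmetric with a zero diagonal.
    ``significant`` (filled by :func:`global_significance`) is symmetric.
    """

    deltas: np.ndarray
    significant: np.ndarray
    species: str
    gor_set: GORSet
    p_values: np.ndarray | None = None
    n_used: np.ndarray | None = None

    @property
    def n_gors(self) -> int:
        return len(self.gor_set)

    def nonsignificant_pairs(self) -> list[tuple[int, int]]:
        """Unordered 1-based GOR id pairs whose global test did not reject."""
        out = []
        for i, j in self.gor_set.pairs():
            if not self.significant[i, j]:
                out.append((self.gor_set[i].gor_id, self.gor_set[j].gor_id))
        return out


@dataclass
class LocalCountMatrix:
    """Per-pair counts of animals with a locally significant difference, M_L."""

    counts: np.ndarray
    n_animals: int
    species: str
    gor_set: GORSet
    #: (animal_id, gor_id) combinations skipped because the group was empty
    skipped: list[tuple[str, int]] = field(default_factory=list)


def comparison_rng(seed: int, *descriptor: object) -> np.random.Generator:
    """Seeded generator for one comparison, independent of evaluation order.

    The descriptor (e.g. species, pair, animal id) is hashed into the
    seed sequence, so every comparison owns a stable stream.
    """
    text = "\x1f".join(str(part) for part in descriptor)
    digest = hashlib.sha256(text.encode()).digest()
    key = int.from_bytes(digest[:8], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def draw_test_samples(
    sample_a: PixelSample,
    sample_b: PixelSample,
    rng: np.random.Generator,
    n_rule: str = "min_whole",
) -> tuple[np.ndarray, np.ndarray]:
    """Equalise two pixel samples to n = min(|a|, |b|).

    Under ``min_whole`` the smaller sample is returned whole and only
    the larger is subsampled (uniformly, without replacement); under
    ``subsample_both`` both sides are drawn, which is slightly noisier.
    """
    for s in (sample_a, sample_b):
        if s.is_empty:
            raise DatasetError(f"cannot test empty sample: {s.source}")
    n = min(sample_a.size, sample_b.size)

    def take(sample: PixelSample) -> np.ndarray:
        if sample.size == n and n_rule == "min_whole":
            return sample.values
        idx = rng.choice(sample.size, size=n, replace=False)
        return sample.values[idx]

    return take(sample_a), take(sample_b)


def mww_one_sided(x, y, direction: str = "x_greater", exact_threshold: int = 12) -> TestResult:
    """One-sided Mann-Whitney-Wilcoxon test for the stated direction.

    For combined sizes up to ``exact_threshold`` with no tied values the
    exact null distribution of U is enumerated; otherwise the normal
    approximation with tie correction (and continuity correction) is
    used. Fully tied input (every value equal across both samples)
    carries no ordering evidence and returns the fixed convention
    p = 1.0 with ``direction='tie'``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise DatasetError("mww_one_sided requires nonempty samples")
    if direction not in ("x_greater", "y_greater"):
        raise ValueError(f"unknown direction {direction!r}")
    mean_diff = float(x.mean() - y.mean())
    n_used = int(min(x.size, y.size))
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return TestResult(p_value=1.0, direction="tie", n_used=n_used, mean_diff=0.0)
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= exact_threshold and not has_ties) else "asymptotic"
    alternative = "greater" if direction == "x_greater" else "less"
    result = mannwhitneyu(x, y, alternative=alternative, method=method)
    if mean_diff > 0:
        observed = "first_greater"
    elif mean_diff < 0:
        observed = "second_greater"
    else:
        observed = "tie"
    return TestResult(
        p_value=float(result.pvalue), direction=observed, n_used=n_used, mean_diff=mean_diff
    )


def _pooled_gor_samples(
    dataset: Dataset, species: str, gor_set: GORSet, include_excluded: bool = False
) -> list[PixelSample]:
    samples = []
    for gor in gor_set:
        sample = pooled_gor_pixels(dataset, species, gor, include_excluded=include_excluded)
        if sample.is_empty:
            raise DatasetError(f"pooled sample empty for GOR {gor.gor_id} ({gor.name}), {species}")
        samples.append(sample)
    return samples


def difference_matrix(
    dataset: Dataset,
    species: str,
    gor_set: GORSet | None = None,
    include_excluded: bool = False,
) -> DifferenceMatrix:
    """Pairwise pooled mean-temperature differences between groups.

    ``deltas[i, j]`` is the mean of group i's pooled pixels minus the
    mean of group j's; a negative entry for (Rump, Neck) therefore reads
    "the rump is colder than the neck".
    """
    gor_set = gor_set or default_gors()
    samples = _pooled_gor_samples(dataset, species, gor_set, include_excluded)
    means = np.array([s.mean() for s in samples])
    deltas = means[:, None] - means[None, :]
    np.fill_diagonal(deltas, 0.0)
    n = len(gor_set)
    return DifferenceMatrix(
        deltas=deltas,
        significant=np.zeros((n, n), dtype=bool),
        species=species,
        gor_set=gor_set,
    )


def global_significance(
    dataset: Dataset,
    species: str,
    gor_set: GORSet | None = None,
    config: TestConfig | None = None,
    include_excluded: bool = False,
) -> DifferenceMatrix:
    """Difference matrix with global significance flags filled.

    For every unordered pair the two pooled samples are equalised and
    tested one-sided in the direction of the observed pooled difference;
    both symmetric cells receive the same flag. Pairs with an exactly
    zero difference are non-significant by convention.
    """
    gor_set = gor_set or default_gors()
    config = config or TestConfig()
    diff = difference_matrix(dataset, species, gor_set, include_excluded)
    samples = _pooled_gor_samples(dataset, species, gor_set, include_excluded)
    n = len(gor_set)
    p_values = np.ones((n, n))
    n_used = np.zeros((n, n), dtype=int)
    for i, j in gor_set.pairs():
        delta = diff.deltas[i, j]
        rng = comparison_rng(
            config.rng_seed, species, "global", gor_set[i].gor_id, gor_set[j].gor_id
        )
        x, y = draw_test_samples(samples[i], samples[j], rng, config.n_rule)
        if delta == 0:
            p = 1.0
        else:
            direction = "x_greater" if delta > 0 else "y_greater"
            p = mww_one_sided(x, y, direction, config.exact_threshold).p_value
        p_values[i, j] = p_values[j, i] = p
        n_used[i, j] = n_used[j, i] = len(x)
        flag = bool(delta != 0 and p < config.alpha)
        diff.significant[i, j] = diff.significant[j, i] = flag
    diff.p_values = p_values
    diff.n_used = n_used
    return diff


def local_count_matrix(
    dataset: Dataset,
    species: str,
    gor_set: GORSet | None = None,
    config: TestConfig | None = None,
    reference: DifferenceMatrix | None = None,
    include_excluded: bool = False,
) -> LocalCountMatrix:
    """Count, per group pair, the animals whose own pixels support the pattern.

    The tested direction is the *global* sign of the pooled difference
    (from ``reference`` or recomputed), so an animal whose own contrast
    is reversed cannot count as support. Animals with an empty group are
    skipped for that pair and recorded in ``skipped``.
    """
    gor_set = gor_set or default_gors()
    config = config or TestConfig()
    if reference is None:
        reference = difference_matrix(dataset, species, gor_set, include_excluded)
    records = dataset.animals(species=species, include_excluded=include_excluded)
    if not records:
        raise DatasetError(f"no {species} records")
    n = len(gor_set)
    counts = np.zeros((n, n), dtype=int)
    skipped: list[tuple[str, int]] = []
    per_animal = []
    for record in records:
        samples = [gor_pixels(record, gor) for gor in gor_set]
        for k, sample in enumerate(samples):
            if sample.is_empty:
                skipped.append((record.animal_id, gor_set[k].gor_id))
        per_animal.append(samples)
    for i, j in gor_set.pairs():
        delta = reference.deltas[i, j]
        if delta == 0:
            continue
        direction = "x_greater" if delta > 0 else "y_greater"
        count = 0
        for record, samples in zip(records, per_animal):
            if samples[i].is_empty or samples[j].is_empty:
                continue
            rng = comparison_rng(
                config.rng_seed,
                species,
                "local",
                gor_set[i].gor_id,
                gor_set[j].gor_id,
                record.animal_id,
            )
            x, y = draw_test_samples(samples[i], samples[j], rng, config.n_rule)
            if mww_one_sided(x, y, direction, config.exact_threshold).p_value < config.alpha:
                count += 1
        counts[i, j] = counts[j, i] = count
    return LocalCountMatrix(
        counts=counts, n_animals=len(records), species=species, gor_set=gor_set, skipped=skipped
    )


def stable_patterns(diff: DifferenceMatrix, local: LocalCountMatrix) -> set[tuple[int, int]]:
    """Group pairs that are globally significant and supported by every animal.

    Returns unordered 1-based GOR id pairs (i < j).
    """
    if len(diff.gor_set) != len(local.gor_set) or diff.species != local.species:
        raise DatasetError("difference and local-count matrices do not match")
    out = set()
    for i, j in diff.gor_set.pairs():
        if diff.significant[i, j] and local.counts[i, j] == local.n_animals:
            out.add((diff.gor_set[i].gor_id, diff.gor_set[j].gor_id))
    return out


def species_roi_comparison(
    dataset: Dataset, roi_id: int, config: TestConfig | None = None
) -> TestResult:
    """Horse-vs-donkey comparison of one ROI's pooled pixels.

    ``mean_diff`` is mean(horses) - mean(donkeys) in °C; the one-sided
    test direction follows the sign of that difference.
    """
    config = config or TestConfig()
    horse = pooled_roi_pixels(dataset, "horse", roi_id)
    donkey = pooled_roi_pixels(dataset, "donkey", roi_id)
    if horse.is_empty or donkey.is_empty:
        raise DatasetError(f"ROI {roi_id} absent in one species")
    rng = comparison_rng(config.rng_seed, "species", "roi", roi_id)
    x, y = draw_test_samples(horse, donkey, rng, config.n_rule)
    delta = horse.mean() - donkey.mean()
    direction = "x_greater" if delta >= 0 else "y_greater"
    result = mww_one_sided(x, y, direction, config.exact_threshold)
    result.mean_diff = delta  # pooled-population difference, not the subsample's
    return result


def compare_metadata(
    dataset: Dataset, metadata_field: str, config: TestConfig | None = None
) -> dict:
    """One-sided MWW on per-animal metadata (hair coat length or SF-Skin).

    Returns the test result plus per-species mean ± sd. The direction
    follows the sign of the species mean difference (donkeys vs horses).
    """
    if metadata_field not in ("hair_coat_length_cm", "sf_skin_mm"):
        raise DatasetError(f"unknown metadata field {metadata_field!r}")
    config = config or TestConfig()
    values: dict[str, list[float]] = {"horse": [], "donkey": []}
    missing = []
    for record in dataset.animals():
        value = getattr(record.metadata, metadata_field)
        if value is None:
            missing.append(record.animal_id)
        else:
            values[record.species].append(float(value))
    if missing:
        raise DatasetError(f"{metadata_field} missing for animals: {missing}")
    for species, vals in values.items():
        if len(vals) < 2:
            raise DatasetError(f"need >= 2 {species} values for {metadata_field}")
    donkey = np.array(values["donkey"])
    horse = np.array(values["horse"])
    delta = float(donkey.mean() - horse.mean())
    direction = "x_greater" if delta >= 0 else "y_greater"
    result = mww_one_sided(donkey, horse, direction, config.exact_threshold)
    return {
        "field": metadata_field,
        "test": result,
        "donkey_mean": float(donkey.mean()),
        "donkey_sd": float(donkey.std(ddof=1)),
        "horse_mean": float(horse.mean()),
        "horse_sd": float(horse.std(ddof=1)),
        "significant": result.p_value < config.alpha_metadata,
    }
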