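"""Cross-species pattern taxonomy and per-animal compliance scoring.

Comparing the two species' difference matrices cell by cell yields a
six-class taxonomy per group pair:

===== ==========================================================
SPS   same sign in both species, globally significant in both
SP    same sign, but not significant in both
HWS   opposite signs, horses on the warmer side, significant in both
HW    as HWS but not significant in both
HCS   opposite signs, horses on the colder side, significant in both
HC    as HCS but not significant in both
===== ==========================================================

The "S" suffix requires global significance in *both* species. For the
significant classes the matrix also carries the minimum shared-animal
count: the smaller of the two species' local support counts, i.e. at
least this many animals of each species show the pattern individually;
a value equal to the species size marks a pattern stable in both.

Compliance scoring asks the converse question for a single animal: for
each group pair, does the animal's own difference have the same sign as
a reference species matrix, and is it locally significant? The S/NS
answers over the 45 pairs profile how typical the animal is -- an
animal with unusual insulation (long hair, patchy hair loss) stands out
as a band of NS cells. When the animal belongs to the reference
species, build the reference without it (leave-one-out).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gors import GORSet, gor_pixels
from .io import AnimalRecord, DatasetError
from .stats import (
    DifferenceMatrix,
    LocalCountMatrix,
    TestConfig,
    comparison_rng,
    draw_test_samples,
    mww_one_sided,
)

__all__ = [
    "PatternClassMatrix",
    "ComplianceMatrix",
    "classify_patterns",
    "taxonomy_summary",
    "compliance_matrix",
    "ns_count",
]

PATTERN_CLASSES = ("SPS", "SP", "HWS", "HW", "HCS", "HC")
SIGNIFICANT_CLASSES = ("SPS", "HWS", "HCS")


@dataclass
class PatternClassMatrix:
    """Per-pair cross-species class plus minimum shared-animal counts.

    ``classes`` holds one of the six class tags off-diagonal and '' on
    the diagonal; ``min_shared`` is defined (>= 0) only for the
    significant classes and -1 elsewhere.
    """

    classes: np.ndarray
    min_shared: np.ndarray
    gor_set: GORSet
    n_horses: int
    n_donkeys: int


@dataclass
class ComplianceMatrix:
    """S/NS per group pair for one animal against a species reference."""

    entries: np.ndarray  # 'S' | 'NS' | '' (diagonal)
    animal_id: str
    reference_species: str
    gor_set: GORSet
    #: pairs marked NS because a group had no pixels for this animal
    empty_pairs: list[tuple[int, int]] = field(default_factory=list)


def _check_same_gors(*matrices) -> GORSet:
    first = matrices[0].gor_set
    ids = [d.gor_id for d in first]
    for m in matrices[1:]:
        if [d.gor_id for d in m.gor_set] != ids:
            raise DatasetError("matrices built on different GOR sets")
    return first


def classify_patterns(
    horse_diff: DifferenceMatrix,
    donkey_diff: DifferenceMatrix,
    horse_local: LocalCountMatrix,
    donkey_local: LocalCountMatrix,
) -> PatternClassMatrix:
    """Assign each unordered group pair to one of the six classes.

    Orientation rule for opposite-sign pairs: on the canonical cell
    (i < j), a positive horse difference with a negative donkey one is
    "horses warmer" (HWS/HW); the reverse is "horses colder" (HCS/HC).
    The class label is defined on the unordered pair, so the mirrored
    cell receives the same tag.
    """
    gor_set = _check_same_gors(horse_diff, donkey_diff, horse_local, donkey_local)
    n = len(gor_set)
    classes = np.full((n, n), "", dtype="<U3")
    min_shared = np.full((n, n), -1, dtype=int)
    for i, j in gor_set.pairs():
        dh = horse_diff.deltas[i, j]
        dd = donkey_diff.deltas[i, j]
        both_sig = bool(horse_diff.significant[i, j] and donkey_diff.significant[i, j])
        if np.sign(dh) == np.sign(dd) or dh == 0 or dd == 0:
            tag = "SPS" if both_sig else "SP"
        elif dh > 0:
            tag = "HWS" if both_sig else "HW"
        else:
            tag = "HCS" if both_sig else "HC"
        classes[i, j] = classes[j, i] = tag
        if tag in SIGNIFICANT_CLASSES:
            shared = min(int(horse_local.counts[i, j]), int(donkey_local.counts[i, j]))
            min_shared[i, j] = min_shared[j, i] = shared
    return PatternClassMatrix(
        classes=classes,
        min_shared=min_shared,
        gor_set=gor_set,
        n_horses=horse_local.n_animals,
        n_donkeys=donkey_local.n_animals,
    )


def taxonomy_summary(classes: PatternClassMatrix) -> dict[str, float]:
    """Fraction of unordered pairs per class (sums to 1 over the six tags)."""
    pairs = classes.gor_set.pairs()
    total = len(pairs)
    counts = {tag: 0 for tag in PATTERN_CLASSES}
    for i, j in pairs:
        counts[str(classes.classes[i, j])] += 1
    return {tag: counts[tag] / total for tag in PATTERN_CLASSES}


def compliance_matrix(
    animal: AnimalRecord,
    reference: DifferenceMatrix,
    gor_set: GORSet | None = None,
    config: TestConfig | None = None,
) -> ComplianceMatrix:
    """Score one animal's agreement with a species' global pattern.

    A pair is S when the animal's own mean difference has the same sign
    as the reference difference AND the one-sided test in the reference
    direction is significant at alpha; otherwise NS. A pair involving a
    group with no pixels for this animal is NS with a logged reason.
    The caller is responsible for building ``reference`` without the
    animal when it belongs to the reference species.
    """
    gor_set = gor_set or reference.gor_set
    _check_same_gors(reference)
    config = config or TestConfig()
    n = len(gor_set)
    entries = np.full((n, n), "", dtype="<U2")
    empty_pairs: list[tuple[int, int]] = []
    samples = [gor_pixels(animal, gor) for gor in gor_set]
    for i, j in gor_set.pairs():
        ref_delta = reference.deltas[i, j]
        if samples[i].is_empty or samples[j].is_empty:
            entries[i, j] = entries[j, i] = "NS"
            empty_pairs.append((gor_set[i].gor_id, gor_set[j].gor_id))
            continue
        own_delta = samples[i].mean() - samples[j].mean()
        tag = "NS"
        if ref_delta != 0 and np.sign(own_delta) == np.sign(ref_delta):
            rng = comparison_rng(
                config.rng_seed,
                "compliance",
                reference.species,
                animal.animal_id,
                gor_set[i].gor_id,
                gor_set[j].gor_id,
            )
            x, y = draw_test_samples(samples[i], samples[j], rng, config.n_rule)
            direction = "x_greater" if ref_delta > 0 else "y_greater"
            if mww_one_sided(x, y, direction, config.exact_threshold).p_value < config.alpha:
                tag = "S"
        entries[i, j] = entries[j, i] = tag
    return ComplianceMatrix(
        entries=entries,
        animal_id=animal.animal_id,
        reference_species=reference.species,
        gor_set=gor_set,
        empty_pairs=empty_pairs,
    )


def ns_count(compliance: ComplianceMatrix) -> int:
    """Number of unordered pairs scored NS (a convenience outlier score)."""
    return sum(
        1 for i, j in compliance.gor_set.pairs() if compliance.entries[i, j] == "NS"
    )
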