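"""Cross-species taxonomy and outlier compliance.

Classifies every GOR pair into the six-class taxonomy (same/opposite
sign x globally significant in both species or not), reports the class
proportions and minimum shared-animal counts, and scores the two
outlier donkeys against the pattern of the sixteen formal donkeys.
Writes results/pattern_classes.csv, results/min_shared.csv,
results/taxonomy_summary.csv and per-outlier compliance matrices.
"""

import argparse
from pathlib import Path

import pandas as pd

import thermopattern as tp

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    dataset = tp.load_dataset(RESULTS / "dataset" / "manifest.yaml")
    config = tp.TestConfig(rng_seed=args.seed)
    gor_set = tp.default_gors()
    names = gor_set.names

    matrices = {}
    for species in ("horse", "donkey"):
        diff = tp.global_significance(dataset, species, gor_set, config)
        local = tp.local_count_matrix(dataset, species, gor_set, config, reference=diff)
        matrices[species] = (diff, local)
    classes = tp.classify_patterns(
        matrices["horse"][0], matrices["donkey"][0],
        matrices["horse"][1], matrices["donkey"][1],
    )
    summary = tp.taxonomy_summary(classes)
    pd.DataFrame(classes.classes, index=names, columns=names).to_csv(
        RESULTS / "pattern_classes.csv"
    )
    pd.DataFrame(classes.min_shared, index=names, columns=names).to_csv(
        RESULTS / "min_shared.csv"
    )
    pd.Series(summary, name="fraction").to_csv(RESULTS / "taxonomy_summary.csv")
    print("Cross-species pattern taxonomy over the 45 GOR pairs:")
    for tag, fraction in summary.items():
        print(f"  {tag}: {100 * fraction:.1f}%")
    print(f"Shared-and-significant patterns (SPS): {100 * summary['SPS']:.1f}%; "
          f"opposite-and-significant: {100 * (summary['HWS'] + summary['HCS']):.1f}%")

    donkeys = dataset.animals("donkey")
    reference = tp.difference_matrix(tp.Dataset(records=donkeys), "donkey")
    for animal_id in ("D.17", "D.18"):
        compliance = tp.compliance_matrix(dataset.get(animal_id), reference, config=config)
        pd.DataFrame(compliance.entries, index=names, columns=names).to_csv(
            RESULTS / f"{animal_id}_compliance.csv"
        )
        print(f"{animal_id} vs the 16 formal donkeys: "
              f"{tp.ns_count(compliance)}/45 pairs out of line (NS)")


if __name__ == "__main__":
    main()
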