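"""Per-animal feature embedding.

Extracts per-ROI mean (and standard-deviation) feature vectors for the
formal animals, embeds them in 2-D with t-SNE (perplexity 5) and
reports how well the embedded neighbourhoods separate the species.
Writes results/embedding_<statistic>.csv and a scatter plot.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from sklearn.metrics import silhouette_score

import thermopattern as tp

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    dataset = tp.load_dataset(RESULTS / "dataset" / "manifest.yaml")
    for statistic in ("mean", "sd"):
        vectors = tp.feature_table(dataset, statistic)
        coords = tp.embed_2d(vectors, tp.EmbedConfig(perplexity=5, rng_seed=args.seed))
        coords.to_csv(RESULTS / f"embedding_{statistic}.csv", index=False)
        score = silhouette_score(coords[["x", "y"]].values, coords["species"].values)
        print(f"{statistic}-feature embedding: species silhouette = {score:.3f}"
              + (" (clusters match species)" if score > 0.5 else " (no clear species clusters)"))
        fig, ax = plt.subplots(figsize=(5, 4))
        for species, marker in (("horse", "o"), ("donkey", "s")):
            sub = coords[coords.species == species]
            ax.scatter(sub.x, sub.y, marker=marker, label=species)
        ax.legend()
        ax.set_title(f"t-SNE of per-ROI {statistic} features")
        fig.savefig(RESULTS / f"embedding_{statistic}.png", dpi=120)
        plt.close(fig)


if __name__ == "__main__":
    main()
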