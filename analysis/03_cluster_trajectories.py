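"""Ordinate samples and cluster developmental protein trajectories.

Relative abundance (each protein scaled to mean 1) feeds a sample PCA
-- developmental stage should order monotonically along PC1 -- and
per-protein stage means feed k-means.  The cluster count is chosen by
majority vote of five validity indices; clusters are relabelled so
Cluster 1 is the decreasing trajectory and the last one increasing.
"""

import argparse
import os

from psdremodel import clustering, quant


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--tabledir", default="results/tables")
    ap.add_argument("--outdir", default="results/tables")
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    filtered = quant.read_quant_table(
        f"{args.tabledir}/mouse_filtered.tsv",
        f"{args.tabledir}/mouse_filtered.samples.tsv",
    )
    ram = clustering.relative_abundance(filtered)
    scores, evr = clustering.pca_samples(ram)
    chosen_k, votes = clustering.select_k(ram.stage_means, seed=args.seed)
    result = clustering.kmeans_trajectories(
        ram.stage_means, chosen_k, restarts=50, seed=args.seed
    )

    os.makedirs(args.outdir, exist_ok=True)
    scores.to_csv(f"{args.outdir}/pca_scores.tsv", sep="\t")
    votes.to_csv(f"{args.outdir}/k_votes.tsv", sep="\t", index=False)
    result.labels.to_csv(f"{args.outdir}/clusters.tsv", sep="\t")
    result.centroids.to_csv(f"{args.outdir}/centroids.tsv", sep="\t")

    print(f"PC1 explains {evr[0]:.1%} of sample variance")
    print(f"validity indices vote k = {chosen_k} "
          f"({votes.to_dict(orient='list')})")
    sizes = result.labels.value_counts().sort_index()
    print("cluster sizes (1 = decreasing ... k = increasing):",
          sizes.to_dict())
    print("centroid stage means:")
    print(result.centroids.round(3).to_string())


if __name__ == "__main__":
    main()
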