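"""Reference-set overlap, local enrichment, and the ASD comparison.

Cluster gene lists are profiled against the reference PSD proteome
collections and tested for enrichment with Fisher's exact test (BH
across sets).  The developmental perinatal log-ratio is then compared
with an ASD case-control table: in the anti-correlated ("immature PSD")
scenario, genes that rise across development are down in ASD cortex
and vice versa, and the two log-ratios show a negative Spearman rho.
"""

import argparse
import os

import numpy as np
import pandas as pd

from psdremodel import crossspecies, enrichment


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--datadir", default="results/data")
    ap.add_argument("--tabledir", default="results/tables")
    ap.add_argument("--outdir", default="results/tables")
    args = ap.parse_args()
    os.makedirs(args.outdir, exist_ok=True)

    clusters = pd.read_csv(f"{args.tabledir}/clusters.tsv", sep="\t",
                           index_col=0).iloc[:, 0]
    filtered = pd.read_csv(f"{args.tabledir}/mouse_filtered.tsv", sep="\t")
    gene_of = pd.Series(filtered["gene_symbol"].to_numpy(),
                        index=filtered["protein_id"].to_numpy())
    groups = {
        f"cluster_{c}": set(gene_of[clusters.index[clusters == c]])
        for c in sorted(clusters.unique())
    }
    groups["all_major"] = set(gene_of)

    refs = enrichment.read_gmt(f"{args.datadir}/psd_references.gmt")
    profile = enrichment.reference_overlap_profile(groups, refs)
    profile["fractions"].to_csv(f"{args.outdir}/reference_overlap.tsv",
                                sep="\t")
    print("fraction of each group found in >= 1 reference PSD dataset:")
    print(profile["in_any"].round(3).to_string())

    # the juvenile (P9-like) reference excludes increasing proteins, so
    # the decreasing cluster should test enriched and the increasing one
    # depleted against the all-detected background
    juvenile = enrichment.read_gmt(f"{args.datadir}/juvenile_psd.gmt")
    annotations = enrichment.read_gmt(f"{args.datadir}/annotations.gmt")
    collection = {**juvenile, **annotations}
    rows = []
    for c in ("cluster_1", "cluster_2", "cluster_3"):
        enr = enrichment.fisher_enrichment(
            groups[c], collection, groups["all_major"]
        )
        enr.insert(0, "query", c)
        rows.append(enr)
    enr_all = pd.concat(rows)
    enr_all.to_csv(f"{args.outdir}/enrichment.tsv", sep="\t")
    for c, enr in zip(("cluster_1", "cluster_2", "cluster_3"), rows):
        top = enr.loc["p9_crude_psd"]
        print(f"{c} vs juvenile P9-like PSD list: OR={top['odds_ratio']:.2f}, "
              f"p={top['p']:.2e}")

    # ASD comparison
    cascade = pd.read_csv(f"{args.tabledir}/cascade_groups.tsv", sep="\t",
                          index_col=0)
    asd = pd.read_csv(f"{args.datadir}/asd_de_table.tsv", sep="\t")
    human = crossspecies.read_timecourse(
        f"{args.datadir}/mrna_human.tsv", f"{args.datadir}/mrna_human.meta.tsv"
    )
    dev_log = np.log2(crossspecies.perinatal_ratio(human))
    risk = enrichment.read_gmt(f"{args.datadir}/risk_genes.gmt")["risk_gene_list"]
    out = crossspecies.asd_comparison(
        {"DDP-MH": set(cascade.index[cascade["DDP-MH"]]),
         "DIP-MH": set(cascade.index[cascade["DIP-MH"]])},
        groups["all_major"],
        dev_log[dev_log.index.isin(groups["all_major"])],
        asd,
        risk_genes=risk,
    )
    out["enrichment"].to_csv(f"{args.outdir}/asd_enrichment.tsv", sep="\t")
    print(f"developmental vs ASD log-ratio: Spearman rho = "
          f"{out['rho_dev_vs_asd']:.2f} over {out['n_rho']} genes")
    for name, rec in out["groups"].items():
        direction = "down" if name.startswith("DIP") else "up"
        frac = (rec["n_down"] if direction == "down" else rec["n_up"])
        print(f"  {name}: {rec['n_asd_de']} ASD-DE genes, "
              f"{frac}/{rec['n_asd_de']} {direction}regulated in ASD, "
              f"{rec['risk_overlap']} on the risk-gene list")
    print(f"risk-gene overlap with DDP-MH u DIP-MH: "
          f"{out['risk_overlap_total']}")


if __name__ == "__main__":
    main()
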