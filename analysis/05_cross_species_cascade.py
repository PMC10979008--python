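"""Trace the DDP/DIP groups through mouse, human and macaque mRNA, and
compare mouse and marmoset proteome remodeling.

The mRNA change leads the protein change, so the correlation between
protein change and mRNA change is highest when the mRNA ratio is taken
from the earliest timepoint.  DDP/DIP whose mRNA change is
sign-concordant in both mouse datasets become DDP-M/DIP-M; those whose
human (macaque) perinatal ratio agrees become DDP-MH/DIP-MH (-MM).
Marmoset proteins with a >2-fold change of mean abundance between 2
and 24 months are Late DDP / Late DIP.
"""

import argparse
import os

import numpy as np
import pandas as pd

from psdremodel import crossspecies, de, quant


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--datadir", default="results/data")
    ap.add_argument("--tabledir", default="results/tables")
    ap.add_argument("--outdir", default="results/tables")
    args = ap.parse_args()
    os.makedirs(args.outdir, exist_ok=True)

    filtered = quant.read_quant_table(
        f"{args.tabledir}/mouse_filtered.tsv",
        f"{args.tabledir}/mouse_filtered.samples.tsv",
    )
    de_table = pd.read_csv(f"{args.tabledir}/de_table.tsv", sep="\t",
                           index_col=0)
    gene_of = pd.Series(
        filtered.data["gene_symbol"].to_numpy(),
        index=filtered.data["protein_id"].to_numpy(),
    )
    ddp = pd.Index(gene_of[de_table.index[de_table["group"] == "DDP"]])
    dip = pd.Index(gene_of[de_table.index[de_table["group"] == "DIP"]])

    courses = {
        name: crossspecies.read_timecourse(
            f"{args.datadir}/mrna_{name}.tsv",
            f"{args.datadir}/mrna_{name}.meta.tsv",
        )
        for name in ("mouse_ds1", "mouse_ds2", "human", "macaque")
    }
    stage_means = quant.compute_stage_summary(filtered).mean
    stage_means.index = gene_of[stage_means.index].to_numpy()
    protein_change = np.log2(stage_means.iloc[:, -1] / stage_means.iloc[:, 0])

    print("protein change vs mRNA change (Spearman rho by mRNA start point):")
    for name in ("mouse_ds1", "mouse_ds2"):
        course = courses[name]
        rhos = [
            crossspecies.change_correlation(protein_change, course, i)[0]
            for i in range(len(course.ages) - 1)
        ]
        print(f"  {name}: " + "  ".join(
            f"P{a:g}:{r:.2f}" for a, r in zip(course.ages, rhos)
        ))

    ddp_m, dip_m, _ = crossspecies.assign_concordant_groups(
        ddp, dip, [courses["mouse_ds1"], courses["mouse_ds2"]]
    )
    primate = crossspecies.assign_primate_groups(
        ddp_m, dip_m, courses["human"], courses["macaque"]
    )
    print(f"cascade: DDP {len(ddp)} -> DDP-M {len(ddp_m)} -> "
          f"DDP-MH {len(primate['ddp_mh'])} / DDP-MM {len(primate['ddp_mm'])}")
    print(f"         DIP {len(dip)} -> DIP-M {len(dip_m)} -> "
          f"DIP-MH {len(primate['dip_mh'])} / DIP-MM {len(primate['dip_mm'])}")

    # marmoset: late remodeling and similarity to the mouse trajectory
    marmoset = quant.read_quant_table(
        f"{args.datadir}/marmoset_quant.tsv",
        f"{args.datadir}/marmoset_samples.tsv",
    )
    marm_filtered = quant.filter_major_proteins(marmoset)
    late = de.late_de(marm_filtered, "2M", "24M", fold=2.0)
    late.to_csv(f"{args.outdir}/late_de.tsv", sep="\t")
    n_lddp = (late["late_group"] == "Late DDP").sum()
    n_ldip = (late["late_group"] == "Late DIP").sum()
    print(f"marmoset late phase (2M -> 24M, >2-fold of mean, n=2): "
          f"{n_lddp} Late DDP, {n_ldip} Late DIP")

    marm_means = quant.compute_stage_summary(marm_filtered).mean
    marm_gene = pd.Series(
        marm_filtered.data["gene_symbol"].to_numpy(),
        index=marm_filtered.data["protein_id"].to_numpy(),
    )
    marm_means.index = marm_gene[marm_means.index].to_numpy()
    mouse_ch = pd.DataFrame({"2w_to_12w": protein_change})
    marm_ch = pd.DataFrame({
        "0M_to_2M": np.log2(marm_means["2M"] / marm_means["0M"]),
        "2M_to_24M": np.log2(marm_means["24M"] / marm_means["2M"]),
    })
    rho_all = crossspecies.proteome_similarity(
        mouse_ch, marm_ch, "spearman_changes"
    ).loc["2w_to_12w", "0M_to_2M"]
    mh = mouse_ch.index.intersection(
        pd.Index(sorted(set(primate["ddp_mh"]) | set(primate["dip_mh"])))
    )
    rho_mh = crossspecies.proteome_similarity(
        mouse_ch.loc[mh], marm_ch, "spearman_changes"
    ).loc["2w_to_12w", "0M_to_2M"]
    print(f"mouse 2-12w vs marmoset 0-2M change correlation: "
          f"rho={rho_all:.2f} all proteins, rho={rho_mh:.2f} restricted to "
          f"DDP-MH/DIP-MH")

    groups = pd.DataFrame(index=pd.Index(sorted(set(ddp) | set(dip)),
                                         name="gene"))
    for name, members in (("DDP", ddp), ("DIP", dip), ("DDP-M", ddp_m),
                          ("DIP-M", dip_m), ("DDP-MH", primate["ddp_mh"]),
                          ("DIP-MH", primate["dip_mh"]),
                          ("DDP-MM", primate["ddp_mm"]),
                          ("DIP-MM", primate["dip_mm"])):
        groups[name] = groups.index.isin(set(members))
    groups.to_csv(f"{args.outdir}/cascade_groups.tsv", sep="\t")


if __name__ == "__main__":
    main()
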