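"""Call differentially expressed proteins and label DDP / DIP.

DE requires a Benjamini-Hochberg adjusted Welch ANOVA p < 0.05 across
the four stages and a max fold change (highest / lowest stage mean)
above 1.5.  DE proteins in the decreasing cluster are the
developmentally decreased postsynaptic proteins (DDP), in the
increasing cluster the increased ones (DIP).
"""

import argparse
import os

import pandas as pd

from psdremodel import de, quant


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--tabledir", default="results/tables")
    ap.add_argument("--outdir", default="results/tables")
    args = ap.parse_args()

    filtered = quant.read_quant_table(
        f"{args.tabledir}/mouse_filtered.tsv",
        f"{args.tabledir}/mouse_filtered.samples.tsv",
    )
    clusters = pd.read_csv(
        f"{args.tabledir}/clusters.tsv", sep="\t", index_col=0
    ).iloc[:, 0]
    pvals = de.anova_per_protein(filtered)
    fc = de.max_fold_change(quant.compute_stage_summary(filtered).mean)
    result = de.call_de(pvals, fc, clusters)

    os.makedirs(args.outdir, exist_ok=True)
    result.table.to_csv(f"{args.outdir}/de_table.tsv", sep="\t")

    n_ddp = len(result.group_members("DDP"))
    n_dip = len(result.group_members("DIP"))
    print(f"{result.n_de} DE proteins of {len(result.table)} "
          f"(q < 0.05 and max FC > 1.5)")
    print(f"DDP {n_ddp} (decreasing cluster), DIP {n_dip} (increasing), "
          f"{result.n_de - n_ddp - n_dip} DE in the flat cluster stay "
          f"unlabelled")


if __name__ == "__main__":
    main()
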