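"""End-to-end pipeline: filter -> cluster -> DE -> cascade -> kinetics
-> enrichment, with a machine-readable run summary.

The pipeline runs either on a synthetic study generated in memory from
a :class:`~psdremodel.synthetic.SimulationConfig` (the default; planted
truth enables recovery metrics) or on files previously written by
:func:`~psdremodel.synthetic.write_dataset`.  Every stage writes its
table under the output directory and contributes counts and statistics
to ``summary.json``; re-running with the same config and seed
reproduces identical outputs.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import adjusted_rand_score

from . import __version__
from . import clustering, crossspecies, de, enrichment, kinetics, quant, synthetic


@dataclass
class PipelineConfig:
    """All thresholds of the cascade, with their conventional defaults."""

    min_unique_peptides: int = 2
    cv_max: float = 100.0
    q_alpha: float = 0.05
    fc_min: float = 1.5
    late_fold: float = 2.0
    asd_alpha: float = 0.05
    k: int | None = 3            # None -> validity-index vote
    k_min: int = 2
    k_max: int = 8
    kmeans_restarts: int = 50
    welch: bool = True
    anova_on_log: bool = False
    seed: int = 0
    outdir: str = "results/pipeline"
    input_dir: str | None = None  # read a written dataset instead of simulating
    simulation: synthetic.SimulationConfig | None = None

    def __post_init__(self) -> None:
        for name in ("min_unique_peptides", "cv_max", "q_alpha", "fc_min",
                     "late_fold", "asd_alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.simulation is None:
            self.simulation = synthetic.SimulationConfig(seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim:
            sim.setdefault("seed", cfg.seed)
            if "stages" in sim:
                sim["stages"] = tuple(tuple(s) for s in sim["stages"])
            cfg.simulation = synthetic.SimulationConfig(**sim)
        return cfg


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, pd.Index)):
        return [_to_jsonable(v) for v in sorted(obj) if True] if isinstance(
            obj, set
        ) else [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), 10)
    if isinstance(obj, np.ndarray):
        return [_to_jsonable(v) for v in obj.tolist()]
    return obj


def _load_inputs(config: PipelineConfig):
    """Simulate the study in memory, or read it from ``input_dir``."""
    sim = config.simulation
    if config.input_dir is None:
        table, truth = synthetic.simulate_quant_table(sim)
        marmoset = synthetic.simulate_marmoset_table(sim, truth)
        courses = synthetic.simulate_transcriptomes(sim, truth)
        asd = synthetic.simulate_asd_table(
            truth, sim.asd_anticorrelation_rho, sim.seed + synthetic.SEED_ASD
        )
        halflife = synthetic.simulate_halflife_table(sim, truth)
        halflife = pd.Series(
            halflife["half_life_days"].to_numpy(), index=halflife["gene"]
        )
        sets = synthetic.simulate_reference_genesets(sim, truth)
    else:
        d = config.input_dir
        table = quant.read_quant_table(
            os.path.join(d, "mouse_quant.tsv"), os.path.join(d, "mouse_samples.tsv")
        )
        marmoset = quant.read_quant_table(
            os.path.join(d, "marmoset_quant.tsv"),
            os.path.join(d, "marmoset_samples.tsv"),
        )
        courses = [
            crossspecies.read_timecourse(
                os.path.join(d, f"mrna_{name}.tsv"),
                os.path.join(d, f"mrna_{name}.meta.tsv"),
            )
            for name in ("mouse_ds1", "mouse_ds2", "human", "macaque")
        ]
        asd = pd.read_csv(os.path.join(d, "asd_de_table.tsv"), sep="\t")
        halflife = kinetics.read_halflife_table(os.path.join(d, "half_lives.tsv"))
        sets = {
            name: enrichment.read_gmt(os.path.join(d, f"{name}.gmt"))
            for name in ("psd_references", "annotations", "juvenile_psd", "risk_genes")
        }
        truth = None
        truth_path = os.path.join(d, "ground_truth.tsv")
        if os.path.exists(truth_path):
            tframe = pd.read_csv(truth_path, sep="\t").set_index("protein_id")
            truth = synthetic.GroundTruth(
                classes=tframe["true_class"],
                gene_of=tframe["gene_symbol"],
            )
    return table, marmoset, courses, asd, halflife, sets, truth


def recovery_metrics(
    predicted_dec, predicted_inc, truth: synthetic.GroundTruth, universe=None
) -> dict:
    """Precision/recall of predicted DDP/DIP genes vs. planted classes.

    Recall is over all planted decreasing/increasing genes (end to
    end); ``universe`` restricts an additional recall figure to genes
    that survived filtering.
    """
    dec_true = set(truth.genes_in_class("decreasing"))
    inc_true = set(truth.genes_in_class("increasing"))
    pdec, pinc = set(predicted_dec), set(predicted_inc)

    def _pr(pred, true):
        tp = len(pred & true)
        prec = tp / len(pred) if pred else np.nan
        rec = tp / len(true) if true else np.nan
        return prec, rec

    prec_d, rec_d = _pr(pdec, dec_true)
    prec_i, rec_i = _pr(pinc, inc_true)
    out = {
        "precision_decreasing": prec_d,
        "recall_decreasing": rec_d,
        "precision_increasing": prec_i,
        "recall_increasing": rec_i,
        "precision": min(prec_d, prec_i),
        "recall": min(rec_d, rec_i),
    }
    if universe is not None:
        uni = set(universe)
        _, rd = _pr(pdec, dec_true & uni)
        _, ri = _pr(pinc, inc_true & uni)
        out["recall_filtered_universe"] = min(rd, ri)
    return out


def cluster_ari(labels: pd.Series, truth: synthetic.GroundTruth) -> float:
    """Adjusted Rand index of cluster labels vs. planted trajectory class."""
    gene_class = pd.Series(
        truth.classes.to_numpy(), index=truth.gene_of.to_numpy()
    )
    shared = labels.index.intersection(gene_class.index)
    true = gene_class[shared]
    keep = true.isin(["decreasing", "flat", "increasing"])
    return float(adjusted_rand_score(true[keep], labels[shared][keep]))


def check_cascade_nesting(sets_chain: list[set]) -> bool:
    """True when each set is contained in the next (smallest first)."""
    return all(
        set(sets_chain[i]) <= set(sets_chain[i + 1])
        for i in range(len(sets_chain) - 1)
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return (and write) the run summary."""
    os.makedirs(config.outdir, exist_ok=True)
    table, marmoset, courses, asd, halflife, sets, truth = _load_inputs(config)
    mouse_ds = [c for c in courses if c.species == "mouse"]
    human = next(c for c in courses if c.species == "human")
    macaque = next(c for c in courses if c.species == "macaque")
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "min_unique_peptides": config.min_unique_peptides,
            "cv_max": config.cv_max,
            "q_alpha": config.q_alpha,
            "fc_min": config.fc_min,
            "late_fold": config.late_fold,
            "asd_alpha": config.asd_alpha,
        },
    }

    # -- filtering ---------------------------------------------------------
    qc = quant.major_protein_qc(table, config.min_unique_peptides, config.cv_max)
    filtered = quant.filter_major_proteins(
        table, config.min_unique_peptides, config.cv_max
    )
    specific = quant.stage_specific_proteins(table)
    qc.to_csv(os.path.join(config.outdir, "qc_report.tsv"), sep="\t")
    quant.write_quant_table(
        filtered,
        os.path.join(config.outdir, "mouse_filtered.tsv"),
        os.path.join(config.outdir, "mouse_samples.tsv"),
    )
    specific.to_csv(os.path.join(config.outdir, "stage_specific.tsv"), sep="\t")
    summary["filtering"] = {
        "n_input": table.n_proteins,
        "n_major": filtered.n_proteins,
        "n_stage_specific": int(specific["stage_specific"].sum()),
        "n_young": int((specific["group"] == "Young").sum()),
        "n_adult": int((specific["group"] == "Adult").sum()),
    }

    # -- clustering --------------------------------------------------------
    ram = clustering.relative_abundance(filtered)
    scores, evr = clustering.pca_samples(ram)
    scores.to_csv(os.path.join(config.outdir, "pca_scores.tsv"), sep="\t")
    if config.k is None:
        chosen_k, votes = clustering.select_k(
            ram.stage_means, config.k_min, config.k_max, seed=config.seed
        )
        votes.to_csv(
            os.path.join(config.outdir, "k_votes.tsv"), sep="\t", index=False
        )
    else:
        chosen_k, votes = config.k, None
    result = clustering.kmeans_trajectories(
        ram.stage_means, chosen_k, config.kmeans_restarts, config.seed
    )
    result.labels.to_csv(os.path.join(config.outdir, "clusters.tsv"), sep="\t")
    result.centroids.to_csv(os.path.join(config.outdir, "centroids.tsv"), sep="\t")
    summary["clustering"] = {
        "chosen_k": chosen_k,
        "cluster_sizes": result.labels.value_counts().sort_index().tolist(),
        "pc1_variance_ratio": float(evr[0]),
    }

    # -- differential expression ------------------------------------------
    pvals = de.anova_per_protein(filtered, config.welch, config.anova_on_log)
    fc = de.max_fold_change(
        quant.compute_stage_summary(filtered).mean
    )
    de_result = de.call_de(pvals, fc, result.labels, config.q_alpha, config.fc_min)
    de_result.table.to_csv(os.path.join(config.outdir, "de_table.tsv"), sep="\t")

    gene_of = pd.Series(
        filtered.data["gene_symbol"].to_numpy(),
        index=filtered.data["protein_id"].to_numpy(),
    )
    ddp_genes = pd.Index(gene_of[de_result.group_members("DDP")].to_numpy())
    dip_genes = pd.Index(gene_of[de_result.group_members("DIP")].to_numpy())
    cluster1_genes = set(gene_of[result.labels.index[result.labels == 1]])
    clusterk_genes = set(gene_of[result.labels.index[result.labels == chosen_k]])
    summary["de"] = {
        "n_de": de_result.n_de,
        "n_ddp": len(ddp_genes),
        "n_dip": len(dip_genes),
        "n_de_unlabelled": int(de_result.n_de - len(ddp_genes) - len(dip_genes)),
    }

    # -- cross-species cascade --------------------------------------------
    stage_means = quant.compute_stage_summary(filtered).mean
    stage_means.index = gene_of[stage_means.index].to_numpy()
    protein_change = pd.Series(
        np.log2(stage_means.iloc[:, -1] / stage_means.iloc[:, 0]),
        index=stage_means.index,
    )
    corr_profile = {}
    for course in mouse_ds:
        per_tp = []
        for i in range(len(course.ages) - 1):
            rho, n_used, _ = crossspecies.change_correlation(
                protein_change, course, from_timepoint=i
            )
            per_tp.append({"from_age": course.ages[i], "rho": rho, "n": n_used})
        corr_profile[course.name] = per_tp
    summary["mrna_protein_correlation"] = corr_profile

    ddp_m, dip_m, n_excl = crossspecies.assign_concordant_groups(
        ddp_genes, dip_genes, mouse_ds
    )
    primate = crossspecies.assign_primate_groups(ddp_m, dip_m, human, macaque)
    cascade = {
        "n_ddp_m": len(ddp_m),
        "n_dip_m": len(dip_m),
        "n_excluded_unmapped": n_excl + primate["n_unmapped"],
        "n_ddp_mh": len(primate["ddp_mh"]),
        "n_dip_mh": len(primate["dip_mh"]),
        "n_ddp_mm": len(primate["ddp_mm"]),
        "n_dip_mm": len(primate["dip_mm"]),
    }
    nested_dec = check_cascade_nesting(
        [set(primate["ddp_mh"]), set(ddp_m), set(ddp_genes), cluster1_genes]
    )
    nested_inc = check_cascade_nesting(
        [set(primate["dip_mh"]), set(dip_m), set(dip_genes), clusterk_genes]
    )
    cascade["nesting_ok"] = bool(nested_dec and nested_inc)
    if not cascade["nesting_ok"]:
        raise AssertionError("cascade nesting violated (DDP chain or DIP chain)")
    summary["cascade"] = cascade
    groups_frame = pd.DataFrame(
        {
            "gene": sorted(set(ddp_genes) | set(dip_genes)),
        }
    ).set_index("gene")
    for name, members in (
        ("DDP", ddp_genes), ("DIP", dip_genes), ("DDP-M", ddp_m), ("DIP-M", dip_m),
        ("DDP-MH", primate["ddp_mh"]), ("DIP-MH", primate["dip_mh"]),
        ("DDP-MM", primate["ddp_mm"]), ("DIP-MM", primate["dip_mm"]),
    ):
        groups_frame[name] = groups_frame.index.isin(set(members))
    groups_frame.to_csv(os.path.join(config.outdir, "cascade_groups.tsv"), sep="\t")

    # -- marmoset: late remodeling and cross-species similarity -----------
    marmoset_filtered = quant.filter_major_proteins(
        marmoset, config.min_unique_peptides, config.cv_max
    )
    late = de.late_de(marmoset_filtered, "2M", "24M", config.late_fold)
    late.to_csv(os.path.join(config.outdir, "late_de.tsv"), sep="\t")
    overlap = crossspecies.dataset_overlap(
        set(marmoset.data.loc[(marmoset.intensities > 0).any(axis=1).to_numpy(),
                              "gene_symbol"]),
        set(table.data.loc[(table.intensities > 0).any(axis=1).to_numpy(),
                           "gene_symbol"]),
    )
    marm_means = quant.compute_stage_summary(marmoset_filtered).mean
    marm_gene_of = pd.Series(
        marmoset_filtered.data["gene_symbol"].to_numpy(),
        index=marmoset_filtered.data["protein_id"].to_numpy(),
    )
    marm_means.index = marm_gene_of[marm_means.index].to_numpy()
    sim_lfq = crossspecies.proteome_similarity(stage_means, marm_means, "pearson_lfq")
    sim_lfq.to_csv(os.path.join(config.outdir, "similarity_lfq.tsv"), sep="\t")

    mouse_changes = pd.DataFrame({"2w_to_12w": protein_change})
    marm_changes = pd.DataFrame(
        {
            "0M_to_2M": np.log2(marm_means["2M"] / marm_means["0M"]),
            "2M_to_24M": np.log2(marm_means["24M"] / marm_means["2M"]),
        }
    )
    sim_changes = crossspecies.proteome_similarity(
        mouse_changes, marm_changes, "spearman_changes"
    )
    mh_genes = set(primate["ddp_mh"]) | set(primate["dip_mh"])
    mh_index = mouse_changes.index.intersection(pd.Index(sorted(mh_genes)))
    sim_changes_mh = crossspecies.proteome_similarity(
        mouse_changes.loc[mh_index], marm_changes, "spearman_changes"
    )
    summary["marmoset"] = {
        "n_major": marmoset_filtered.n_proteins,
        "n_late_ddp": int((late["late_group"] == "Late DDP").sum()),
        "n_late_dip": int((late["late_group"] == "Late DIP").sum()),
        "overlap_with_mouse": overlap,
        "rho_changes_all": float(sim_changes.loc["2w_to_12w", "0M_to_2M"]),
        "rho_changes_ddp_dip_mh": float(sim_changes_mh.loc["2w_to_12w", "0M_to_2M"]),
        "rho_late_vs_neonatal": float(
            crossspecies.proteome_similarity(
                marm_changes[["0M_to_2M"]], marm_changes[["2M_to_24M"]],
                "spearman_changes",
            ).iloc[0, 0]
        ),
    }

    # -- kinetics ----------------------------------------------------------
    med_ddp, n_ddp_hl, _ = kinetics.median_half_life(ddp_m, halflife)
    med_dip, n_dip_hl, _ = kinetics.median_half_life(dip_m, halflife)
    lag_rows = []
    for group, med in (("DDP-M", med_ddp), ("DIP-M", med_dip)):
        model = kinetics.KineticModel(med)
        lag_rows.append(
            {
                "group": group,
                "median_half_life_days": med,
                "lag_50pct_days": kinetics.lag_to_fraction(model, 0.5),
                "lag_90pct_days": kinetics.lag_to_fraction(model, 0.9),
            }
        )
    pd.DataFrame(lag_rows).to_csv(
        os.path.join(config.outdir, "kinetics.tsv"), sep="\t", index=False
    )
    summary["kinetics"] = {
        "median_half_life_ddp_m": med_ddp,
        "median_half_life_dip_m": med_dip,
        "n_mapped": n_ddp_hl + n_dip_hl,
        "lag_90pct_ddp_m_days": lag_rows[0]["lag_90pct_days"],
        "lag_90pct_dip_m_days": lag_rows[1]["lag_90pct_days"],
    }

    # -- enrichment and reference overlap ---------------------------------
    all_genes = set(gene_of)
    cluster_groups = {
        f"cluster_{c}": set(
            gene_of[result.labels.index[result.labels == c]]
        )
        for c in range(1, chosen_k + 1)
    }
    cluster_groups["all_major"] = all_genes
    profile = enrichment.reference_overlap_profile(
        cluster_groups, sets["psd_references"]
    )
    profile["fractions"].to_csv(
        os.path.join(config.outdir, "reference_overlap.tsv"), sep="\t"
    )
    background = set().union(*sets["psd_references"].values())
    enr = enrichment.fisher_enrichment(
        all_genes & background, sets["annotations"], background
    )
    enr.to_csv(os.path.join(config.outdir, "enrichment.tsv"), sep="\t")
    summary["enrichment"] = {
        "frac_in_any_reference": float(profile["in_any"]["all_major"]),
        "top_annotation_p": float(enr["p"].iloc[0]),
    }

    # -- ASD comparison ----------------------------------------------------
    dev_log = pd.Series(
        np.log2(crossspecies.perinatal_ratio(human)),
        name="dev_log2fc",
    )
    asd_res = crossspecies.asd_comparison(
        {"DDP-MH": set(primate["ddp_mh"]), "DIP-MH": set(primate["dip_mh"])},
        all_genes,
        dev_log[dev_log.index.isin(all_genes)],
        asd,
        config.asd_alpha,
        risk_genes=sets["risk_genes"]["risk_gene_list"],
    )
    asd_res["enrichment"].to_csv(
        os.path.join(config.outdir, "asd_enrichment.tsv"), sep="\t"
    )
    summary["asd"] = {
        "rho_dev_vs_asd": asd_res["rho_dev_vs_asd"],
        "n_rho": asd_res["n_rho"],
        "groups": asd_res["groups"],
        "risk_overlap_total": asd_res.get("risk_overlap_total"),
    }

    # -- recovery against planted truth ------------------------------------
    if truth is not None:
        summary["recovery"] = recovery_metrics(
            ddp_genes, dip_genes, truth, universe=all_genes
        )
        summary["recovery"]["cluster_ari"] = cluster_ari(
            pd.Series(result.labels.to_numpy(), index=gene_of[result.labels.index]),
            truth,
        )
        spec_pred = set(
            table.data.set_index("protein_id").loc[
                specific.index[specific["stage_specific"]], "gene_symbol"
            ]
        )
        spec_true = set(truth.genes_in_class("young-specific", "adult-specific"))
        summary["recovery"]["stage_specific_recall"] = (
            len(spec_pred & spec_true) / len(spec_true) if spec_true else np.nan
        )

    with open(os.path.join(config.outdir, "summary.json"), "w") as fh:
        json.dump(_to_jsonable(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def make_fixtures(seed: int = 0, outdir: str = "results/fixtures") -> dict:
    """Write a miniature full-structure dataset for fast tests."""
    config = synthetic.SimulationConfig(
        n_proteins=200,
        frac_ddp=0.2,
        frac_dip=0.2,
        frac_stage_specific=0.05,
        seed=seed,
    )
    paths = synthetic.write_dataset(config, outdir)
    with open(os.path.join(outdir, "config.yaml"), "w") as fh:
        yaml.safe_dump(
            {
                "seed": seed,
                "input_dir": outdir,
                "simulation": {
                    k: (
                        [list(s) for s in v] if k == "stages"
                        else list(v) if isinstance(v, tuple) else v
                    )
                    for k, v in asdict(config).items()
                },
            },
            fh,
        )
    return paths
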