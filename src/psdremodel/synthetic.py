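"""Synthetic LFQ proteome and transcriptome generator with known truth.

Every downstream stage of the pipeline is exercised against data from
this module, which emulates a developmental PSD study design: a 16-sample mouse
PSD matrix (4 stages x 4 replicates, ages 2/3/6/12 weeks), 10-sample
marmoset matrices (5 ages x 2 replicates, 0-24 months), mouse / human /
macaque mRNA time courses in which the mRNA step leads the protein
change, a neuronal protein half-life table, an ASD case-control
differential-expression table anti-correlated with the developmental
change, and reference gene-set collections.

Planted protein classes are ``decreasing``, ``flat``, ``increasing``,
``young-specific`` and ``adult-specific``.  Intensities are simulated on
the log2 scale (base level ~ Normal(20, 2), a realistic LFQ dynamic
range); replicate noise is log-normal with a stated coefficient of
variation; missingness is logistic in log-intensity (missing not at
random), except for the structural absences of stage-specific proteins.

All randomness flows from one integer seed; sub-generators use
documented offsets (``seed + k``) so each output is reproducible in
isolation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quant import QuantTable

# seed offsets for the sub-generators (documented contract)
SEED_QUANT = 0
SEED_MARMOSET = 1
SEED_MRNA = 2
SEED_ASD = 3
SEED_HALFLIFE = 4
SEED_GENESETS = 5

MOUSE_STAGES = (("2w", 14.0), ("3w", 21.0), ("6w", 42.0), ("12w", 84.0))
MARMOSET_STAGES = (
    ("0M", 0.0),
    ("2M", 61.0),
    ("3M", 91.0),
    ("6M", 183.0),
    ("24M", 730.0),
)

# postnatal ages (days) of the two emulated mouse cortex time courses
MOUSE_MRNA_AGES_1 = (4.0, 7.0, 10.0, 15.0, 21.0, 90.0)
MOUSE_MRNA_AGES_2 = (1.0, 4.0, 14.0, 28.0, 90.0)
# primate-like courses: ages in years, negative = prenatal
PRIMATE_MRNA_AGES = (-0.35, -0.25, -0.15, -0.05, 0.05, 0.25, 0.75, 2.0, 8.0, 20.0)


@dataclass
class SimulationConfig:
    """Ground-truth parameters of one synthetic study.

    ``frac_ddp`` / ``frac_dip`` are the proportions of planted
    decreasing / increasing proteins; ``effect_log2fc`` is the total
    log2 change of their stage means across the time course;
    ``noise_cv_percent`` the within-stage replicate CV on the linear
    scale.  ``frac_stage_specific`` proteins (split evenly Young/Adult)
    are fully detected in one edge stage and structurally absent
    elsewhere.  ``dropout_midpoint``/``dropout_steepness`` parameterize
    the logistic missing-not-at-random dropout on log2 intensity.
    ``mrna_lead_timepoints`` shifts the planted mRNA step earlier than
    the protein change by that many grid indices.
    """

    n_proteins: int = 2000
    stages: tuple = MOUSE_STAGES
    replicates_per_stage: int = 4
    frac_ddp: float = 0.15
    frac_dip: float = 0.15
    effect_log2fc: float = 1.5
    noise_cv_percent: float = 20.0
    frac_stage_specific: float = 0.05
    dropout_midpoint: float = 12.0
    dropout_steepness: float = 1.0
    mrna_lead_timepoints: int = 2
    halflife_lognormal_params: tuple = (9.0, 0.8)  # (median days, log-sd)
    asd_anticorrelation_rho: float = -0.48
    seed: int = 0
    region: str = "whole_brain"
    species: str = "mouse"

    def __post_init__(self) -> None:
        if self.n_proteins <= 0 or self.replicates_per_stage <= 0:
            raise ValueError("counts must be positive")
        for name in ("frac_ddp", "frac_dip", "frac_stage_specific"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_ddp + self.frac_dip + self.frac_stage_specific > 1.0:
            raise ValueError("class fractions exceed 1")
        if self.noise_cv_percent < 0:
            raise ValueError("noise_cv_percent must be non-negative")
        if len(self.stages) < 2:
            raise ValueError("need at least two stages")

    @property
    def stage_labels(self) -> list[str]:
        return [s for s, _ in self.stages]

    @property
    def stage_ages(self) -> np.ndarray:
        return np.asarray([a for _, a in self.stages], dtype=float)


@dataclass
class GroundTruth:
    """Per-protein planted labels and quantities.

    ``classes`` maps protein_id -> trajectory class.  ``gene_of``
    maps protein_id -> gene symbol (one gene per protein in the
    simulation).  ``mrna_log2fc`` holds, per generated transcriptome
    dataset, the planted total log2 change of the cognate mRNA.
    ``dev_score`` is the continuous developmental log-ratio against
    which the ASD table is calibrated; ``half_life_days`` is filled by
    :func:`simulate_halflife_table`.
    """

    classes: pd.Series
    gene_of: pd.Series
    mrna_log2fc: dict = field(default_factory=dict)
    dev_score: pd.Series | None = None
    half_life_days: pd.Series | None = None
    asd_de_genes: set = field(default_factory=set)

    def genes_in_class(self, *names: str) -> pd.Index:
        mask = self.classes.isin(names)
        return pd.Index(self.gene_of[self.classes.index[mask]].to_numpy())


def _log2_noise_sd(cv_percent: float) -> float:
    """Log2-scale sd giving a linear-scale CV of ``cv_percent``.

    For a log-normal variable, CV^2 = exp(sigma_ln^2) - 1.
    """
    cv = cv_percent / 100.0
    return float(np.sqrt(np.log1p(cv * cv)) / np.log(2.0))


def _class_counts(config: SimulationConfig) -> dict[str, int]:
    n = config.n_proteins
    n_dec = round(config.frac_ddp * n)
    n_inc = round(config.frac_dip * n)
    n_ss = round(config.frac_stage_specific * n)
    n_young = n_ss // 2 + n_ss % 2
    n_adult = n_ss // 2
    n_flat = n - n_dec - n_inc - n_ss
    if n_flat < 0:
        raise ValueError("class fractions exceed 1 after rounding")
    return {
        "decreasing": n_dec,
        "increasing": n_inc,
        "young-specific": n_young,
        "adult-specific": n_adult,
        "flat": n_flat,
    }


def _planted_stage_means(
    classes: np.ndarray, base_log2: np.ndarray, n_stages: int, effect: float
) -> np.ndarray:
    """Log2 stage means: monotone log-linear for non-flat classes."""
    ramp = np.linspace(0.0, 1.0, n_stages)  # stage index scaled to [0, 1]
    means = np.tile(base_log2[:, None], (1, n_stages))
    dec = classes == "decreasing"
    inc = classes == "increasing"
    means[dec] += effect * (0.5 - ramp)[None, :]
    means[inc] += effect * (ramp - 0.5)[None, :]
    return means


def simulate_quant_table(
    config: SimulationConfig,
    stages: tuple | None = None,
    replicates: int | None = None,
    seed_offset: int = SEED_QUANT,
    truth: GroundTruth | None = None,
    region: str | None = None,
    species: str | None = None,
) -> tuple[QuantTable, GroundTruth]:
    """Simulate an LFQ quant matrix with planted trajectory classes.

    With the default arguments this produces the 16-sample mouse design;
    passing marmoset ``stages``/``replicates`` (and the truth from the
    mouse run, so classes are shared across species) produces the
    10-sample marmoset design.  Stage-specific proteins are fully
    detected in their edge stage and structurally missing elsewhere;
    all other zeros come from the logistic MNAR dropout.
    """
    stages = tuple(stages if stages is not None else config.stages)
    reps = int(replicates if replicates is not None else config.replicates_per_stage)
    if reps <= 0:
        raise ValueError("replicates must be positive")
    rng = np.random.default_rng(config.seed + seed_offset)
    n = config.n_proteins
    n_stages = len(stages)

    if truth is None:
        counts = _class_counts(config)
        classes = np.concatenate(
            [np.repeat(name, k) for name, k in counts.items()]
        )
        rng.shuffle(classes)
        protein_ids = np.array([f"P{i:05d}" for i in range(n)])
        genes = np.array([f"GENE{i:05d}" for i in range(n)])
        truth = GroundTruth(
            classes=pd.Series(classes, index=protein_ids, name="true_class"),
            gene_of=pd.Series(genes, index=protein_ids, name="gene_symbol"),
        )
    classes = truth.classes.to_numpy()
    protein_ids = truth.classes.index.to_numpy()
    genes = truth.gene_of.reindex(truth.classes.index).to_numpy()

    base = rng.normal(20.0, 2.0, size=n)
    means_log2 = _planted_stage_means(classes, base, n_stages, config.effect_log2fc)

    sd = _log2_noise_sd(config.noise_cv_percent)
    noise = rng.normal(0.0, 1.0, size=(n, n_stages, reps)) * sd
    values_log2 = means_log2[:, :, None] + noise
    intensity = np.exp2(values_log2)

    # logistic MNAR dropout on log2 intensity
    p_miss = 1.0 / (
        1.0 + np.exp(config.dropout_steepness * (values_log2 - config.dropout_midpoint))
    )
    missing = rng.random(size=intensity.shape) < p_miss

    # structural detection pattern for stage-specific proteins: fully
    # detected in the first (Young) / last (Adult) stage, absent elsewhere
    young = classes == "young-specific"
    adult = classes == "adult-specific"
    missing[young, 0, :] = False
    missing[young, 1:, :] = True
    missing[adult, -1, :] = False
    missing[adult, :-1, :] = True
    intensity[missing] = 0.0

    sample_names, stage_col, age_col, rep_col = [], [], [], []
    for label, age in stages:
        for r in range(1, reps + 1):
            sample_names.append(f"{label}_rep{r}")
            stage_col.append(label)
            age_col.append(age)
            rep_col.append(r)
    flat = intensity.reshape(n, n_stages * reps)
    data = pd.DataFrame(flat, columns=sample_names)
    # peptide count tracks abundance: low-intensity proteins are the ones
    # identified by a single peptide, as in real LFQ output
    lam = np.clip((base - 12.0) / 1.2, 0.2, 25.0)
    data.insert(0, "unique_peptides", 1 + rng.poisson(lam))
    data.insert(0, "gene_symbol", genes)
    data.insert(0, "protein_id", protein_ids)
    samples = pd.DataFrame(
        {
            "stage": stage_col,
            "age": age_col,
            "replicate": rep_col,
            "region": region or config.region,
            "species": species or config.species,
        },
        index=pd.Index(sample_names, name="sample"),
    )
    return QuantTable(data, samples), truth


def simulate_marmoset_table(
    config: SimulationConfig, truth: GroundTruth
) -> QuantTable:
    """10-sample marmoset matrix (5 ages x 2 replicates), shared truth."""
    table, _ = simulate_quant_table(
        config,
        stages=MARMOSET_STAGES,
        replicates=2,
        seed_offset=SEED_MARMOSET,
        truth=truth,
        region="neocortex",
        species="marmoset",
    )
    return table


# --------------------------------------------------------------------------
# transcriptomes


@dataclass
class TimeCourseSpec:
    name: str
    species: str
    ages: np.ndarray
    birth_index: int | None  # index of first postnatal timepoint
    protein_step_index: int  # grid index matching the protein change midpoint


def _default_timecourse_specs(config: SimulationConfig) -> list[TimeCourseSpec]:
    specs = []
    for name, ages in (
        ("mouse_ds1", MOUSE_MRNA_AGES_1),
        ("mouse_ds2", MOUSE_MRNA_AGES_2),
    ):
        ages = np.asarray(ages, dtype=float)
        mid_age = float(config.stage_ages.mean())
        step = int(np.argmin(np.abs(ages - mid_age)))
        specs.append(TimeCourseSpec(name, "mouse", ages, None, step))
    for name, species in (("human", "human"), ("macaque", "macaque")):
        ages = np.asarray(PRIMATE_MRNA_AGES, dtype=float)
        birth = int(np.searchsorted(ages, 0.0))
        # the primate protein change is perinatal: anchor at the first
        # postnatal timepoint so the led mRNA step falls before birth
        specs.append(TimeCourseSpec(name, species, ages, birth, birth))
    return specs


def simulate_transcriptomes(
    config: SimulationConfig,
    truth: GroundTruth,
    specs: list[TimeCourseSpec] | None = None,
    noise_cv_percent: float | None = None,
):
    """Generate mRNA time courses whose step leads the protein change.

    For decreasing/increasing proteins the cognate mRNA executes a
    sigmoidal step of the same sign and magnitude, centred
    ``config.mrna_lead_timepoints`` grid indices *earlier* than the
    protein change (for the primate-like courses the step therefore
    falls before the birth marker).  Flat proteins get flat mRNA plus
    noise.  Returns a list of :class:`~psdremodel.crossspecies.ExpressionTimeCourse`.

    Records the planted per-dataset mRNA log2 change and the continuous
    developmental score in ``truth``.
    """
    from .crossspecies import ExpressionTimeCourse

    if truth is None:
        raise ValueError("ground truth from the matching quant simulation required")
    if specs is None:
        specs = _default_timecourse_specs(config)
    rng = np.random.default_rng(config.seed + SEED_MRNA)
    cv = config.noise_cv_percent if noise_cv_percent is None else noise_cv_percent
    sd = _log2_noise_sd(cv)

    classes = truth.classes.to_numpy()
    genes = truth.gene_of.reindex(truth.classes.index).to_numpy()
    sign = np.where(
        classes == "decreasing", -1.0, np.where(classes == "increasing", 1.0, 0.0)
    )
    effect = config.effect_log2fc

    courses = []
    for spec in specs:
        t_idx = np.arange(len(spec.ages), dtype=float)
        step_idx = spec.protein_step_index - config.mrna_lead_timepoints
        # steep sigmoid in index space; centred between grid points so a
        # zero-lead step still completes by the protein-change index
        sig = 1.0 / (1.0 + np.exp(-(t_idx - (step_idx - 0.5)) / 0.25))
        base = rng.normal(6.0, 1.0, size=len(classes))
        log2m = (
            base[:, None]
            + sign[:, None] * effect * (sig[None, :] - 0.5)
            + rng.normal(0.0, sd, size=(len(classes), len(spec.ages)))
        )
        values = pd.DataFrame(
            np.exp2(log2m),
            index=pd.Index(genes, name="gene"),
            columns=[f"t{i}" for i in range(len(spec.ages))],
        )
        courses.append(
            ExpressionTimeCourse(
                values=values,
                ages=spec.ages,
                birth_index=spec.birth_index,
                species=spec.species,
                name=spec.name,
            )
        )
        planted = sign * effect * (sig[-1] - sig[0])
        truth.mrna_log2fc[spec.name] = pd.Series(
            planted, index=pd.Index(genes, name="gene")
        )
    # developmental score: the realized human perinatal log-ratio (the
    # quantity the ASD comparison correlates against); falls back to the
    # planted change plus spread when no human-like course was requested
    human = next((c for c in courses if c.birth_index is not None), None)
    if human is not None:
        from .crossspecies import perinatal_ratio

        truth.dev_score = np.log2(perinatal_ratio(human)).rename("dev_log2fc")
    else:
        truth.dev_score = pd.Series(
            sign * effect + rng.normal(0.0, 0.15, size=len(classes)),
            index=pd.Index(genes, name="gene"),
            name="dev_log2fc",
        )
    return courses


# --------------------------------------------------------------------------
# ASD table, half-lives, gene sets


def simulate_asd_table(
    truth: GroundTruth,
    rho_target: float,
    seed: int,
    frac_de: float = 0.3,
) -> pd.DataFrame:
    """ASD case-control DE table anti-correlated with development.

    Draws per-gene ASD log2 fold changes from a Gaussian copula on the
    developmental score so their Spearman correlation approaches
    ``rho_target`` (must lie in [-1, 0]; the model is anti-correlation).
    The Pearson parameter of the copula is 2*sin(pi*rho_s/6), the exact
    bivariate-normal relation between Spearman and Pearson correlation.
    P-values put the planted ASD-DE fraction below 0.05.
    """
    if truth.dev_score is None:
        raise ValueError("run simulate_transcriptomes first (dev_score missing)")
    if not -1.0 <= rho_target <= 0.0:
        raise ValueError("rho_target must be in [-1, 0]")
    rng = np.random.default_rng(seed)
    dev = truth.dev_score
    n = len(dev)
    # normal scores of the developmental ranks
    ranks = pd.Series(dev.to_numpy()).rank(method="average").to_numpy()
    from scipy.stats import norm

    z_dev = norm.ppf(ranks / (n + 1.0))
    rho_p = 2.0 * np.sin(np.pi * rho_target / 6.0)
    z_asd = rho_p * z_dev + np.sqrt(max(0.0, 1.0 - rho_p**2)) * rng.normal(size=n)
    log2fc = 0.5 * z_asd

    n_de = round(frac_de * n)
    de_idx = np.argsort(-np.abs(z_asd))[:n_de]  # strongest changes are DE
    p = rng.uniform(0.05, 1.0, size=n)
    p[de_idx] = rng.uniform(1e-8, 0.05, size=n_de)
    table = pd.DataFrame(
        {"gene": dev.index.to_numpy(), "log2fc_asd": log2fc, "p_value": p}
    )
    truth.asd_de_genes = set(table.loc[de_idx, "gene"])
    return table


def simulate_halflife_table(config: SimulationConfig, truth: GroundTruth) -> pd.DataFrame:
    """Log-normal neuronal protein half-lives (median days, log-sd)."""
    median, shape = config.halflife_lognormal_params
    if median <= 0 or shape < 0:
        raise ValueError("half-life parameters must be positive")
    rng = np.random.default_rng(config.seed + SEED_HALFLIFE)
    genes = truth.gene_of.to_numpy()
    t_half = median * np.exp(shape * rng.normal(size=len(genes)))
    truth.half_life_days = pd.Series(
        t_half, index=pd.Index(genes, name="gene"), name="half_life_days"
    )
    return pd.DataFrame({"gene": genes, "half_life_days": t_half})


def simulate_reference_genesets(
    config: SimulationConfig,
    truth: GroundTruth,
    n_references: int = 16,
    coverage: float = 0.6,
    n_risk_genes: int = 18,
) -> dict[str, dict[str, set]]:
    """Reference gene-set collections mirroring a study's external inputs.

    * ``psd_references`` -- ``n_references`` adult PSD proteome lists,
      random subsets (each covering ``coverage`` of the non-young
      proteins) so their union covers nearly every major protein;
    * ``juvenile_psd`` -- a P9-like crude-PSD list biased toward
      decreasing and young-specific proteins;
    * ``go_like`` -- a "postsynaptic density"-style annotation set;
    * ``risk_genes`` -- an SFARI-style list drawn from the planted
      decreasing/increasing genes.
    """
    rng = np.random.default_rng(config.seed + SEED_GENESETS)
    genes = truth.gene_of.to_numpy()
    classes = truth.classes.to_numpy()
    adultish = genes[classes != "young-specific"]
    refs = {}
    for i in range(n_references):
        k = rng.binomial(len(adultish), coverage)
        refs[f"psd_ref_{i + 1:02d}"] = set(rng.choice(adultish, size=k, replace=False))
    juvenileish = genes[np.isin(classes, ["decreasing", "young-specific", "flat"])]
    k = min(512, len(juvenileish))
    juvenile = set(rng.choice(juvenileish, size=k, replace=False))
    go_like = set(rng.choice(genes, size=round(0.8 * len(genes)), replace=False))
    changing = genes[np.isin(classes, ["decreasing", "increasing"])]
    risk = set(rng.choice(changing, size=min(n_risk_genes, len(changing)), replace=False))
    return {
        "psd_references": refs,
        "annotations": {"postsynaptic_density_like": go_like},
        "juvenile_psd": {"p9_crude_psd": juvenile},
        "risk_genes": {"risk_gene_list": risk},
    }


# --------------------------------------------------------------------------
# writers


def write_truth(truth: GroundTruth, path) -> None:
    frame = pd.DataFrame(
        {
            "protein_id": truth.classes.index,
            "gene_symbol": truth.gene_of.reindex(truth.classes.index).to_numpy(),
            "true_class": truth.classes.to_numpy(),
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def write_dataset(config: SimulationConfig, outdir) -> dict:
    """Write the complete synthetic study to ``outdir``; returns paths."""
    from .crossspecies import write_timecourse
    from .enrichment import write_gmt
    from . import quant as q

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    table, truth = simulate_quant_table(config)
    paths["quant"] = os.path.join(outdir, "mouse_quant.tsv")
    paths["quant_meta"] = os.path.join(outdir, "mouse_samples.tsv")
    q.write_quant_table(table, paths["quant"], paths["quant_meta"])

    marmoset = simulate_marmoset_table(config, truth)
    paths["marmoset"] = os.path.join(outdir, "marmoset_quant.tsv")
    paths["marmoset_meta"] = os.path.join(outdir, "marmoset_samples.tsv")
    q.write_quant_table(marmoset, paths["marmoset"], paths["marmoset_meta"])

    courses = simulate_transcriptomes(config, truth)
    for course in courses:
        base = os.path.join(outdir, f"mrna_{course.name}")
        write_timecourse(course, base + ".tsv", base + ".meta.tsv")
        paths[f"mrna_{course.name}"] = base + ".tsv"

    asd = simulate_asd_table(
        truth, config.asd_anticorrelation_rho, config.seed + SEED_ASD
    )
    paths["asd"] = os.path.join(outdir, "asd_de_table.tsv")
    asd.to_csv(paths["asd"], sep="\t", index=False, float_format="%.6g")

    halflife = simulate_halflife_table(config, truth)
    paths["halflife"] = os.path.join(outdir, "half_lives.tsv")
    halflife.to_csv(paths["halflife"], sep="\t", index=False, float_format="%.6g")

    sets = simulate_reference_genesets(config, truth)
    for name, collection in sets.items():
        paths[name] = os.path.join(outdir, f"{name}.gmt")
        write_gmt(collection, paths[name])

    paths["truth"] = os.path.join(outdir, "ground_truth.tsv")
    write_truth(truth, paths["truth"])
    return paths
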