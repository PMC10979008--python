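"""Quantification tables and major-protein filtering.

Label-free quantification (LFQ) of a purified postsynaptic-density (PSD)
fraction yields a proteins x samples intensity matrix in which a zero
intensity means the protein was not detected in that run.  This module
parses such matrices together with per-sample metadata (developmental
stage, replicate, region, species) and applies the selection rules used
throughout the analysis:

* *major proteins* -- at least two unique peptides, quantified (nonzero)
  in every sample, within-stage coefficient of variation below a cap in
  every stage, and one protein per gene (the one with the highest total
  signal);
* *stage-specific proteins* -- detected in every replicate of at least
  one stage while undetected in every replicate of at least one other
  stage, split into "Young" and "Adult" groups by which stages carry the
  full detections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ANNOTATION_COLUMNS = ["protein_id", "gene_symbol", "unique_peptides"]


@dataclass
class QuantTable:
    """A proteins x samples LFQ intensity matrix with sample metadata.

    Parameters
    ----------
    data:
        One row per protein.  Must contain the columns ``protein_id``,
        ``gene_symbol`` and ``unique_peptides`` plus one numeric column
        per sample.  Zero encodes "not detected" (LFQ convention); NaN
        on input is coerced to zero.
    samples:
        Indexed by sample name, with columns ``stage`` (label),
        ``age`` (numeric, same units within a table), ``replicate``
        (integer) and optionally ``region`` and ``species``.
    """

    data: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ANNOTATION_COLUMNS:
            if col not in self.data.columns:
                raise ValueError(f"quant table is missing required column {col!r}")
        if self.samples.index.duplicated().any():
            dup = self.samples.index[self.samples.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample names in metadata: {dup}")
        for col in ("stage", "age", "replicate"):
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata is missing column {col!r}")
        missing = [s for s in self.samples.index if s not in self.data.columns]
        if missing:
            raise ValueError(f"samples missing from quant matrix: {missing}")
        mat = self.data[self.sample_names].apply(pd.to_numeric)
        mat = mat.fillna(0.0)
        if (mat.to_numpy() < 0).any():
            raise ValueError("negative intensities are not allowed")
        self.data = self.data.copy()
        self.data[self.sample_names] = mat

    # -- convenience views -------------------------------------------------

    @property
    def sample_names(self) -> list[str]:
        return list(self.samples.index)

    @property
    def stage_order(self) -> list[str]:
        """Stage labels ordered by age."""
        order = self.samples.sort_values(["age", "replicate"])["stage"]
        return list(dict.fromkeys(order))

    @property
    def intensities(self) -> pd.DataFrame:
        """proteins x samples intensity matrix indexed by protein_id."""
        mat = self.data.set_index("protein_id")[self.sample_names]
        return mat.astype(float)

    def stage_samples(self, stage: str) -> list[str]:
        return list(self.samples.index[self.samples["stage"] == stage])

    def subset(self, protein_ids) -> "QuantTable":
        keep = self.data["protein_id"].isin(set(protein_ids))
        return QuantTable(self.data.loc[keep].reset_index(drop=True), self.samples)

    @property
    def n_proteins(self) -> int:
        return len(self.data)


@dataclass
class StageSummary:
    """Per-protein, per-stage replicate summaries (proteins x stages frames).

    ``cv`` is the percent coefficient of variation, 100 * sd / mean with
    the sample (n-1) standard deviation, defined only where the stage
    mean is positive (NaN otherwise).  ``detected`` counts replicates
    with nonzero intensity.
    """

    mean: pd.DataFrame
    sd: pd.DataFrame
    cv: pd.DataFrame
    detected: pd.DataFrame
    n_replicates: pd.Series = field(default_factory=pd.Series)


def read_quant_table(path, metadata_path) -> QuantTable:
    """Read a TSV/CSV quant matrix plus its sample-metadata sidecar.

    Every numeric sample column of the matrix must be described in the
    metadata (an unmapped column is an error naming it); extra metadata
    columns are preserved.  Duplicate protein rows are accepted here --
    the per-gene collapse happens in :func:`filter_major_proteins`.
    """
    sep_m = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    sep_s = "\t" if str(metadata_path).endswith((".tsv", ".txt")) else ","
    data = pd.read_csv(path, sep=sep_m)
    meta = pd.read_csv(metadata_path, sep=sep_s)
    if "sample" not in meta.columns:
        raise ValueError("sample metadata must have a 'sample' column")
    meta = meta.set_index("sample")
    unmapped = [
        c for c in data.columns if c not in ANNOTATION_COLUMNS and c not in meta.index
    ]
    if unmapped:
        raise ValueError(
            f"matrix columns not described in sample metadata: {unmapped}"
        )
    return QuantTable(data, meta)


def write_quant_table(table: QuantTable, path, metadata_path) -> None:
    cols = ANNOTATION_COLUMNS + table.sample_names
    table.data[cols].to_csv(path, sep="\t", index=False, float_format="%.6f")
    table.samples.reset_index(names="sample").to_csv(
        metadata_path, sep="\t", index=False
    )


def compute_stage_summary(table: QuantTable) -> StageSummary:
    """Mean, sample sd, CV% and detection count per protein and stage."""
    mat = table.intensities
    stages = table.stage_order
    means, sds, dets, nreps = {}, {}, {}, {}
    for stage in stages:
        cols = table.stage_samples(stage)
        sub = mat[cols]
        means[stage] = sub.mean(axis=1)
        sds[stage] = sub.std(axis=1, ddof=1)
        dets[stage] = (sub > 0).sum(axis=1)
        nreps[stage] = len(cols)
    mean = pd.DataFrame(means)
    sd = pd.DataFrame(sds)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = 100.0 * sd / mean
    cv = cv.where(mean > 0)
    return StageSummary(
        mean=mean,
        sd=sd,
        cv=cv,
        detected=pd.DataFrame(dets),
        n_replicates=pd.Series(nreps),
    )


def major_protein_qc(
    table: QuantTable,
    min_unique_peptides: int = 2,
    cv_max: float = 100.0,
    cv_on_log: bool = False,
) -> pd.DataFrame:
    """Per-protein pass/fail booleans for the three major-protein criteria.

    Criteria: (1) ``unique_peptides >= min_unique_peptides``;
    (2) quantified (nonzero) in every sample; (3) CV% below ``cv_max``
    in every stage.  ``cv_on_log`` switches the CV to log2 intensities
    (the default linear scale is the standard CV definition).
    """
    mat = table.intensities
    idx = table.data.set_index("protein_id")
    c1 = idx["unique_peptides"] >= min_unique_peptides
    c2 = (mat > 0).all(axis=1)
    if cv_on_log:
        logged = table.data.copy()
        logged[table.sample_names] = np.log2(mat.where(mat > 0)).fillna(0.0)
        summary = compute_stage_summary(QuantTable(logged, table.samples))
    else:
        summary = compute_stage_summary(table)
    c3 = (summary.cv < cv_max).all(axis=1) & summary.cv.notna().all(axis=1)
    # positional assembly: duplicate protein_id rows must not trip alignment
    qc = pd.DataFrame(
        {
            "min_unique_peptides": c1.to_numpy(),
            "quantified_in_all": c2.to_numpy(),
            "cv_below_max": c3.to_numpy(),
        },
        index=pd.Index(table.data["protein_id"], name="protein_id"),
    )
    qc["pass_all"] = qc.all(axis=1)
    return qc


def filter_major_proteins(
    table: QuantTable,
    min_unique_peptides: int = 2,
    cv_max: float = 100.0,
    cv_on_log: bool = False,
) -> QuantTable:
    """Retain major proteins and collapse to one protein per gene.

    Applies the three QC criteria of :func:`major_protein_qc`, then for
    each gene keeps the single protein with the highest total signal
    intensity (ties broken toward the lexicographically smallest
    protein id, for determinism).  Idempotent.
    """
    qc = major_protein_qc(table, min_unique_peptides, cv_max, cv_on_log)
    keep_ids = qc.index[qc["pass_all"]]
    data = table.data[table.data["protein_id"].isin(keep_ids)].copy()
    if data.empty:
        warnings.warn("no proteins pass the major-protein criteria")
        return QuantTable(data, table.samples)
    totals = data[table.sample_names].sum(axis=1)
    data = data.assign(_total=totals)
    data = data.sort_values(["gene_symbol", "_total", "protein_id"],
                            ascending=[True, False, True])
    data = data.drop_duplicates("gene_symbol", keep="first")
    data = data.drop(columns="_total").sort_values("protein_id")
    return QuantTable(data.reset_index(drop=True), table.samples)


def stage_specific_proteins(table: QuantTable, n_edge_stages: int = 2) -> pd.DataFrame:
    """Flag stage-restricted proteins and group them as Young / Adult.

    A protein is stage-specific when it is detected in *every* replicate
    of at least one stage and in *no* replicate of at least one other
    stage.  It is grouped "Young" when its fully-detected stages include
    one of the earliest ``n_edge_stages`` stages and none of the latest,
    "Adult" for the mirror case; proteins whose full detections span
    both ends (or only middle stages) are stage-specific but belong to
    neither group.

    Returns a frame indexed by protein_id with boolean
    ``stage_specific`` and string ``group`` in {"Young", "Adult", ""}.
    """
    summary = compute_stage_summary(table)
    stages = list(summary.detected.columns)
    nrep = summary.n_replicates
    full = summary.detected.eq(nrep, axis=1)
    none = summary.detected.eq(0)
    specific = full.any(axis=1) & none.any(axis=1)

    early = stages[:n_edge_stages]
    late = stages[-n_edge_stages:]
    full_early = full[early].any(axis=1)
    full_late = full[late].any(axis=1)
    group = pd.Series("", index=full.index, dtype=object)
    group[specific & full_early & ~full_late] = "Young"
    group[specific & full_late & ~full_early] = "Adult"
    return pd.DataFrame({"stage_specific": specific, "group": group})
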