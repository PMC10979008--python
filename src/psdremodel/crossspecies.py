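"""Cross-species mRNA-protein concordance and the group cascade.

Starting from the DDP/DIP protein groups, the cascade asks whether each
protein's developmental change is mirrored by its cognate mRNA:

* DDP-M / DIP-M -- the mRNA log-ratio (adult vs. earliest shared
  postnatal timepoint) has the concordant sign in *both* mouse cortex
  transcriptome datasets;
* DDP-MH / DIP-MH (and -MM) -- the perinatal ratio R (mean postnatal /
  mean prenatal abundance) of the human (macaque) homolog is below /
  above 1.

The module also provides set-level statistics: Spearman correlation of
protein and mRNA changes, pairwise proteome similarity across species,
detection overlap between datasets, and the comparison of developmental
change against an ASD case-control differential-expression table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ExpressionTimeCourse:
    """Genes x timepoints abundance with real ages and a birth marker.

    ``birth_index`` is the index of the first postnatal timepoint (None
    for postnatal-only data).  Genes containing any zero value are
    removed by :meth:`drop_zero_genes` before ratio analyses, since a
    zero abundance makes the log-ratio undefined.
    """

    values: pd.DataFrame
    ages: np.ndarray
    birth_index: int | None = None
    species: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        if len(self.ages) != self.values.shape[1]:
            raise ValueError("ages must match the timepoint columns")
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError("timepoints must be strictly ordered by age")
        if self.birth_index is not None and not (
            0 < self.birth_index < len(self.ages)
        ):
            raise ValueError("birth index must split the timepoints")

    def drop_zero_genes(self) -> "ExpressionTimeCourse":
        keep = (self.values > 0).all(axis=1)
        return ExpressionTimeCourse(
            self.values.loc[keep], self.ages, self.birth_index, self.species, self.name
        )

    def log_ratio(self, from_index: int, to_index: int = -1) -> pd.Series:
        """Per-gene log2 abundance ratio between two timepoints."""
        course = self.drop_zero_genes()
        v = course.values
        return np.log2(v.iloc[:, to_index] / v.iloc[:, from_index]).rename("log2_ratio")


def write_timecourse(course: ExpressionTimeCourse, path, meta_path) -> None:
    course.values.to_csv(path, sep="\t", float_format="%.6g")
    meta = pd.DataFrame(
        {
            "timepoint": course.values.columns,
            "age": course.ages,
            "postnatal": [
                1 if course.birth_index is None or i >= course.birth_index else 0
                for i in range(len(course.ages))
            ],
        }
    )
    meta.attrs["species"] = course.species
    with open(meta_path, "w") as fh:
        fh.write(f"# species={course.species}\tname={course.name}\n")
        meta.to_csv(fh, sep="\t", index=False)


def read_timecourse(path, meta_path) -> ExpressionTimeCourse:
    values = pd.read_csv(path, sep="\t", index_col=0)
    with open(meta_path) as fh:
        header = fh.readline().strip()
        meta = pd.read_csv(fh, sep="\t")
    fields = dict(
        part.split("=", 1) for part in header.lstrip("# ").split("\t") if "=" in part
    )
    postnatal = meta["postnatal"].to_numpy()
    birth = None if postnatal.all() else int(np.argmax(postnatal == 1))
    return ExpressionTimeCourse(
        values=values,
        ages=meta["age"].to_numpy(dtype=float),
        birth_index=birth,
        species=fields.get("species", ""),
        name=fields.get("name", ""),
    )


@dataclass
class HomologMap:
    """Source -> target gene-identifier mapping (a function after ties).

    Duplicate sources are resolved deterministically to the
    lexicographically smallest target.  Lookups fall back to a
    case-insensitive match on the source symbol.
    """

    mapping: pd.Series
    unmapped: list = field(default_factory=list)

    def __post_init__(self) -> None:
        frame = self.mapping.rename("target").rename_axis("source").reset_index()
        frame = frame.sort_values(["source", "target"]).drop_duplicates(
            "source", keep="first"
        )
        self.mapping = frame.set_index("source")["target"]
        self._folded = pd.Series(
            self.mapping.to_numpy(),
            index=self.mapping.index.str.upper(),
        )
        self._folded = self._folded[~self._folded.index.duplicated()]

    @classmethod
    def identity(cls, genes) -> "HomologMap":
        idx = pd.Index(genes)
        return cls(pd.Series(idx.to_numpy(), index=idx))

    @classmethod
    def from_tsv(cls, path) -> "HomologMap":
        frame = pd.read_csv(path, sep="\t")
        return cls(pd.Series(frame.iloc[:, 1].to_numpy(), index=frame.iloc[:, 0]))

    def map_genes(self, genes) -> pd.Series:
        """Map gene ids, case-insensitive fallback; unmapped recorded."""
        genes = pd.Index(genes)
        exact = self.mapping.reindex(genes)
        folded = self._folded.reindex(genes.str.upper())
        out = pd.Series(
            np.where(exact.notna(), exact.to_numpy(), folded.to_numpy()), index=genes
        )
        self.unmapped = list(genes[out.isna()])
        if self.unmapped:
            warnings.warn(f"{len(self.unmapped)} genes could not be mapped")
        return out.dropna()


# --------------------------------------------------------------------------
# change correlation and the cascade


def change_correlation(
    protein_changes: pd.Series,
    course: ExpressionTimeCourse,
    from_timepoint: int,
    to_timepoint: int = -1,
):
    """Spearman rho of protein vs. mRNA log change over mapped genes.

    ``protein_changes`` is a per-gene protein log-ratio (adult vs.
    earliest stage); the mRNA log-ratio runs from ``from_timepoint`` to
    ``to_timepoint`` (default the last, adult).  Genes absent from the
    course are dropped and counted.  Returns ``(rho, n_used, n_dropped)``.
    """
    mrna = course.log_ratio(from_timepoint, to_timepoint)
    shared = protein_changes.index.intersection(mrna.index)
    dropped = len(protein_changes) - len(shared)
    if len(shared) < 3:
        raise ValueError("fewer than 3 genes shared with the time course")
    rho = stats.spearmanr(protein_changes[shared], mrna[shared]).statistic
    return float(rho), len(shared), dropped


def assign_concordant_groups(
    ddp_genes,
    dip_genes,
    courses: list[ExpressionTimeCourse],
    from_timepoint: int = 0,
    to_timepoint: int = -1,
):
    """DDP-M / DIP-M: per-gene mRNA sign concordance in every dataset.

    A DDP gene joins DDP-M when its mRNA log-ratio (``to`` vs ``from``
    timepoint) is negative in *all* supplied datasets; a DIP gene joins
    DIP-M when it is positive in all.  Genes absent from any dataset
    are excluded and reported.  Returns
    ``(ddp_m, dip_m, n_excluded)`` with the groups as Index objects.
    """
    if len(courses) < 1:
        raise ValueError("at least one transcriptome dataset required")
    ratios = [c.log_ratio(from_timepoint, to_timepoint) for c in courses]

    def _concordant(genes, sign):
        genes = pd.Index(genes)
        shared = genes
        for r in ratios:
            shared = shared.intersection(r.index)
        ok = shared
        for r in ratios:
            vals = r[ok]
            ok = ok[np.sign(vals.to_numpy()) == sign]
        return ok, len(genes) - len(shared)

    ddp_m, excl_d = _concordant(ddp_genes, -1)
    dip_m, excl_i = _concordant(dip_genes, +1)
    return ddp_m, dip_m, excl_d + excl_i


def perinatal_ratio(course: ExpressionTimeCourse) -> pd.Series:
    """R = mean postnatal / mean prenatal abundance per gene.

    R < 1 reads "decreased" across birth, R > 1 "increased".  Invariant
    under rescaling a gene's whole course.
    """
    if course.birth_index is None:
        raise ValueError("course has no birth marker")
    course = course.drop_zero_genes()
    pre = course.values.iloc[:, : course.birth_index].mean(axis=1)
    post = course.values.iloc[:, course.birth_index:].mean(axis=1)
    return (post / pre).rename("perinatal_ratio")


def assign_primate_groups(
    ddp_m,
    dip_m,
    human_course: ExpressionTimeCourse,
    macaque_course: ExpressionTimeCourse | None = None,
    human_map: HomologMap | None = None,
    macaque_map: HomologMap | None = None,
) -> dict:
    """Filter DDP-M / DIP-M by the primate perinatal ratio.

    DDP-M genes whose human homolog has R < 1 become DDP-MH; DIP-M
    genes with R > 1 become DIP-MH; analogously -MM with the macaque
    course.  R exactly 1 is excluded from both directions.  Unmapped
    genes are excluded and counted under ``n_unmapped``.
    """
    out = {"n_unmapped": 0}

    def _filter(genes, course, hmap, want_decreased):
        genes = pd.Index(genes)
        if hmap is not None:
            mapped = hmap.map_genes(genes)
            out["n_unmapped"] += len(genes) - len(mapped)
            lookup = mapped
        else:
            lookup = pd.Series(genes.to_numpy(), index=genes)
        ratio = perinatal_ratio(course)
        hom = lookup[lookup.isin(ratio.index)]
        out["n_unmapped"] += len(lookup) - len(hom)
        r = ratio[hom.to_numpy()].to_numpy()
        keep = r < 1.0 if want_decreased else r > 1.0
        return pd.Index(hom.index[keep])

    out["ddp_mh"] = _filter(ddp_m, human_course, human_map, True)
    out["dip_mh"] = _filter(dip_m, human_course, human_map, False)
    if macaque_course is not None:
        out["ddp_mm"] = _filter(ddp_m, macaque_course, macaque_map, True)
        out["dip_mm"] = _filter(dip_m, macaque_course, macaque_map, False)
    return out


# --------------------------------------------------------------------------
# dataset-level comparisons


def proteome_similarity(
    frame_a: pd.DataFrame, frame_b: pd.DataFrame, mode: str = "pearson_lfq"
) -> pd.DataFrame:
    """Pairwise column correlations between two gene-indexed frames.

    ``pearson_lfq`` correlates raw abundance columns (stage-mean LFQ
    intensities); ``spearman_changes`` rank-correlates columns of
    per-protein log fold changes.  Frames are joined on their shared
    gene index (supply homolog-mapped indexes for cross-species use).
    """
    shared = frame_a.index.intersection(frame_b.index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared genes")
    a = frame_a.loc[shared]
    b = frame_b.loc[shared]
    out = pd.DataFrame(index=a.columns, columns=b.columns, dtype=float)
    for ca in a.columns:
        for cb in b.columns:
            if mode == "pearson_lfq":
                out.loc[ca, cb] = stats.pearsonr(a[ca], b[cb]).statistic
            elif mode == "spearman_changes":
                out.loc[ca, cb] = stats.spearmanr(a[ca], b[cb]).statistic
            else:
                raise ValueError(f"unknown mode {mode!r}")
    return out


def dataset_overlap(set_a, set_b) -> dict:
    """|A n B| and the two directional fractions."""
    a, b = set(set_a), set(set_b)
    shared = a & b
    return {
        "n_shared": len(shared),
        "frac_a": len(shared) / len(a) if a else 0.0,
        "frac_b": len(shared) / len(b) if b else 0.0,
    }


def asd_comparison(
    groups: dict,
    background,
    dev_logratio: pd.Series,
    asd_table: pd.DataFrame,
    alpha: float = 0.05,
    risk_genes=None,
) -> dict:
    """Compare developmental change against an ASD case-control table.

    ``asd_table`` needs columns ``gene``, ``log2fc_asd`` and
    ``p_value``; ASD-DE genes are those with raw p below ``alpha`` (no
    multiplicity adjustment, by design of the comparison).  Returns per
    group the Fisher enrichment of ASD-DE genes against ``background``,
    the up/down split of the ASD change within the group's ASD-DE
    genes, the overall Spearman rho between developmental log-ratio and
    ASD log-ratio, and the intersection with an optional risk-gene
    list.
    """
    from .enrichment import fisher_enrichment

    for col in ("gene", "log2fc_asd", "p_value"):
        if col not in asd_table.columns:
            raise ValueError(f"ASD table is missing column {col!r}")
    asd = asd_table.set_index("gene")
    background = set(background) & set(asd.index)
    de_genes = set(asd.index[asd["p_value"] < alpha]) & background

    enr = fisher_enrichment(
        de_genes, {name: set(g) for name, g in groups.items()}, background
    )
    out = {"enrichment": enr, "groups": {}}
    for name, genes in groups.items():
        de_in = (set(genes) & de_genes)
        up = sum(asd.loc[g, "log2fc_asd"] > 0 for g in de_in)
        down = len(de_in) - up
        rec = {
            "n": len(set(genes) & background),
            "n_asd_de": len(de_in),
            "n_up": int(up),
            "n_down": int(down),
            "frac_down": down / len(de_in) if de_in else np.nan,
        }
        if risk_genes is not None:
            rec["risk_overlap"] = len(set(genes) & set(risk_genes))
        out["groups"][name] = rec

    shared = dev_logratio.index.intersection(asd.index)
    rho = stats.spearmanr(
        dev_logratio[shared], asd.loc[shared, "log2fc_asd"]
    ).statistic
    out["rho_dev_vs_asd"] = float(rho)
    out["n_rho"] = len(shared)
    if risk_genes is not None:
        union = set().union(*[set(g) for g in groups.values()])
        out["risk_overlap_total"] = len(union & set(risk_genes))
    return out
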