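"""Differential expression across developmental stages.

A protein is differentially expressed (DE) when (1) its
Benjamini-Hochberg adjusted one-way ANOVA p-value is below 0.05 and
(2) its max fold change -- the ratio of the highest to the lowest stage
mean -- exceeds 1.5.  DE proteins in the decreasing trajectory cluster
are the developmentally decreased postsynaptic proteins (DDP), those in
the increasing cluster the developmentally increased ones (DIP); DE
proteins in intermediate (flat) clusters are counted but unlabelled.

The ANOVA defaults to Welch's unequal-variance form (the default of
R's ``oneway.test``); the classical equal-variance form and a log2
intensity scale are available as switches since either choice is
defensible for LFQ data.  For the two-replicate marmoset late stages no
test is attempted: proteins with a >2-fold change of mean abundance
between two ages are flagged Late DDP / Late DIP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quant import QuantTable

_MIN_P = np.nextafter(0.0, 1.0)


def welch_anova(values: np.ndarray, group_sizes: list[int]) -> np.ndarray:
    """Vectorized Welch one-way ANOVA over the rows of ``values``.

    ``values`` has one column per observation, grouped contiguously with
    ``group_sizes`` columns per group.  Returns one p-value per row.
    Degenerate rows (zero variance in every group) give p = 1 when all
    group means coincide and the smallest positive float otherwise.
    """
    values = np.asarray(values, dtype=float)
    k = len(group_sizes)
    if k < 2:
        raise ValueError("need at least two groups")
    if any(n < 2 for n in group_sizes):
        raise ValueError("need at least two replicates per group")
    edges = np.concatenate([[0], np.cumsum(group_sizes)])
    means = np.stack(
        [values[:, edges[j]:edges[j + 1]].mean(axis=1) for j in range(k)], axis=1
    )
    var = np.stack(
        [values[:, edges[j]:edges[j + 1]].var(axis=1, ddof=1) for j in range(k)],
        axis=1,
    )
    n = np.asarray(group_sizes, dtype=float)

    all_zero_var = (var == 0).all(axis=1)
    equal_means = np.ptp(means, axis=1) == 0
    # guard zero variances so the Welch weights stay finite
    var_safe = np.where(var > 0, var, _MIN_P)

    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        w = n / var_safe
        W = w.sum(axis=1)
        grand = (w * means).sum(axis=1) / W
        A = (w * (means - grand[:, None]) ** 2).sum(axis=1) / (k - 1)
        frac = ((1.0 - w / W[:, None]) ** 2 / (n - 1.0)).sum(axis=1)
        B = 1.0 + 2.0 * (k - 2) / (k * k - 1.0) * frac
        F = A / B
        df2 = (k * k - 1.0) / (3.0 * frac)
    p = stats.f.sf(F, k - 1, df2)
    p = np.where(equal_means, 1.0, p)
    p = np.where(all_zero_var & ~equal_means, _MIN_P, p)
    return np.clip(p, _MIN_P, 1.0)


def classic_anova(values: np.ndarray, group_sizes: list[int]) -> np.ndarray:
    """Equal-variance one-way ANOVA (row-wise), via scipy."""
    edges = np.concatenate([[0], np.cumsum(group_sizes)])
    groups = [values[:, edges[j]:edges[j + 1]] for j in range(len(group_sizes))]
    with np.errstate(divide="ignore", invalid="ignore"):
        p = stats.f_oneway(*groups, axis=1).pvalue
    p = np.asarray(p, dtype=float)
    equal = np.ptp(
        np.stack([g.mean(axis=1) for g in groups], axis=1), axis=1
    ) == 0
    p = np.where(np.isnan(p) | equal, 1.0, p)
    return np.clip(p, _MIN_P, 1.0)


def anova_per_protein(
    table: QuantTable, welch: bool = True, on_log: bool = False
) -> pd.Series:
    """One-way ANOVA p-value per protein, intensities grouped by stage."""
    stages = table.stage_order
    if len(stages) < 2:
        raise ValueError("need at least two stages")
    cols, sizes = [], []
    for s in stages:
        cc = table.stage_samples(s)
        cols.extend(cc)
        sizes.append(len(cc))
    mat = table.intensities[cols].to_numpy()
    if on_log:
        mat = np.log2(np.where(mat > 0, mat, np.nan))
    p = welch_anova(mat, sizes) if welch else classic_anova(mat, sizes)
    return pd.Series(p, index=table.intensities.index, name="p_anova")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def max_fold_change(stage_means: pd.DataFrame) -> pd.Series:
    """max(stage means) / min(stage means), direction-free, >= 1."""
    means = stage_means.to_numpy(dtype=float)
    if (means <= 0).any():
        raise ValueError("stage means must be positive")
    fc = means.max(axis=1) / means.min(axis=1)
    return pd.Series(fc, index=stage_means.index, name="max_fc")


@dataclass
class DEResult:
    table: pd.DataFrame  # per protein: p, q, max_fc, de, cluster, group

    @property
    def de_proteins(self) -> pd.Index:
        return self.table.index[self.table["de"]]

    def group_members(self, group: str) -> pd.Index:
        return self.table.index[self.table["group"] == group]

    @property
    def n_de(self) -> int:
        return int(self.table["de"].sum())


def call_de(
    pvalues: pd.Series,
    fold_changes: pd.Series,
    clusters: pd.Series,
    q_alpha: float = 0.05,
    fc_min: float = 1.5,
) -> DEResult:
    """DE flag plus DDP/DIP labels from cluster membership.

    ``clusters`` uses the trend-ordered convention of
    :func:`~psdremodel.clustering.kmeans_trajectories`: cluster 1 is the
    decreasing trajectory and the highest cluster id the increasing
    one.  DE proteins there become DDP and DIP respectively; DE
    proteins in intermediate clusters stay unlabelled (``group`` "").
    """
    if not pvalues.index.equals(fold_changes.index):
        raise ValueError("p-value and fold-change indexes differ")
    missing = pvalues.index.difference(clusters.index)
    if len(missing):
        raise ValueError(f"proteins missing a cluster label: {list(missing[:5])}")
    clusters = clusters.reindex(pvalues.index)
    q = pd.Series(bh_adjust(pvalues.to_numpy()), index=pvalues.index, name="q")
    de = (q < q_alpha) & (fold_changes > fc_min)
    k = int(clusters.max())
    group = pd.Series("", index=pvalues.index, dtype=object)
    group[de & (clusters == 1)] = "DDP"
    group[de & (clusters == k)] = "DIP"
    table = pd.DataFrame(
        {
            "p_anova": pvalues,
            "q": q,
            "max_fc": fold_changes,
            "de": de,
            "cluster": clusters,
            "group": group,
        }
    )
    return DEResult(table)


def late_de(
    table: QuantTable,
    stage_a: str = "2M",
    stage_b: str = "24M",
    fold: float = 2.0,
) -> pd.DataFrame:
    """Two-timepoint fold-change rule for small-n late-stage data.

    No significance test is attempted (n = 2 per age): proteins whose
    mean-abundance ratio stage_b/stage_a falls below 1/fold are Late
    DDP, above ``fold`` Late DIP (strict inequalities; a ratio exactly
    at the boundary is neither).
    """
    for s in (stage_a, stage_b):
        if s not in table.stage_order:
            raise ValueError(f"stage {s!r} not present in the table")
    mat = table.intensities
    mean_a = mat[table.stage_samples(stage_a)].mean(axis=1)
    mean_b = mat[table.stage_samples(stage_b)].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = mean_b / mean_a
    group = pd.Series("", index=mat.index, dtype=object)
    group[ratio < 1.0 / fold] = "Late DDP"
    group[ratio > fold] = "Late DIP"
    return pd.DataFrame(
        {"mean_a": mean_a, "mean_b": mean_b, "ratio": ratio, "late_group": group}
    )
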