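"""First-order turnover kinetics: why protein change lags the mRNA step.

The PSD proteins whose developmental change tracks transcription have
half-lives of roughly a week, so a step change in mRNA abundance takes
days to weeks to propagate to the protein pool.  The minimal model is
first-order synthesis-degradation,

    dP/dt = k_s * m(t) - k_d * P,     k_d = ln 2 / t_half,

whose response to an instantaneous fold-change step in m at t0 is the
closed-form relaxation

    P(t) = P_inf + (P0 - P_inf) * exp(-k_d * (t - t0)),

normalized so P0 = 1 at the pre-step steady state and P_inf equals the
mRNA fold change.  The half-time of the transition equals the protein
half-life, and the time to traverse a fraction f of the change is
t_half * log2(1 / (1 - f)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class KineticModel:
    """First-order turnover with half-life in days."""

    half_life_days: float

    def __post_init__(self) -> None:
        if self.half_life_days <= 0:
            raise ValueError("half-life must be positive")

    @property
    def k_d(self) -> float:
        """Degradation rate constant, per day."""
        return float(np.log(2.0) / self.half_life_days)


def read_halflife_table(path) -> pd.Series:
    frame = pd.read_csv(path, sep="\t")
    table = pd.Series(
        frame["half_life_days"].to_numpy(), index=frame["gene"], name="half_life_days"
    )
    if (table <= 0).any():
        raise ValueError("half-lives must be positive")
    return table


def median_half_life(genes, table: pd.Series):
    """Median half-life over mapped genes; returns (median, n, n_unmapped).

    The median uses the mid-mean convention for even counts.
    """
    genes = pd.Index(genes)
    shared = genes.intersection(table.index)
    if len(shared) == 0:
        raise ValueError("no genes overlap the half-life table")
    return float(table[shared].median()), len(shared), len(genes) - len(shared)


def simulate_protein_lag(
    model: KineticModel,
    t0: float = 0.0,
    fold: float = 2.0,
    horizon: float = 100.0,
    n_points: int = 1001,
) -> pd.DataFrame:
    """Closed-form protein trajectory after an mRNA fold-change step.

    Normalized to the pre-step steady state (P = 1 for t < t0); the new
    steady state is the mRNA fold change.
    """
    if fold <= 0:
        raise ValueError("fold must be positive")
    t = np.linspace(0.0, horizon, n_points)
    p = np.where(
        t < t0, 1.0, fold + (1.0 - fold) * np.exp(-model.k_d * (t - t0))
    )
    return pd.DataFrame({"t_days": t, "protein": p})


def lag_to_fraction(model: KineticModel, fraction: float) -> float:
    """Days for the protein to traverse ``fraction`` of its total change."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    return float(model.half_life_days * np.log2(1.0 / (1.0 - fraction)))
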