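"""Gene-set enrichment by Fisher's exact test, and reference overlaps.

A local stand-in for web enrichment services: a query gene list is
tested against each set of a GMT-style collection with the one-sided
(enrichment) Fisher exact test on the 2x2 table

    a = |query & set|    b = |query \\ set|
    c = |set \\ query|    d = rest of the background,

with Benjamini-Hochberg adjustment across sets.  Odds ratios are
reported with the Haldane (+0.5) correction for display only; p-values
always come from the exact hypergeometric tail.
"""

from __future__ import annotations

import warnings

import pandas as pd
from scipy import stats

from .de import bh_adjust


def read_gmt(path) -> dict[str, set]:
    """Read a GMT file: name <tab> description <tab> genes..."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_gmt(collection: dict, path, description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name in sorted(collection):
            genes = "\t".join(sorted(collection[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


def fisher_test_2x2(a: int, b: int, c: int, d: int, alternative: str = "greater"):
    """Exact Fisher p and sample odds ratio for one table.

    The odds ratio is ad/bc; the Haldane +0.5 correction is applied
    only when a cell is zero, and only to the reported ratio -- the
    p-value always comes from the exact conditional distribution.
    """
    p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative).pvalue
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return float(p), float(odds)


def fisher_enrichment(
    query,
    collection: dict,
    background,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Fisher enrichment of ``query`` in each set, BH across sets.

    Query genes outside the background are dropped (with a warning);
    set members outside the background are ignored for the table.
    Returns a frame indexed by set name with the 2x2 cells, odds ratio,
    raw p and BH q, sorted by p.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    query = set(query)
    outside = query - background
    if outside:
        warnings.warn(f"{len(outside)} query genes outside the background; dropped")
        query &= background
    rows = []
    for name in sorted(collection):
        members = set(collection[name]) & background
        a = len(query & members)
        b = len(query - members)
        c = len(members - query)
        d = len(background) - a - b - c
        p, odds = fisher_test_2x2(a, b, c, d, alternative)
        rows.append((name, a, b, c, d, odds, p))
    frame = pd.DataFrame(
        rows, columns=["set", "a", "b", "c", "d", "odds_ratio", "p"]
    ).set_index("set")
    frame["q"] = bh_adjust(frame["p"].to_numpy())
    return frame.sort_values("p")


def reference_overlap_profile(groups: dict, references: dict) -> dict:
    """Overlap of each group with each reference PSD list.

    Returns ``counts`` and ``fractions`` (group x reference frames,
    fractions of the group found in the reference) plus a per-group
    ``in_any`` summary: the fraction of group members present in at
    least one reference.
    """
    counts = pd.DataFrame(index=sorted(groups), columns=sorted(references), dtype=int)
    fracs = pd.DataFrame(index=sorted(groups), columns=sorted(references), dtype=float)
    union = set().union(*references.values()) if references else set()
    in_any = {}
    for g in sorted(groups):
        gset = set(groups[g])
        for r in sorted(references):
            n = len(gset & set(references[r]))
            counts.loc[g, r] = n
            fracs.loc[g, r] = n / len(gset) if gset else 0.0
        in_any[g] = len(gset & union) / len(gset) if gset else 0.0
    return {"counts": counts, "fractions": fracs, "in_any": pd.Series(in_any)}
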