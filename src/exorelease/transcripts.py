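"""RNA-count filtering, the low-expression minimum, and transporter screening.

Gene counts are quality-filtered (all-zero genes, then genes with <=10
counts in more than 90% of samples), a low-expression minimum (LEM) is set
at the 25th linear-interpolation percentile of per-gene mean counts, and
annotated transporter genes are classified by the nested criteria: above
the LEM; additionally differentially expressed (Q < 0.01 in an externally
produced DE table); additionally carrying a stationary-phase log2 fold
change > 1. The DE model itself is an input, not recomputed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


def filter_genes(counts: pd.DataFrame) -> pd.DataFrame:
    """Remove all-zero genes, then genes with counts <=10 in >90% of samples.

    ``counts`` is genes x samples. The 90% rule is strict: a gene low in
    exactly 90% of samples is kept. Idempotent.
    """
    X = counts.to_numpy()
    keep = ~(X == 0).all(axis=1)
    out = counts.loc[keep]
    frac_low = (out.to_numpy() <= 10).mean(axis=1)
    return out.loc[frac_low <= 0.9]


@dataclass
class LEMResult:
    """Low-expression minimum and per-gene expression flags.

    ``lem_count`` is the 25th percentile (linear interpolation) of per-gene
    mean counts; a gene is above the LEM iff its mean count is strictly
    greater.
    """

    lem_count: float
    gene_means: pd.Series
    above_lem: pd.Series

    @property
    def n_above(self) -> int:
        return int(self.above_lem.sum())


def compute_lem(counts: pd.DataFrame, quantile: float = 0.25) -> LEMResult:
    """Low-expression minimum from the per-gene mean-count distribution."""
    if len(counts) < 4:
        raise ValueError("need at least 4 genes to place a quartile threshold")
    means = counts.mean(axis=1)
    lem = float(np.quantile(means.to_numpy(), quantile))  # linear interpolation
    above = means > lem
    return LEMResult(lem_count=lem, gene_means=means, above_lem=above)


@dataclass
class TransporterClassification:
    """Nested transporter counts: total >= above_lem >= de >= de_lfc."""

    total: int
    above_lem: int
    de: int                 # above LEM and Q < 0.01
    de_lfc: int             # additionally some stationary LFC > 1
    below_lem: int
    ids: dict[str, list]    # category -> gene ids

    def __post_init__(self) -> None:
        ok = (
            self.total >= self.above_lem >= self.de >= self.de_lfc
            and self.above_lem + self.below_lem == self.total
        )
        if not ok:  # defensive: the constructor below can never violate this
            raise ValueError("transporter counts violate nesting invariants")

    def as_row(self) -> dict[str, int]:
        return {
            "total": self.total,
            "above_lem": self.above_lem,
            "de": self.de,
            "de_lfc": self.de_lfc,
            "below_lem": self.below_lem,
        }


def classify_transporters(
    lem: LEMResult,
    de: pd.DataFrame,
    transporter_ids,
    q_max: float = 0.01,
    lfc_min: float = 1.0,
) -> TransporterClassification:
    """Nested classification of transporter genes (expression, DE, LFC).

    ``de`` is indexed by gene id with a ``Q`` column and one ``LFC_*``
    column per stationary time point. Transporter ids absent from the
    count table are warned about and dropped; above-LEM transporters with
    no DE entry are counted as not differentially expressed.
    """
    ids = list(dict.fromkeys(transporter_ids))
    known = [i for i in ids if i in lem.above_lem.index]
    missing = [i for i in ids if i not in lem.above_lem.index]
    if missing:
        warnings.warn(
            f"{len(missing)} transporter ids absent from the count table; dropped",
            stacklevel=2,
        )
    above = [i for i in known if lem.above_lem[i]]
    lfc_cols = [c for c in de.columns if c.startswith("LFC")]

    de_ids, de_lfc_ids = [], []
    for i in above:
        if i not in de.index:
            warnings.warn(f"no DE entry for above-LEM transporter {i!r}; counted as not-DE",
                          stacklevel=2)
            continue
        if de.loc[i, "Q"] < q_max:
            de_ids.append(i)
            if (de.loc[i, lfc_cols].to_numpy(dtype=float) > lfc_min).any():
                de_lfc_ids.append(i)
    below = [i for i in known if not lem.above_lem[i]]
    return TransporterClassification(
        total=len(known),
        above_lem=len(above),
        de=len(de_ids),
        de_lfc=len(de_lfc_ids),
        below_lem=len(below),
        ids={
            "above_lem": above,
            "de": de_ids,
            "de_lfc": de_lfc_ids,
            "below_lem": below,
        },
    )
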