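"""Cross-strain partitioning of released features and identification summaries.

Released-feature id sets from three strains are partitioned into the seven
disjoint regions of a three-set Venn diagram (strain-unique, each
pairwise-only overlap, and the triple overlap). Feature identity across
strains is the aligned-table feature id; features from different
polarity/ionization modes are never merged.
"""

from __future__ import annotations

import decimal
import warnings
from dataclasses import dataclass
from itertools import combinations


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round-half-up (0.25 -> 0.3 at 1 digit), matching printed percentages."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass
class VennPartition:
    """Disjoint regions of a k-set partition of released feature ids.

    ``unique`` maps strain -> ids found only in that strain; ``pairwise``
    maps frozenset({a, b}) -> ids in exactly those two strains; ``triple``
    holds ids common to all strains (for k=3; in general, the full
    intersection).
    """

    unique: dict[str, set]
    pairwise: dict[frozenset, set]
    triple: set

    @property
    def strains(self) -> list[str]:
        return list(self.unique)

    def per_strain_total(self, strain: str) -> int:
        n = len(self.unique[strain]) + len(self.triple)
        for pair, ids in self.pairwise.items():
            if strain in pair:
                n += len(ids)
        return n

    @property
    def grand_total(self) -> int:
        return (
            sum(len(v) for v in self.unique.values())
            + sum(len(v) for v in self.pairwise.values())
            + len(self.triple)
        )

    def region_counts(self) -> dict[str, int]:
        out = {f"unique_{s}": len(ids) for s, ids in self.unique.items()}
        out.update(
            {"pair_" + "_".join(sorted(p)): len(ids) for p, ids in self.pairwise.items()}
        )
        out["all"] = len(self.triple)
        return out


def venn_partition(released: dict[str, set]) -> VennPartition:
    """Partition per-strain released-id sets into disjoint Venn regions.

    Exact set algebra; written for the three-strain design but correct for
    any number of sets >= 2 (``triple`` is then the full intersection and
    ``pairwise`` the ids in exactly two sets).
    """
    strains = list(released)
    sets = {s: set(ids) for s, ids in released.items()}
    membership: dict[str, frozenset] = {}
    for s, ids in sets.items():
        for i in ids:
            membership[i] = membership.get(i, frozenset()) | {s}
    unique = {s: {i for i, m in membership.items() if m == frozenset({s})} for s in strains}
    pairwise = {
        frozenset(p): {i for i, m in membership.items() if m == frozenset(p)}
        for p in combinations(strains, 2)
    }
    triple = {i for i, m in membership.items() if m == frozenset(strains)}
    return VennPartition(unique=unique, pairwise=pairwise, triple=triple)


def shared_fraction(p: VennPartition) -> dict[str, float]:
    """Headline fractions of a partition, as printed percentages.

    - ``shared_ge2``: features in at least two strains (pairwise + triple).
    - ``shared_ge2_pct``: 100 * shared_ge2 / sum of strain-unique counts
      (the denominator that reproduces the reported ~16.9%).
    - ``triple_of_shared_pct``: 100 * triple / shared_ge2.
    - ``unique_pct_<strain>``: 100 * unique / grand total of distinct features.
    Division by zero yields NaN, never an exception.
    """
    shared_ge2 = sum(len(v) for v in p.pairwise.values()) + len(p.triple)
    uniques = sum(len(v) for v in p.unique.values())
    grand = p.grand_total
    out: dict[str, float] = {"shared_ge2": float(shared_ge2), "grand_total": float(grand)}
    out["shared_ge2_pct"] = (
        round_half_up(100.0 * shared_ge2 / uniques) if uniques else float("nan")
    )
    out["triple_of_shared_pct"] = (
        round_half_up(100.0 * len(p.triple) / shared_ge2) if shared_ge2 else float("nan")
    )
    for s in p.strains:
        out[f"unique_pct_{s}"] = (
            round_half_up(100.0 * len(p.unique[s]) / grand) if grand else float("nan")
        )
    return out


@dataclass
class IdentificationSummary:
    """MSI identification-level breakdown of released features.

    MSI level 1 = identified against an authentic standard, level 2 =
    putative MS/MS match, level 3 = compound class only; everything else is
    unidentified. The identified fraction counts levels 1-2 only.
    """

    levels: dict[str, object]  # feature id -> 1 | 2 | 3 | "unidentified"
    counts: dict[object, int]
    identified_pct: float

    @property
    def total(self) -> int:
        return len(self.levels)


def identification_summary(released_ids, annotations: dict[str, int]) -> IdentificationSummary:
    """Attach MSI levels to released ids and compute the identified fraction."""
    released = list(released_ids)
    known = set(released)
    extra = [i for i in annotations if i not in known]
    if extra:
        warnings.warn(
            f"annotations for {len(extra)} unknown feature ids ignored", stacklevel=2
        )
    levels = {}
    for i in released:
        lv = annotations.get(i)
        levels[i] = lv if lv in (1, 2, 3) else "unidentified"
    counts = {k: 0 for k in (1, 2, 3, "unidentified")}
    for lv in levels.values():
        counts[lv] += 1
    n_ident = counts[1] + counts[2]
    pct = round_half_up(100.0 * n_ident / len(released)) if released else float("nan")
    return IdentificationSummary(levels=levels, counts=counts, identified_pct=pct)
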