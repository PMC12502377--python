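"""Set-overlap statistics between systems at any taxonomic rank.

Three complementary views of how much two or more formularies share:

* **directional overlap** — ``100 * |A ∩ B| / |A|``, the percentage of
  system A's taxa also used by system B.  Asymmetric by construction
  ("69.2% of the herbs used in Kampo overlap with those in TCM" is a
  statement about Kampo's herb list, not TCM's).
* **Jaccard** — ``100 * |A ∩ B| / |A ∪ B|``, the symmetric companion.
* **multiway shared fraction** — intersection over union across all
  systems at once.  The denominator choice (union) is a package
  convention; raw intersection and union counts are always reported so
  any alternative denominator can be recomputed.

Venn region counts classify every taxon by the exact subset of systems
using it; the counts partition the union.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import AbstractSet, Iterable, Mapping

__all__ = [
    "directional_overlap",
    "jaccard",
    "multiway_counts",
    "multiway_shared",
    "venn_regions",
    "OverlapReport",
    "compare_systems",
]


def directional_overlap(a: AbstractSet, b: AbstractSet) -> float:
    """Percent of *a*'s members also present in *b* (``100·|A∩B|/|A|``)."""
    if not a:
        raise ValueError("directional overlap has an undefined denominator for an empty base set")
    return 100.0 * len(set(a) & set(b)) / len(a)


def jaccard(a: AbstractSet, b: AbstractSet) -> float:
    """Percent Jaccard similarity ``100·|A∩B|/|A∪B|``."""
    union = set(a) | set(b)
    if not union:
        raise ValueError("Jaccard undefined for two empty sets")
    return 100.0 * len(set(a) & set(b)) / len(union)


def multiway_counts(sets: Iterable[AbstractSet]) -> tuple[int, int]:
    """(intersection size, union size) over all given sets."""
    sets = [set(s) for s in sets]
    if len(sets) < 2:
        raise ValueError("multiway overlap requires at least 2 sets")
    inter = set.intersection(*sets)
    union = set.union(*sets)
    return len(inter), len(union)


def multiway_shared(sets: Iterable[AbstractSet]) -> float:
    """Percent of the union shared by every set (intersection / union)."""
    inter, union = multiway_counts(sets)
    if union == 0:
        raise ValueError("multiway shared fraction undefined: all sets empty")
    return 100.0 * inter / union


def venn_regions(sets: Mapping[str, AbstractSet]) -> dict[frozenset, int]:
    """Count taxa belonging to *exactly* each non-empty subset of systems.

    Returns a map keyed by ``frozenset`` of system labels; every
    non-empty subset gets a key (zero counts included), and the counts
    sum to the union size.
    """
    systems = sorted(sets)
    if len(systems) < 2:
        raise ValueError("venn regions require at least 2 systems")
    regions: dict[frozenset, int] = {
        frozenset(c): 0
        for r in range(1, len(systems) + 1)
        for c in combinations(systems, r)
    }
    union = set()
    for s in systems:
        union |= set(sets[s])
    for taxon in union:
        members = frozenset(s for s in systems if taxon in sets[s])
        regions[members] += 1
    return regions


@dataclass
class OverlapReport:
    """All overlap statistics for one rank in one bundle.

    Percentages are raw (unrounded) floats; rendering rounds half-up at
    report time only.
    """

    rank: str
    per_set_sizes: dict[str, int]
    directional: dict[tuple[str, str], float]  # (A, B) -> % of A in B
    jaccard: dict[frozenset, float]
    intersection_size: int
    union_size: int
    multiway_shared: float
    venn_regions: dict[frozenset, int]


def compare_systems(sets: Mapping[str, AbstractSet], rank: str = "species") -> OverlapReport:
    """Compute the full overlap report across ≥2 taxon sets."""
    systems = sorted(sets)
    if len(systems) < 2:
        raise ValueError("need at least 2 systems to compare")
    for s in systems:
        if not sets[s]:
            raise ValueError(f"system {s!r} has an empty taxon set at rank {rank!r}")
    directional = {
        (a, b): directional_overlap(sets[a], sets[b])
        for a in systems
        for b in systems
    }
    jac = {
        frozenset((a, b)): jaccard(sets[a], sets[b])
        for a, b in combinations(systems, 2)
    }
    inter, union = multiway_counts(sets.values())
    return OverlapReport(
        rank=rank,
        per_set_sizes={s: len(sets[s]) for s in systems},
        directional=directional,
        jaccard=jac,
        intersection_size=inter,
        union_size=union,
        multiway_shared=100.0 * inter / union,
        venn_regions=venn_regions(sets),
    )
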