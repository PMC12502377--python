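"""Per-system usage-frequency statistics.

Two denominators matter and are easy to confuse:

* **formulation frequency** (support) — the fraction of a system's
  formulations containing a herb, or containing at least one herb of a
  taxon.  "Fabaceae appears in 70% of TCM formulations" is this.
* **herb share** — the fraction of a system's *distinct herb list*
  belonging to a taxon.  "Lamiales constitutes 9.6% of the recorded
  herbs" is this.

Every support is an integer count over an integer denominator; raw
fractions are kept and rounding happens only at rendering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

from .model import Formulary, Taxonomy, rollup

__all__ = [
    "SupportTable",
    "herb_support",
    "taxon_formulation_frequency",
    "taxon_herb_share",
    "mean_formulation_size",
    "top_k",
]


@dataclass
class SupportTable:
    """Named counts over a fixed denominator.

    ``unit`` documents what the names are ("herb" or "family@...") and
    ``denominator_kind`` what the denominator counts (formulations for
    supports, distinct herbs for shares).
    """

    system: str
    unit: str
    denominator: int
    counts: dict[str, int]
    denominator_kind: str = "formulations"

    def support(self, name: str) -> float:
        """Fraction for *name*; absent names are 0 on query."""
        return self.counts.get(name, 0) / self.denominator

    @property
    def entries(self) -> dict[str, float]:
        return {name: c / self.denominator for name, c in self.counts.items()}

    def __iter__(self) -> Iterator[tuple[str, float]]:
        return iter(self.entries.items())

    def __len__(self) -> int:
        return len(self.counts)


def herb_support(formulary: Formulary) -> SupportTable:
    """Fraction of formulations containing each herb."""
    if formulary.n == 0:
        raise ValueError("herb support undefined for an empty formulary")
    return SupportTable(
        system=formulary.system,
        unit="herb",
        denominator=formulary.n,
        counts=dict(formulary.herb_counts()),
    )


def taxon_formulation_frequency(
    formulary: Formulary, rank: str, taxonomy: Taxonomy
) -> SupportTable:
    """Fraction of formulations containing ≥1 herb of each taxon at *rank*."""
    if formulary.n == 0:
        raise ValueError("taxon frequency undefined for an empty formulary")
    rolled = rollup(formulary, rank, taxonomy)
    counts: dict[str, int] = {}
    for taxa in rolled.per_formulation:
        for t in taxa:
            counts[t] = counts.get(t, 0) + 1
    return SupportTable(
        system=formulary.system,
        unit=f"taxon@{rank}",
        denominator=formulary.n,
        counts=counts,
    )


def taxon_herb_share(formulary: Formulary, rank: str, taxonomy: Taxonomy) -> SupportTable:
    """Fraction of the system's distinct herbs belonging to each taxon.

    The denominator is the distinct standardized herb list of the
    formulary (not the formulation count).
    """
    herbs = formulary.herb_set()
    if not herbs:
        raise ValueError("herb share undefined for an empty formulary")
    counts: dict[str, int] = {}
    for herb in herbs:
        rec = taxonomy.get(herb)
        value = rec.rank_value(rank) if rec is not None else ""
        if not value:
            from .model import RankValueError

            raise RankValueError(f"species without a {rank} value: {herb}")
        counts[value] = counts.get(value, 0) + 1
    return SupportTable(
        system=formulary.system,
        unit=f"taxon@{rank}",
        denominator=len(herbs),
        counts=counts,
        denominator_kind="distinct_herbs",
    )


def mean_formulation_size(formulary: Formulary) -> float:
    """Arithmetic mean number of herbs per formulation."""
    if formulary.n == 0:
        raise ValueError("mean size undefined for an empty formulary")
    return sum(f.size for f in formulary) / formulary.n


def top_k(table: SupportTable, k: int) -> list[tuple[str, float]]:
    """Top *k* entries, descending by support, ties broken by name."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(table.entries.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]
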