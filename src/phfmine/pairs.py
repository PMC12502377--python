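"""Herb-pair statistics and dependency mining.

A pair's **support** is the fraction of a system's formulations
containing both herbs.  The **co-occurrence score** of herb *a* on herb
*b* is the conditional frequency of *b* among formulations containing
*a* — the confidence of the directed rule *a → b*.  A score of 1 means
*a* never appears without *b*; a pair scoring 1 in both directions is a
*mutual dependency* (each herb guarantees the other).

Rule mining enumerates directed pairs passing a support threshold
(strict ``>`` — "combinations exceeding 5%") and a confidence threshold
(``≥ 0.8`` by default, with a strictness flag, since printed example
rules all have confidence 1 and satisfy either reading).

Pairs are unordered for support and directed for confidence; self-pairs
are excluded from mining; pairs never co-occurring are never
materialized (sparse contract) and are 0 on query.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import AbstractSet, Mapping

import numpy as np
import pandas as pd

from .model import Formulary

__all__ = [
    "PairStats",
    "Rule",
    "RuleSet",
    "pair_counts",
    "pair_support",
    "pair_stats",
    "cooccurrence_score",
    "score_matrix",
    "mine_rules",
    "qualifying_pairs",
    "CrossSystemPairReport",
    "cross_system_pairs",
]

Pair = tuple[str, str]


def _ordered(a: str, b: str) -> Pair:
    return (a, b) if a < b else (b, a)


def pair_counts(formulary: Formulary) -> Counter:
    """Co-occurrence counts for every unordered pair seen ≥1 time.

    Keys are ``(a, b)`` with ``a < b`` lexicographically.
    """
    counts: Counter = Counter()
    for f in formulary:
        for a, b in combinations(sorted(f.herbs), 2):
            counts[(a, b)] += 1
    return counts


def pair_support(formulary: Formulary) -> dict[Pair, float]:
    """Fraction of formulations containing both herbs of each pair."""
    if formulary.n == 0:
        raise ValueError("pair support undefined for an empty formulary")
    n = formulary.n
    return {p: c / n for p, c in pair_counts(formulary).items()}


@dataclass(frozen=True)
class PairStats:
    """Support and both directed confidences for one unordered pair.

    ``herb_a < herb_b`` lexicographically.  In count arithmetic,
    ``conf_a_to_b * support(a) == conf_b_to_a * support(b) == support``
    exactly (Bayes consistency).
    """

    herb_a: str
    herb_b: str
    support_count: int
    support: float
    conf_a_to_b: float
    conf_b_to_a: float


def pair_stats(formulary: Formulary) -> list[PairStats]:
    """Per-pair support and directed confidences, sparse over seen pairs."""
    n = formulary.n
    if n == 0:
        raise ValueError("pair statistics undefined for an empty formulary")
    herb_c = formulary.herb_counts()
    out = []
    for (a, b), c in sorted(pair_counts(formulary).items()):
        out.append(
            PairStats(
                herb_a=a,
                herb_b=b,
                support_count=c,
                support=c / n,
                conf_a_to_b=c / herb_c[a],
                conf_b_to_a=c / herb_c[b],
            )
        )
    return out


def cooccurrence_score(formulary: Formulary, a: str, b: str) -> float:
    """Conditional frequency of *b* among formulations containing *a*.

    ``score(a, a) = 1`` by convention.  Undefined (raises) when *a*
    never occurs.
    """
    count_a = formulary.herb_counts().get(a, 0)
    if count_a == 0:
        raise ValueError(f"co-occurrence score undefined: {a!r} has support 0")
    if a == b:
        return 1.0
    both = sum(1 for f in formulary if a in f.herbs and b in f.herbs)
    return both / count_a


def score_matrix(
    formulary: Formulary, herb_order: list[str] | None = None
) -> pd.DataFrame:
    """Square matrix of co-occurrence scores; row *i* is P(column | row).

    Row herb conditions, column herb is scored: entry ``(i, j)`` is the
    score of herb *i* on herb *j*.  The diagonal is 1 and the matrix is
    generally asymmetric.  This is the heatmap input.
    """
    herbs = herb_order if herb_order is not None else sorted(formulary.herb_set())
    if not herbs:
        raise ValueError("score matrix undefined for an empty formulary")
    idx = {h: i for i, h in enumerate(herbs)}
    m = np.zeros((formulary.n, len(herbs)), dtype=np.int64)
    for r, f in enumerate(formulary):
        for h in f.herbs:
            if h in idx:
                m[r, idx[h]] = 1
    co = m.T @ m  # co[i, j] = #formulations containing both i and j
    diag = np.diag(co).astype(float)
    if np.any(diag == 0):
        missing = [h for h, i in idx.items() if diag[i] == 0]
        raise ValueError(f"herbs with support 0 in score matrix: {missing}")
    scores = co / diag[:, None]
    np.fill_diagonal(scores, 1.0)
    return pd.DataFrame(scores, index=herbs, columns=herbs)


@dataclass(frozen=True)
class Rule:
    """A directed dependency: formulations with *antecedent* contain
    *consequent* with frequency *confidence*."""

    antecedent: str
    consequent: str
    support_count: int
    support: float
    confidence: float


@dataclass
class RuleSet:
    """Mined directed pair dependencies for one system."""

    system: str
    min_support: float
    min_conf: float
    conf_strict: bool
    n_formulations: int
    rules: list[Rule] = field(default_factory=list)
    #: unordered pairs with confidence exactly 1 in both directions
    mutual: list[Pair] = field(default_factory=list)

    @property
    def always_rules(self) -> list[Rule]:
        """Rules with confidence exactly 1 (antecedent never alone)."""
        return [r for r in self.rules if r.confidence == 1.0]

    def rule_pairs(self) -> set[Pair]:
        return {_ordered(r.antecedent, r.consequent) for r in self.rules}


def mine_rules(
    formulary: Formulary,
    min_support: float = 0.05,
    min_conf: float = 0.8,
    conf_strict: bool = False,
) -> RuleSet:
    """Mine directed pair rules passing both thresholds.

    Support is strict (``pair support > min_support``); confidence is
    ``≥ min_conf`` by default or ``>`` with ``conf_strict=True``.
    Confidence-1 rules are the "always" dependencies; pairs whose both
    directions have confidence 1 are listed as mutual dependencies.
    """
    n = formulary.n
    if n == 0:
        raise ValueError("rule mining undefined for an empty formulary")
    herb_c = formulary.herb_counts()
    rules: list[Rule] = []
    conf1: dict[Pair, int] = {}
    for (a, b), c in sorted(pair_counts(formulary).items()):
        if c / n <= min_support:
            continue
        for ant, cons in ((a, b), (b, a)):
            conf = c / herb_c[ant]
            passes = conf > min_conf if conf_strict else conf >= min_conf
            if passes:
                rules.append(
                    Rule(
                        antecedent=ant,
                        consequent=cons,
                        support_count=c,
                        support=c / n,
                        confidence=conf,
                    )
                )
            if conf == 1.0:
                conf1[(a, b)] = conf1.get((a, b), 0) + 1
    mutual = sorted(p for p, k in conf1.items() if k == 2)
    return RuleSet(
        system=formulary.system,
        min_support=min_support,
        min_conf=min_conf,
        conf_strict=conf_strict,
        n_formulations=n,
        rules=rules,
        mutual=mutual,
    )


def qualifying_pairs(
    formulary: Formulary, min_support: float = 0.05
) -> set[Pair]:
    """Unordered pairs with support strictly above the threshold."""
    n = formulary.n
    return {p for p, c in pair_counts(formulary).items() if c / n > min_support}


@dataclass
class CrossSystemPairReport:
    """Comparison of qualifying pair sets across systems."""

    min_support: float
    per_system_counts: dict[str, int]
    shared_all: list[Pair]
    directional: dict[tuple[str, str], float]  # % of A's pairs also in B
    jaccard: dict[frozenset, float]


def cross_system_pairs(
    pair_sets: Mapping[str, AbstractSet[Pair]], min_support: float = 0.05
) -> CrossSystemPairReport:
    """Compare the qualifying pair sets of ≥2 systems.

    Reports the pairs common to all systems, plus pairwise directional
    overlaps and Jaccard similarities between systems' pair sets (both
    are given because shared-fraction statements leave the denominator
    ambiguous).
    """
    from .overlap import directional_overlap, jaccard

    systems = sorted(pair_sets)
    if len(systems) < 2:
        raise ValueError("cross-system comparison requires at least 2 systems")
    shared = set.intersection(*(set(pair_sets[s]) for s in systems))
    directional = {
        (a, b): directional_overlap(pair_sets[a], pair_sets[b])
        for a in systems
        for b in systems
        if pair_sets[a]
    }
    jac = {
        frozenset((a, b)): jaccard(pair_sets[a], pair_sets[b])
        for a, b in combinations(systems, 2)
        if pair_sets[a] or pair_sets[b]
    }
    return CrossSystemPairReport(
        min_support=min_support,
        per_system_counts={s: len(pair_sets[s]) for s in systems},
        shared_all=sorted(shared),
        directional=directional,
        jaccard=jac,
    )
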