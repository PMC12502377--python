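"""Independent brute-force oracles used to cross-check the library.

Everything here works on plain lists of herb sets and dictionaries, by
exhaustive enumeration, sharing no code with the implementation under
test.
"""

from __future__ import annotations

from itertools import combinations


def directional(a: set, b: set) -> float:
    return 100.0 * len(a & b) / len(a)


def jaccard(a: set, b: set) -> float:
    return 100.0 * len(a & b) / len(a | b)


def multiway(sets: list[set]) -> float:
    inter = set(sets[0])
    union = set()
    for s in sets:
        inter &= s
        union |= s
    return 100.0 * len(inter) / len(union)


def venn(named_sets: dict[str, set]) -> dict[frozenset, int]:
    union = set()
    for s in named_sets.values():
        union |= s
    out: dict[frozenset, int] = {}
    for x in union:
        key = frozenset(k for k, s in named_sets.items() if x in s)
        out[key] = out.get(key, 0) + 1
    return out


def herb_support(form_sets: list[set]) -> dict[str, float]:
    n = len(form_sets)
    herbs = set().union(*form_sets) if form_sets else set()
    return {h: sum(1 for f in form_sets if h in f) / n for h in herbs}


def mean_size(form_sets: list[set]) -> float:
    return sum(len(f) for f in form_sets) / len(form_sets)


def pair_support(form_sets: list[set]) -> dict[tuple, float]:
    n = len(form_sets)
    herbs = sorted(set().union(*form_sets))
    out = {}
    for a, b in combinations(herbs, 2):
        c = sum(1 for f in form_sets if a in f and b in f)
        if c:
            out[(a, b)] = c / n
    return out


def score(form_sets: list[set], a: str, b: str) -> float:
    if a == b:
        return 1.0
    na = sum(1 for f in form_sets if a in f)
    nab = sum(1 for f in form_sets if a in f and b in f)
    return nab / na


def mine(
    form_sets: list[set],
    min_support: float = 0.05,
    min_conf: float = 0.8,
    conf_strict: bool = False,
) -> set[tuple]:
    """All directed rules (antecedent, consequent) passing the thresholds."""
    n = len(form_sets)
    herbs = sorted(set().union(*form_sets))
    rules = set()
    for a in herbs:
        for b in herbs:
            if a == b:
                continue
            nab = sum(1 for f in form_sets if a in f and b in f)
            na = sum(1 for f in form_sets if a in f)
            if nab / n <= min_support or na == 0:
                continue
            conf = nab / na
            if (conf > min_conf) if conf_strict else (conf >= min_conf):
                rules.add((a, b))
    return rules


def mutual_pairs(form_sets: list[set], min_support: float = 0.05) -> set[tuple]:
    """Unordered pairs above the support threshold with confidence 1 both ways."""
    n = len(form_sets)
    herbs = sorted(set().union(*form_sets))
    out = set()
    for a, b in combinations(herbs, 2):
        nab = sum(1 for f in form_sets if a in f and b in f)
        na = sum(1 for f in form_sets if a in f)
        nb = sum(1 for f in form_sets if b in f)
        if nab / n > min_support and nab == na == nb:
            out.add((a, b))
    return out


def taxon_frequency(form_sets: list[set], lineage: dict[str, str]) -> dict[str, float]:
    n = len(form_sets)
    taxa = set(lineage[h] for f in form_sets for h in f)
    return {
        t: sum(1 for f in form_sets if any(lineage[h] == t for h in f)) / n
        for t in taxa
    }


def herb_share(form_sets: list[set], lineage: dict[str, str]) -> dict[str, float]:
    herbs = set().union(*form_sets)
    taxa = {lineage[h] for h in herbs}
    return {t: sum(1 for h in herbs if lineage[h] == t) / len(herbs) for t in taxa}
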