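"""Rendering and serialization of analysis outputs.

Raw fractions are kept throughout the library; this module is the only
place percentages are rounded (half-up, one decimal by default) for
display, mirroring how printed tables round.
"""

from __future__ import annotations

import hashlib
import json
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping

import pandas as pd

from .frequency import SupportTable, herb_support, top_k
from .model import Formulary
from .overlap import OverlapReport
from .pairs import CrossSystemPairReport, RuleSet, pair_stats

__all__ = [
    "percent",
    "support_table_frame",
    "write_support_table",
    "overlap_report_dict",
    "write_overlap_report",
    "venn_frame",
    "ruleset_frame",
    "write_ruleset",
    "pair_listing_frame",
    "cross_system_dict",
    "table1_frame",
    "write_manifest",
]


def percent(fraction: float, ndigits: int = 1) -> float:
    """Render a fraction as a percentage, rounded half-up.

    ``percent(0.200/0.600)`` → ``33.3``; banker's rounding is avoided
    because printed tables round halves up.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(fraction * 100.0)).quantize(q, rounding=ROUND_HALF_UP))


def support_table_frame(table: SupportTable) -> pd.DataFrame:
    rows = [
        {
            "name": name,
            "count": table.counts[name],
            "fraction": table.counts[name] / table.denominator,
            "percent": percent(table.counts[name] / table.denominator),
        }
        for name, _ in sorted(table.entries.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["name", "count", "fraction", "percent"])


def write_support_table(table: SupportTable, path: str | Path) -> None:
    support_table_frame(table).to_csv(path, sep="\t", index=False)


def overlap_report_dict(report: OverlapReport) -> dict:
    """JSON-ready view of an overlap report (percents rounded 1 d.p.)."""
    return {
        "rank": report.rank,
        "per_set_sizes": dict(report.per_set_sizes),
        "directional_percent": {
            f"{a}->{b}": percent(v / 100.0) for (a, b), v in sorted(report.directional.items())
        },
        "jaccard_percent": {
            "|".join(sorted(k)): percent(v / 100.0) for k, v in report.jaccard.items()
        },
        "intersection_size": report.intersection_size,
        "union_size": report.union_size,
        "multiway_shared_percent": percent(report.multiway_shared / 100.0),
        "venn_regions": {
            "+".join(sorted(k)): v for k, v in report.venn_regions.items()
        },
    }


def write_overlap_report(report: OverlapReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(overlap_report_dict(report), indent=1, sort_keys=True))


def venn_frame(report: OverlapReport) -> pd.DataFrame:
    """Venn region table: one binary membership mask column per system."""
    systems = sorted(report.per_set_sizes)
    rows = []
    for region, count in sorted(
        report.venn_regions.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
    ):
        row = {s: int(s in region) for s in systems}
        row["count"] = count
        rows.append(row)
    return pd.DataFrame(rows, columns=[*systems, "count"])


def ruleset_frame(rs: RuleSet) -> pd.DataFrame:
    mutual = {frozenset(p) for p in rs.mutual}
    rows = [
        {
            "antecedent": r.antecedent,
            "consequent": r.consequent,
            "support_count": r.support_count,
            "support": r.support,
            "confidence": r.confidence,
            "mutual_flag": int(frozenset((r.antecedent, r.consequent)) in mutual),
        }
        for r in sorted(rs.rules, key=lambda r: (-r.confidence, r.antecedent, r.consequent))
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "antecedent",
            "consequent",
            "support_count",
            "support",
            "confidence",
            "mutual_flag",
        ],
    )


def write_ruleset(rs: RuleSet, path: str | Path) -> None:
    ruleset_frame(rs).to_csv(path, sep="\t", index=False)


def pair_listing_frame(formulary: Formulary) -> pd.DataFrame:
    """Long-format pair listing: support and both directed scores."""
    rows = [
        {
            "herb_a": p.herb_a,
            "herb_b": p.herb_b,
            "support_count": p.support_count,
            "support": p.support,
            "score_a_on_b": p.conf_a_to_b,
            "score_b_on_a": p.conf_b_to_a,
        }
        for p in pair_stats(formulary)
    ]
    return pd.DataFrame(
        rows,
        columns=["herb_a", "herb_b", "support_count", "support", "score_a_on_b", "score_b_on_a"],
    )


def cross_system_dict(report: CrossSystemPairReport) -> dict:
    return {
        "min_support": report.min_support,
        "per_system_counts": dict(report.per_system_counts),
        "shared_all": [list(p) for p in report.shared_all],
        "directional_percent": {
            f"{a}->{b}": percent(v / 100.0) for (a, b), v in sorted(report.directional.items())
        },
        "jaccard_percent": {
            "|".join(sorted(k)): percent(v / 100.0) for k, v in report.jaccard.items()
        },
    }


def table1_frame(formularies: Mapping[str, Formulary], k: int = 5) -> pd.DataFrame:
    """Summary table of the top-k herbs and top-k herb pairs per system."""
    rows = []
    for system in sorted(formularies):
        fl = formularies[system]
        herbs = top_k(herb_support(fl), k)
        pairs = sorted(
            ((p.support, p.herb_a, p.herb_b) for p in pair_stats(fl)),
            key=lambda t: (-t[0], t[1], t[2]),
        )[:k]
        for i in range(max(len(herbs), len(pairs))):
            h = herbs[i] if i < len(herbs) else ("", float("nan"))
            p = pairs[i] if i < len(pairs) else (float("nan"), "", "")
            rows.append(
                {
                    "system": system,
                    "rank": i + 1,
                    "herb": h[0],
                    "herb_percent": percent(h[1]) if h[0] else "",
                    "pair_herb_1": p[1],
                    "pair_herb_2": p[2],
                    "pair_percent": percent(p[0]) if p[1] else "",
                }
            )
    return pd.DataFrame(rows)


def write_manifest(
    path: str | Path,
    inputs: Mapping[str, str | Path],
    config: Mapping,
) -> None:
    """Machine-readable run manifest: input hashes, config echo, version."""
    from . import __version__

    manifest = {
        "tool": "phfmine",
        "version": __version__,
        "inputs": {
            name: {
                "path": str(p),
                "sha256": hashlib.sha256(Path(p).read_bytes()).hexdigest(),
            }
            for name, p in inputs.items()
        },
        "config": dict(config),
    }
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True))
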