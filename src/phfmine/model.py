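"""Core data model: taxa, ingredients, formulations, formularies.

A *formulary* is the complete set of formulations belonging to one
traditional medical system (e.g. all 100 TCM classical prescriptions).
Each formulation holds a *set* of standardized herb species: a species
appearing twice in one recipe (different plant parts or preparations)
counts once, because every downstream statistic is a formulation-level
proportion.

Name standardization is a pure table lookup: a raw name resolves through
a synonym table onto an accepted species binomial carried by a taxonomy
table, after case-folding and whitespace normalization.  No fuzzy
matching and no live taxonomy-service queries are performed, so results
are reproducible from the two tables alone.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Mapping

import pandas as pd

__all__ = [
    "RANKS",
    "TaxonRecord",
    "Taxonomy",
    "SynonymTable",
    "Ingredient",
    "Formulation",
    "Formulary",
    "IngestionLog",
    "SchemaError",
    "RankValueError",
    "standardize_name",
    "ingest_formulation_table",
    "rollup",
    "Rollup",
    "read_formulation_table",
    "write_corpus_json",
    "read_corpus_json",
]

#: Supported taxonomic ranks, most specific first.
RANKS = ("species", "genus", "family", "order", "class", "phylum", "kingdom")

#: Kingdoms treated as botanical by default.  The corpora analysed here
#: are plant formularies; algae appear in small numbers in the source
#: pharmacopoeias and are retained.
DEFAULT_BOTANICAL_KINGDOMS = frozenset({"Plantae", "Algae"})


class SchemaError(ValueError):
    """An input table violates the documented column contract."""


class RankValueError(ValueError):
    """A species lacks a lineage value at a requested rank."""


def _norm(name: str) -> str:
    """Case-fold and collapse internal whitespace for name matching."""
    return " ".join(str(name).split()).casefold()


@dataclass(frozen=True)
class TaxonRecord:
    """An accepted species binomial with its ranked lineage.

    Rank fields may be empty above genus for unplaced taxa; analyses at
    a given rank refuse species with an empty value there rather than
    silently inventing a bucket.
    """

    accepted_name: str
    kingdom: str = ""
    phylum: str = ""
    class_: str = ""
    order: str = ""
    family: str = ""
    genus: str = ""
    synonyms: tuple[str, ...] = ()

    def rank_value(self, rank: str) -> str:
        if rank == "species":
            return self.accepted_name
        if rank == "class":
            return self.class_
        if rank not in RANKS:
            raise ValueError(f"unknown rank: {rank!r}")
        return getattr(self, rank)


class Taxonomy:
    """A lookup table of accepted species names and their lineages."""

    def __init__(self, records: Iterable[TaxonRecord]):
        self._records: dict[str, TaxonRecord] = {}
        self._index: dict[str, str] = {}  # normalized name -> accepted
        for rec in records:
            if rec.accepted_name in self._records:
                raise SchemaError(
                    f"duplicate accepted name in taxonomy: {rec.accepted_name!r}"
                )
            self._records[rec.accepted_name] = rec
            self._index[_norm(rec.accepted_name)] = rec.accepted_name

    def __contains__(self, name: str) -> bool:
        return name in self._records

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[TaxonRecord]:
        return iter(self._records.values())

    def get(self, accepted_name: str) -> TaxonRecord | None:
        return self._records.get(accepted_name)

    def resolve(self, raw: str) -> str | None:
        """Return the accepted name whose normalized form matches *raw*."""
        return self._index.get(_norm(raw))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Taxonomy":
        required = {"accepted_name"}
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(f"taxonomy table missing required column: {sorted(missing)[0]}")
        df = df.fillna("")
        recs = [
            TaxonRecord(
                accepted_name=str(r["accepted_name"]).strip(),
                kingdom=str(r.get("kingdom", "")).strip(),
                phylum=str(r.get("phylum", "")).strip(),
                class_=str(r.get("class", r.get("class_", ""))).strip(),
                order=str(r.get("order", "")).strip(),
                family=str(r.get("family", "")).strip(),
                genus=str(r.get("genus", "")).strip(),
            )
            for r in df.to_dict("records")
        ]
        return cls(recs)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Taxonomy":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype=str))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "accepted_name": r.accepted_name,
                "genus": r.genus,
                "family": r.family,
                "order": r.order,
                "class": r.class_,
                "phylum": r.phylum,
                "kingdom": r.kingdom,
            }
            for r in self
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


class SynonymTable:
    """Maps raw (source-text) names onto accepted species names.

    Every synonym maps to exactly one accepted name; matching is
    case-insensitive and whitespace-normalized.
    """

    def __init__(self, mapping: Mapping[str, str] | None = None):
        self._map: dict[str, str] = {}
        for raw, accepted in (mapping or {}).items():
            self.add(raw, accepted)

    def add(self, raw: str, accepted: str) -> None:
        key = _norm(raw)
        if key in self._map and self._map[key] != accepted:
            raise SchemaError(
                f"synonym {raw!r} maps to both {self._map[key]!r} and {accepted!r}"
            )
        self._map[key] = accepted

    def resolve(self, raw: str) -> str | None:
        return self._map.get(_norm(raw))

    def __len__(self) -> int:
        return len(self._map)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SynonymTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        for col in ("raw_name", "accepted_name"):
            if col not in df.columns:
                raise SchemaError(f"synonym table missing required column: {col}")
        tbl = cls()
        for r in df.itertuples(index=False):
            tbl.add(str(r.raw_name), str(r.accepted_name))
        return tbl

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self._map.items()), columns=["raw_name", "accepted_name"]
        ).to_csv(path, sep="\t", index=False)


IngredientStatus = Literal["resolved", "unresolved", "non_botanical"]


@dataclass(frozen=True)
class Ingredient:
    """One raw ingredient occurrence and its standardization outcome.

    The original raw name is always preserved so every entry stays
    traceable to its source text.
    """

    raw_name: str
    accepted_name: str = ""
    status: IngredientStatus = "unresolved"
    amount: float | None = None
    unit: str | None = None


@dataclass(frozen=True)
class Formulation:
    """One named remedy from one system: a set of standardized herbs."""

    formulation_id: str
    system: str
    name: str
    herbs: frozenset[str]
    metadata: tuple[tuple[str, str], ...] = ()

    @property
    def size(self) -> int:
        return len(self.herbs)


@dataclass
class Formulary:
    """All formulations of one medical system."""

    system: str
    formulations: list[Formulation] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.formulations)

    def herb_set(self) -> frozenset[str]:
        out: set[str] = set()
        for f in self.formulations:
            out |= f.herbs
        return frozenset(out)

    def herb_counts(self) -> Counter:
        c: Counter = Counter()
        for f in self.formulations:
            c.update(f.herbs)
        return c

    def __iter__(self) -> Iterator[Formulation]:
        return iter(self.formulations)


@dataclass
class IngestionLog:
    """Counts and notes accumulated while ingesting a formulation table."""

    rows_read: int = 0
    resolved: int = 0
    unresolved: int = 0
    unresolved_kept: int = 0
    non_botanical: int = 0
    duplicates_collapsed: int = 0
    empty_formulations_dropped: int = 0
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "rows_read": self.rows_read,
            "resolved": self.resolved,
            "unresolved": self.unresolved,
            "unresolved_kept": self.unresolved_kept,
            "non_botanical": self.non_botanical,
            "duplicates_collapsed": self.duplicates_collapsed,
            "empty_formulations_dropped": self.empty_formulations_dropped,
            "notes": list(self.notes),
        }


def standardize_name(
    raw: str, synonyms: SynonymTable, taxonomy: Taxonomy
) -> Ingredient:
    """Resolve a raw ingredient name to an accepted species binomial.

    Resolution order: the raw name itself is an accepted name in the
    taxonomy table; otherwise it is a known synonym.  Matching is
    case-insensitive and whitespace-normalized.  A name matching neither
    table comes back with status ``unresolved`` — that is a data state,
    not an error.
    """
    raw = str(raw)
    accepted = taxonomy.resolve(raw)
    if accepted is None:
        accepted = synonyms.resolve(raw)
    if accepted is None:
        return Ingredient(raw_name=raw, status="unresolved")
    return Ingredient(raw_name=raw, accepted_name=accepted, status="resolved")


REQUIRED_COLUMNS = ("formulation_id", "system", "formulation_name", "ingredient_raw_name")


def read_formulation_table(path: str | Path) -> pd.DataFrame:
    """Read an ingredient-level formulation table (CSV/TSV/XLSX).

    The table is one row per formulation–ingredient pair with columns
    ``formulation_id, system, formulation_name, ingredient_raw_name``
    and optional ``amount, unit``.  An Excel workbook with the same
    column layout (the integrated formulation-list format) is read
    through the identical contract.
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        df = pd.read_excel(path, dtype=str)
    else:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        df = pd.read_csv(path, sep=sep, dtype=str)
    return df


def ingest_formulation_table(
    rows: pd.DataFrame,
    synonyms: SynonymTable,
    taxonomy: Taxonomy,
    botanical_kingdoms: Iterable[str] | None = None,
    allow_fungi: bool = False,
    unresolved_policy: Literal["strict", "keep"] = "strict",
    systems: Iterable[str] | None = None,
) -> tuple[dict[str, Formulary], IngestionLog]:
    """Standardize an ingredient-level table into per-system formularies.

    Parameters
    ----------
    rows
        Ingredient-level table; see :func:`read_formulation_table`.
    botanical_kingdoms
        Kingdoms admitted into the analysis (default Plantae + Algae).
        Ingredients resolving to species outside the whitelist are
        dropped with status ``non_botanical`` (e.g. honey).
    allow_fungi
        Admit Fungi as a whitelisted exception; each admitted fungal
        species is surfaced in the ingestion log, because formularies
        described as purely plant-based sometimes carry a medicinal
        fungus under a plant-style binomial.
    unresolved_policy
        ``strict`` drops unresolved raw names with a logged warning;
        ``keep`` retains the raw name as its own species with an empty
        lineage (excluded from rank rollups).
    systems
        Optional whitelist of system labels; rows with other labels
        raise :class:`SchemaError`.

    Returns
    -------
    (formularies, log)
        One :class:`Formulary` per system plus an :class:`IngestionLog`.
    """
    for col in REQUIRED_COLUMNS:
        if col not in rows.columns:
            raise SchemaError(f"missing required column: {col}")
    kingdoms = set(botanical_kingdoms) if botanical_kingdoms is not None else set(
        DEFAULT_BOTANICAL_KINGDOMS
    )
    if allow_fungi:
        kingdoms.add("Fungi")
    allowed_systems = set(systems) if systems is not None else None

    log = IngestionLog(rows_read=len(rows))

    dup_mask = rows.duplicated(subset=["formulation_id", "ingredient_raw_name"])
    n_dup = int(dup_mask.sum())
    if n_dup:
        log.duplicates_collapsed = n_dup
        log.notes.append(f"collapsed {n_dup} duplicate (formulation_id, raw_name) rows")
        rows = rows[~dup_mask]

    # formulation_id -> (system, name, set of herbs); insertion ordered
    pending: dict[str, tuple[str, str, set[str]]] = {}
    fungi_seen: set[str] = set()

    for r in rows.itertuples(index=False):
        fid = str(r.formulation_id)
        system = str(r.system)
        fname = str(r.formulation_name)
        if allowed_systems is not None and system not in allowed_systems:
            raise SchemaError(f"unknown system label: {system!r}")
        if fid not in pending:
            pending[fid] = (system, fname, set())
        ing = standardize_name(str(r.ingredient_raw_name), synonyms, taxonomy)
        if ing.status == "unresolved":
            log.unresolved += 1
            if unresolved_policy == "keep":
                log.unresolved_kept += 1
                pending[fid][2].add(ing.raw_name)
            continue
        rec = taxonomy.get(ing.accepted_name)
        kingdom = rec.kingdom if rec is not None else ""
        if rec is not None and kingdom and kingdom not in kingdoms:
            log.non_botanical += 1
            continue
        if kingdom == "Fungi" and ing.accepted_name not in fungi_seen:
            fungi_seen.add(ing.accepted_name)
            log.notes.append(
                f"fungal species admitted by whitelist exception: {ing.accepted_name}"
            )
        log.resolved += 1
        pending[fid][2].add(ing.accepted_name)

    formularies: dict[str, Formulary] = {}
    for fid, (system, fname, herbs) in pending.items():
        if not herbs:
            log.empty_formulations_dropped += 1
            continue
        formularies.setdefault(system, Formulary(system=system)).formulations.append(
            Formulation(
                formulation_id=fid, system=system, name=fname, herbs=frozenset(herbs)
            )
        )
    return formularies, log


@dataclass(frozen=True)
class Rollup:
    """Per-formulation taxon sets at one rank, plus the distinct set."""

    rank: str
    per_formulation: tuple[frozenset[str], ...]
    distinct: frozenset[str]


def rollup(formulary: Formulary, rank: str, taxonomy: Taxonomy) -> Rollup:
    """Map each formulation's herb set to ancestor taxa at *rank*.

    ``rank="species"`` returns the herb sets unchanged.  A species
    missing from the taxonomy table, or carrying an empty value at the
    requested rank, aborts with :class:`RankValueError` naming every
    offending species — rank statistics must not silently drop herbs.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank: {rank!r} (expected one of {RANKS})")
    if rank == "species":
        per = tuple(f.herbs for f in formulary)
        return Rollup(rank=rank, per_formulation=per, distinct=formulary.herb_set())

    mapping: dict[str, str] = {}
    missing: list[str] = []
    for herb in sorted(formulary.herb_set()):
        rec = taxonomy.get(herb)
        value = rec.rank_value(rank) if rec is not None else ""
        if not value:
            missing.append(herb)
        else:
            mapping[herb] = value
    if missing:
        raise RankValueError(
            f"species without a {rank} value: {', '.join(missing)}"
        )
    per = tuple(frozenset(mapping[h] for h in f.herbs) for f in formulary)
    distinct = frozenset(mapping.values())
    return Rollup(rank=rank, per_formulation=per, distinct=distinct)


# -- corpus (de)serialization -------------------------------------------------

def write_corpus_json(formularies: Mapping[str, Formulary], path: str | Path) -> None:
    """Serialize formularies losslessly to a documented JSON layout.

    Layout: ``{"systems": {label: [{"formulation_id", "name", "herbs"}]}}``
    with herb lists sorted, so equal corpora serialize identically.
    """
    doc = {
        "systems": {
            system: [
                {
                    "formulation_id": f.formulation_id,
                    "name": f.name,
                    "herbs": sorted(f.herbs),
                }
                for f in formularies[system]
            ]
            for system in sorted(formularies)
        }
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def read_corpus_json(path: str | Path) -> dict[str, Formulary]:
    doc = json.loads(Path(path).read_text())
    out: dict[str, Formulary] = {}
    for system, fl in doc["systems"].items():
        out[system] = Formulary(
            system=system,
            formulations=[
                Formulation(
                    formulation_id=f["formulation_id"],
                    system=system,
                    name=f["name"],
                    herbs=frozenset(f["herbs"]),
                )
                for f in fl
            ],
        )
    return out
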