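import json

import pandas as pd
import pytest

from phfmine.model import (
    RANKS,
    RankValueError,
    SchemaError,
    ingest_formulation_table,
    read_corpus_json,
    rollup,
    standardize_name,
    write_corpus_json,
)

from conftest import make_formulary, random_corpus


@pytest.mark.parametrize(
    "raw, expected_status, expected_accepted",
    [
        # a known synonym resolves onto its accepted binomial
        ("Poria cocos", "resolved", "Wolfiporia cocos"),
        # an accepted name resolves to itself
        ("Zingiber officinale", "resolved", "Zingiber officinale"),
        # case and whitespace are normalized before lookup
        ("  glycyrrhiza   URALENSIS ", "resolved", "Glycyrrhiza uralensis"),
        ("GAN CAO", "resolved", "Glycyrrhiza uralensis"),
        # a name absent from both tables is unresolved, not an error
        ("Herba imaginaria", "unresolved", ""),
    ],
)
def test_standardize_name(toy_taxonomy, toy_synonyms, raw, expected_status, expected_accepted):
    ing = standardize_name(raw, toy_synonyms, toy_taxonomy)
    assert ing.status == expected_status
    assert ing.accepted_name == expected_accepted
    assert ing.raw_name == raw  # original text always preserved


def test_standardize_name_is_pure(toy_taxonomy, toy_synonyms):
    a = standardize_name("Poria cocos", toy_synonyms, toy_taxonomy)
    b = standardize_name("Poria cocos", toy_synonyms, toy_taxonomy)
    assert a == b


def test_ingest_toy_table_hand_enumeration(toy_rows, toy_taxonomy, toy_synonyms):
    """Hand count on the six-row toy table under the strict policy with
    the fungus admitted: honey dropped as non-botanical, one name
    unresolved, one duplicate raw row collapsed."""
    formularies, log = ingest_formulation_table(
        toy_rows, toy_synonyms, toy_taxonomy, allow_fungi=True
    )
    assert set(formularies) == {"TCM"}
    fl = formularies["TCM"]
    by_id = {f.formulation_id: f.herbs for f in fl}
    assert by_id["F1"] == {"Glycyrrhiza uralensis", "Wolfiporia cocos"}
    assert by_id["F2"] == {"Zingiber officinale"}
    assert log.rows_read == 6
    assert log.duplicates_collapsed == 1
    assert log.resolved == 3
    assert log.unresolved == 1
    assert log.non_botanical == 1  # honey
    assert any("Wolfiporia cocos" in n for n in log.notes)  # fungus surfaced
    # herb-set sizes sum to retained resolved rows after deduplication
    assert sum(f.size for f in fl) == 3


def test_ingest_fungus_excluded_by_default(toy_rows, toy_taxonomy, toy_synonyms):
    formularies, log = ingest_formulation_table(toy_rows, toy_synonyms, toy_taxonomy)
    assert formularies["TCM"].herb_set() == {
        "Glycyrrhiza uralensis",
        "Zingiber officinale",
    }
    assert log.non_botanical == 2  # honey and the fungus


def test_ingest_set_semantics_two_raws_one_species(toy_taxonomy, toy_synonyms):
    """Two raw spellings of one species in one formulation collapse to a
    single herb; the other formulation is untouched."""
    rows = pd.DataFrame(
        [
            ("F1", "TCM", "A", "Glycyrrhiza uralensis"),
            ("F1", "TCM", "A", "Gan Cao"),
            ("F2", "TCM", "B", "Panax ginseng"),
        ],
        columns=["formulation_id", "system", "formulation_name", "ingredient_raw_name"],
    )
    formularies, _ = ingest_formulation_table(rows, toy_synonyms, toy_taxonomy)
    by_id = {f.formulation_id: f.herbs for f in formularies["TCM"]}
    assert by_id["F1"] == {"Glycyrrhiza uralensis"}
    assert by_id["F2"] == {"Panax ginseng"}


def test_ingest_unresolved_keep_policy(toy_rows, toy_taxonomy, toy_synonyms):
    formularies, log = ingest_formulation_table(
        toy_rows, toy_synonyms, toy_taxonomy, unresolved_policy="keep"
    )
    assert "Herba imaginaria" in formularies["TCM"].herb_set()
    assert log.unresolved_kept == 1


def test_ingest_missing_column_is_fatal(toy_taxonomy, toy_synonyms):
    rows = pd.DataFrame({"formulation_id": ["F1"], "system": ["TCM"]})
    with pytest.raises(SchemaError, match="formulation_name"):
        ingest_formulation_table(rows, toy_synonyms, toy_taxonomy)


def test_ingest_empty_formulations_dropped(toy_taxonomy, toy_synonyms):
    rows = pd.DataFrame(
        [("F1", "TCM", "A", "Herba imaginaria"), ("F2", "TCM", "B", "Panax ginseng")],
        columns=["formulation_id", "system", "formulation_name", "ingredient_raw_name"],
    )
    formularies, log = ingest_formulation_table(rows, toy_synonyms, toy_taxonomy)
    assert {f.formulation_id for f in formularies["TCM"]} == {"F2"}
    assert log.empty_formulations_dropped == 1


def test_ingest_unknown_system_rejected(toy_rows, toy_taxonomy, toy_synonyms):
    with pytest.raises(SchemaError, match="system"):
        ingest_formulation_table(
            toy_rows, toy_synonyms, toy_taxonomy, systems={"Kampo"}
        )


def test_rollup_species_is_identity(toy_taxonomy):
    fl = make_formulary([{"Glycyrrhiza uralensis", "Panax ginseng"}, {"Panax ginseng"}])
    r = rollup(fl, "species", toy_taxonomy)
    assert r.per_formulation == tuple(f.herbs for f in fl)
    assert r.distinct == fl.herb_set()


def test_rollup_family_and_order(toy_taxonomy):
    # three species in two orders: Apiales (ginseng, angelica) + Fabales
    fl = make_formulary(
        [{"Glycyrrhiza uralensis", "Panax ginseng", "Angelica sinensis"}]
    )
    fam = rollup(fl, "family", toy_taxonomy)
    assert fam.per_formulation[0] == {"Fabaceae", "Araliaceae", "Apiaceae"}
    order = rollup(fl, "order", toy_taxonomy)
    assert order.per_formulation[0] == {"Fabales", "Apiales"}
    assert len(order.distinct) == 2


def test_rollup_missing_rank_value_names_species(toy_taxonomy):
    fl = make_formulary([{"Incertae sedisplant", "Panax ginseng"}])
    with pytest.raises(RankValueError, match="Incertae sedisplant"):
        rollup(fl, "order", toy_taxonomy)


def test_rollup_distinct_counts_monotone_up_ranks(toy_taxonomy):
    """Distinct-taxon counts never increase as the rank gets coarser."""
    fl = make_formulary(
        [
            {"Glycyrrhiza uralensis", "Panax ginseng"},
            {"Angelica sinensis", "Zingiber officinale", "Paeonia lactiflora"},
        ]
    )
    counts = [len(rollup(fl, rank, toy_taxonomy).distinct) for rank in RANKS]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_corpus_json_round_trip_is_lossless(tmp_path):
    formularies = {
        "TCM": make_formulary([{"a x", "b y"}, {"b y"}], "TCM"),
        "Kampo": make_formulary([{"c z"}], "Kampo"),
    }
    p1 = tmp_path / "c1.json"
    p2 = tmp_path / "c2.json"
    write_corpus_json(formularies, p1)
    again = read_corpus_json(p1)
    write_corpus_json(again, p2)
    assert p1.read_text() == p2.read_text()
    assert {s: [f.herbs for f in fl] for s, fl in again.items()} == {
        s: [f.herbs for f in fl] for s, fl in formularies.items()
    }


def test_reingest_of_serialized_corpus_is_idempotent(tmp_path, toy_taxonomy, toy_synonyms):
    """Exporting an ingested corpus as a table and re-ingesting it gives
    identical formularies."""
    rows = pd.DataFrame(
        [
            ("F1", "TCM", "A", "Gan Cao"),
            ("F1", "TCM", "A", "Panax ginseng"),
            ("F2", "TCM", "B", "Zingiber officinale"),
        ],
        columns=["formulation_id", "system", "formulation_name", "ingredient_raw_name"],
    )
    first, _ = ingest_formulation_table(rows, toy_synonyms, toy_taxonomy)
    exported = pd.DataFrame(
        [
            (f.formulation_id, f.system, f.name, herb)
            for fl in first.values()
            for f in fl
            for herb in sorted(f.herbs)
        ],
        columns=["formulation_id", "system", "formulation_name", "ingredient_raw_name"],
    )
    second, _ = ingest_formulation_table(exported, toy_synonyms, toy_taxonomy)
    assert {s: {f.formulation_id: f.herbs for f in fl} for s, fl in first.items()} == {
        s: {f.formulation_id: f.herbs for f in fl} for s, fl in second.items()
    }


def test_excel_reader_same_contract_as_tsv(tmp_path, toy_taxonomy, toy_synonyms):
    """An Excel workbook with the integrated-list column layout ingests
    identically to the equivalent TSV."""
    from phfmine.model import read_formulation_table

    rows = pd.DataFrame(
        [("F1", "TCM", "A", "Gan Cao"), ("F2", "Kampo", "B", "Zingiber officinale")],
        columns=["formulation_id", "system", "formulation_name", "ingredient_raw_name"],
    )
    xlsx = tmp_path / "phf.xlsx"
    tsv = tmp_path / "phf.tsv"
    rows.to_excel(xlsx, index=False)
    rows.to_csv(tsv, sep="\t", index=False)
    from_xlsx, _ = ingest_formulation_table(
        read_formulation_table(xlsx), toy_synonyms, toy_taxonomy
    )
    from_tsv, _ = ingest_formulation_table(
        read_formulation_table(tsv), toy_synonyms, toy_taxonomy
    )
    assert {s: [f.herbs for f in fl] for s, fl in from_xlsx.items()} == {
        s: [f.herbs for f in fl] for s, fl in from_tsv.items()
    }


def test_random_corpora_survive_json_round_trip(tmp_path):
    for seed in range(25):
        fl = make_formulary(random_corpus(seed))
        p = tmp_path / f"{seed}.json"
        write_corpus_json({"TCM": fl}, p)
        back = read_corpus_json(p)["TCM"]
        assert [f.herbs for f in back] == [f.herbs for f in fl]
        json.loads(p.read_text())  # layout stays valid JSON
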