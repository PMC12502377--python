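import random

import pandas as pd
import pytest

from phfmine.model import (
    Formulary,
    Formulation,
    SynonymTable,
    Taxonomy,
    TaxonRecord,
)


@pytest.fixture(scope="session")
def toy_taxonomy() -> Taxonomy:
    recs = [
        TaxonRecord("Glycyrrhiza uralensis", "Plantae", "Tracheophyta", "Magnoliopsida",
                    "Fabales", "Fabaceae", "Glycyrrhiza"),
        TaxonRecord("Panax ginseng", "Plantae", "Tracheophyta", "Magnoliopsida",
                    "Apiales", "Araliaceae", "Panax"),
        TaxonRecord("Angelica sinensis", "Plantae", "Tracheophyta", "Magnoliopsida",
                    "Apiales", "Apiaceae", "Angelica"),
        TaxonRecord("Zingiber officinale", "Plantae", "Tracheophyta", "Liliopsida",
                    "Zingiberales", "Zingiberaceae", "Zingiber"),
        TaxonRecord("Paeonia lactiflora", "Plantae", "Tracheophyta", "Magnoliopsida",
                    "Saxifragales", "Paeoniaceae", "Paeonia"),
        # a medicinal fungus recorded under a plant-style binomial
        TaxonRecord("Wolfiporia cocos", "Fungi", "Basidiomycota", "Agaricomycetes",
                    "Polyporales", "Polyporaceae", "Wolfiporia"),
        # an animal product (honey source), never botanical
        TaxonRecord("Apis mellifera", "Animalia", "Arthropoda", "Insecta",
                    "Hymenoptera", "Apidae", "Apis"),
        # unplaced above genus: no order value
        TaxonRecord("Incertae sedisplant", "Plantae", "Tracheophyta", "", "", "",
                    "Incertae"),
    ]
    return Taxonomy(recs)


@pytest.fixture(scope="session")
def toy_synonyms() -> SynonymTable:
    return SynonymTable(
        {
            "Poria cocos": "Wolfiporia cocos",
            "Honey": "Apis mellifera",
            "Gan Cao": "Glycyrrhiza uralensis",
        }
    )


@pytest.fixture()
def toy_rows() -> pd.DataFrame:
    """Six-row toy table: one honey row, one unresolved row, one synonym
    row, one duplicated raw row (hand enumeration in the tests)."""
    rows = [
        ("F1", "TCM", "Decoction One", "Glycyrrhiza uralensis"),
        ("F1", "TCM", "Decoction One", "Poria cocos"),
        ("F1", "TCM", "Decoction One", "Honey"),
        ("F1", "TCM", "Decoction One", "Herba imaginaria"),
        ("F2", "TCM", "Decoction Two", "Zingiber officinale"),
        ("F2", "TCM", "Decoction Two", "Zingiber officinale"),
    ]
    return pd.DataFrame(
        rows, columns=["formulation_id", "system", "formulation_name", "ingredient_raw_name"]
    )


def make_formulary(form_sets, system="TCM") -> Formulary:
    """Wrap plain herb sets into a Formulary."""
    return Formulary(
        system=system,
        formulations=[
            Formulation(
                formulation_id=f"{system}-{i}",
                system=system,
                name=f"f{i}",
                herbs=frozenset(h),
            )
            for i, h in enumerate(form_sets)
        ],
    )


def random_corpus(seed, max_herbs=10, max_forms=8):
    """Small random corpus: a list of non-empty herb sets."""
    rng = random.Random(seed)
    herbs = [f"h{i:02d}" for i in range(rng.randint(2, max_herbs))]
    n = rng.randint(1, max_forms)
    sets = []
    for _ in range(n):
        k = rng.randint(1, len(herbs))
        sets.append(set(rng.sample(herbs, k)))
    return sets


def random_sets(seed, n_sets=3, universe=20):
    """Random family of non-empty sets over a small universe."""
    rng = random.Random(seed)
    items = [f"x{i}" for i in range(universe)]
    return {
        f"S{j}": set(rng.sample(items, rng.randint(1, universe)))
        for j in range(n_sets)
    }
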