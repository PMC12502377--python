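import dataclasses
import math

import pytest

from phfmine.frequency import herb_support, mean_formulation_size
from phfmine.model import rollup, write_corpus_json
from phfmine.overlap import venn_regions
from phfmine.pairs import mine_rules, pair_counts
from phfmine.synth import (
    InfeasibleConfigError,
    PlantedRule,
    SynthConfig,
    build_pools,
    emulate_study_shape,
    generate,
    model_expected_support,
)


def small_config(**over) -> SynthConfig:
    base = dict(
        systems=("S",),
        n_formulations={"S": 500},
        herb_pool={"S": 30},
        mean_size={"S": 5.0},
        popularity_exponent={"S": 0.8},
    )
    base.update(over)
    return SynthConfig(**base)


def corpus_key(gen) -> str:
    import io

    buf = io.StringIO()
    for s in gen.config.systems:
        for f in gen.formularies[s]:
            buf.write(f.formulation_id + ":" + ",".join(sorted(f.herbs)) + ";")
    return buf.getvalue()


def test_same_config_and_seed_give_identical_corpora(tmp_path):
    cfg = small_config()
    g1, g2 = generate(cfg, seed=11), generate(cfg, seed=11)
    assert corpus_key(g1) == corpus_key(g2)
    p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
    write_corpus_json(g1.formularies, p1)
    write_corpus_json(g2.formularies, p2)
    assert p1.read_bytes() == p2.read_bytes()
    assert corpus_key(generate(cfg, seed=12)) != corpus_key(g1)


def test_infeasible_configs_fail_before_sampling():
    with pytest.raises(InfeasibleConfigError, match="mean formulation size"):
        generate(small_config(mean_size={"S": 40.0}))
    with pytest.raises(InfeasibleConfigError, match="confidence"):
        generate(
            small_config(
                planted_rules=(PlantedRule("S", "a b", "c d", 0.0),)
            )
        )
    with pytest.raises(InfeasibleConfigError, match="region counts"):
        SynthConfig(
            systems=("A", "B"),
            n_formulations={"A": 5, "B": 5},
            herb_pool={"A": 10, "B": 10},
            mean_size={"A": 3, "B": 3},
            popularity_exponent={"A": 1, "B": 1},
            region_counts={frozenset({"A"}): 3, frozenset({"B"}): 10, frozenset({"A", "B"}): 1},
        ).validate()


def test_observed_herbs_cover_the_configured_pool():
    """Every pool herb appears in at least one formulation, so observed
    distinct herb sets equal the configured pools."""
    cfg = small_config(popularity_exponent={"S": 1.3})
    gen = generate(cfg, seed=3)
    assert gen.formularies["S"].herb_set() == frozenset(build_pools(cfg)["S"])


def test_pairwise_overlap_fraction_realized_in_pools():
    cfg = SynthConfig(
        systems=("A", "B"),
        n_formulations={"A": 20, "B": 20},
        herb_pool={"A": 40, "B": 50},
        mean_size={"A": 4, "B": 4},
        popularity_exponent={"A": 0.8, "B": 0.8},
        cross_system_overlap={("A", "B"): 0.5},
    )
    pools = build_pools(cfg)
    a, b = set(pools["A"]), set(pools["B"])
    assert len(a) == 40 and len(b) == 50
    assert len(a & b) == 20  # 50% of A's pool shared with B


def test_planted_conf1_rule_recovered_exactly():
    """A deterministic dependency planted at antecedent support ~0.2 is
    mined back with confidence exactly 1."""
    cfg = small_config()
    pool = build_pools(cfg)["S"]
    ant, cons = pool[2], pool[10]
    cfg = dataclasses.replace(
        cfg, planted_rules=(PlantedRule("S", ant, cons, 1.0),)
    )
    gen = generate(cfg, seed=5)
    fl = gen.formularies["S"]
    sup = herb_support(fl).support(ant)
    assert sup > 0.05
    rs = mine_rules(fl)
    match = [r for r in rs.rules if r.antecedent == ant and r.consequent == cons]
    assert match and match[0].confidence == 1.0
    # the pair support equals the antecedent support: ant never appears alone
    assert pair_counts(fl)[tuple(sorted((ant, cons)))] == fl.herb_counts()[ant]


def test_planted_partial_confidence_within_binomial_error():
    """A confidence-0.9 dependency is estimated within binomial sampling
    error of its target at n=500."""
    cfg = small_config()
    pool = build_pools(cfg)["S"]
    ant, cons = pool[1], pool[12]
    cfg = dataclasses.replace(
        cfg, planted_rules=(PlantedRule("S", ant, cons, 0.9),)
    )
    gen = generate(cfg, seed=7)
    fl = gen.formularies["S"]
    n_ant = fl.herb_counts()[ant]
    n_both = pair_counts(fl)[tuple(sorted((ant, cons)))]
    conf_hat = n_both / n_ant
    # baseline co-occurrence can only push the estimate up, never below
    se = math.sqrt(0.9 * 0.1 / n_ant)
    assert conf_hat >= 0.9 - 3 * se
    assert conf_hat <= 1.0


def test_empirical_supports_converge_to_popularity_model():
    """At n=5000 every herb's empirical support is close to the
    popularity model's Monte-Carlo expectation."""
    cfg = SynthConfig(
        systems=("S",),
        n_formulations={"S": 5000},
        herb_pool={"S": 20},
        mean_size={"S": 4.0},
        popularity_exponent={"S": 1.0},
        synonym_every=0,
    )
    gen = generate(cfg, seed=2)
    emp = herb_support(gen.formularies["S"])
    pool = build_pools(cfg)["S"]
    for rank in (0, 1, 4, 10, 19):
        expect = model_expected_support(20, 1.0, 4.0, rank, n_samples=6000, seed=99)
        assert emp.support(pool[rank]) == pytest.approx(expect, abs=0.03)


def test_study_preset_structure_is_exact():
    """The study-shape preset reproduces the published corpus structure
    deterministically: counts, pool sizes, union, and the Venn design."""
    cfg = emulate_study_shape()
    gen = generate(cfg, seed=0)
    fls = gen.formularies
    assert [fls[s].n for s in cfg.systems] == [100, 200, 142, 170]
    assert [len(fls[s].herb_set()) for s in cfg.systems] == [135, 130, 239, 272]
    union = set().union(*(fls[s].herb_set() for s in cfg.systems))
    assert len(union) == 546
    regions = venn_regions({s: fls[s].herb_set() for s in cfg.systems})
    assert regions[frozenset(cfg.systems)] == 12
    assert regions[frozenset({"TCM"})] == 42
    # 5 algal species among the 546
    algae = [h for h in union if gen.taxonomy.get(h).kingdom == "Algae"]
    assert len(algae) == 5


def test_study_preset_taxonomy_supports_rank_rollup():
    cfg = emulate_study_shape()
    gen = generate(cfg, seed=1)
    for s in cfg.systems:
        fam = rollup(gen.formularies[s], "family", gen.taxonomy)
        order = rollup(gen.formularies[s], "order", gen.taxonomy)
        assert 1 < len(order.distinct) <= len(fam.distinct) <= cfg.n_families


def test_study_preset_calibration_sanity_single_seed():
    """One-seed smoke check of the calibrated statistics (the multi-seed
    tolerance check lives in the acceptance suite)."""
    gen = generate(emulate_study_shape(), seed=4)
    tcm = gen.formularies["TCM"]
    assert abs(mean_formulation_size(tcm) - 6.8) < 0.6
    top = max(herb_support(tcm).entries.values())
    assert abs(top - 0.60) < 0.10
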