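"""The a priori criteria chain, cross-family intersection and
co-segregation rules, checked against independent set-algebra oracles."""

import numpy as np
import pytest

from famprio.model import (
    AffectednessStatus,
    ConfigError,
    CosegRule,
    FilterConfig,
    Individual,
    Pedigree,
)
from famprio.phenotyping import apply_nviq_exclusion, assign_affectedness_cohort
from famprio.phenotyping import CriterionTable
from famprio.workflow1 import (
    apply_a_priori_filters,
    apply_coseg_rules,
    build_family_comparison_list,
    coseg_ok,
    cross_family_gene_intersection,
    rare_or_novel_filter,
    run_workflow1,
)

from ._oracles import oracle_workflow1, random_mini_cohort
from .conftest import make_variant, matrix_for

CFG = FilterConfig()


def test_empty_variant_list_passes_through():
    gm = matrix_for(["a", "b"], [], np.zeros((2, 0)))
    kept, trace = apply_a_priori_filters([], gm, ["a", "b"], CFG)
    assert kept == []
    assert trace.records == []


def test_cadd_boundary_excluded_with_named_criterion():
    v_low = make_variant(pos=1, cadd_phred=19.9)
    v_ok = make_variant(pos=2, cadd_phred=20.0)
    gm = matrix_for(["a", "b"], [v_low, v_ok], [[1, 1], [1, 1]])
    kept, trace = apply_a_priori_filters([v_low, v_ok], gm, ["a", "b"], CFG)
    assert [v.pos for v in kept] == [2]
    assert trace.failures(v_low.key) == ["iv_cadd"]


def test_unknown_cadd_or_gerp_fails_conservatively():
    v = make_variant(cadd_phred=None, gerp=None)
    gm = matrix_for(["a", "b"], [v], [[1], [1]])
    kept, trace = apply_a_priori_filters([v], gm, ["a", "b"], CFG)
    assert kept == []
    assert set(trace.failures(v.key)) == {"iv_cadd", "v_gerp"}
    relaxed = FilterConfig(unknown_scores_fail=False)
    kept2, _ = apply_a_priori_filters([v], gm, ["a", "b"], relaxed)
    assert kept2 == [v]


def test_sharing_counts_carriers_not_alleles():
    v = make_variant()
    # one homozygote is one sharer, not two
    gm = matrix_for(["a", "b"], [v], [[2], [0]])
    kept, _ = apply_a_priori_filters([v], gm, ["a", "b"], CFG)
    assert kept == []
    gm2 = matrix_for(["a", "b"], [v], [[2], [1]])
    kept2, _ = apply_a_priori_filters([v], gm2, ["a", "b"], CFG)
    assert kept2 == [v]


def test_missing_genotype_is_not_a_sharer():
    v = make_variant()
    gm = matrix_for(["a", "b"], [v], [[1], [-1]])
    kept, _ = apply_a_priori_filters([v], gm, ["a", "b"], CFG)
    assert kept == []


@pytest.mark.parametrize(
    "maf,n_damaging,expected",
    [(0.009, 0, True), (None, 3, True), (None, 1, False), (0.02, 5, False)],
)
def test_rare_or_novel_semantics(maf, n_damaging, expected):
    calls = {
        p: "damaging" if i < n_damaging else "tolerated"
        for i, p in enumerate(
            ("SIFT", "PolyPhen2", "MutationAssessor", "PROVEAN", "MutationTaster")
        )
    }
    v = make_variant(maf={} if maf is None else {"NFE": maf}, predictor_calls=calls)
    kept = rare_or_novel_filter([v], "NFE", CFG)
    assert (v in kept) is expected


def test_unresolvable_subpopulation_is_config_error():
    with pytest.raises(ConfigError):
        rare_or_novel_filter([make_variant()], "", CFG)


def test_gene_intersection_requires_two_families():
    a = make_variant(gene="SHARED", pos=1)
    b = make_variant(gene="SHARED", pos=2)
    only = make_variant(gene="PRIVATE", pos=3)
    lists = {"F1": [a, only], "F2": [b]}
    shared = cross_family_gene_intersection(lists)
    assert shared == {"SHARED"}
    assert cross_family_gene_intersection(lists, gene_blocklist=frozenset({"SHARED"})) == set()


def test_gene_intersection_matches_bruteforce_on_random_fixture():
    rng = np.random.default_rng(7)
    genes = [f"G{i}" for i in range(12)]
    lists = {}
    for f in range(6):
        lists[f"F{f}"] = [
            make_variant(gene=str(g), pos=100 * f + i + 1)
            for i, g in enumerate(rng.choice(genes, size=5, replace=False))
        ]
    got = cross_family_gene_intersection(lists)
    counts = {}
    for vs in lists.values():
        for g in {v.gene for v in vs}:
            counts[g] = counts.get(g, 0) + 1
    assert got == {g for g, n in counts.items() if n >= 2}


def _statuses(mapping):
    return {
        i: AffectednessStatus(individual_id=i, combined_affected=c)
        for i, c in mapping.items()
    }


def test_coseg_rejects_unaffected_carrier():
    ped = Pedigree(
        "F1",
        [Individual("a"), Individual("b"), Individual("c")],
    )
    v = make_variant()
    st = _statuses({"a": "yes", "b": "yes", "c": "no"})
    gm = matrix_for(["a", "b", "c"], [v], [[1], [1], [1]])
    assert not coseg_ok(v.key, gm, st, ped, CosegRule("F1"))
    tolerant = CosegRule("F1", max_unaffected_carriers=1)
    assert coseg_ok(v.key, gm, st, ped, tolerant)


def test_coseg_requires_all_genotyped_affected_to_carry():
    ped = Pedigree("F1", [Individual("a"), Individual("b"), Individual("c")])
    v = make_variant()
    st = _statuses({"a": "yes", "b": "yes", "c": "yes"})
    gm = matrix_for(["a", "b", "c"], [v], [[1], [1], [0]])
    assert not coseg_ok(v.key, gm, st, ped, CosegRule("F1"))
    # the non-carrier's genotype goes missing: no longer counted
    gm2 = matrix_for(["a", "b", "c"], [v], [[1], [1], [-1]])
    assert coseg_ok(v.key, gm2, st, ped, CosegRule("F1"))


def test_coseg_rule_unknown_individual_is_config_error():
    ped = Pedigree("F1", [Individual("a")])
    v = make_variant()
    gm = matrix_for(["a"], [v], [[1]])
    with pytest.raises(ConfigError):
        coseg_ok(v.key, gm, _statuses({"a": "yes"}), ped, CosegRule("F1", required_carriers=("ghost",)))


def test_four_affected_carriers_across_two_families_gate():
    v1 = make_variant(gene="G", pos=1)
    v2 = make_variant(gene="G", pos=2)
    peds = {
        "F1": Pedigree("F1", [Individual("a1"), Individual("a2")]),
        "F2": Pedigree("F2", [Individual("b1"), Individual("b2")]),
    }
    statuses = {
        "F1": _statuses({"a1": "yes", "a2": "yes"}),
        "F2": _statuses({"b1": "yes", "b2": "yes"}),
    }
    gm = matrix_for(["a1", "a2", "b1", "b2"], [v1, v2],
                    [[1, 0], [1, 0], [0, 1], [1, 1]])
    lists = {"F1": [v1], "F2": [v2]}
    _, genes = apply_coseg_rules(lists, gm, statuses, peds, {}, CFG)
    assert genes == {"G"}
    # drop one carrier: only 3 affected across the two families
    gm2 = matrix_for(["a1", "a2", "b1", "b2"], [v1, v2],
                     [[1, 0], [1, 0], [0, 0], [0, 1]])
    _, genes2 = apply_coseg_rules(lists, gm2, statuses, peds, {}, CFG)
    assert genes2 == set()


def test_workflow1_equals_bruteforce_oracle_on_random_cohorts():
    rng = np.random.default_rng(1234)
    for _ in range(20):
        variants, gm, statuses, peds = random_mini_cohort(rng)
        res = run_workflow1(variants, gm, statuses, peds, CFG)
        oracle = oracle_workflow1(variants, gm, statuses, peds, CFG)
        got_comparison = {
            fam: {v.key for v in vs} for fam, vs in res.comparison_lists.items()
        }
        assert got_comparison == oracle["comparison"]
        assert res.shared_genes == oracle["shared_genes"]
        assert {f: {v.key for v in vs} for f, vs in res.coseg_lists.items()} == oracle["coseg"]
        assert res.final_genes == oracle["final_genes"]


def test_cascade_counts_non_increasing(noisy_cohort):
    c = noisy_cohort
    statuses = assign_affectedness_cohort(c.phenotypes, CriterionTable.flat(c.spec.criterion_cut))
    statuses = apply_nviq_exclusion(statuses, c.phenotypes)
    by_fam = {
        fam: {i: statuses[i] for i in ped.member_ids if i in statuses}
        for fam, ped in c.pedigrees.items()
    }
    res = run_workflow1(c.variants, c.genotypes, by_fam, c.pedigrees, CFG)
    for fam, counts in res.ledger.items():
        seq = [counts["input"], counts["a_priori"], counts["rare_or_novel"],
               counts["on_shared_genes"], counts["coseg"], counts["final"]]
        assert seq == sorted(seq, reverse=True)


def test_comparison_lists_are_sorted_and_deterministic():
    vs = [make_variant(gene=g, pos=p) for g, p in (("B", 5), ("A", 9), ("A", 2))]
    lists = build_family_comparison_list({"F1": vs})
    assert [(v.gene, v.pos) for v in lists["F1"]] == [("A", 2), ("A", 9), ("B", 5)]
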