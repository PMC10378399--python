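"""Candidate-gene prioritization semantics and region lookup."""

import numpy as np
import pytest

from famprio.model import ConfigError, FilterConfig, ValidationError
from famprio.phenotyping import (
    CriterionTable,
    affected_ids,
    apply_nviq_exclusion,
    assign_affectedness_cohort,
    unaffected_ids,
)
from famprio.workflow1 import run_workflow1
from famprio.workflow2 import candidate_gene_filter, region_lookup

from .conftest import make_variant, matrix_for

CFG = FilterConfig()
GENES = ["CAND1", "CAND2"]


def test_candidate_variant_at_relaxed_maf_is_prioritized():
    v = make_variant(gene="CAND1", maf={"NFE": 0.05})
    gm = matrix_for(["a", "b"], [v], [[1], [1]])
    kept = candidate_gene_filter([v], gm, ["a", "b"], GENES, CFG)
    assert kept == [v]


@pytest.mark.parametrize("maf,expected", [(0.069, True), (0.07, False), (0.08, False)])
def test_candidate_maf_bound_is_strict(maf, expected):
    v = make_variant(gene="CAND1", maf={"NFE": maf})
    gm = matrix_for(["a", "b"], [v], [[1], [1]])
    kept = candidate_gene_filter([v], gm, ["a", "b"], GENES, CFG)
    assert (v in kept) is expected


def test_unknown_maf_passes_candidate_screen_by_default():
    v = make_variant(gene="CAND1", maf={})
    gm = matrix_for(["a", "b"], [v], [[1], [1]])
    assert candidate_gene_filter([v], gm, ["a", "b"], GENES, CFG) == [v]
    strict = FilterConfig(unknown_maf_passes_candidate=False)
    assert candidate_gene_filter([v], gm, ["a", "b"], GENES, strict) == []


def test_non_candidate_gene_is_absent_even_if_passing():
    v = make_variant(gene="ELSEWHERE")
    gm = matrix_for(["a", "b"], [v], [[1], [1]])
    assert candidate_gene_filter([v], gm, ["a", "b"], GENES, CFG) == []


def test_unaffected_sibling_carrier_blocks_prioritization():
    # a variant called in the proband and a TEGI-unaffected sibling must
    # not be prioritized under the zero-unaffected-carrier default
    v = make_variant(gene="CAND1")
    gm = matrix_for(["proband", "aff_sib", "unaff_sib"], [v], [[1], [1], [1]])
    kept = candidate_gene_filter(
        [v], gm, ["proband", "aff_sib"], GENES, CFG, unaffected_ids=["unaff_sib"]
    )
    assert kept == []


def test_empty_gene_list_is_config_error():
    v = make_variant(gene="CAND1")
    gm = matrix_for(["a"], [v], [[1]])
    with pytest.raises(ConfigError):
        candidate_gene_filter([v], gm, ["a"], [], CFG)


def test_workflow1_candidate_hits_are_contained_in_workflow2(clean_cohort):
    """Workflow 2's bounds are strictly weaker on candidate genes: every
    workflow-1 prioritized variant on a listed gene must reappear."""
    c = clean_cohort
    statuses = assign_affectedness_cohort(
        c.phenotypes, CriterionTable.flat(c.spec.criterion_cut)
    )
    statuses = apply_nviq_exclusion(statuses, c.phenotypes)
    by_fam = {
        fam: {i: statuses[i] for i in ped.member_ids if i in statuses}
        for fam, ped in c.pedigrees.items()
    }
    res1 = run_workflow1(c.variants, c.genotypes, by_fam, c.pedigrees, CFG)
    gene_list = sorted({v.gene for vs in res1.final_variants.values() for v in vs})
    assert gene_list, "planted gene should have been prioritized"
    for fam, ped in c.pedigrees.items():
        aff = affected_ids(by_fam[fam])
        unaff = unaffected_ids(by_fam[fam])
        if len(aff) < CFG.min_affected_sharers:
            continue
        w2 = candidate_gene_filter(
            c.variants, c.genotypes, aff, gene_list, CFG,
            unaffected_ids=unaff, family_subpop=ped.members[0].subpopulation,
        )
        w1_keys = {v.key for v in res1.final_variants.get(fam, [])
                   if v.gene in gene_list}
        assert w1_keys <= {v.key for v in w2}
        assert {v.gene for v in w2} <= set(gene_list)


# ---------------------------------------------------------------------------
# region lookup


def test_region_boundaries_are_inclusive():
    v_start = make_variant(chrom="6", pos=100)
    v_end = make_variant(chrom="6", pos=200)
    v_out = make_variant(chrom="6", pos=201)
    hits = region_lookup([v_start, v_end, v_out], [("6", 100, 200)])
    assert [(v.pos, r) for v, r in hits] == [(100, ("6", 100, 200)), (200, ("6", 100, 200))]


def test_empty_region_list_gives_empty_output():
    assert region_lookup([make_variant()], []) == []


def test_reversed_region_rejected():
    with pytest.raises(ValidationError):
        region_lookup([make_variant()], [("1", 50, 10)])


def test_region_lookup_matches_bruteforce_scan():
    rng = np.random.default_rng(55)
    variants = [
        make_variant(chrom=str(rng.integers(1, 4)), pos=int(rng.integers(1, 1000)))
        for _ in range(200)
    ]
    regions = [
        (str(rng.integers(1, 4)), int(lo), int(lo + rng.integers(0, 200)))
        for lo in rng.integers(1, 900, size=10)
    ]
    got = {(v.key, r) for v, r in region_lookup(variants, regions)}
    expected = {
        (v.key, (c, lo, hi))
        for v in variants
        for (c, lo, hi) in regions
        if v.chrom == c and lo <= v.pos <= hi
    }
    assert got == expected
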