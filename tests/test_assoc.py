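"""Burden test, carrier tally, causality rule and the family-clustered t."""

import numpy as np
import pytest
from scipy import stats

from famprio.assoc import (
    burden_table_from_maf,
    classify_causality,
    clustered_t_test,
    fisher_burden_test,
    tally_additional_probands,
)
from famprio.model import BurdenTable, CausalityEvidence, ValidationError

from ._oracles import fisher_enumeration


def test_no_carriers_anywhere_gives_p_one():
    assert fisher_burden_test(BurdenTable(0, 308, 0, 113770)) == 1.0


def test_reference_absent_variant_is_highly_significant():
    # two carrier alleles among 238 readable proband alleles, zero in a
    # 113,770-allele reference
    p = fisher_burden_test(BurdenTable(2, 238, 0, 113770))
    assert p < 0.0001


def test_balanced_small_table_gives_p_one():
    assert fisher_burden_test(BurdenTable(1, 10, 1, 10)) == 1.0


def test_zero_allele_total_is_an_error():
    with pytest.raises(ValidationError):
        fisher_burden_test(BurdenTable(0, 0, 1, 10))


def test_p_invariant_under_row_and_column_swaps():
    rng = np.random.default_rng(3)
    for _ in range(50):
        a, b, c, d = (int(x) for x in rng.integers(0, 20, size=4))
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            continue
        t = BurdenTable(a, a + b, c, c + d)
        p = fisher_burden_test(t)
        rows = BurdenTable(c, c + d, a, a + b)
        cols = BurdenTable(b, a + b, d, c + d)
        assert fisher_burden_test(rows) == pytest.approx(p, rel=1e-12)
        assert fisher_burden_test(cols) == pytest.approx(p, rel=1e-12)


def test_fisher_matches_exact_enumeration_on_small_tables():
    rng = np.random.default_rng(9)
    for _ in range(200):
        a, b, c, d = (int(x) for x in rng.integers(0, 13, size=4))
        if a + b == 0 or c + d == 0:
            continue
        p = fisher_burden_test(BurdenTable(a, a + b, c, c + d))
        strict, slack = fisher_enumeration(a, b, c, d)
        assert strict - 1e-9 <= p <= slack + 1e-9


def test_reference_count_reconstruction_from_maf():
    t = burden_table_from_maf(4, 308, 0.0089, 113770)
    assert t.carrier_alleles_ref == round(0.0089 * 113770)
    t0 = burden_table_from_maf(2, 238, 0.00008, 113770, reference_ac=0)
    assert t0.carrier_alleles_ref == 0


# ---------------------------------------------------------------------------
# tally


def test_disjoint_carrier_lists_sum():
    t = tally_additional_probands(
        {"v1": [("p1", True), ("p2", True), ("p3", False)],
         "v2": [("p4", True), ("p5", True)]}
    )
    assert (t.n_total, t.n_affected, t.n_unaffected) == (5, 4, 1)


def test_shared_proband_counted_once():
    t = tally_additional_probands(
        {"GLI3": [("shared", True), ("x", True)], "PDHA2": [("shared", True)]}
    )
    assert t.n_total == 2
    assert t.per_variant == {"GLI3": 2, "PDHA2": 1}


def test_tally_is_idempotent_and_order_invariant():
    lists = {"a": [("p1", True), ("p2", False)], "b": [("p1", True)]}
    t1 = tally_additional_probands(lists)
    t2 = tally_additional_probands(dict(reversed(list(lists.items()))))
    doubled = {k: v + v for k, v in lists.items()}
    t3 = tally_additional_probands(doubled)
    assert t1.ids == t2.ids == t3.ids
    assert t1.n_total == t2.n_total == t3.n_total


def test_inconsistent_affectedness_rejected():
    with pytest.raises(ValidationError):
        tally_additional_probands({"a": [("p1", True)], "b": [("p1", False)]})


# ---------------------------------------------------------------------------
# causality rule


def evidence(**kw):
    base = dict(
        maf=0.001, gerp_positive=True, cadd_ge_threshold=True, n_damaging=4,
        hope_size_change="increase", hope_charge_change="none",
        coseg_confirmed=True, n_discovery_families=1,
        n_additional_probands=0, n_unaffected_carriers=0,
    )
    base.update(kw)
    return CausalityEvidence(**base)


def test_common_variant_is_benign():
    v = classify_causality("k", evidence(maf=0.0536, n_unaffected_carriers=4))
    assert v.verdict == "B"
    assert v.criteria_fired[1] is False


def test_replicated_fully_supported_variant_is_pathogenic():
    v = classify_causality(
        "k", evidence(n_discovery_families=2, n_additional_probands=2, n_damaging=5)
    )
    assert v.verdict == "P"


def test_single_family_without_replication_is_likely_pathogenic():
    v = classify_causality("k", evidence())
    assert v.verdict == "Likely P"
    assert all(v.criteria_fired.values())


def test_unaffected_carrier_overrides_to_benign():
    v = classify_causality(
        "k", evidence(n_additional_probands=2, n_unaffected_carriers=1)
    )
    assert v.verdict == "B"
    off = classify_causality(
        "k",
        evidence(n_additional_probands=2, n_unaffected_carriers=1),
        unaffected_carrier_benign=False,
    )
    assert off.verdict == "P"


def test_missing_structural_annotation_fails_conservatively():
    v = classify_causality(
        "k",
        evidence(hope_size_change="none_reported", hope_charge_change="none_reported"),
    )
    assert v.verdict == "B"
    assert v.criteria_fired[6] is False


# ---------------------------------------------------------------------------
# clustered t


def test_identical_group_means_give_t_zero():
    values = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
    groups = ["A", "A", "A", "B", "B", "B"]
    clusters = ["f1", "f2", "f3", "f4", "f5", "f6"]
    res = clustered_t_test(values, groups, clusters)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.pvalue == pytest.approx(1.0)


def test_singleton_clusters_reduce_to_welch():
    rng = np.random.default_rng(21)
    x = rng.normal(0, 1, 9)
    y = rng.normal(0.5, 2, 7)
    values = np.concatenate([x, y])
    groups = ["A"] * 9 + ["B"] * 7
    clusters = [f"c{i}" for i in range(16)]
    res = clustered_t_test(values, groups, clusters)
    welch = stats.ttest_ind(x, y, equal_var=False)
    assert res.statistic == pytest.approx(welch.statistic, rel=1e-12)
    assert res.pvalue == pytest.approx(welch.pvalue, rel=1e-12)
    assert res.df == pytest.approx(welch.df, rel=1e-12)


def test_group_with_single_cluster_is_an_error():
    with pytest.raises(ValidationError, match="cluster"):
        clustered_t_test([1, 2, 3, 4], ["A", "A", "B", "B"], ["f1", "f1", "f2", "f3"])


def test_cluster_spanning_both_groups_is_an_error():
    with pytest.raises(ValidationError, match="span"):
        clustered_t_test(
            [1, 2, 3, 4], ["A", "A", "B", "B"], ["f1", "f2", "f2", "f3"]
        )
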