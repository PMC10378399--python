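"""Whole-exome-wide rare/novel variant prioritization (workflow 1).

The chain per family:

1. a priori criteria (i)-(vii): exonic/splicing class, not synonymous,
   outside segmental duplications, CADD Phred >= 20, positive GERP score,
   shared by >= 2 affected family members, >= 2 of 5 damaging in-silico
   calls;
2. rare (subpopulation MAF <= 0.01) or novel (unknown MAF with predicted
   deleterious effect);
3. family comparison lists -> cross-family gene intersection (genes with a
   qualifying variant in >= 2 families);
4. family-specific co-segregation rules, with an overall gate requiring
   >= 4 affected carriers across >= 2 families per surviving gene.

Each decision is written to a :class:`~famprio.model.FilterTrace` so the
per-stage count ledger can be reconstructed exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .model import (
    AffectednessStatus,
    AnnotatedVariant,
    ConfigError,
    CosegRule,
    FilterConfig,
    FilterTrace,
    GenotypeMatrix,
    Pedigree,
    VariantKey,
)

__all__ = [
    "CRITERIA",
    "apply_a_priori_filters",
    "rare_or_novel_filter",
    "build_family_comparison_list",
    "cross_family_gene_intersection",
    "apply_coseg_rules",
    "run_workflow1",
    "Workflow1Result",
]

#: Criterion labels in the order they are applied (and traced).
CRITERIA = (
    "i_func_class",
    "ii_not_synonymous",
    "iii_not_segdup",
    "iv_cadd",
    "v_gerp",
    "vi_affected_sharing",
    "vii_damaging_predictors",
)


def _variant_predicates(
    v: AnnotatedVariant, config: FilterConfig
) -> list[tuple[str, bool, object]]:
    """The pure per-variant criteria (i)-(v) and (vii) with their evidence.

    Unknown CADD or GERP fails its criterion when ``unknown_scores_fail``
    (the default): only scored, predicted-deleterious variants are
    prioritized.
    """
    unknown_ok = not config.unknown_scores_fail
    cadd_pass = (v.cadd_phred >= config.cadd_min) if v.cadd_phred is not None else unknown_ok
    gerp_pass = (v.gerp > 0.0) if v.gerp is not None else unknown_ok
    return [
        ("i_func_class", v.func_class in config.allowed_func_classes, v.func_class),
        ("ii_not_synonymous", v.exonic_effect != "synonymous", v.exonic_effect),
        ("iii_not_segdup", not v.segdup, v.segdup),
        ("iv_cadd", cadd_pass, v.cadd_phred),
        ("v_gerp", gerp_pass, v.gerp),
        (
            "vii_damaging_predictors",
            v.n_damaging >= config.min_damaging_predictors,
            v.n_damaging,
        ),
    ]


def apply_a_priori_filters(
    variants: Sequence[AnnotatedVariant],
    genotypes: GenotypeMatrix,
    affected_ids: Sequence[str],
    config: FilterConfig,
    family_id: str = "",
    trace: Optional[FilterTrace] = None,
) -> tuple[list[AnnotatedVariant], FilterTrace]:
    """Apply criteria (i)-(vii) for one family.

    ``affected_ids`` are the family's genotyped-eligible affected members
    (NV-IQ-excluded individuals must already be removed).  The sharing
    criterion (vi) counts distinct affected carriers with a called genotype;
    missing genotypes never count as reference.
    """
    if not affected_ids:
        raise ConfigError("apply_a_priori_filters requires a nonempty affected set")
    trace = trace if trace is not None else FilterTrace()
    kept: list[AnnotatedVariant] = []
    for v in variants:
        checks = _variant_predicates(v, config)
        n_sharers = len(genotypes.carriers(v.key, among=affected_ids))
        checks.insert(
            5, ("vi_affected_sharing", n_sharers >= config.min_affected_sharers, n_sharers)
        )
        ok = True
        for name, passed, value in checks:
            trace.record(family_id, v.key, name, passed, value)
            ok = ok and passed
        if ok:
            kept.append(v)
    return kept, trace


def rare_or_novel_filter(
    variants: Sequence[AnnotatedVariant],
    family_subpop: str,
    config: FilterConfig,
    family_id: str = "",
    trace: Optional[FilterTrace] = None,
) -> list[AnnotatedVariant]:
    """Keep rare variants (subpop MAF <= threshold) plus novel ones.

    Novel means unknown frequency in the family's subpopulation together
    with a predicted deleterious effect (>= the configured number of
    damaging in-silico calls).  Unknown MAF is never coerced to zero.
    """
    if not family_subpop:
        raise ConfigError("family subpopulation is unresolvable")
    trace = trace if trace is not None else FilterTrace()
    kept = []
    for v in variants:
        maf = v.maf_in(family_subpop)
        if maf is None:
            passed = v.n_damaging >= config.min_damaging_predictors
            value = f"novel(n_damaging={v.n_damaging})"
        else:
            passed = maf <= config.rare_maf_max
            value = maf
        trace.record(family_id, v.key, "rare_or_novel", passed, value)
        if passed:
            kept.append(v)
    return kept


def _sorted_variants(variants: Sequence[AnnotatedVariant]) -> list[AnnotatedVariant]:
    return sorted(variants, key=lambda v: (v.gene, v.chrom, v.pos, v.ref, v.alt))


def build_family_comparison_list(
    per_family: Mapping[str, Sequence[AnnotatedVariant]],
) -> dict[str, list[AnnotatedVariant]]:
    """Deterministic per-family comparison lists, sorted by (gene, chrom, pos)."""
    return {fam: _sorted_variants(vs) for fam, vs in sorted(per_family.items())}


def cross_family_gene_intersection(
    family_lists: Mapping[str, Sequence[AnnotatedVariant]],
    min_families: int = 2,
    gene_blocklist: frozenset = frozenset(),
) -> set[str]:
    """Genes with a qualifying variant in at least ``min_families`` families."""
    if len(family_lists) < 2:
        raise ConfigError("cross-family intersection needs >= 2 family lists")
    fams_by_gene: dict[str, set[str]] = {}
    for fam, variants in family_lists.items():
        for v in variants:
            fams_by_gene.setdefault(v.gene, set()).add(fam)
    return {
        g
        for g, fams in fams_by_gene.items()
        if len(fams) >= min_families and g not in gene_blocklist
    }


def coseg_ok(
    variant_key: VariantKey,
    genotypes: GenotypeMatrix,
    statuses: Mapping[str, AffectednessStatus],
    pedigree: Pedigree,
    rule: CosegRule,
) -> bool:
    """Evaluate one family's co-segregation rule for one variant.

    Individuals with missing genotypes or NV-IQ exclusion are left out of
    both the required-carrier and the unaffected-carrier counts.
    """
    for ind in rule.required_carriers:
        if ind not in pedigree:
            raise ConfigError(
                f"coseg rule for {rule.family_id} references unknown individual {ind!r}"
            )
    members = [m.id for m in pedigree.members]
    if rule.branch is not None:
        members = [m.id for m in pedigree.members if m.branch_label == rule.branch]
    eligible = [
        i
        for i in members
        if i in statuses and not statuses[i].excluded_low_nviq
    ]
    genotyped = set(genotypes.genotyped(variant_key, among=eligible))
    carriers = set(genotypes.carriers(variant_key, among=eligible))
    affected = {i for i in genotyped if statuses[i].combined_affected == "yes"}
    unaffected = {i for i in genotyped if statuses[i].combined_affected == "no"}
    if rule.require_all_affected_carry and not affected <= carriers:
        return False
    if len(carriers & unaffected) > rule.max_unaffected_carriers:
        return False
    required = set(rule.required_carriers)
    if required and not required <= carriers:
        return False
    return True


def apply_coseg_rules(
    family_lists: Mapping[str, Sequence[AnnotatedVariant]],
    genotypes: GenotypeMatrix,
    statuses_by_family: Mapping[str, Mapping[str, AffectednessStatus]],
    pedigrees: Mapping[str, Pedigree],
    rules: Mapping[str, CosegRule],
    config: FilterConfig,
    trace: Optional[FilterTrace] = None,
) -> tuple[dict[str, list[AnnotatedVariant]], set[str]]:
    """Family co-segregation lists plus the overall surviving gene set.

    A gene survives overall only when, across >= ``config.min_families``
    families whose co-segregating lists contain it, at least
    ``config.min_total_affected_carriers`` affected individuals carry a
    variant on it.
    """
    trace = trace if trace is not None else FilterTrace()
    coseg_lists: dict[str, list[AnnotatedVariant]] = {}
    carriers_by_gene: dict[str, dict[str, set[str]]] = {}
    for fam, variants in sorted(family_lists.items()):
        rule = rules.get(fam, CosegRule(family_id=fam))
        statuses = statuses_by_family[fam]
        ped = pedigrees[fam]
        kept = []
        for v in variants:
            ok = coseg_ok(v.key, genotypes, statuses, ped, rule)
            trace.record(fam, v.key, "coseg", ok, None)
            if ok:
                kept.append(v)
                aff = [
                    i
                    for i in genotypes.carriers(v.key, among=ped.member_ids)
                    if i in statuses
                    and statuses[i].combined_affected == "yes"
                    and not statuses[i].excluded_low_nviq
                ]
                carriers_by_gene.setdefault(v.gene, {}).setdefault(fam, set()).update(aff)
        coseg_lists[fam] = _sorted_variants(kept)
    final_genes = {
        g
        for g, by_fam in carriers_by_gene.items()
        if len(by_fam) >= config.min_families
        and sum(len(c) for c in by_fam.values()) >= config.min_total_affected_carriers
    }
    return coseg_lists, final_genes


@dataclass
class Workflow1Result:
    comparison_lists: dict[str, list[AnnotatedVariant]]
    shared_genes: set[str]
    coseg_lists: dict[str, list[AnnotatedVariant]]
    final_genes: set[str]
    final_variants: dict[str, list[AnnotatedVariant]]
    trace: FilterTrace
    ledger: dict[str, dict[str, int]] = field(default_factory=dict)


def run_workflow1(
    variants: Sequence[AnnotatedVariant],
    genotypes: GenotypeMatrix,
    statuses_by_family: Mapping[str, Mapping[str, AffectednessStatus]],
    pedigrees: Mapping[str, Pedigree],
    config: FilterConfig,
    rules: Optional[Mapping[str, CosegRule]] = None,
    default_subpop: Optional[str] = None,
) -> Workflow1Result:
    """Execute the full exome-wide prioritization cascade over all families."""
    from .phenotyping import affected_ids as _affected

    rules = rules or {}
    trace = FilterTrace()
    ledger: dict[str, dict[str, int]] = {}
    per_family: dict[str, list[AnnotatedVariant]] = {}
    for fam in sorted(pedigrees):
        statuses = statuses_by_family.get(fam, {})
        aff = _affected(dict(statuses))
        ledger[fam] = {"input": len(variants)}
        if not aff:
            per_family[fam] = []
            ledger[fam]["a_priori"] = 0
            ledger[fam]["rare_or_novel"] = 0
            continue
        fam_members = set(pedigrees[fam].member_ids)
        aff = [i for i in aff if i in fam_members]
        if len(aff) < config.min_affected_sharers:
            per_family[fam] = []
            ledger[fam]["a_priori"] = 0
            ledger[fam]["rare_or_novel"] = 0
            continue
        subpop = (
            config.subpopulation_by_family.get(fam)
            or default_subpop
            or pedigrees[fam].members[0].subpopulation
        )
        surv, _ = apply_a_priori_filters(
            variants, genotypes, aff, config, family_id=fam, trace=trace
        )
        ledger[fam]["a_priori"] = len(surv)
        surv = rare_or_novel_filter(surv, subpop, config, family_id=fam, trace=trace)
        ledger[fam]["rare_or_novel"] = len(surv)
        per_family[fam] = surv

    comparison = build_family_comparison_list(per_family)
    shared = cross_family_gene_intersection(
        comparison, config.min_families, config.gene_blocklist
    )
    on_shared = {
        fam: [v for v in vs if v.gene in shared] for fam, vs in comparison.items()
    }
    for fam in ledger:
        ledger[fam]["on_shared_genes"] = len(on_shared.get(fam, []))
    coseg_lists, final_genes = apply_coseg_rules(
        on_shared, genotypes, statuses_by_family, pedigrees, rules, config, trace
    )
    final_variants = {
        fam: [v for v in vs if v.gene in final_genes]
        for fam, vs in coseg_lists.items()
    }
    for fam in ledger:
        ledger[fam]["coseg"] = len(coseg_lists.get(fam, []))
        ledger[fam]["final"] = len(final_variants.get(fam, []))
    return Workflow1Result(
        comparison_lists=comparison,
        shared_genes=shared,
        coseg_lists=coseg_lists,
        final_genes=final_genes,
        final_variants=final_variants,
        trace=trace,
        ledger=ledger,
    )
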