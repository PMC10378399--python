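"""Targeted candidate-gene prioritization (workflow 2) and region lookup.

Workflow 2 re-screens each family's variants against a user-supplied list
of previously reported candidate genes at a relaxed frequency bound
(subpopulation MAF < 0.07).  Cross-family sharing is *not* required — a hit
on a published candidate already has externally reported support — but the
within-family criteria stand: non-synonymous, outside segmental
duplications, CADD/GERP/predictor thresholds, >= 2 affected carriers and no
unaffected carriers (the default co-segregation-style guard).
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

from .model import (
    AnnotatedVariant,
    ConfigError,
    FilterConfig,
    FilterTrace,
    GenotypeMatrix,
    ValidationError,
)

__all__ = ["candidate_gene_filter", "region_lookup", "read_gene_list", "read_regions"]


def read_gene_list(path) -> list[str]:
    """One gene symbol per line; blank lines and ``#`` comments ignored."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line)
    return genes


def candidate_gene_filter(
    variants: Sequence[AnnotatedVariant],
    genotypes: GenotypeMatrix,
    affected_ids: Sequence[str],
    gene_list: Iterable[str],
    config: FilterConfig,
    unaffected_ids: Sequence[str] = (),
    family_subpop: str = "NFE",
    family_id: str = "",
    trace: Optional[FilterTrace] = None,
) -> list[AnnotatedVariant]:
    """Prioritize variants on listed candidate genes for one family.

    A variant is retained when it (a) lies on a listed gene, (b) has
    subpopulation MAF strictly below ``config.candidate_maf_max`` (unknown
    MAF passes by default, consistent with the novel-variant handling in
    workflow 1), (c) is non-synonymous, outside segmental duplications, in
    an allowed functional class, and meets the CADD/GERP/predictor
    thresholds, and (d) is carried by >= ``config.min_affected_sharers``
    affected members with at most ``config.max_unaffected_carriers``
    unaffected carriers.
    """
    genes = set(gene_list)
    if not genes:
        raise ConfigError("candidate gene list is empty")
    from .workflow1 import _variant_predicates

    trace = trace if trace is not None else FilterTrace()
    kept = []
    for v in variants:
        maf = v.maf_in(family_subpop)
        if maf is None:
            maf_ok = config.unknown_maf_passes_candidate
        else:
            maf_ok = maf < config.candidate_maf_max
        checks = [("on_candidate_gene", v.gene in genes, v.gene),
                  ("candidate_maf", maf_ok, maf)]
        checks.extend(_variant_predicates(v, config))
        n_aff = len(genotypes.carriers(v.key, among=affected_ids))
        n_unaff = len(genotypes.carriers(v.key, among=unaffected_ids))
        checks.append(
            ("vi_affected_sharing", n_aff >= config.min_affected_sharers, n_aff)
        )
        checks.append(
            ("no_unaffected_carriers", n_unaff <= config.max_unaffected_carriers, n_unaff)
        )
        ok = True
        for name, passed, value in checks:
            trace.record(family_id, v.key, f"w2_{name}", passed, value)
            ok = ok and passed
        if ok:
            kept.append(v)
    return sorted(kept, key=lambda v: (v.gene, v.chrom, v.pos, v.ref, v.alt))


def read_regions(path) -> list[tuple[str, int, int]]:
    """BED-like TSV of chrom/start/end, 1-based fully inclusive in this dialect."""
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, start, end = line.split("\t")[:3]
            regions.append((chrom, int(start), int(end)))
    return regions


def region_lookup(
    variants: Sequence[AnnotatedVariant],
    regions: Sequence[tuple[str, int, int]],
) -> list[tuple[AnnotatedVariant, tuple[str, int, int]]]:
    """Variants whose position falls inside any region (1-based inclusive).

    Returns (variant, matching region) pairs; a variant inside several
    regions is reported once per region, in input order.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in regions:
        if start > end:
            raise ValidationError(f"region start > end: {chrom}:{start}-{end}")
        # IntervalTree is half-open; +1 makes the end position inclusive.
        trees.setdefault(chrom, IntervalTree()).addi(start, end + 1, (chrom, start, end))
    hits = []
    for v in variants:
        tree = trees.get(v.chrom)
        if tree is None:
            continue
        for iv in sorted(tree[v.pos], key=lambda i: (i.begin, i.end)):
            hits.append((v, iv.data))
    return hits
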