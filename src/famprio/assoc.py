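"""Proband-vs-reference burden tests, carrier tallies, causality rules,
and the family-clustered two-sample t procedure.

The burden comparison is an exact two-sided Fisher test on a 2x2
allele-count table: carrier vs non-carrier alleles in the study probands
against the same split in a population reference (reference allele count is
reconstructed as ``round(MAF x AN)`` when only a frequency is published).
Two-sided p-values follow the minimum-likelihood convention — the sum of
probabilities of all tables with fixed margins no more probable than the
observed one — matching common statistical software.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .model import (
    BurdenTable,
    CausalityEvidence,
    ClassificationVerdict,
    ValidationError,
    VariantKey,
)

__all__ = [
    "fisher_burden_test",
    "burden_table_from_maf",
    "tally_additional_probands",
    "TallyResult",
    "classify_causality",
    "clustered_t_test",
    "ClusteredTResult",
]

#: Nominal reference allele number (gnomAD v2.1.1 NFE exomes scale) used to
#: reconstruct reference allele counts from published frequencies.
DEFAULT_REFERENCE_AN = 113_770


def fisher_burden_test(table: BurdenTable) -> float:
    """Exact two-sided Fisher p for a proband-vs-reference allele table."""
    if table.total_alleles_probands == 0 or table.total_alleles_ref == 0:
        raise ValidationError("Fisher test undefined with a zero allele total")
    a = table.carrier_alleles_probands
    b = table.total_alleles_probands - a
    c = table.carrier_alleles_ref
    d = table.total_alleles_ref - c
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue)


def burden_table_from_maf(
    carrier_alleles_probands: int,
    total_alleles_probands: int,
    reference_maf: float,
    reference_an: int = DEFAULT_REFERENCE_AN,
    reference_ac: Optional[int] = None,
) -> BurdenTable:
    """Build the 2x2 table from a published reference frequency.

    ``reference_ac`` overrides the ``round(MAF x AN)`` reconstruction, e.g.
    for a variant never observed in the reference subpopulation (AC = 0).
    """
    ac = int(round(reference_maf * reference_an)) if reference_ac is None else reference_ac
    return BurdenTable(
        carrier_alleles_probands=carrier_alleles_probands,
        total_alleles_probands=total_alleles_probands,
        carrier_alleles_ref=ac,
        total_alleles_ref=reference_an,
    )


@dataclass
class TallyResult:
    """Distinct-proband carrier tally with an affectedness breakdown."""

    n_total: int
    n_affected: int
    n_unaffected: int
    ids: frozenset[str]
    per_variant: dict = field(default_factory=dict)


def tally_additional_probands(
    carriers_by_variant: Mapping[object, Iterable[tuple[str, bool]]],
) -> TallyResult:
    """Count distinct probands carrying any listed variant.

    ``carriers_by_variant`` maps a variant identifier to ``(proband_id,
    affected)`` pairs.  A proband carrying variants on several genes is
    counted once; the affected/unaffected breakdown is also over distinct
    IDs.  The tally is a pure set union, hence idempotent and order
    invariant.
    """
    status: dict[str, bool] = {}
    per_variant = {}
    for var, carriers in carriers_by_variant.items():
        pairs = list(carriers)
        per_variant[var] = len({pid for pid, _ in pairs})
        for pid, affected in pairs:
            if pid in status and status[pid] != bool(affected):
                raise ValidationError(
                    f"proband {pid!r} listed with inconsistent affectedness"
                )
            status[pid] = bool(affected)
    n_aff = sum(1 for a in status.values() if a)
    return TallyResult(
        n_total=len(status),
        n_affected=n_aff,
        n_unaffected=len(status) - n_aff,
        ids=frozenset(status),
        per_variant=per_variant,
    )


def classify_causality(
    variant_key: VariantKey,
    evidence: CausalityEvidence,
    maf_max: float = 0.05,
    min_damaging: int = 2,
    require_replication_for_p: bool = True,
    unaffected_carrier_benign: bool = True,
) -> ClassificationVerdict:
    """Rule-based pathogenic / likely-pathogenic / benign verdict.

    The six criteria: (1) MAF < 0.05; (2) co-segregating OR carried by more
    than one proband OR a significant amino-acid structural change; (3)
    positive GERP score; (4) CADD Phred >= 20; (5) >= 2 of 5 damaging
    in-silico calls; (6) an amino-acid size or charge change in the
    structural annotation.  A variant missing any of (1), (3)-(6) is benign,
    as is (by default) one carried by any affected-range-unaffected
    individual — carriage by unaffected family members or probands is direct
    evidence against causality.  Meeting all six yields pathogenic when
    replication support exists (>= 2 discovery families or >= 1 additional
    proband carrier); with within-family evidence only, the verdict is
    likely pathogenic, reflecting that limited phenotype availability caps
    the attainable co-segregation evidence.
    """
    e = evidence
    structural_change = (
        e.hope_size_change in ("increase", "decrease")
        or e.hope_charge_change not in ("none", "none_reported")
    )
    # Probands carrying = one per discovery family plus the additional ones.
    carried_by_probands = e.n_discovery_families + e.n_additional_probands
    criteria = {
        1: e.maf is not None and e.maf < maf_max,
        2: e.coseg_confirmed or carried_by_probands > 1 or structural_change,
        3: e.gerp_positive,
        4: e.cadd_ge_threshold,
        5: e.n_damaging >= min_damaging,
        6: structural_change,
    }
    notes = []
    if not all(criteria[k] for k in (1, 3, 4, 5, 6)):
        verdict = "B"
        failed = [k for k in (1, 3, 4, 5, 6) if not criteria[k]]
        notes.append(f"criteria failed: {failed}")
    elif unaffected_carrier_benign and e.n_unaffected_carriers > 0:
        verdict = "B"
        notes.append(
            f"{e.n_unaffected_carriers} unaffected carrier(s): evidence against causality"
        )
    else:
        replicated = (
            e.n_discovery_families >= 2 or e.n_additional_probands >= 1
        )
        if criteria[2] and (replicated or not require_replication_for_p):
            verdict = "P"
        else:
            verdict = "Likely P"
            if not replicated:
                notes.append("no replication beyond the discovery family")
    return ClassificationVerdict(
        variant_key=variant_key,
        verdict=verdict,
        criteria_fired=criteria,
        evidence_notes="; ".join(notes),
    )


@dataclass
class ClusteredTResult:
    statistic: float
    df: float
    pvalue: float
    n_clusters: tuple[int, int]


def clustered_t_test(
    values: Sequence[float],
    group_labels: Sequence,
    cluster_labels: Sequence,
) -> ClusteredTResult:
    """Two-sample t test accounting for variance at the cluster (family) level.

    Observations are collapsed to unweighted cluster means and the two
    groups of cluster means are compared with Welch's t and
    Satterthwaite-approximated degrees of freedom.  Siblings share a family
    environment, so the family mean is the independent sampling unit; when
    every cluster holds a single observation this reduces exactly to Welch's
    t on the raw values.
    """
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    cluster_labels = np.asarray(cluster_labels)
    if not (len(values) == len(group_labels) == len(cluster_labels)):
        raise ValidationError("values, group_labels, cluster_labels lengths differ")
    groups = sorted(set(group_labels.tolist()))
    if len(groups) != 2:
        raise ValidationError(f"expected exactly 2 groups, got {groups}")
    means = []
    for g in groups:
        mask = group_labels == g
        clusters = set(cluster_labels[mask].tolist())
        overlap = clusters & set(cluster_labels[~mask].tolist())
        if overlap:
            raise ValidationError(f"cluster(s) {sorted(overlap)} span both groups")
        if len(clusters) < 2:
            raise ValidationError(
                f"group {g!r} has {len(clusters)} cluster(s); >= 2 required"
            )
        m = [
            float(values[mask & (cluster_labels == c)].mean())
            for c in sorted(clusters, key=str)
        ]
        means.append(np.array(m))
    res = stats.ttest_ind(means[0], means[1], equal_var=False)
    return ClusteredTResult(
        statistic=float(res.statistic),
        df=float(res.df),
        pvalue=float(res.pvalue),
        n_clusters=(len(means[0]), len(means[1])),
    )
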