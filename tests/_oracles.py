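"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — direct set algebra, explicit loops
and exact rational arithmetic — and shares no code with the package's
implementations it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np

from famprio.model import (
    AffectednessStatus,
    AnnotatedVariant,
    FilterConfig,
    GenotypeMatrix,
    Individual,
    Pedigree,
)

# ---------------------------------------------------------------------------
# exact Fisher two-sided p by full hypergeometric enumeration


def fisher_enumeration(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher p for [[a,b],[c,d]] by exact-Fraction enumeration.

    Returns (strict, slack) sums: tables with probability strictly <= the
    observed one, and with the 1+1e-7 relative tie slack common in
    floating-point implementations.  The true convention value lies between
    the two.
    """
    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    denom = comb(n, c1)
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    probs = {
        k: Fraction(comb(r1, k) * comb(n - r1, c1 - k), denom)
        for k in range(lo, hi + 1)
    }
    p_obs = probs[a]
    slack_bound = p_obs * Fraction(10_000_001, 10_000_000)
    strict = sum(p for p in probs.values() if p <= p_obs)
    slack = sum(p for p in probs.values() if p <= slack_bound)
    return float(strict), float(slack)


# ---------------------------------------------------------------------------
# brute-force workflow 1


def _affected(statuses: dict[str, AffectednessStatus]) -> list[str]:
    return [
        i
        for i, s in statuses.items()
        if s.combined_affected == "yes" and not s.excluded_low_nviq
    ]


def _unaffected(statuses: dict[str, AffectednessStatus]) -> list[str]:
    return [
        i
        for i, s in statuses.items()
        if s.combined_affected == "no" and not s.excluded_low_nviq
    ]


def _dosage(gm: GenotypeMatrix, ind: str, key) -> int:
    if ind not in gm.individuals:
        return -1
    return gm.dosage_of(ind, key)


def oracle_workflow1(
    variants: list[AnnotatedVariant],
    genotypes: GenotypeMatrix,
    statuses_by_family: dict[str, dict[str, AffectednessStatus]],
    pedigrees: dict[str, Pedigree],
    config: FilterConfig,
) -> dict:
    """Direct set-algebra evaluation of the whole exome-wide workflow.

    Builds per-criterion truth sets per family, intersects them, applies
    the rare-or-novel screen, the cross-family gene rule, the default
    co-segregation predicate and the carriers-across-families gate.
    """
    per_family: dict[str, set] = {}
    for fam, ped in pedigrees.items():
        st = dict(statuses_by_family.get(fam, {}))
        aff = [i for i in _affected(st) if i in ped.member_ids]
        if len(aff) < config.min_affected_sharers:
            per_family[fam] = set()
            continue
        subpop = ped.members[0].subpopulation
        sets = []
        sets.append({v.key for v in variants if v.func_class in config.allowed_func_classes})
        sets.append({v.key for v in variants if v.exonic_effect != "synonymous"})
        sets.append({v.key for v in variants if not v.segdup})
        sets.append({
            v.key for v in variants
            if v.cadd_phred is not None and v.cadd_phred >= config.cadd_min
        })
        sets.append({v.key for v in variants if v.gerp is not None and v.gerp > 0})
        sets.append({
            v.key for v in variants
            if sum(1 for i in aff if _dosage(genotypes, i, v.key) >= 1)
            >= config.min_affected_sharers
        })
        sets.append({
            v.key for v in variants
            if sum(1 for c in v.predictor_calls.values() if c == "damaging")
            >= config.min_damaging_predictors
        })
        rare = set()
        for v in variants:
            maf = v.maf.get(subpop)
            if maf is None:
                if sum(1 for c in v.predictor_calls.values() if c == "damaging") >= config.min_damaging_predictors:
                    rare.add(v.key)
            elif maf <= config.rare_maf_max:
                rare.add(v.key)
        sets.append(rare)
        keep = set.intersection(*sets)
        per_family[fam] = keep

    by_key = {v.key: v for v in variants}
    genes_in_fam = {
        fam: {by_key[k].gene for k in keys} for fam, keys in per_family.items()
    }
    shared_genes = set()
    for fam, genes in genes_in_fam.items():
        for g in genes:
            if g in config.gene_blocklist:
                continue
            others = sum(1 for f2, g2 in genes_in_fam.items() if g in g2)
            if others >= config.min_families:
                shared_genes.add(g)

    coseg: dict[str, set] = {}
    gene_support: dict[str, dict[str, set]] = {}
    for fam, keys in per_family.items():
        ped = pedigrees[fam]
        st = dict(statuses_by_family.get(fam, {}))
        aff = set(_affected(st)) & set(ped.member_ids)
        unaff = set(_unaffected(st)) & set(ped.member_ids)
        ok_keys = set()
        for k in keys:
            if by_key[k].gene not in shared_genes:
                continue
            genotyped_aff = {i for i in aff if _dosage(genotypes, i, k) >= 0}
            genotyped_unaff = {i for i in unaff if _dosage(genotypes, i, k) >= 0}
            carriers_aff = {i for i in genotyped_aff if _dosage(genotypes, i, k) >= 1}
            carriers_unaff = {i for i in genotyped_unaff if _dosage(genotypes, i, k) >= 1}
            if genotyped_aff != carriers_aff:
                continue  # a genotyped affected member does not carry
            if carriers_unaff:
                continue
            ok_keys.add(k)
            gene_support.setdefault(by_key[k].gene, {}).setdefault(fam, set()).update(
                carriers_aff
            )
        coseg[fam] = ok_keys
    final_genes = {
        g
        for g, by_fam in gene_support.items()
        if len(by_fam) >= config.min_families
        and sum(len(s) for s in by_fam.values()) >= config.min_total_affected_carriers
    }
    final = {
        fam: {k for k in keys if by_key[k].gene in final_genes}
        for fam, keys in coseg.items()
    }
    return {
        "comparison": per_family,
        "shared_genes": shared_genes,
        "coseg": coseg,
        "final_genes": final_genes,
        "final": final,
    }


# ---------------------------------------------------------------------------
# random mini-cohorts for oracle equivalence


def random_mini_cohort(rng: np.random.Generator, n_families: int = 3, max_variants: int = 50):
    """A small random cohort with adversarial annotation/genotype draws.

    Pass probabilities sit near the thresholds so every predicate exercises
    both branches; genotypes include missingness; statuses include unknowns
    and NV-IQ exclusions.
    """
    n_var = int(rng.integers(1, max_variants + 1))
    genes = [f"G{int(rng.integers(0, max(2, n_var // 2)))}" for _ in range(n_var)]
    variants = []
    for j in range(n_var):
        maf_known = rng.random() < 0.8
        variants.append(
            AnnotatedVariant(
                chrom=str(int(rng.integers(1, 23))),
                pos=j + 1,
                ref="A",
                alt="G",
                gene=genes[j],
                func_class=str(rng.choice(["exonic", "splicing", "intronic", "UTR"])),
                exonic_effect=str(rng.choice(["nonsynonymous", "synonymous", "stopgain"])),
                segdup=bool(rng.random() < 0.2),
                cadd_phred=None if rng.random() < 0.1 else float(rng.uniform(15, 25)),
                gerp=None if rng.random() < 0.1 else float(rng.uniform(-2, 2)),
                predictor_calls={
                    p: str(rng.choice(["damaging", "tolerated", "unknown"]))
                    for p in ("SIFT", "PolyPhen2", "MutationAssessor", "PROVEAN", "MutationTaster")
                },
                maf=(
                    {"NFE": float(rng.uniform(0, 0.02)), "AFR": float(rng.uniform(0, 0.02))}
                    if maf_known
                    else {}
                ),
            )
        )
    pedigrees = {}
    statuses = {}
    all_ids = []
    for f in range(n_families):
        fam = f"FAM{f}"
        father, mother = f"{fam}_F", f"{fam}_M"
        members = [
            Individual(father, sex="male"),
            Individual(mother, sex="female"),
        ]
        for k in range(int(rng.integers(2, 5))):
            members.append(
                Individual(f"{fam}_C{k}", father_id=father, mother_id=mother)
            )
        pedigrees[fam] = Pedigree(fam, members)
        st = {}
        for m in members:
            combined = str(rng.choice(["yes", "no", "unknown"], p=[0.4, 0.3, 0.3]))
            st[m.id] = AffectednessStatus(
                individual_id=m.id,
                combined_affected=combined,
                excluded_low_nviq=bool(rng.random() < 0.1),
            )
        statuses[fam] = st
        all_ids.extend(m.id for m in members)
    dosage = rng.choice([-1, 0, 1, 2], size=(len(all_ids), n_var), p=[0.1, 0.55, 0.25, 0.1])
    gm = GenotypeMatrix(all_ids, [v.key for v in variants], dosage.astype(np.int8))
    return variants, gm, statuses, pedigrees
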