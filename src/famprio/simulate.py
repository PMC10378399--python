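"""Synthetic cohort generator: pedigrees, genotypes, annotations, phenotypes.

The generator emulates the study design the pipeline assumes: a handful of
multi-generation families ascertained for predominance of a dichotomized
grammar-impairment phenotype, exome-scale annotated variant tables, one or
more planted rare variants whose carriers are affected with penetrance
``f1`` (non-carriers with phenocopy rate ``f0``), and partial phenotype
availability — only members inside the instrument's 3;0-8;11 age window
receive grammar scores, so parents and grandparents stay status-unknown,
exactly the data pattern that motivates the configurable co-segregation
rules.

Defaults mirror the emulated study scale: eight families (one of African
ancestry, the rest non-Finnish European), three-generation two-branch
pedigrees, 20,000 background exonic variants, penetrance 0.8 and phenocopy
rate 0.07 (the prevalence of specific language impairment in English-speaking
populations).  Planted families are *ascertained*: transmission and
phenotypes are redrawn until at least ``min_planted_carriers`` scored,
non-excluded affected carriers exist, mirroring how study families are
selected for informativeness.

Everything is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .model import (
    MISSING,
    PREDICTORS,
    AnnotatedVariant,
    GenotypeMatrix,
    Individual,
    Pedigree,
    ValidationError,
    VariantKey,
)
from .phenotyping import AGE_MAX_MONTHS, AGE_MIN_MONTHS, CriterionTable
from .model import PhenotypeRecord

__all__ = [
    "FamilyTemplate",
    "PlantedVariant",
    "CohortSpec",
    "SimulatedCohort",
    "template_size",
    "simulate_pedigree",
    "gene_drop",
    "simulate_annotations",
    "simulate_phenotypes",
    "simulate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class FamilyTemplate:
    """Pedigree shape: founder couple, optional branches, sibships."""

    generations: int = 3
    n_branches: int = 2
    sibship: int = 2


def template_size(template: FamilyTemplate) -> int:
    """Closed-form member count for a template.

    Two generations: founder couple plus ``sibship`` children.  Three
    generations: founder couple plus, per branch, one of their children,
    a married-in spouse, and ``sibship`` grandchildren.
    """
    t = template
    if t.sibship < 1 or t.n_branches < 1:
        raise ValidationError("template needs sibship >= 1 and n_branches >= 1")
    if t.generations == 2:
        return 2 + t.sibship
    if t.generations == 3:
        return 2 + t.n_branches * (2 + t.sibship)
    raise ValidationError(f"unsupported generations: {t.generations}")


@dataclass(frozen=True)
class PlantedVariant:
    """A causal variant planted into selected families.

    ``families`` are cohort family indices whose scored members are
    ascertained to include affected carriers; ``maf`` is the founder /
    reference subpopulation allele frequency; ``f1``/``f0`` are penetrance
    and phenocopy rate of the liability threshold model.
    """

    gene: str = "PLANTED_1"
    maf: float = 0.005
    f1: float = 0.8
    f0: float = 0.07
    families: tuple[int, ...] = (0, 1)
    profile: str = "causal"

    def __post_init__(self) -> None:
        if not (0.0 <= self.f0 <= self.f1 <= 1.0):
            raise ValidationError("need 0 <= f0 <= f1 <= 1")
        if not (0.0 <= self.maf <= 1.0):
            raise ValidationError("planted MAF out of [0,1]")


#: Background per-criterion pass rates (independent draws).
DEFAULT_PASS_RATES = {
    "func": 0.60,      # exonic/splicing class
    "nonsyn": 0.50,    # not synonymous
    "segdup": 0.95,    # outside segmental duplications
    "cadd": 0.15,      # CADD Phred >= 20
    "gerp": 0.60,      # positive GERP
    "damaging": 0.30,  # >= 2 of 5 damaging calls
    "rare": 0.40,      # subpopulation MAF <= 0.01
}


@dataclass
class CohortSpec:
    n_families: int = 8
    template: FamilyTemplate = field(default_factory=FamilyTemplate)
    planted: tuple[PlantedVariant, ...] = (PlantedVariant(),)
    n_background: int = 20_000
    missingness: float = 0.02
    age_window: tuple[int, int] = (AGE_MIN_MONTHS, AGE_MAX_MONTHS)
    criterion_cut: float = 80.0
    low_nviq_rate: float = 0.05
    discordant_rate: float = 0.10
    pass_rates: dict = field(default_factory=lambda: dict(DEFAULT_PASS_RATES))
    unknown_maf_rate: float = 0.05
    afr_families: tuple[int, ...] = (-1,)  # index -1 = last family
    min_planted_carriers: int = 2
    two_timepoint_rate: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("missingness", "low_nviq_rate", "discordant_rate",
                     "unknown_maf_rate", "two_timepoint_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} out of [0,1]: {v}")
        for p in self.planted:
            for idx in p.families:
                if not (-self.n_families <= idx < self.n_families):
                    raise ValidationError(
                        f"planted family index {idx} out of range for "
                        f"{self.n_families} families"
                    )

    def family_subpop(self, index: int) -> str:
        afr = {i % self.n_families for i in self.afr_families}
        return "AFR" if index in afr else "NFE"


@dataclass
class SimulatedCohort:
    spec: CohortSpec
    variants: list[AnnotatedVariant]
    genotypes: GenotypeMatrix
    pedigrees: dict[str, Pedigree]
    phenotypes: list[PhenotypeRecord]
    truth: dict


# ---------------------------------------------------------------------------
# pedigree


def simulate_pedigree(
    template: FamilyTemplate, family_id: str, subpop: str = "NFE"
) -> Pedigree:
    """Deterministic pedigree instantiation of a template."""
    size = template_size(template)  # validates the template
    members: list[Individual] = []
    f1 = f"{family_id}_G1F"
    m1 = f"{family_id}_G1M"
    members.append(Individual(f1, sex="male", subpopulation=subpop))
    members.append(Individual(m1, sex="female", subpopulation=subpop))
    if template.generations == 2:
        for k in range(1, template.sibship + 1):
            members.append(
                Individual(
                    f"{family_id}_C{k}",
                    father_id=f1,
                    mother_id=m1,
                    sex="male" if k % 2 else "female",
                    subpopulation=subpop,
                )
            )
    else:
        for b in range(1, template.n_branches + 1):
            branch = f"B{b}"
            parent_sex = "male" if b % 2 else "female"
            bp = f"{family_id}_{branch}P"
            sp = f"{family_id}_{branch}S"
            members.append(
                Individual(
                    bp, father_id=f1, mother_id=m1, sex=parent_sex,
                    branch_label=branch, subpopulation=subpop,
                )
            )
            members.append(
                Individual(
                    sp, sex="female" if parent_sex == "male" else "male",
                    branch_label=branch, subpopulation=subpop,
                )
            )
            father, mother = (bp, sp) if parent_sex == "male" else (sp, bp)
            for k in range(1, template.sibship + 1):
                members.append(
                    Individual(
                        f"{family_id}_{branch}C{k}",
                        father_id=father,
                        mother_id=mother,
                        sex="male" if k % 2 else "female",
                        branch_label=branch,
                        subpopulation=subpop,
                    )
                )
    ped = Pedigree(family_id, members)
    assert len(ped) == size
    return ped


def _topo_ids(pedigree: Pedigree) -> list[str]:
    g = nx.DiGraph()
    g.add_nodes_from(pedigree.member_ids)
    for m in pedigree.members:
        for p in (m.father_id, m.mother_id):
            if p is not None:
                g.add_edge(p, m.id)
    return list(nx.lexicographical_topological_sort(g))


# ---------------------------------------------------------------------------
# gene dropping


def gene_drop(
    pedigree: Pedigree,
    founder_freqs: np.ndarray,
    rng: np.random.Generator,
    missingness: float = 0.0,
    variant_keys: Optional[Sequence[VariantKey]] = None,
    forced_het: Optional[dict[int, str]] = None,
) -> GenotypeMatrix:
    """Drop variants through a pedigree by Mendelian transmission.

    Founders draw dosages from Hardy-Weinberg at each variant's founder
    frequency; every non-founder receives one allele per parent, each a
    Bernoulli(parental dosage / 2) draw.  ``forced_het`` pins named founders
    heterozygous at given variant columns (used for planting).  Missingness
    masks entries *after* transmission, so a masked genotype still shaped
    the phenotypes downstream.
    """
    freqs = np.asarray(founder_freqs, dtype=float)
    n_var = freqs.shape[0]
    order = _topo_ids(pedigree)
    idx = {ind: i for i, ind in enumerate(order)}
    dos = np.zeros((len(order), n_var), dtype=np.int8)
    for ind in order:
        member = pedigree.get(ind)
        i = idx[ind]
        if member.father_id is None and member.mother_id is None:
            dos[i] = rng.binomial(2, freqs)
        else:
            pat = dos[idx[member.father_id]] / 2.0
            mat = dos[idx[member.mother_id]] / 2.0
            dos[i] = (rng.random(n_var) < pat).astype(np.int8) + (
                rng.random(n_var) < mat
            ).astype(np.int8)
    if forced_het:
        # re-drop descendants of the forced founder for those columns
        for col, founder in forced_het.items():
            dos[idx[founder], col] = 1
            for ind in order:
                member = pedigree.get(ind)
                if member.father_id is None:
                    continue
                i = idx[ind]
                pat = dos[idx[member.father_id], col] / 2.0
                mat = dos[idx[member.mother_id], col] / 2.0
                dos[i, col] = int(rng.random() < pat) + int(rng.random() < mat)
    if missingness > 0:
        mask = rng.random(dos.shape) < missingness
        dos[mask] = MISSING
    # reorder rows to pedigree member order
    rows = [idx[m.id] for m in pedigree.members]
    keys = (
        list(variant_keys)
        if variant_keys is not None
        else [("sim", j + 1, "A", "G") for j in range(n_var)]
    )
    return GenotypeMatrix(pedigree.member_ids, keys, dos[rows, :])


# ---------------------------------------------------------------------------
# annotations


def _causal_annotation(
    key: VariantKey, gene: str, maf: float, rng: np.random.Generator
) -> AnnotatedVariant:
    n_dam = int(rng.integers(3, 6))
    calls = {p: ("damaging" if i < n_dam else "tolerated")
             for i, p in enumerate(PREDICTORS)}
    return AnnotatedVariant(
        chrom=key[0], pos=key[1], ref=key[2], alt=key[3],
        gene=gene,
        func_class="exonic",
        exonic_effect="nonsynonymous",
        segdup=False,
        cadd_phred=float(rng.uniform(25, 40)),
        gerp=float(rng.uniform(2, 6)),
        predictor_calls=calls,
        maf={"NFE": maf, "AFR": maf},
        hope_size_change="increase",
        hope_charge_change="pos_to_neu",
        aa_change="p.Sim1Var",
    )


def _background_annotation(
    key: VariantKey, gene: str, spec: CohortSpec, rng: np.random.Generator
) -> tuple[AnnotatedVariant, float]:
    """One background variant plus its hidden true founder frequency."""
    r = spec.pass_rates
    func = "exonic" if rng.random() < r["func"] else "intronic"
    effect = "nonsynonymous" if rng.random() < r["nonsyn"] else "synonymous"
    segdup = rng.random() >= r["segdup"]
    cadd = float(rng.uniform(20, 45)) if rng.random() < r["cadd"] else float(rng.uniform(0, 19.9))
    gerp = float(rng.uniform(0.1, 6)) if rng.random() < r["gerp"] else float(rng.uniform(-6, 0))
    n_dam = int(rng.integers(2, 6)) if rng.random() < r["damaging"] else int(rng.integers(0, 2))
    perm = rng.permutation(len(PREDICTORS))
    calls = {
        PREDICTORS[j]: ("damaging" if rank < n_dam else "tolerated")
        for rank, j in enumerate(perm)
    }
    if rng.random() < spec.unknown_maf_rate:
        maf = {}
        true_freq = float(np.exp(rng.uniform(np.log(1e-4), np.log(0.05))))
    else:
        if rng.random() < r["rare"]:
            f = float(np.exp(rng.uniform(np.log(1e-5), np.log(0.01))))
        else:
            f = float(rng.uniform(0.0101, 0.5))
        maf = {"NFE": f, "AFR": min(1.0, f * float(rng.uniform(0.5, 2.0)))}
        true_freq = f
    v = AnnotatedVariant(
        chrom=key[0], pos=key[1], ref=key[2], alt=key[3],
        gene=gene,
        func_class=func,
        exonic_effect=effect if func == "exonic" else "unknown",
        segdup=segdup,
        cadd_phred=cadd,
        gerp=gerp,
        predictor_calls=calls,
        maf=maf,
    )
    return v, true_freq


def simulate_annotations(
    spec: CohortSpec, rng: np.random.Generator
) -> tuple[list[AnnotatedVariant], np.ndarray]:
    """Annotation table for planted + background variants.

    Planted variants use the causal-like profile (pass every a priori
    threshold by construction); background variants draw each criterion
    independently at the configured pass rates.  Returns the variants and
    the hidden true founder frequencies used by the gene dropper.
    """
    variants: list[AnnotatedVariant] = []
    true_freqs = []
    for k, pv in enumerate(spec.planted):
        key = (str(k % 22 + 1), 1_000_000 + k, "A", "G")
        variants.append(_causal_annotation(key, pv.gene, pv.maf, rng))
        true_freqs.append(pv.maf)
    for j in range(spec.n_background):
        key = (str(j % 22 + 1), 2_000_000 + j, "C", "T")
        gene = f"BG{j // 2:06d}"
        v, f = _background_annotation(key, gene, spec, rng)
        variants.append(v)
        true_freqs.append(f)
    return variants, np.array(true_freqs)


# ---------------------------------------------------------------------------
# phenotypes


def _draw_probe_set(
    affected: bool, cut: float, rng: np.random.Generator, discordant: bool
) -> dict[str, float]:
    def below() -> float:
        return float(rng.uniform(max(0.0, cut - 30), cut - 2))

    def above() -> float:
        return float(rng.uniform(cut + 2, min(100.0, cut + 18)))

    if affected and discordant:
        # screener in the unaffected range, composite dragged below by be/do
        s = above()
        bedo = float(rng.uniform(0.0, max(0.0, 3 * (cut - 2) - 2 * s - 2)))
    elif affected:
        s = below()
        bedo = below()
    else:
        s = above()
        bedo = above()
    jitter = float(rng.uniform(0, min(2.0, 100 - s, s)))
    return {
        "third_person_singular": s + jitter * (1 if s + jitter <= 100 else 0),
        "past_tense": s - jitter,
        "be_do": min(100.0, max(0.0, bedo)),
    }


def simulate_phenotypes(
    pedigree: Pedigree,
    planted_dosages: dict[str, int],
    f1: float,
    f0: float,
    spec: CohortSpec,
    rng: np.random.Generator,
) -> list[PhenotypeRecord]:
    """Grammar-probe and standard-score records for the scorable members.

    Only the youngest generation falls inside the instrument's age window;
    carriers of any planted variant score below criterion with probability
    ``f1``, non-carriers with probability ``f0``.  Scores are drawn on the
    assigned side of the criterion, with a configurable fraction of
    affected children discordant (screener unaffected, composite affected).
    """
    lo, hi = spec.age_window
    cut = spec.criterion_cut
    records: list[PhenotypeRecord] = []
    for m in pedigree.members:
        is_child = m.father_id is not None and not pedigree.children_of(m.id)
        if not is_child:
            continue  # adults: no grammar phenotype available
        carrier = planted_dosages.get(m.id, 0) >= 1
        affected = rng.random() < (f1 if carrier else f0)
        discordant = affected and rng.random() < spec.discordant_rate
        low_nviq = rng.random() < spec.low_nviq_rate
        nviq = float(rng.uniform(70, 85)) if low_nviq else float(rng.uniform(86, 130))
        n_tp = 2 if rng.random() < spec.two_timepoint_rate else 1
        age = float(rng.uniform(lo, hi - 12 * (n_tp - 1)))
        for t in range(n_tp):
            shift = -15.0 if affected else 0.0
            records.append(
                PhenotypeRecord(
                    individual_id=m.id,
                    timepoint=age + 12 * t,
                    probe_scores=_draw_probe_set(affected, cut, rng, discordant),
                    omnibus_ss=float(np.clip(rng.normal(100 + shift, 15), 55, 145)),
                    recept_vocab_ss=float(np.clip(rng.normal(100 + shift, 15), 55, 145)),
                    nviq_ss=nviq,
                )
            )
    return records


# ---------------------------------------------------------------------------
# cohort assembly


def _scored_affected_carriers(
    pedigree: Pedigree,
    records: list[PhenotypeRecord],
    dosages: dict[str, int],
    spec: CohortSpec,
) -> int:
    from .phenotyping import (
        apply_nviq_exclusion,
        assign_affectedness_cohort,
    )

    table = CriterionTable.flat(spec.criterion_cut)
    statuses = assign_affectedness_cohort(records, table)
    statuses = apply_nviq_exclusion(statuses, records)
    return sum(
        1
        for ind, s in statuses.items()
        if s.combined_affected == "yes"
        and not s.excluded_low_nviq
        and dosages.get(ind, 0) >= 1
    )


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Generate a full cohort: annotations, pedigrees, genotypes, phenotypes.

    Planted families are redrawn (transmission of the planted column plus
    the family's phenotypes) until ascertainment holds: at least
    ``spec.min_planted_carriers`` scored, non-excluded affected carriers
    per planted variant.  All randomness flows from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    variants, true_freqs = simulate_annotations(spec, rng)
    keys = [v.key for v in variants]
    n_planted = len(spec.planted)
    planted_fams: dict[int, list[int]] = {}
    for k, pv in enumerate(spec.planted):
        for idx in pv.families:
            planted_fams.setdefault(idx % spec.n_families, []).append(k)

    pedigrees: dict[str, Pedigree] = {}
    blocks: list[np.ndarray] = []
    all_ids: list[str] = []
    phenotypes: list[PhenotypeRecord] = []
    truth_carriers: dict[str, list[str]] = {pv.gene: [] for pv in spec.planted}

    for fidx in range(spec.n_families):
        fam_id = f"F{fidx + 1:03d}"
        subpop = spec.family_subpop(fidx)
        ped = simulate_pedigree(spec.template, fam_id, subpop)
        pedigrees[fam_id] = ped
        max_tries = 500
        for attempt in range(max_tries):
            forced = {}
            for k in planted_fams.get(fidx, []):
                founder = ped.founders()[int(rng.integers(0, 2))].id
                forced[k] = founder
            gm = gene_drop(
                ped, true_freqs, rng, missingness=0.0, variant_keys=keys,
                forced_het=forced or None,
            )
            planted_dos = {
                ind: max(
                    (gm.dosage_of(ind, keys[k]) for k in range(n_planted)),
                    default=0,
                )
                for ind in ped.member_ids
            }
            # penetrance of the family's planted variant (first if several)
            if planted_fams.get(fidx):
                pv = spec.planted[planted_fams[fidx][0]]
                f1, f0 = pv.f1, pv.f0
            else:
                f1, f0 = (spec.planted[0].f1, spec.planted[0].f0) if spec.planted else (0.0, 0.07)
            records = simulate_phenotypes(ped, planted_dos, f1, f0, spec, rng)
            if not planted_fams.get(fidx):
                break
            ok = all(
                _scored_affected_carriers(
                    ped,
                    records,
                    {i: gm.dosage_of(i, keys[k]) for i in ped.member_ids},
                    spec,
                )
                >= spec.min_planted_carriers
                for k in planted_fams[fidx]
            )
            if ok:
                break
        else:
            raise ValidationError(
                f"ascertainment failed for family {fam_id} after {max_tries} tries"
            )
        phenotypes.extend(records)
        for k, pv in enumerate(spec.planted):
            truth_carriers[pv.gene].extend(
                i for i in ped.member_ids if gm.dosage_of(i, keys[k]) >= 1
            )
        blocks.append(gm.dosage)
        all_ids.extend(ped.member_ids)

    dosage = np.vstack(blocks) if blocks else np.zeros((0, len(keys)), dtype=np.int8)
    if spec.missingness > 0:
        mask = rng.random(dosage.shape) < spec.missingness
        dosage = dosage.copy()
        dosage[mask] = MISSING
    genotypes = GenotypeMatrix(all_ids, keys, dosage)
    truth = {
        "planted": [
            {"gene": pv.gene, "key": list(keys[k]), "maf": pv.maf,
             "f1": pv.f1, "f0": pv.f0,
             "families": [f"F{(i % spec.n_families) + 1:03d}" for i in pv.families],
             "carriers": sorted(truth_carriers[pv.gene])}
            for k, pv in enumerate(spec.planted)
        ],
        "seed": spec.seed,
    }
    return SimulatedCohort(
        spec=spec,
        variants=variants,
        genotypes=genotypes,
        pedigrees=pedigrees,
        phenotypes=phenotypes,
        truth=truth,
    )


def write_cohort(cohort: SimulatedCohort, outdir) -> dict[str, Path]:
    """Emit VCF + PED + phenotype CSV + truth JSON for a simulated cohort."""
    from .io import write_ped, write_phenotypes, write_vcf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "cohort.vcf",
        "ped": outdir / "cohort.ped",
        "phenotypes": outdir / "phenotypes.csv",
        "truth": outdir / "truth.json",
    }
    write_vcf(paths["vcf"], cohort.variants, cohort.genotypes)
    write_ped(paths["ped"], cohort.pedigrees)
    write_phenotypes(paths["phenotypes"], cohort.phenotypes)
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=2)
    return paths
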