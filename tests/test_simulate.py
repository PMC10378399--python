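"""Generator statistics: Mendelian transmission, Hardy-Weinberg founders,
annotation pass-rate laws, phenotype model calibration, reproducibility."""

import numpy as np
import pytest

from famprio.model import Individual, Pedigree, ValidationError
from famprio.phenotyping import CriterionTable, assign_affectedness_cohort
from famprio.simulate import (
    CohortSpec,
    FamilyTemplate,
    PlantedVariant,
    gene_drop,
    simulate_annotations,
    simulate_cohort,
    simulate_pedigree,
    simulate_phenotypes,
    template_size,
)


@pytest.mark.parametrize(
    "template,expected",
    [
        (FamilyTemplate(2, 1, 3), 5),
        (FamilyTemplate(3, 2, 2), 10),
        (FamilyTemplate(3, 3, 4), 20),
    ],
)
def test_member_count_matches_counting_formula(template, expected):
    assert template_size(template) == expected
    assert len(simulate_pedigree(template, "F1")) == expected


def test_impossible_template_rejected():
    with pytest.raises(ValidationError):
        template_size(FamilyTemplate(4, 2, 2))
    with pytest.raises(ValidationError):
        template_size(FamilyTemplate(3, 0, 2))


def test_same_seed_gives_identical_cohort():
    spec = CohortSpec(n_families=2, n_background=40, seed=77)
    a = simulate_cohort(spec)
    b = simulate_cohort(CohortSpec(n_families=2, n_background=40, seed=77))
    assert a.genotypes == b.genotypes
    assert a.truth == b.truth
    assert a.phenotypes == b.phenotypes
    c = simulate_cohort(CohortSpec(n_families=2, n_background=40, seed=78))
    assert c.genotypes != a.genotypes


def test_zero_frequency_variant_never_appears():
    ped = simulate_pedigree(FamilyTemplate(), "F1")
    gm = gene_drop(ped, np.array([0.0]), np.random.default_rng(0))
    assert (gm.dosage == 0).all()


def test_het_by_het_cross_segregates_one_two_one():
    rng = np.random.default_rng(42)
    n_kids = 4000
    father, mother = Individual("f", sex="male"), Individual("m", sex="female")
    kids = [
        Individual(f"k{i}", father_id="f", mother_id="m") for i in range(n_kids)
    ]
    ped = Pedigree("F1", [father, mother] + kids)
    # rejection-sample until both founders are heterozygous
    for _ in range(100):
        gm = gene_drop(ped, np.array([0.5]), rng)
        key = gm.variants[0]
        if gm.dosage_of("f", key) == 1 and gm.dosage_of("m", key) == 1:
            break
    else:
        pytest.fail("never drew a het x het founder pair")
    counts = np.bincount(gm.dosage[2:, 0], minlength=3)
    frac = counts / n_kids
    se = np.sqrt(np.array([0.25, 0.5, 0.25]) * np.array([0.75, 0.5, 0.75]) / n_kids)
    assert np.all(np.abs(frac - [0.25, 0.5, 0.25]) < 4 * se)


def test_founder_frequency_approaches_specified_maf():
    n = 5000
    founders = [Individual(f"x{i}") for i in range(n)]
    ped = Pedigree("F1", founders)
    maf = 0.12
    gm = gene_drop(ped, np.array([maf]), np.random.default_rng(5))
    freq = gm.dosage[:, 0].sum() / (2 * n)
    se = np.sqrt(maf * (1 - maf) / (2 * n))
    assert abs(freq - maf) < 3 * se


def test_missingness_rate_is_respected():
    ped = simulate_pedigree(FamilyTemplate(3, 2, 3), "F1")
    rng = np.random.default_rng(8)
    gm = gene_drop(ped, np.full(2000, 0.3), rng, missingness=0.2)
    observed = (gm.dosage == -1).mean()
    assert abs(observed - 0.2) < 0.01


def test_causal_profile_passes_every_threshold_by_construction():
    spec = CohortSpec(n_families=2, n_background=0, seed=1)
    rng = np.random.default_rng(1)
    variants, _ = simulate_annotations(spec, rng)
    v = variants[0]
    assert v.func_class == "exonic"
    assert v.exonic_effect == "nonsynonymous"
    assert not v.segdup
    assert v.cadd_phred >= 20
    assert v.gerp > 0
    assert v.n_damaging >= 2
    assert v.maf_in("NFE") <= 0.01


def test_background_joint_pass_rate_follows_product_law():
    spec = CohortSpec(n_families=2, n_background=10_000, seed=13)
    rng = np.random.default_rng(13)
    variants, _ = simulate_annotations(spec, rng)
    background = variants[len(spec.planted):]
    r = spec.pass_rates
    expected = r["func"] * r["nonsyn"] * r["segdup"] * r["cadd"] * r["gerp"] * r["damaging"]
    hits = sum(
        1
        for v in background
        if v.func_class in ("exonic", "splicing", "exonic;splicing")
        and v.exonic_effect != "synonymous"
        and not v.segdup
        and v.cadd_phred >= 20
        and v.gerp > 0
        and v.n_damaging >= 2
    )
    p_hat = hits / len(background)
    se = np.sqrt(expected * (1 - expected) / len(background))
    assert abs(p_hat - expected) < 4 * se


def test_full_penetrance_phenotypes_mirror_carrier_status():
    spec = CohortSpec(n_families=1, n_background=0, low_nviq_rate=0.0,
                      discordant_rate=0.0, seed=2, planted=())
    ped = simulate_pedigree(FamilyTemplate(3, 2, 3), "F1")
    rng = np.random.default_rng(2)
    children = [m.id for m in ped.members if m.father_id and not ped.children_of(m.id)]
    dosages = {c: (1 if i % 2 == 0 else 0) for i, c in enumerate(children)}
    records = simulate_phenotypes(ped, dosages, f1=1.0, f0=0.0, spec=spec, rng=rng)
    statuses = assign_affectedness_cohort(records, CriterionTable.flat(80.0))
    # adults receive no grammar phenotype at all
    assert set(statuses) == set(children)
    for c in children:
        expected = "yes" if dosages[c] else "no"
        assert statuses[c].combined_affected == expected


def test_penetrance_and_phenocopy_rates_are_calibrated():
    spec = CohortSpec(n_families=1, n_background=0, low_nviq_rate=0.0, seed=3,
                      two_timepoint_rate=0.0, planted=())
    rng = np.random.default_rng(3)
    n = 1000
    father, mother = Individual("f"), Individual("m")
    kids = [Individual(f"k{i}", father_id="f", mother_id="m") for i in range(n)]
    ped = Pedigree("F1", [father, mother] + kids)
    dosages = {f"k{i}": (1 if i < n // 2 else 0) for i in range(n)}
    records = simulate_phenotypes(ped, dosages, f1=0.8, f0=0.05, spec=spec, rng=rng)
    statuses = assign_affectedness_cohort(records, CriterionTable.flat(80.0))
    carrier_rate = np.mean(
        [statuses[f"k{i}"].combined_affected == "yes" for i in range(n // 2)]
    )
    noncarrier_rate = np.mean(
        [statuses[f"k{i}"].combined_affected == "yes" for i in range(n // 2, n)]
    )
    assert abs(carrier_rate - 0.8) < 4 * np.sqrt(0.8 * 0.2 / (n // 2))
    assert abs(noncarrier_rate - 0.05) < 4 * np.sqrt(0.05 * 0.95 / (n // 2))


def test_truth_records_planted_carriers_before_masking():
    spec = CohortSpec(
        n_families=2, n_background=10, missingness=0.3, seed=9,
        planted=(PlantedVariant(f1=1.0, f0=0.0, families=(0, 1)),),
    )
    c = simulate_cohort(spec)
    planted = c.truth["planted"][0]
    assert len(planted["carriers"]) >= 2 * spec.min_planted_carriers
    assert planted["families"] == ["F001", "F002"]


def test_afr_family_assignment():
    spec = CohortSpec(n_families=3, n_background=0, seed=4)
    c = simulate_cohort(spec)
    subpops = {fam: ped.members[0].subpopulation for fam, ped in c.pedigrees.items()}
    assert subpops == {"F001": "NFE", "F002": "NFE", "F003": "AFR"}
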