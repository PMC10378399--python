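import numpy as np
import pytest

from famprio.model import AnnotatedVariant, GenotypeMatrix, Individual, Pedigree
from famprio.simulate import CohortSpec, PlantedVariant, simulate_cohort


@pytest.fixture
def trio():
    return Pedigree(
        "T1",
        [
            Individual("dad", sex="male"),
            Individual("mom", sex="female"),
            Individual("kid", father_id="dad", mother_id="mom", sex="male"),
        ],
    )


def make_variant(**kw):
    """A variant that passes every a priori criterion unless overridden."""
    defaults = dict(
        chrom="1",
        pos=100,
        ref="A",
        alt="G",
        gene="GENE1",
        func_class="exonic",
        exonic_effect="nonsynonymous",
        segdup=False,
        cadd_phred=25.0,
        gerp=3.0,
        predictor_calls={
            "SIFT": "damaging",
            "PolyPhen2": "damaging",
            "MutationAssessor": "tolerated",
            "PROVEAN": "tolerated",
            "MutationTaster": "tolerated",
        },
        maf={"NFE": 0.005, "AFR": 0.005},
    )
    defaults.update(kw)
    return AnnotatedVariant(**defaults)


@pytest.fixture
def passing_variant():
    return make_variant()


def matrix_for(individuals, variants, rows):
    return GenotypeMatrix(
        individuals, [v.key for v in variants], np.asarray(rows, dtype=np.int8)
    )


@pytest.fixture(scope="session")
def clean_cohort():
    """Deterministic small cohort: planted variant fully penetrant, no
    phenocopies, no missingness — the planted gene must be recoverable."""
    spec = CohortSpec(
        n_families=4,
        n_background=80,
        planted=(PlantedVariant(f1=1.0, f0=0.0, families=(0, 1)),),
        missingness=0.0,
        low_nviq_rate=0.0,
        seed=11,
    )
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Cohort at the generator's realistic noise settings (scaled down)."""
    spec = CohortSpec(n_families=4, n_background=300, seed=23)
    return simulate_cohort(spec)
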