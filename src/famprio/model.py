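"""Core data types for family-based rare-variant prioritization.

The pipeline works on four in-memory containers: annotated variants
(:class:`AnnotatedVariant`), an individual x variant dosage matrix
(:class:`GenotypeMatrix`), family structures (:class:`Pedigree`) and
longitudinal phenotype rows (:class:`PhenotypeRecord`).  Variants are keyed
by ``(chrom, pos, ref, alt)`` with 1-based, fully closed VCF coordinates
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "PREDICTORS",
    "FUNC_CLASSES",
    "EXONIC_EFFECTS",
    "MISSING",
    "VariantKey",
    "FormatError",
    "ValidationError",
    "ConfigError",
    "AnnotatedVariant",
    "GenotypeMatrix",
    "Individual",
    "Pedigree",
    "PhenotypeRecord",
    "AffectednessStatus",
    "FilterConfig",
    "CosegRule",
    "FilterTrace",
    "BurdenTable",
    "CausalityEvidence",
    "ClassificationVerdict",
]

#: The five in-silico pathogenicity programs consulted per variant.
PREDICTORS = ("SIFT", "PolyPhen2", "MutationAssessor", "PROVEAN", "MutationTaster")

FUNC_CLASSES = frozenset(
    {"exonic", "splicing", "exonic;splicing", "intronic", "UTR", "intergenic", "other"}
)
EXONIC_EFFECTS = frozenset(
    {"nonsynonymous", "synonymous", "stopgain", "stoploss", "frameshift",
     "nonframeshift", "unknown"}
)
HOPE_SIZE = frozenset({"increase", "decrease", "none_reported"})
HOPE_CHARGE = frozenset(
    {"pos_to_neu", "neg_to_neu", "neu_to_pos", "neu_to_neg", "none", "none_reported"}
)
PREDICTOR_CALLS = frozenset({"damaging", "tolerated", "unknown"})

#: Sentinel dosage for an uncalled genotype.  Missing is *not* reference.
MISSING = -1

VariantKey = tuple[str, int, str, str]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """Parsed content violates a model invariant."""


class ConfigError(ValueError):
    """A configuration value is unusable (unresolvable subpopulation, etc.)."""


@dataclass
class AnnotatedVariant:
    """One biallelic variant with its functional annotations.

    ``maf`` maps subpopulation labels (``NFE``, ``AFR``, ...) to allele
    frequencies; an absent or ``None`` entry means *unknown*, which is
    deliberately distinct from 0 (unknown-frequency variants feed the
    "novel" branch of the rare/novel filter).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    func_class: str = "other"
    exonic_effect: str = "unknown"
    segdup: bool = False
    cadd_phred: Optional[float] = None
    gerp: Optional[float] = None
    predictor_calls: dict[str, str] = field(default_factory=dict)
    maf: dict[str, Optional[float]] = field(default_factory=dict)
    rsid: Optional[str] = None
    aa_change: Optional[str] = None
    hope_size_change: str = "none_reported"
    hope_charge_change: str = "none_reported"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        if self.func_class not in FUNC_CLASSES:
            raise ValidationError(f"unknown func_class {self.func_class!r}")
        if self.exonic_effect not in EXONIC_EFFECTS:
            raise ValidationError(f"unknown exonic_effect {self.exonic_effect!r}")
        if self.hope_size_change not in HOPE_SIZE:
            raise ValidationError(f"unknown hope_size_change {self.hope_size_change!r}")
        if self.hope_charge_change not in HOPE_CHARGE:
            raise ValidationError(
                f"unknown hope_charge_change {self.hope_charge_change!r}"
            )
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValidationError("CADD Phred score must be nonnegative")
        # Exactly five predictor keys; unnamed programs default to unknown.
        extra = set(self.predictor_calls) - set(PREDICTORS)
        if extra:
            raise ValidationError(f"unknown predictor(s): {sorted(extra)}")
        for p in PREDICTORS:
            self.predictor_calls.setdefault(p, "unknown")
        bad = {c for c in self.predictor_calls.values() if c not in PREDICTOR_CALLS}
        if bad:
            raise ValidationError(f"unknown predictor call(s): {sorted(bad)}")
        for pop, f in self.maf.items():
            if f is not None and not (0.0 <= f <= 1.0):
                raise ValidationError(f"MAF for {pop} out of [0,1]: {f}")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def n_damaging(self) -> int:
        """Number of the five in-silico programs calling this variant damaging."""
        return sum(1 for c in self.predictor_calls.values() if c == "damaging")

    def maf_in(self, subpop: str) -> Optional[float]:
        """Allele frequency in ``subpop``, or None when unknown."""
        return self.maf.get(subpop)


class GenotypeMatrix:
    """Individual x variant alt-allele dosage matrix.

    Dosages are 0/1/2 or :data:`MISSING` (-1).  A missing genotype is never
    treated as homozygous reference: carrier/genotyped queries exclude it.
    """

    def __init__(
        self,
        individuals: Sequence[str],
        variants: Sequence[VariantKey],
        dosage: np.ndarray,
    ) -> None:
        self.individuals = list(individuals)
        self.variants = [tuple(v) for v in variants]
        arr = np.asarray(dosage, dtype=np.int8)
        if arr.shape != (len(self.individuals), len(self.variants)):
            raise ValidationError(
                f"dosage shape {arr.shape} does not match "
                f"({len(self.individuals)}, {len(self.variants)})"
            )
        bad = ~np.isin(arr, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValidationError(
                f"dosage contains values outside {{0,1,2,missing}}: "
                f"{sorted(set(arr[bad].tolist()))}"
            )
        if len(set(self.individuals)) != len(self.individuals):
            raise ValidationError("duplicate individual IDs")
        if len(set(self.variants)) != len(self.variants):
            raise ValidationError("duplicate variant keys")
        self.dosage = arr
        self._irow = {ind: i for i, ind in enumerate(self.individuals)}
        self._vcol = {key: j for j, key in enumerate(self.variants)}

    @classmethod
    def empty(cls, individuals: Sequence[str] = ()) -> "GenotypeMatrix":
        return cls(individuals, [], np.zeros((len(individuals), 0), dtype=np.int8))

    def dosage_of(self, individual: str, key: VariantKey) -> int:
        return int(self.dosage[self._irow[individual], self._vcol[tuple(key)]])

    def genotyped(self, key: VariantKey, among: Optional[Iterable[str]] = None) -> list[str]:
        """Individuals with a called genotype for ``key`` (optionally restricted)."""
        col = self.dosage[:, self._vcol[tuple(key)]]
        pool = self.individuals if among is None else [i for i in among if i in self._irow]
        return [i for i in pool if col[self._irow[i]] != MISSING]

    def carriers(self, key: VariantKey, among: Optional[Iterable[str]] = None) -> list[str]:
        """Individuals carrying >=1 alt allele (homozygotes counted once)."""
        col = self.dosage[:, self._vcol[tuple(key)]]
        pool = self.individuals if among is None else [i for i in among if i in self._irow]
        return [i for i in pool if col[self._irow[i]] >= 1]

    def subset_individuals(self, individuals: Sequence[str]) -> "GenotypeMatrix":
        rows = [self._irow[i] for i in individuals]
        return GenotypeMatrix(individuals, self.variants, self.dosage[rows, :])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.variants == other.variants
            and np.array_equal(self.dosage, other.dosage)
        )

    def __repr__(self) -> str:
        return (
            f"GenotypeMatrix({len(self.individuals)} individuals x "
            f"{len(self.variants)} variants)"
        )


@dataclass(frozen=True)
class Individual:
    id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: str = "unknown"  # male / female / unknown
    branch_label: Optional[str] = None
    subpopulation: str = "NFE"


class Pedigree:
    """A single family: individuals with resolvable, acyclic parent links."""

    def __init__(self, family_id: str, members: Sequence[Individual]) -> None:
        self.family_id = family_id
        self.members = list(members)
        ids = [m.id for m in self.members]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate member IDs in family {family_id}")
        self._by_id = {m.id: m for m in self.members}
        for m in self.members:
            for parent in (m.father_id, m.mother_id):
                if parent is not None and parent not in self._by_id:
                    raise ValidationError(
                        f"family {family_id}: unknown parent ID {parent!r} for {m.id}"
                    )
        g = nx.DiGraph()
        g.add_nodes_from(ids)
        for m in self.members:
            for parent in (m.father_id, m.mother_id):
                if parent is not None:
                    g.add_edge(parent, m.id)
        if not nx.is_directed_acyclic_graph(g):
            raise ValidationError(f"family {family_id}: cyclic parentage")
        self._graph = g

    @property
    def member_ids(self) -> list[str]:
        return [m.id for m in self.members]

    def get(self, individual_id: str) -> Individual:
        return self._by_id[individual_id]

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._by_id

    def founders(self) -> list[Individual]:
        return [m for m in self.members if m.father_id is None and m.mother_id is None]

    def children_of(self, parent_id: str) -> list[Individual]:
        return [
            m for m in self.members if parent_id in (m.father_id, m.mother_id)
        ]

    def __len__(self) -> int:
        return len(self.members)

    def __repr__(self) -> str:
        return f"Pedigree({self.family_id!r}, {len(self)} members)"


@dataclass
class PhenotypeRecord:
    """One individual's grammar-test scores at one timepoint.

    ``probe_scores`` holds percentages for the third-person-singular,
    past-tense and combined be/do elicitation probes; standard scores are on
    the usual mean-100/SD-15 scale.
    """

    individual_id: str
    timepoint: float  # age in months
    probe_scores: dict[str, Optional[float]] = field(default_factory=dict)
    omnibus_ss: Optional[float] = None
    recept_vocab_ss: Optional[float] = None
    nviq_ss: Optional[float] = None

    PROBES = ("third_person_singular", "past_tense", "be_do")

    def __post_init__(self) -> None:
        for probe, v in self.probe_scores.items():
            if probe not in self.PROBES:
                raise ValidationError(f"unknown probe {probe!r}")
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValidationError(f"probe {probe} out of [0,100]: {v}")
        for name in ("omnibus_ss", "recept_vocab_ss", "nviq_ss"):
            v = getattr(self, name)
            if v is not None and not (40.0 <= v <= 160.0):
                raise ValidationError(f"{name} out of plausible range [40,160]: {v}")


@dataclass
class AffectednessStatus:
    """Categorical affectedness derived from grammar-test performance.

    ``combined_affected`` is *yes* when either the screener or the composite
    measure is in the affected range; ``discordant`` marks individuals whose
    two measures disagree (both known, exactly one affected).
    """

    individual_id: str
    screener_affected: str = "unknown"  # yes / no / unknown
    composite_affected: str = "unknown"
    combined_affected: str = "unknown"
    discordant: bool = False
    excluded_low_nviq: bool = False


def combine_measures(screener: str, composite: str) -> tuple[str, bool]:
    """Combined status and discordance from the two per-measure calls."""
    if "yes" in (screener, composite):
        combined = "yes"
    elif screener == "no" and composite == "no":
        combined = "no"
    elif "no" in (screener, composite):
        # one known-unaffected, the other unknown: not demonstrably affected
        combined = "no"
    else:
        combined = "unknown"
    discordant = {screener, composite} == {"yes", "no"}
    return combined, discordant


@dataclass
class FilterConfig:
    """Thresholds for the a priori criteria chain and both workflows.

    Defaults mirror the published criteria: exonic/splicing class, not
    synonymous, outside segmental duplications, CADD Phred >= 20, positive
    GERP, shared by >= 2 affected family members, >= 2/5 damaging in-silico
    calls, subpopulation MAF <= 0.01 (workflow 1) or < 0.07 (workflow 2).
    """

    rare_maf_max: float = 0.01
    min_affected_sharers: int = 2
    min_damaging_predictors: int = 2
    cadd_min: float = 20.0
    allowed_func_classes: frozenset = frozenset({"exonic", "splicing", "exonic;splicing"})
    gene_blocklist: frozenset = frozenset()
    subpopulation_by_family: dict[str, str] = field(default_factory=dict)
    unknown_scores_fail: bool = True  # unknown CADD/GERP fail their criteria
    min_families: int = 2
    min_total_affected_carriers: int = 4  # across >= min_families families
    candidate_maf_max: float = 0.07
    unknown_maf_passes_candidate: bool = True
    max_unaffected_carriers: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.rare_maf_max <= 1 and 0 <= self.candidate_maf_max <= 1):
            raise ConfigError("MAF thresholds must lie in [0,1]")
        if self.min_affected_sharers < 2:
            raise ConfigError("min_affected_sharers must be >= 2")
        if self.min_damaging_predictors < 0 or self.min_damaging_predictors > 5:
            raise ConfigError("min_damaging_predictors must be in 0..5")

    def subpop_for(self, family_id: str, default: Optional[str] = None) -> str:
        pop = self.subpopulation_by_family.get(family_id, default)
        if pop is None:
            raise ConfigError(f"no subpopulation configured for family {family_id!r}")
        return pop


@dataclass
class CosegRule:
    """Family-specific co-segregation predicate.

    Default semantics: every genotyped, non-excluded affected member carries
    the variant and no genotyped unaffected member does.  ``required_carriers``
    can pin named individuals; ``branch`` restricts evaluation to one pedigree
    branch.
    """

    family_id: str
    require_all_affected_carry: bool = True
    max_unaffected_carriers: int = 0
    required_carriers: tuple[str, ...] = ()
    branch: Optional[str] = None


class FilterTrace:
    """Ordered per-variant record of every filtering decision."""

    def __init__(self) -> None:
        self.records: list[dict] = []

    def record(
        self,
        family_id: str,
        key: VariantKey,
        criterion: str,
        passed: bool,
        value: object = None,
    ) -> None:
        self.records.append(
            {
                "family": family_id,
                "chrom": key[0],
                "pos": key[1],
                "ref": key[2],
                "alt": key[3],
                "criterion": criterion,
                "passed": bool(passed),
                "value": value,
            }
        )

    def failures(self, key: VariantKey) -> list[str]:
        return [
            r["criterion"]
            for r in self.records
            if (r["chrom"], r["pos"], r["ref"], r["alt"]) == tuple(key)
            and not r["passed"]
        ]

    def to_frame(self):
        import pandas as pd

        cols = ["family", "chrom", "pos", "ref", "alt", "criterion", "passed", "value"]
        return pd.DataFrame(self.records, columns=cols)


@dataclass
class BurdenTable:
    """2x2 allele-count table: study probands vs a reference population."""

    carrier_alleles_probands: int
    total_alleles_probands: int
    carrier_alleles_ref: int
    total_alleles_ref: int

    def __post_init__(self) -> None:
        for name in (
            "carrier_alleles_probands",
            "total_alleles_probands",
            "carrier_alleles_ref",
            "total_alleles_ref",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.carrier_alleles_probands > self.total_alleles_probands:
            raise ValidationError("proband carriers exceed proband total")
        if self.carrier_alleles_ref > self.total_alleles_ref:
            raise ValidationError("reference carriers exceed reference total")


@dataclass
class CausalityEvidence:
    """Everything the six-criterion causality rule consumes for one variant.

    Threshold facts (CADD >= 20, positive GERP) are booleans so the rule can
    run on published summary rows that report threshold passage without the
    underlying scores.
    """

    maf: Optional[float]
    gerp_positive: bool
    cadd_ge_threshold: bool
    n_damaging: int
    hope_size_change: str = "none_reported"
    hope_charge_change: str = "none_reported"
    coseg_confirmed: bool = False
    n_discovery_families: int = 1
    n_additional_probands: int = 0
    n_unaffected_carriers: int = 0


@dataclass
class ClassificationVerdict:
    variant_key: VariantKey
    verdict: str  # "P" / "Likely P" / "B"
    criteria_fired: dict[int, bool] = field(default_factory=dict)
    evidence_notes: str = ""
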