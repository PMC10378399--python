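"""Grammar-test scoring and categorical affectedness assignment.

The instrument elicits tense/agreement-marking probes from children aged
3;0-8;11.  The *screener* score is the mean of the third-person-singular and
past-tense probe percentages; the *elicited grammar composite* additionally
includes the be/do probes.  An individual is affected on a measure when
their lowest score across timepoints falls below the age-referenced
criterion; the combined status is affected when either measure is.

The instrument manual's criterion scores are not public, so
:class:`CriterionTable` is a required config input; :func:`CriterionTable.flat`
provides the single-cut default used by the synthetic cohort generator.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .model import (
    AffectednessStatus,
    ConfigError,
    PhenotypeRecord,
    ValidationError,
    combine_measures,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CriterionTable",
    "screener_score",
    "composite_score",
    "assign_affectedness",
    "apply_nviq_exclusion",
]

#: Instrument age range in months (3;0 through 8;11).
AGE_MIN_MONTHS = 36
AGE_MAX_MONTHS = 107


@dataclass(frozen=True)
class AgeBand:
    lo_months: float
    hi_months: float  # inclusive
    screener_cut: float
    composite_cut: float


class CriterionTable:
    """Age-banded criterion (cut) scores for the two measures.

    Bands must be non-overlapping and jointly cover the instrument's age
    range; scores strictly below the band's cut are in the affected range.
    """

    def __init__(self, bands: Sequence[AgeBand]) -> None:
        bands = sorted(bands, key=lambda b: b.lo_months)
        for b in bands:
            if b.lo_months > b.hi_months:
                raise ValidationError("age band with lo > hi")
            for cut in (b.screener_cut, b.composite_cut):
                if not (0.0 <= cut <= 100.0):
                    raise ValidationError(f"criterion score out of [0,100]: {cut}")
        for a, b in zip(bands, bands[1:]):
            if b.lo_months <= a.hi_months:
                raise ValidationError("overlapping age bands")
        if not bands or bands[0].lo_months > AGE_MIN_MONTHS or bands[-1].hi_months < AGE_MAX_MONTHS:
            raise ValidationError(
                f"age bands must cover {AGE_MIN_MONTHS}..{AGE_MAX_MONTHS} months"
            )
        gaps = [
            (a.hi_months, b.lo_months)
            for a, b in zip(bands, bands[1:])
            if b.lo_months - a.hi_months > 1
        ]
        if gaps:
            raise ValidationError(f"age bands leave gaps: {gaps}")
        self.bands = list(bands)

    @classmethod
    def flat(cls, cut: float = 80.0) -> "CriterionTable":
        """Single criterion across all ages (synthetic-cohort default)."""
        return cls([AgeBand(AGE_MIN_MONTHS, AGE_MAX_MONTHS, cut, cut)])

    @classmethod
    def from_csv(cls, path) -> "CriterionTable":
        """Read bands from CSV columns lo_months,hi_months,screener_cut,composite_cut."""
        bands = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                bands.append(
                    AgeBand(
                        float(row["lo_months"]),
                        float(row["hi_months"]),
                        float(row["screener_cut"]),
                        float(row["composite_cut"]),
                    )
                )
        return cls(bands)

    def criterion_for(self, age_months: float, measure: str) -> float:
        for b in self.bands:
            if b.lo_months <= age_months <= b.hi_months:
                return b.screener_cut if measure == "screener" else b.composite_cut
        raise ConfigError(f"no criterion band covers age {age_months} months")

    def covers(self, age_months: float) -> bool:
        return any(b.lo_months <= age_months <= b.hi_months for b in self.bands)


def screener_score(probe_scores: dict) -> Optional[float]:
    """Mean of the third-person-singular and past-tense probe percentages.

    Returns None (-> affectedness unknown) when either probe is missing.
    """
    tps = probe_scores.get("third_person_singular")
    pt = probe_scores.get("past_tense")
    if tps is None or pt is None:
        return None
    return (tps + pt) / 2.0


def composite_score(
    probe_scores: dict, weights: Optional[Sequence[float]] = None
) -> Optional[float]:
    """Elicited grammar composite: screener probes plus the be/do probes.

    By default an unweighted mean of the three probe percentages
    (third-person singular, past tense, combined be/do); ``weights`` lets a
    user supply the instrument manual's exact weighting.
    """
    vals = [
        probe_scores.get("third_person_singular"),
        probe_scores.get("past_tense"),
        probe_scores.get("be_do"),
    ]
    if any(v is None for v in vals):
        return None
    if weights is None:
        return sum(vals) / len(vals)
    if len(weights) != 3 or sum(weights) <= 0:
        raise ConfigError("composite weights must be 3 nonnegative values")
    return sum(w * v for w, v in zip(weights, vals)) / sum(weights)


def _measure_affected(
    records: Iterable[PhenotypeRecord],
    criterion_table: CriterionTable,
    measure: str,
    strict: bool = True,
) -> str:
    """Affectedness on one measure from the lowest score across timepoints.

    Each timepoint's score is compared against the criterion for the age at
    that timepoint; a single sub-criterion timepoint makes the individual
    affected (the lowest-score rule).  ``strict`` keeps scores exactly at
    criterion in the unaffected range.
    """
    scorer = screener_score if measure == "screener" else composite_score
    any_scored = False
    for rec in records:
        score = scorer(rec.probe_scores)
        if score is None or not criterion_table.covers(rec.timepoint):
            continue
        any_scored = True
        cut = criterion_table.criterion_for(rec.timepoint, measure)
        below = score < cut if strict else score <= cut
        if below:
            return "yes"
    return "no" if any_scored else "unknown"


def assign_affectedness(
    records: Sequence[PhenotypeRecord],
    criterion_table: CriterionTable,
    strict: bool = True,
) -> AffectednessStatus:
    """Categorical affectedness for one individual across all timepoints."""
    if not records:
        raise ValidationError("assign_affectedness needs >= 1 phenotype record")
    ids = {r.individual_id for r in records}
    if len(ids) != 1:
        raise ValidationError(f"records span multiple individuals: {sorted(ids)}")
    screener = _measure_affected(records, criterion_table, "screener", strict)
    composite = _measure_affected(records, criterion_table, "composite", strict)
    combined, discordant = combine_measures(screener, composite)
    return AffectednessStatus(
        individual_id=records[0].individual_id,
        screener_affected=screener,
        composite_affected=composite,
        combined_affected=combined,
        discordant=discordant,
    )


def assign_affectedness_cohort(
    records: Sequence[PhenotypeRecord],
    criterion_table: CriterionTable,
    strict: bool = True,
) -> dict[str, AffectednessStatus]:
    """Group records by individual and assign affectedness to each."""
    by_ind: dict[str, list[PhenotypeRecord]] = {}
    for rec in records:
        by_ind.setdefault(rec.individual_id, []).append(rec)
    return {
        ind: assign_affectedness(recs, criterion_table, strict)
        for ind, recs in by_ind.items()
    }


def apply_nviq_exclusion(
    statuses: dict[str, AffectednessStatus],
    records: Sequence[PhenotypeRecord],
    threshold: float = 85.0,
) -> dict[str, AffectednessStatus]:
    """Flag individuals with non-verbal IQ at or below ``threshold``.

    Mirrors the study entrance criterion (NV-IQ standard score > 85):
    individuals at or below it are excluded from sharing and co-segregation
    counts.  The lowest NV-IQ across timepoints is used; individuals with no
    NV-IQ score are retained with a warning.
    """
    nviq: dict[str, float] = {}
    seen: set[str] = set()
    for rec in records:
        seen.add(rec.individual_id)
        if rec.nviq_ss is not None:
            prev = nviq.get(rec.individual_id)
            nviq[rec.individual_id] = rec.nviq_ss if prev is None else min(prev, rec.nviq_ss)
    out: dict[str, AffectednessStatus] = {}
    for ind, status in statuses.items():
        excluded = False
        if ind in nviq:
            excluded = nviq[ind] <= threshold
        elif ind in seen:
            logger.warning(
                "individual %s has no NV-IQ score; retained (exclusion not evaluable)",
                ind,
            )
        out[ind] = AffectednessStatus(
            individual_id=status.individual_id,
            screener_affected=status.screener_affected,
            composite_affected=status.composite_affected,
            combined_affected=status.combined_affected,
            discordant=status.discordant,
            excluded_low_nviq=excluded,
        )
    return out


def affected_ids(
    statuses: dict[str, AffectednessStatus], include_excluded: bool = False
) -> list[str]:
    """IDs with combined affected status, dropping NV-IQ-excluded members."""
    return sorted(
        ind
        for ind, s in statuses.items()
        if s.combined_affected == "yes" and (include_excluded or not s.excluded_low_nviq)
    )


def unaffected_ids(
    statuses: dict[str, AffectednessStatus], include_excluded: bool = False
) -> list[str]:
    return sorted(
        ind
        for ind, s in statuses.items()
        if s.combined_affected == "no" and (include_excluded or not s.excluded_low_nviq)
    )
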