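"""Bundled datasets.

``load_worked_example`` returns the package's worked example: twelve
Sanger-confirmed variants from a family-based exome study of a grammar
impairment phenotype, with the per-variant summary attributes needed by the
carrier tally, the burden test and the causality classifier (subpopulation
MAF, in-silico damaging counts, structural-change annotations,
co-segregation status, and carrier lists over 154 probands — 8 discovery
plus 146 additional).

Additional-proband carrier IDs are synthetic labels that encode the
published per-variant counts and their two footnote subtleties: one
additional proband (``S01``) carries variants on both GLI3 and PDHA2, and
one FLNB carrier (``M4299``) is a discovery-family proband and therefore
excluded from the additional-proband tally.  Genomic positions in this
table are synthetic ordinals (the summary data do not include coordinates)
and serve only as unique keys.  ``reported_*`` columns are published
expectations retained for comparison; no computation reads them.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .model import BurdenTable, CausalityEvidence
from .assoc import DEFAULT_REFERENCE_AN, burden_table_from_maf

__all__ = [
    "load_worked_example",
    "load_candidate_genes",
    "worked_example_carriers",
    "worked_example_evidence",
    "worked_example_burden_tables",
]


def _data_path(name: str):
    return resources.files("famprio.data").joinpath(name)


def load_worked_example() -> pd.DataFrame:
    """The 12-variant worked example as a DataFrame (one row per variant)."""
    with resources.as_file(_data_path("worked_example_variants.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    for col in ("pos", "n_damaging", "unaffected_family_carriers",
                "discovery_carrier_alleles", "proband_alleles_total", "workflow"):
        df[col] = df[col].astype(int)
    df["maf"] = df["maf"].astype(float)
    return df


def load_candidate_genes() -> list[str]:
    """The shipped placeholder candidate-gene list (user-replaceable)."""
    from .workflow2 import read_gene_list

    with resources.as_file(_data_path("candidate_genes.txt")) as p:
        return read_gene_list(p)


def _ids(cell: str) -> list[str]:
    return [] if cell in (".", "") else cell.split(",")


def worked_example_carriers() -> dict[str, list[tuple[str, bool]]]:
    """Per-variant additional-proband carrier lists keyed by rsID.

    Pairs are (proband_id, affected); discovery-family carriers (the FLNB
    footnote) are not additional probands and are left out.
    """
    df = load_worked_example()
    out: dict[str, list[tuple[str, bool]]] = {}
    for row in df.itertuples(index=False):
        pairs = [(pid, True) for pid in _ids(row.additional_affected_ids)]
        pairs += [(pid, False) for pid in _ids(row.additional_unaffected_ids)]
        out[row.rsid] = pairs
    return out


def worked_example_evidence() -> dict[str, CausalityEvidence]:
    """Causality-rule inputs per variant, keyed by rsID."""
    df = load_worked_example()
    out = {}
    for row in df.itertuples(index=False):
        n_additional = len(_ids(row.additional_affected_ids)) + len(
            _ids(row.additional_unaffected_ids)
        )
        out[row.rsid] = CausalityEvidence(
            maf=row.maf,
            gerp_positive=row.gerp_positive == "yes",
            cadd_ge_threshold=row.cadd_ge20 == "yes",
            n_damaging=row.n_damaging,
            hope_size_change=row.hope_size,
            hope_charge_change=row.hope_charge,
            coseg_confirmed=row.coseg_confirmed == "yes",
            n_discovery_families=len(_ids(row.discovery_families)),
            n_additional_probands=n_additional,
            n_unaffected_carriers=len(_ids(row.additional_unaffected_ids))
            + row.unaffected_family_carriers,
        )
    return out


def worked_example_burden_tables(
    reference_an: int = DEFAULT_REFERENCE_AN,
) -> dict[str, BurdenTable]:
    """Proband-vs-reference allele tables for the variants with a reported test.

    Carrier alleles = discovery probands carrying (one allele each, all
    heterozygous) + additional probands carrying; the reference allele count
    is ``round(MAF x AN)`` unless the row pins it (the NOL6 variant absent
    from the NFE reference has AC = 0).
    """
    df = load_worked_example()
    out = {}
    for row in df.itertuples(index=False):
        if row.reported_p == "NA":
            continue
        carriers = (
            row.discovery_carrier_alleles
            + len(_ids(row.additional_affected_ids))
            + len(_ids(row.additional_unaffected_ids))
            + len(_ids(row.extra_discovery_ids))
        )
        override = None if row.ref_ac_override == "." else int(row.ref_ac_override)
        out[row.rsid] = burden_table_from_maf(
            carrier_alleles_probands=carriers,
            total_alleles_probands=row.proband_alleles_total,
            reference_maf=row.maf,
            reference_an=reference_an,
            reference_ac=override,
        )
    return out
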