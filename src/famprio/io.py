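"""Readers and writers for the file formats the pipeline touches.

Genotypes travel as VCF (v4.x) with per-variant annotations carried in
documented INFO keys, or as a flat tab-delimited table with ``dosage_<ID>``
columns.  Pedigrees are 6-column PED with optional subpopulation and branch
columns; phenotypes are long-format CSV.  All columns are documented in
``docs/schemas.md``.

Two parsing rules are deliberate and asserted by tests: an absent MAF is
*unknown*, never 0 (unknown-frequency variants are candidates for the
"novel" filter branch), and a missing genotype is never coerced to
homozygous reference.
"""

from __future__ import annotations

import csv
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .model import (
    MISSING,
    PREDICTORS,
    AnnotatedVariant,
    ClassificationVerdict,
    FormatError,
    GenotypeMatrix,
    Individual,
    Pedigree,
    PhenotypeRecord,
    ValidationError,
    VariantKey,
)

__all__ = [
    "read_variant_table",
    "read_pedigree",
    "read_pedigrees",
    "read_phenotypes",
    "write_vcf",
    "write_ped",
    "write_phenotypes",
    "write_report",
    "normalize_predictor_call",
]

#: INFO keys used for annotations in VCF round trips.
_INFO_KEYS = {
    "GENE": "gene",
    "FUNC": "func_class",
    "EXONIC_FUNC": "exonic_effect",
    "CADD": "cadd_phred",
    "GERP": "gerp",
    "AA_CHANGE": "aa_change",
    "HOPE_SIZE": "hope_size_change",
    "HOPE_CHARGE": "hope_charge_change",
}

_VOCAB = None


def _predictor_vocab() -> dict:
    global _VOCAB
    if _VOCAB is None:
        text = resources.files("famprio.data").joinpath("predictor_vocab.yaml").read_text()
        _VOCAB = yaml.safe_load(text)
    return _VOCAB


def normalize_predictor_call(raw: object, program: Optional[str] = None) -> str:
    """Map a program's raw output code (D, P, deleterious, ...) onto the
    damaging/tolerated/unknown vocabulary via the shipped mapping file.

    Program-specific maps take precedence: single-letter codes collide
    across programs.
    """
    if raw is None:
        return "unknown"
    s = str(raw).strip()
    if not s or s == ".":
        return "unknown"
    if s in ("damaging", "tolerated", "unknown"):
        return s
    vocab = _predictor_vocab()
    specific = vocab.get(program, {}) if program else {}
    default = vocab.get("default", {})
    return specific.get(s, default.get(s, default.get(s.lower(), "unknown")))


# ---------------------------------------------------------------------------
# variant tables


def _validate_vcf_header(path) -> None:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("##fileformat=VCF"):
            raise FormatError(f"{path}: line 1: missing ##fileformat=VCF header")
        for lineno, line in enumerate(fh, start=2):
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                return
            raise FormatError(f"{path}: line {lineno}: expected #CHROM header line")
    raise FormatError(f"{path}: no #CHROM header line found")


def _info_variant(chrom, pos, ref, alt, rsid, info_get) -> AnnotatedVariant:
    fields = {}
    for key, attr in _INFO_KEYS.items():
        val = info_get(key)
        if val is not None:
            fields[attr] = val
    if "cadd_phred" in fields:
        fields["cadd_phred"] = float(fields["cadd_phred"])
    if "gerp" in fields:
        fields["gerp"] = float(fields["gerp"])
    calls = {}
    for p in PREDICTORS:
        raw = info_get(p.upper())
        if raw is not None:
            calls[p] = normalize_predictor_call(raw, p)
    maf = {}
    for pop in ("NFE", "AFR"):
        val = info_get(f"MAF_{pop}")
        if val is not None:
            maf[pop] = float(val)
    return AnnotatedVariant(
        chrom=str(chrom),
        pos=int(pos),
        ref=str(ref),
        alt=str(alt),
        segdup=bool(info_get("SEGDUP")),
        predictor_calls=calls,
        maf=maf,
        rsid=rsid if rsid not in (None, ".", "") else None,
        **fields,
    )


def _read_vcf(path) -> tuple[list[AnnotatedVariant], GenotypeMatrix]:
    from cyvcf2 import VCF

    _validate_vcf_header(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: list[AnnotatedVariant] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        gts = rec.genotypes  # [[a1, a2, phased], ...]
        # Multiallelic records are split into one biallelic entry per ALT.
        for alt_i, alt in enumerate(rec.ALT, start=1):
            variants.append(
                _info_variant(
                    rec.CHROM, rec.POS, rec.REF, alt, rec.ID, rec.INFO.get
                )
            )
            col = np.full(len(samples), MISSING, dtype=np.int8)
            for s, gt in enumerate(gts):
                alleles = [a for a in gt[:-1]]
                if any(a < 0 for a in alleles):
                    continue
                col[s] = sum(1 for a in alleles if a == alt_i)
            columns.append(col)
    dosage = (
        np.stack(columns, axis=1)
        if columns
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return variants, GenotypeMatrix(samples, [v.key for v in variants], dosage)


#: default column map for the flat TSV dialect
TSV_COLUMNS = {
    "chrom": "chrom",
    "pos": "pos",
    "ref": "ref",
    "alt": "alt",
    "gene": "gene",
    "func_class": "func_class",
    "exonic_effect": "exonic_effect",
    "segdup": "segdup",
    "cadd_phred": "cadd_phred",
    "gerp": "gerp",
    "rsid": "rsid",
    "aa_change": "aa_change",
    "hope_size_change": "hope_size_change",
    "hope_charge_change": "hope_charge_change",
}


def _opt_float(val) -> Optional[float]:
    if val is None or (isinstance(val, float) and np.isnan(val)) or val in ("", "."):
        return None
    return float(val)


def _read_tsv(path, column_map: Optional[Mapping[str, str]] = None):
    cmap = dict(TSV_COLUMNS)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for required in ("chrom", "pos", "ref", "alt"):
        if cmap[required] not in df.columns:
            raise FormatError(f"{path}: missing required column {cmap[required]!r}")
    sample_cols = [c for c in df.columns if c.startswith("dosage_")]
    samples = [c[len("dosage_"):] for c in sample_cols]
    variants: list[AnnotatedVariant] = []
    dosage = np.full((len(samples), len(df)), MISSING, dtype=np.int8)
    for j, row in enumerate(df.itertuples(index=False)):
        row = row._asdict()

        def get(field, default=None):
            col = cmap.get(field)
            if col in row and row[col] != "":
                return row[col]
            return default

        calls = {
            p: normalize_predictor_call(row.get(p, row.get(p.lower())), p)
            for p in PREDICTORS
        }
        maf = {}
        for pop in ("NFE", "AFR"):
            v = _opt_float(row.get(f"maf_{pop.lower()}", ""))
            if v is not None:
                maf[pop] = v
        variants.append(
            AnnotatedVariant(
                chrom=str(get("chrom")),
                pos=int(get("pos")),
                ref=str(get("ref")),
                alt=str(get("alt")),
                gene=str(get("gene", "")),
                func_class=str(get("func_class", "other")),
                exonic_effect=str(get("exonic_effect", "unknown")),
                segdup=str(get("segdup", "False")).lower() in ("true", "1", "yes"),
                cadd_phred=_opt_float(get("cadd_phred")),
                gerp=_opt_float(get("gerp")),
                predictor_calls=calls,
                maf=maf,
                rsid=get("rsid"),
                aa_change=get("aa_change"),
                hope_size_change=str(get("hope_size_change", "none_reported")),
                hope_charge_change=str(get("hope_charge_change", "none_reported")),
            )
        )
        for s, col in enumerate(sample_cols):
            raw = row[col]
            if raw == ".":
                continue
            if raw not in ("0", "1", "2"):
                raise ValidationError(
                    f"{path}: dosage {raw!r} for sample {samples[s]} "
                    f"outside {{0,1,2,.}}"
                )
            dosage[s, j] = int(raw)
    return variants, GenotypeMatrix(samples, [v.key for v in variants], dosage)


def read_variant_table(
    path,
    dialect: str = "vcf",
    column_map: Optional[Mapping[str, str]] = None,
) -> tuple[list[AnnotatedVariant], GenotypeMatrix]:
    """Read an annotated variant table plus its dosage matrix.

    ``dialect`` is ``"vcf"`` (annotations in INFO keys) or ``"tsv"`` (flat
    annotation table with ``dosage_<sample>`` columns; ``column_map``
    overrides the default column names).  Duplicate (chrom,pos,ref,alt)
    keys are rejected; multiallelic VCF records are split into biallelic
    entries.
    """
    if dialect == "vcf":
        return _read_vcf(path)
    if dialect == "tsv":
        return _read_tsv(path, column_map)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_vcf(
    path,
    variants: Sequence[AnnotatedVariant],
    genotypes: GenotypeMatrix,
) -> None:
    """Write variants + dosages as a plain-text VCF with annotation INFO keys."""
    lines = ["##fileformat=VCFv4.2"]
    info_defs = [
        ('GENE', 'String', 'Gene symbol'),
        ('FUNC', 'String', 'Functional class'),
        ('EXONIC_FUNC', 'String', 'Exonic effect'),
        ('CADD', 'Float', 'CADD Phred score'),
        ('GERP', 'Float', 'GERP score'),
        ('MAF_NFE', 'Float', 'Non-Finnish European allele frequency'),
        ('MAF_AFR', 'Float', 'African/African-American allele frequency'),
        ('AA_CHANGE', 'String', 'Protein change'),
        ('HOPE_SIZE', 'String', 'Structural size change'),
        ('HOPE_CHARGE', 'String', 'Structural charge change'),
    ]
    for p in PREDICTORS:
        info_defs.append((p.upper(), 'String', f'{p} call'))
    for key, typ, desc in info_defs:
        num = "1"
        lines.append(f'##INFO=<ID={key},Number={num},Type={typ},Description="{desc}">')
    lines.append('##INFO=<ID=SEGDUP,Number=0,Type=Flag,Description="Segmental duplication">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    seen: list[str] = []
    for v in variants:
        if v.chrom not in seen:
            seen.append(v.chrom)
    for chrom in seen:
        lines.append(f"##contig=<ID={chrom}>")
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header += genotypes.individuals
    lines.append("\t".join(header))
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    for v in variants:
        info = []
        for key, attr in _INFO_KEYS.items():
            val = getattr(v, attr)
            if val is not None and val != "":
                info.append(f"{key}={val}")
        if v.segdup:
            info.append("SEGDUP")
        for p in PREDICTORS:
            info.append(f"{p.upper()}={v.predictor_calls.get(p, 'unknown')}")
        for pop, f in sorted(v.maf.items()):
            if f is not None:
                info.append(f"MAF_{pop}={f:.8g}")
        row = [
            v.chrom,
            str(v.pos),
            v.rsid or ".",
            v.ref,
            v.alt,
            ".",
            "PASS",
            ";".join(info) if info else ".",
            "GT",
        ]
        row += [
            gt_str[genotypes.dosage_of(ind, v.key)] for ind in genotypes.individuals
        ]
        lines.append("\t".join(row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# pedigrees


def read_pedigrees(path, default_subpop: str = "NFE") -> dict[str, Pedigree]:
    """Read a PED file (6 columns + optional subpopulation and branch).

    Columns: family, individual, father, mother, sex (1=male, 2=female),
    phenotype (ignored here — affectedness comes from the phenotype table),
    then optionally subpopulation and branch label.  ``0`` marks a missing
    parent.  Row order is irrelevant: children may precede their parents.
    """
    rows_by_family: dict[str, list[Individual]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise FormatError(f"{path}: line {lineno}: expected >= 6 PED columns")
            fam, ind, father, mother, sex = parts[0], parts[1], parts[2], parts[3], parts[4]
            subpop = parts[6] if len(parts) > 6 else default_subpop
            branch = parts[7] if len(parts) > 7 and parts[7] != "." else None
            rows_by_family.setdefault(fam, []).append(
                Individual(
                    id=ind,
                    father_id=None if father == "0" else father,
                    mother_id=None if mother == "0" else mother,
                    sex={"1": "male", "2": "female"}.get(sex, "unknown"),
                    branch_label=branch,
                    subpopulation=subpop,
                )
            )
    return {fam: Pedigree(fam, members) for fam, members in rows_by_family.items()}


def read_pedigree(path, family_id: Optional[str] = None, default_subpop: str = "NFE") -> Pedigree:
    """Read a single family from a PED file (error if ambiguous)."""
    peds = read_pedigrees(path, default_subpop)
    if family_id is not None:
        return peds[family_id]
    if len(peds) != 1:
        raise ValidationError(
            f"{path} holds {len(peds)} families; pass family_id to disambiguate"
        )
    return next(iter(peds.values()))


def write_ped(path, pedigrees: Mapping[str, Pedigree] | Pedigree) -> None:
    if isinstance(pedigrees, Pedigree):
        pedigrees = {pedigrees.family_id: pedigrees}
    sex_code = {"male": "1", "female": "2"}
    with open(path, "w") as fh:
        for fam in sorted(pedigrees):
            for m in pedigrees[fam].members:
                fh.write(
                    "\t".join(
                        [
                            fam,
                            m.id,
                            m.father_id or "0",
                            m.mother_id or "0",
                            sex_code.get(m.sex, "0"),
                            "0",
                            m.subpopulation,
                            m.branch_label or ".",
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# phenotypes

_PHENO_COLS = [
    "individual_id",
    "age_months",
    "third_person_singular",
    "past_tense",
    "be_do",
    "omnibus_ss",
    "recept_vocab_ss",
    "nviq_ss",
]


def read_phenotypes(path) -> list[PhenotypeRecord]:
    """Long-format phenotype CSV: one row per individual per timepoint."""
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_PHENO_COLS) - set(reader.fieldnames or ())
        if missing:
            raise FormatError(f"{path}: missing phenotype columns {sorted(missing)}")
        for row in reader:
            probes = {
                p: _opt_float(row[p])
                for p in ("third_person_singular", "past_tense", "be_do")
            }
            records.append(
                PhenotypeRecord(
                    individual_id=row["individual_id"],
                    timepoint=float(row["age_months"]),
                    probe_scores={k: v for k, v in probes.items() if v is not None},
                    omnibus_ss=_opt_float(row["omnibus_ss"]),
                    recept_vocab_ss=_opt_float(row["recept_vocab_ss"]),
                    nviq_ss=_opt_float(row["nviq_ss"]),
                )
            )
    return records


def write_phenotypes(path, records: Sequence[PhenotypeRecord]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_PHENO_COLS)
        for r in records:
            writer.writerow(
                [
                    r.individual_id,
                    repr(float(r.timepoint)),
                ]
                + [
                    "" if r.probe_scores.get(p) is None else repr(float(r.probe_scores[p]))
                    for p in ("third_person_singular", "past_tense", "be_do")
                ]
                + [
                    "" if v is None else repr(float(v))
                    for v in (r.omnibus_ss, r.recept_vocab_ss, r.nviq_ss)
                ]
            )


# ---------------------------------------------------------------------------
# report

REPORT_COLUMNS = [
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "family",
    "rsid",
    "aa_change",
    "criteria_failed",
    "coseg",
    "fisher_p",
    "verdict",
]


def write_report(
    prioritized: Mapping[str, Sequence[AnnotatedVariant]],
    verdicts: Mapping[VariantKey, ClassificationVerdict],
    path,
    coseg_status: Optional[Mapping[tuple[str, VariantKey], bool]] = None,
    fisher_p: Optional[Mapping[VariantKey, float]] = None,
    trace=None,
) -> pd.DataFrame:
    """Tab-delimited report: one row per (variant, family).

    Deterministic column order, stable sort by (gene, chrom, pos); rerunning
    on the same inputs yields a byte-identical file.
    """
    coseg_status = coseg_status or {}
    fisher_p = fisher_p or {}
    rows = []
    for fam, variants in prioritized.items():
        for v in variants:
            failed = sorted(trace.failures(v.key)) if trace is not None else []
            verdict = verdicts.get(v.key)
            p = fisher_p.get(v.key)
            rows.append(
                {
                    "gene": v.gene,
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "ref": v.ref,
                    "alt": v.alt,
                    "family": fam,
                    "rsid": v.rsid or ".",
                    "aa_change": v.aa_change or ".",
                    "criteria_failed": ",".join(failed) if failed else ".",
                    "coseg": {True: "yes", False: "no", None: "."}[
                        coseg_status.get((fam, v.key))
                    ],
                    "fisher_p": "." if p is None else f"{p:.6g}",
                    "verdict": verdict.verdict if verdict else ".",
                }
            )
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    df = df.sort_values(
        ["gene", "chrom", "pos", "ref", "alt", "family"], kind="stable"
    ).reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False)
    return df
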