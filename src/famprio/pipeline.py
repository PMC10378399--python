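"""End-to-end orchestration: phenotyping -> workflow 1 -> workflow 2 ->
association/classification, with a per-stage count ledger and a
machine-readable run manifest.

A run is a pure function of (inputs, config, seed): manifests carry a
content hash over the configuration and input digests, so reruns of the
same config produce identical manifests except for the timestamp field.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
import yaml

from . import __version__
from .assoc import (
    DEFAULT_REFERENCE_AN,
    burden_table_from_maf,
    classify_causality,
    fisher_burden_test,
)
from .io import (
    read_pedigrees,
    read_phenotypes,
    read_variant_table,
    write_report,
)
from .model import (
    AnnotatedVariant,
    CausalityEvidence,
    ConfigError,
    CosegRule,
    FilterConfig,
    GenotypeMatrix,
    Pedigree,
    PhenotypeRecord,
)
from .phenotyping import (
    CriterionTable,
    affected_ids,
    apply_nviq_exclusion,
    assign_affectedness_cohort,
    unaffected_ids,
)
from .workflow1 import Workflow1Result, run_workflow1
from .workflow2 import candidate_gene_filter, read_gene_list

__all__ = ["PipelineConfig", "PipelineError", "RunResult", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Declarative configuration for a full run.

    Either point at input files (``variant_table``/``pedigree_file``/
    ``phenotype_file``) or set ``simulate`` to a cohort spec mapping to
    generate inputs in memory.
    """

    variant_table: Optional[str] = None
    dialect: str = "vcf"
    pedigree_file: Optional[str] = None
    phenotype_file: Optional[str] = None
    simulate: Optional[dict] = None
    criterion_cut: float = 80.0
    criterion_csv: Optional[str] = None
    nviq_threshold: float = 85.0
    filter: FilterConfig = field(default_factory=FilterConfig)
    coseg_rules: dict[str, CosegRule] = field(default_factory=dict)
    candidate_gene_file: Optional[str] = None
    reference_an: int = DEFAULT_REFERENCE_AN
    outdir: Optional[str] = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        filt = raw.pop("filter", {})
        if isinstance(filt, dict):
            if "allowed_func_classes" in filt:
                filt["allowed_func_classes"] = frozenset(filt["allowed_func_classes"])
            if "gene_blocklist" in filt:
                filt["gene_blocklist"] = frozenset(filt["gene_blocklist"])
            filt = FilterConfig(**filt)
        rules = {
            fam: CosegRule(family_id=fam, **spec) if isinstance(spec, dict) else spec
            for fam, spec in raw.pop("coseg_rules", {}).items()
        }
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(filter=filt, coseg_rules=rules, **raw)

    def to_canonical_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["filter"]["allowed_func_classes"] = sorted(
            self.filter.allowed_func_classes
        )
        d["filter"]["gene_blocklist"] = sorted(self.filter.gene_blocklist)
        return d


@dataclass
class RunResult:
    statuses_by_family: dict[str, dict]
    workflow1: Workflow1Result
    workflow2: dict[str, list[AnnotatedVariant]]
    verdicts: dict
    fisher_p: dict
    report: pd.DataFrame
    ledger: dict
    manifest: dict


def _sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_inputs(config: PipelineConfig):
    if config.simulate is not None:
        from .simulate import CohortSpec, FamilyTemplate, PlantedVariant, simulate_cohort

        raw = dict(config.simulate)
        raw.setdefault("seed", config.seed)
        if "template" in raw and isinstance(raw["template"], dict):
            raw["template"] = FamilyTemplate(**raw["template"])
        if "planted" in raw:
            raw["planted"] = tuple(
                PlantedVariant(**p) if isinstance(p, dict) else p
                for p in raw["planted"]
            )
        cohort = simulate_cohort(CohortSpec(**raw))
        return cohort.variants, cohort.genotypes, cohort.pedigrees, cohort.phenotypes
    for name in ("variant_table", "pedigree_file", "phenotype_file"):
        if getattr(config, name) is None:
            raise ConfigError(f"config needs {name} (or a simulate block)")
    variants, genotypes = read_variant_table(config.variant_table, config.dialect)
    pedigrees = read_pedigrees(config.pedigree_file)
    phenotypes = read_phenotypes(config.phenotype_file)
    return variants, genotypes, pedigrees, phenotypes


def run_pipeline(config: PipelineConfig) -> RunResult:
    """Execute phenotyping, both workflows, association and classification.

    Any stage failure aborts with the stage name and cause.  When
    ``config.outdir`` is set, reports, the stage-count ledger and the run
    manifest are written there as TSV/JSON.
    """
    t0 = time.time()
    try:
        variants, genotypes, pedigrees, phenotypes = _load_inputs(config)
    except Exception as e:
        raise PipelineError("load_inputs", e) from e

    try:
        table = (
            CriterionTable.from_csv(config.criterion_csv)
            if config.criterion_csv
            else CriterionTable.flat(config.criterion_cut)
        )
        statuses = assign_affectedness_cohort(phenotypes, table)
        statuses = apply_nviq_exclusion(statuses, phenotypes, config.nviq_threshold)
        statuses_by_family = {
            fam: {i: statuses[i] for i in ped.member_ids if i in statuses}
            for fam, ped in pedigrees.items()
        }
    except Exception as e:
        raise PipelineError("phenotyping", e) from e

    try:
        w1 = run_workflow1(
            variants, genotypes, statuses_by_family, pedigrees,
            config.filter, config.coseg_rules,
        )
    except Exception as e:
        raise PipelineError("workflow1", e) from e

    try:
        if config.candidate_gene_file:
            gene_list = read_gene_list(config.candidate_gene_file)
        else:
            from .datasets import load_candidate_genes

            gene_list = load_candidate_genes()
        w2: dict[str, list[AnnotatedVariant]] = {}
        for fam, ped in sorted(pedigrees.items()):
            fam_statuses = statuses_by_family.get(fam, {})
            aff = affected_ids(fam_statuses)
            unaff = unaffected_ids(fam_statuses)
            if len(aff) < config.filter.min_affected_sharers:
                w2[fam] = []
                continue
            subpop = config.filter.subpopulation_by_family.get(
                fam, ped.members[0].subpopulation
            )
            w2[fam] = candidate_gene_filter(
                variants, genotypes, aff, gene_list, config.filter,
                unaffected_ids=unaff, family_subpop=subpop, family_id=fam,
                trace=w1.trace,
            )
    except Exception as e:
        raise PipelineError("workflow2", e) from e

    try:
        prioritized: dict[str, list[AnnotatedVariant]] = {}
        for fam in pedigrees:
            merged = {v.key: v for v in w1.final_variants.get(fam, [])}
            merged.update({v.key: v for v in w2.get(fam, [])})
            prioritized[fam] = sorted(
                merged.values(), key=lambda v: (v.gene, v.chrom, v.pos)
            )
        verdicts = {}
        fisher_p = {}
        coseg_status = {}
        by_key: dict = {}
        for fam, vs in prioritized.items():
            for v in vs:
                by_key.setdefault(v.key, {"variant": v, "families": set()})
                by_key[v.key]["families"].add(fam)
                in_coseg = any(
                    u.key == v.key for u in w1.coseg_lists.get(fam, [])
                ) or any(u.key == v.key for u in w2.get(fam, []))
                coseg_status[(fam, v.key)] = in_coseg
        scored = [i for i, s in statuses.items() if s.combined_affected == "yes"
                  and not s.excluded_low_nviq and i in genotypes._irow]
        for key, entry in by_key.items():
            v = entry["variant"]
            fams = entry["families"]
            n_unaff_carriers = 0
            for fam in fams:
                fam_statuses = statuses_by_family.get(fam, {})
                unaff = unaffected_ids(fam_statuses)
                n_unaff_carriers += len(genotypes.carriers(key, among=unaff))
            evidence = CausalityEvidence(
                maf=min((m for m in v.maf.values() if m is not None), default=None),
                gerp_positive=v.gerp is not None and v.gerp > 0,
                cadd_ge_threshold=v.cadd_phred is not None
                and v.cadd_phred >= config.filter.cadd_min,
                n_damaging=v.n_damaging,
                hope_size_change=v.hope_size_change,
                hope_charge_change=v.hope_charge_change,
                coseg_confirmed=any(coseg_status.get((fam, key)) for fam in fams),
                n_discovery_families=len(fams),
                n_additional_probands=0,
                n_unaffected_carriers=n_unaff_carriers,
            )
            verdicts[key] = classify_causality(key, evidence)
            ref_maf = min((m for m in v.maf.values() if m is not None), default=None)
            if ref_maf is not None and scored:
                n_carrier = len(genotypes.carriers(key, among=scored))
                fisher_p[key] = fisher_burden_test(
                    burden_table_from_maf(
                        n_carrier, 2 * len(scored), ref_maf, config.reference_an
                    )
                )
    except Exception as e:
        raise PipelineError("assoc_classify", e) from e

    ledger = {
        "workflow1": w1.ledger,
        "workflow2": {fam: len(vs) for fam, vs in w2.items()},
        "prioritized": {fam: len(vs) for fam, vs in prioritized.items()},
    }
    canonical = json.dumps(
        {
            "config": _jsonable(PipelineConfig.to_canonical_dict(config)),
            "inputs": {
                name: _sha256_file(p)
                for name, p in (
                    ("variant_table", config.variant_table),
                    ("pedigree_file", config.pedigree_file),
                    ("phenotype_file", config.phenotype_file),
                )
                if p is not None
            },
        },
        sort_keys=True,
    )
    manifest = {
        "content_hash": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": config.seed,
        "version": __version__,
        "n_variants": len(variants),
        "n_individuals": len(genotypes.individuals),
        "n_families": len(pedigrees),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
        "elapsed_s": round(time.time() - t0, 3),
    }

    outdir = Path(config.outdir) if config.outdir else None
    report = None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        report = write_report(
            prioritized, verdicts, outdir / "report.tsv",
            coseg_status=coseg_status, fisher_p=fisher_p, trace=w1.trace,
        )
        w1.trace.to_frame().to_csv(outdir / "trace.tsv", sep="\t", index=False)
        with open(outdir / "ledger.json", "w") as fh:
            json.dump(ledger, fh, indent=2, sort_keys=True)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    else:
        import io as _io

        report = write_report(
            prioritized, verdicts, _io.StringIO(),
            coseg_status=coseg_status, fisher_p=fisher_p, trace=w1.trace,
        )
    return RunResult(
        statuses_by_family=statuses_by_family,
        workflow1=w1,
        workflow2=w2,
        verdicts=verdicts,
        fisher_p=fisher_p,
        report=report,
        ledger=ledger,
        manifest=manifest,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)
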