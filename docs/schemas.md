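# File schemas

All formats are plain text. Coordinates are 1-based and fully closed
throughout; variant identity is always `(chrom, pos, ref, alt)`.

## Variant tables

### VCF dialect (`read_variant_table(path, dialect="vcf")`)

Standard VCF v4.x with genotypes in `GT`. Missing genotypes (`./.`) are
*missing*, never reference. Multiallelic records are split into biallelic
entries (per-ALT allele counts). Annotations are carried in INFO keys:

| INFO key            | Type   | Meaning                                         |
|---------------------|--------|-------------------------------------------------|
| `GENE`              | String | gene symbol                                     |
| `FUNC`              | String | `exonic`, `splicing`, `exonic;splicing`, `intronic`, `UTR`, `intergenic`, `other` |
| `EXONIC_FUNC`       | String | `nonsynonymous`, `synonymous`, `stopgain`, `stoploss`, `frameshift`, `nonframeshift`, `unknown` |
| `SEGDUP`            | Flag   | inside a segmental duplication                  |
| `CADD`              | Float  | CADD Phred score                                |
| `GERP`              | Float  | GERP conservation score                         |
| `MAF_NFE`, `MAF_AFR`| Float  | subpopulation allele frequency; **absent = unknown, not 0** |
| `SIFT`, `POLYPHEN2`, `MUTATIONASSESSOR`, `PROVEAN`, `MUTATIONTASTER` | String | raw predictor calls, normalized via `data/predictor_vocab.yaml` |
| `AA_CHANGE`         | String | protein HGVS                                    |
| `HOPE_SIZE`         | String | `increase`, `decrease`, `none_reported`         |
| `HOPE_CHARGE`       | String | `pos_to_neu`, `neg_to_neu`, `neu_to_pos`, `neu_to_neg`, `none`, `none_reported` |

### Flat TSV dialect (`dialect="tsv"`)

One row per variant. Required columns `chrom`, `pos`, `ref`, `alt`;
optional annotation columns named as the `AnnotatedVariant` fields
(`gene`, `func_class`, `exonic_effect`, `segdup`, `cadd_phred`, `gerp`,
`maf_nfe`, `maf_afr`, `rsid`, `aa_change`, `hope_size_change`,
`hope_charge_change`, plus the five predictor columns by program name).
Genotypes go in `dosage_<sample>` columns with values `0`, `1`, `2` or `.`
(missing). A `column_map` argument renames columns for other annotation
toolchains. Empty MAF cells are unknown.

## Pedigrees (PED)

Whitespace-delimited, 6 required columns plus 2 optional:

    family  individual  father  mother  sex  phenotype  [subpopulation]  [branch]

`0` marks a missing parent; sex is `1` male / `2` female; the PED
phenotype column is ignored (affectedness is derived from the phenotype
CSV). Subpopulation defaults to `NFE`; branch `.` means unlabeled. Row
order is free — children may precede parents.

## Phenotypes (CSV)

Long format, one row per individual per timepoint:

    individual_id, age_months, third_person_singular, past_tense, be_do,
    omnibus_ss, recept_vocab_ss, nviq_ss

Probe columns are percentages in [0, 100]; `*_ss` are standard scores
(mean 100, SD 15). Empty cells are missing.

## Criterion table (CSV)

Age-banded criterion scores: `lo_months, hi_months, screener_cut,
composite_cut`. Bands must cover ages 36–107 months without overlap.

## Candidate genes / regions

Gene list: one symbol per line, `#` comments allowed. Region list:
BED-like TSV `chrom  start  end`, **1-based fully inclusive** in this
dialect (unlike BED's half-open 0-based convention).

## Report (TSV)

One row per (variant, family), sorted by (gene, chrom, pos):
`gene, chrom, pos, ref, alt, family, rsid, aa_change, criteria_failed,
coseg, fisher_p, verdict`. `criteria_failed` lists any a priori criteria
the variant failed anywhere in the run; `.` means none recorded.
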