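# famprio

Family-based rare-variant prioritization for a grammar-defined language
impairment phenotype.

Children with specific language impairment (SLI) struggle to acquire
language despite average non-verbal intelligence. Tense/agreement-marking
probes (a screener score and an elicited grammar composite) dichotomize
this phenotype precisely in ages 3;0–8;11, and it is highly heritable —
which makes multiplex families informative for rare-variant discovery even
when only the child generation can be phenotyped. `famprio` implements
that analysis for geneticists and speech-language researchers working with
annotated exome data from such families:

- **Phenotyping** — screener = mean(third-person singular, past tense);
  composite adds the be/do probes; affectedness from the lowest score
  across timepoints vs an age-referenced criterion; NV-IQ ≤ 85 exclusion.
- **Workflow 1 (exome-wide)** — a priori criteria: exonic/splicing, not
  synonymous, outside segmental duplications, CADD Phred ≥ 20, GERP > 0,
  shared by ≥ 2 affected family members, ≥ 2/5 damaging in-silico calls;
  rare (subpopulation MAF ≤ 0.01) or novel (unknown MAF, predicted
  deleterious); genes shared across ≥ 2 families; family co-segregation
  rules with a ≥ 4-affected-carriers-across-≥ 2-families gate.
- **Workflow 2 (candidate genes)** — the same within-family criteria at
  MAF < 0.07 against a user-supplied candidate-gene list, without the
  cross-family requirement; plus 1-based-inclusive region lookup.
- **Association & classification** — exact two-sided Fisher tests of
  carrier vs non-carrier alleles in probands against a population
  reference (reference AC = round(MAF × AN), AN = 113,770 default);
  distinct-proband carrier tallies; and a six-criterion
  pathogenic / likely-pathogenic / benign rule
  (MAF < 0.05; co-segregation or multi-proband carriage or structural
  change; GERP > 0; CADD ≥ 20; ≥ 2/5 damaging; amino-acid size/charge
  change) with replication required for P and an unaffected-carrier
  benign override.
- **Synthetic cohorts** — pedigree templates, Hardy–Weinberg founders with
  Mendelian gene dropping, annotation profiles, and a penetrance/phenocopy
  liability model, so the entire chain is testable without data access.
- **Clustered t test** — two-sample comparison on family means (Welch +
  Satterthwaite) for covariates like maternal education, where siblings
  are not independent.

See `docs/methods.md` for the model details and `docs/schemas.md` for all
file formats (VCF/TSV variant tables, PED, phenotype CSV, reports).

## Worked example

The package bundles a 12-variant worked example: Sanger-confirmed variants
from a family-based exome study of the grammar phenotype, with per-variant
carrier lists over 154 probands (8 discovery + 146 additional), encoded so
the tally, burden-test and classification operations run on real printed
summary data. `python examples/04_worked_example.py` prints:

```
distinct additional probands carrying a prioritized variant: 17
  affected on a grammar measure: 13
  unaffected on both measures:   4 (all carry the common GLI3 variant)

gene     rsid         MAF      Fisher p   verdict
PDHA2    rs147966234  0.0089      0.3589   P
PCDHB3   rs61739886   0.0064      0.4539   P
FURIN    rs150925934  0.0017     0.09801   P
NOL6     rs114465306  8e-05     4.34e-06   P
NOL6     rs114110943  0.006           NA   Likely P
IQGAP3   rs147754283  5e-05           NA   Likely P
IQGAP3   rs112144116  0.0034     0.08973   P
BAHCC1   rs369588790  6e-05           NA   Likely P
BAHCC1   rs200719992  0.0066          NA   Likely P
GLI3     rs35364414   0.0536       0.447   B
FLNB     rs116826041  0.0093      0.3788   B
KMT2D    rs146044282  0.0015          NA   Likely P
```

The tally counts distinct probands (one proband carries variants on both
GLI3 and PDHA2 and is counted once). A Fisher p above 0.05 means proband
carrier rates are compatible with the reference subpopulation frequency;
the NOL6 variant, never observed in the non-Finnish European reference, is
the one significant excess. Verdicts combine predicted deleteriousness
with segregation evidence: the common GLI3 variant and the FLNB variant
carried by an unaffected sibling come out benign; fully supported variants
without replication beyond one family stay "Likely P".

The other examples cover the simulator (`01`), phenotype scoring (`02`),
both filtering workflows on a simulated cohort with a planted causal
variant (`03`), and a one-config pipeline run with ledger and manifest
(`05`). A thin CLI wraps the same stages:

```sh
famprio simulate --seed 7 --out scratch/cohort
famprio run --config config.yaml --out scratch/run
famprio classify --out verdicts.tsv
```

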