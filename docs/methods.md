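# Methods

## The analysis this package implements

Specific language impairment (SLI) is a deficit in language acquisition in
children with otherwise typical development and average non-verbal
intelligence. Grammar probes of tense/agreement marking — a screener score
(mean of the third-person-singular and past-tense elicitation probes) and
an elicited grammar composite that adds the be/do probes — dichotomize the
phenotype with high sensitivity and specificity in ages 3;0–8;11, and the
trait is strongly heritable. `famprio` implements the family-based
rare-variant prioritization that this phenotype enables: given exomes for
multi-generation families ascertained for predominance of affectedness,
find rare, predicted-deleterious variants that co-segregate with low
grammar performance across families, test prioritized variants for carrier
excess against a population reference, and grade their causal support.

## Affectedness model

An individual is affected on a measure when any timepoint's score falls
below the age-referenced criterion — the "lowest score across timepoints"
rule, which makes affectedness monotone: lowering a probe score or adding
a timepoint can never move someone from affected to unaffected (both
properties are tested). Ties at the criterion are unaffected
(`strict=True`; configurable, since "low performance" phrasing does not
fix the boundary). The combined status is affected when either measure is;
individuals whose two measures disagree are flagged discordant but count
as affected. The composite is an unweighted mean of the three probe
percentages; the instrument manual's exact weighting is proprietary, so
weights are a parameter. Criterion scores are likewise not public:
`CriterionTable` is a required config, with a flat 80% cut as the
simulation default. Individuals with non-verbal IQ ≤ 85 (the study-entry
bound) are flagged and excluded from all sharing and co-segregation
counts; missing NV-IQ retains the individual with a logged warning.

## Variant prioritization

Both workflows share the a priori criteria: (i) functional class exonic /
splicing / exonic;splicing, (ii) not synonymous, (iii) outside segmental
duplications, (iv) CADD Phred ≥ 20, (v) GERP > 0, (vi) carried by ≥ 2
affected family members, (vii) ≥ 2 of 5 damaging in-silico calls (SIFT,
PolyPhen-2, MutationAssessor, PROVEAN, MutationTaster). Decisions per
variant are written to a trace so per-stage counts reconstruct exactly.

Numerical/policy choices, all config-exposed:

- **Unknown scores fail.** A variant with no CADD or GERP value fails
  criteria (iv)/(v): only scored, predicted-deleterious variants are
  prioritized. `unknown_scores_fail=False` passes them through.
- **Unknown frequency is never zero.** Workflow 1 keeps variants with
  subpopulation MAF ≤ 0.01 *or* unknown MAF plus a predicted deleterious
  effect ("novel" variants). Workflow 2's relaxed screen (MAF < 0.07,
  strict) passes unknown-MAF variants by default, consistently.
- **Carriers are individuals, not alleles.** A homozygote is one sharer.
  A missing genotype is neither carrier nor non-carrier; the individual
  simply drops out of that variant's counts.
- **Subpopulation-matched frequency.** Each family filters against its
  own subpopulation's MAF (non-Finnish European or African here; the map
  is a config input).

Workflow 1 then intersects family comparison lists at the gene level
(gene kept when ≥ 2 families contribute a qualifying variant; a blocklist
models genes excluded on external evidence such as protein expression),
applies per-family co-segregation rules, and finally requires ≥ 4 affected
carriers across ≥ 2 families per surviving gene. The default
co-segregation rule — every genotyped, non-excluded affected member
carries; zero genotyped unaffected carriers — stands in for family-specific
criteria, which in a real study depend on pedigree structure and are
supplied per family (`CosegRule` supports pinned carriers, branch
restriction and an unaffected-carrier allowance).

Workflow 2 drops the cross-family requirement (a hit on a previously
reported candidate gene already has external support) but keeps the
within-family criteria including the zero-unaffected-carrier guard, which
is what keeps a variant seen in a proband and their unaffected sibling out
of the output. Region lookup is a separate 1-based-inclusive interval
query for targeted follow-up of previously linked regions.

## Burden test and causality rule

The burden comparison is an exact two-sided Fisher test on carrier vs
non-carrier *alleles*: study probands (heterozygous carriers contribute
one allele; the proband allele total is 2 × readable probands) against a
population reference. References usually publish frequencies, not counts,
so the reference allele count is reconstructed as `round(MAF × AN)` with
AN = 113,770 by default (a nominal non-Finnish-European exome allele
number). Bound-style conclusions (p > 0.05, p < 1e-4) are insensitive to
AN across [50k, 300k] — asserted in tests — but exact published p-values
are generally not recoverable from frequencies alone. Two-sided p follows
the minimum-likelihood convention (sum of fixed-margin tables no more
probable than the observed), delegated to `scipy.stats.fisher_exact` and
verified against an exact-rational enumeration oracle.

The causality rule grades each variant on six criteria: (1) MAF < 0.05,
(2) co-segregation OR carriage by > 1 proband OR a significant amino-acid
structural change, (3) positive GERP, (4) CADD ≥ 20, (5) ≥ 2/5 damaging
calls, (6) an amino-acid size or charge change in the structural
annotation (missing structural output fails conservatively). Failing any
of (1), (3)–(6) is benign. Two interpretive toggles, on by default, were
needed to make the rule self-consistent with graded verdicts:
*pathogenic* additionally requires replication beyond the discovery
family (≥ 2 discovery families or ≥ 1 additional proband carrier) —
otherwise the verdict is *likely pathogenic*, reflecting that partial
phenotype availability caps attainable co-segregation evidence — and any
carrier unaffected on both grammar measures forces *benign*, since
carriage without the phenotype is direct evidence against causality.
With both toggles the rule reproduces all 12 verdicts of the bundled
worked example.

The distinct-proband tally is a set union over per-variant carrier lists
(a proband carrying variants on two genes counts once), with an
affected/unaffected breakdown; it is idempotent and order-invariant by
construction.

## Family-clustered t test

Group comparisons over siblings violate independence, so the two-sample t
procedure collapses observations to unweighted family means and applies
Welch's t with Satterthwaite degrees of freedom to the cluster means —
the family, not the child, is the sampling unit. When every cluster has
one observation this reduces exactly to Welch's t on the raw data (tested
algebraically), and under normal family effects it is calibrated: the
type-I error at nominal 5% lands in [0.03, 0.07] over 1000 null
simulations in the acceptance suite. Cluster-robust OLS sandwich
estimators were deliberately not used: with ~10–20 families per group the
unadjusted CR0 variance is anticonservative, whereas cluster-mean Welch
is exact under the exchangeable random-effects null. Requirements: two
groups, ≥ 2 clusters per group, no cluster spanning both groups.

## Synthetic cohort generator

The generator produces the statistical structure the analysis assumes and
nothing more. Defaults emulate the target study design: 8 families
(three-generation, two-branch, sibship 2 → 10 members each, 80 total), one
family of African ancestry, 20,000 background exonic variants (real
per-family exomes carry 12k–47k), and only the youngest generation inside
the 3;0–8;11 window receives grammar scores (32 of 80), so parents are
status-unknown exactly as in real data.

- **Pedigrees** are deterministic template instantiations; member counts
  follow a closed form (2 + branches × (2 + sibship) for three
  generations) asserted in tests.
- **Gene dropping**: founders draw Hardy–Weinberg dosages at the variant's
  founder frequency; each child receives one allele per parent as a
  Bernoulli(parental dosage/2) draw. Missingness masks genotypes *after*
  transmission, so a masked carrier still shaped the phenotypes.
  Mendelian 1:2:1 segregation and founder-frequency convergence are
  tested against binomial error bounds.
- **Annotations**: planted variants use a causal-like profile that passes
  every a priori threshold by construction; background variants draw each
  criterion independently at configured pass rates (defaults: exonic 0.60,
  non-synonymous 0.50, non-segdup 0.95, CADD-pass 0.15, GERP-pass 0.60,
  ≥2-damaging 0.30, rare 0.40), so the joint pass rate follows a product
  law that is tested empirically. Real predictors correlate; independence
  is a simplification noted below.
- **Phenotypes**: a threshold Bernoulli liability model — carriers of a
  planted variant score below criterion with probability f1 (default 0.8),
  non-carriers with f0 (default 0.07, the SLI prevalence in
  English-speaking populations); probe scores are then drawn on the
  assigned side of the criterion, with a configurable fraction of affected
  children discordant (screener unaffected, composite affected) and a 5%
  low-NV-IQ rate among scored children.
- **Ascertainment**: planted families are redrawn (planted-variant
  transmission plus the family's phenotypes) until at least
  `min_planted_carriers` (2) scored, non-excluded affected carriers
  exist. This mirrors recruiting families for informativeness and is what
  makes the planted-gene recovery property exact rather than
  probabilistic: at f1 = 1, f0 = 0 and zero missingness, recovery is 100%
  across replicates, and it degrades monotonically as missingness grows.

What passing tests on synthetic cohorts do *not* show: robustness to
linkage disequilibrium, correlated predictors, population stratification
within a family set, sequencing artifacts, or miscalled pedigrees — none
of which the generator emulates. Results on real data depend on
annotation quality and on family-specific co-segregation rules chosen by
the analyst.

## Problem sizes used by the test and acceptance suites

Simulation-based checks run on scaled-down cohorts chosen once: oracle
equivalence on 100 random cohorts of ≤ 50 variants and 2–4 families;
planted-variant recovery on 200 replicates per missingness level
(2 families, 30 background variants); Fisher-vs-enumeration exhaustively
over all 2×2 tables with total ≤ 30 plus a seeded sample with row margins
≤ 30; clustered-t calibration over 1000 null simulations with 10 families
of 3 children per group. The acceptance script reuses these sizes (100
recovery replicates) and finishes in seconds.

## Known limitations

- The bundled candidate-gene list is a placeholder drawn from the SLI/DLD
  literature; a real analysis substitutes the analyst's curated list.
- The composite weighting, criterion scores, and family-specific
  co-segregation rules are configuration, not knowledge the package
  ships; defaults are documented stand-ins.
- Reference allele counts reconstructed from frequencies make exact
  published p-values unattainable in principle; only bounds are asserted.
- Compound-heterozygote / multi-hit models and any upstream sequencing,
  alignment, calling or annotation computation are out of scope.
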