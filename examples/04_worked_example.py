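"""The bundled 12-variant worked example end to end.

Twelve Sanger-confirmed variants from a family-based exome study of a
grammar-impairment phenotype: tally the distinct additional probands
carrying them, run the proband-vs-reference Fisher burden tests, and apply
the six-criterion causality rule.
"""

from famprio.assoc import (
    classify_causality,
    fisher_burden_test,
    tally_additional_probands,
)
from famprio.datasets import (
    load_worked_example,
    worked_example_burden_tables,
    worked_example_carriers,
    worked_example_evidence,
)

df = load_worked_example()
tally = tally_additional_probands(worked_example_carriers())
print(f"distinct additional probands carrying a prioritized variant: {tally.n_total}")
print(f"  affected on a grammar measure: {tally.n_affected}")
print(f"  unaffected on both measures:   {tally.n_unaffected} "
      "(all carry the common GLI3 variant)")

print("\ngene     rsid         MAF      Fisher p   verdict")
tables = worked_example_burden_tables()
evidence = worked_example_evidence()
for row in df.itertuples(index=False):
    p = f"{fisher_burden_test(tables[row.rsid]):.4g}" if row.rsid in tables else "NA"
    verdict = classify_causality(row.rsid, evidence[row.rsid]).verdict
    print(f"{row.gene:8s} {row.rsid:12s} {row.maf:<8g} {p:>9s}   {verdict}")

# A p-value above 0.05 means proband carrier rates are compatible with the
# reference subpopulation frequency; the NOL6 variant (absent from the
# reference) is the one significant excess.  Verdicts: P needs all six
# criteria plus replication beyond one family; a carrier unaffected on the
# grammar measures (GLI3, FLNB) forces benign.
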