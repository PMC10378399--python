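"""Score grammar probes and assign categorical affectedness.

Demonstrates the two derived scores (screener = mean of third-person
singular and past tense; composite adds the be/do probes), the
lowest-score-across-timepoints rule, discordant measures, and the
non-verbal-IQ exclusion.
"""

from famprio.model import PhenotypeRecord
from famprio.phenotyping import (
    CriterionTable,
    apply_nviq_exclusion,
    assign_affectedness,
    composite_score,
    screener_score,
)

criterion = CriterionTable.flat(80.0)  # single 80% criterion across ages

probes = {"third_person_singular": 80.0, "past_tense": 60.0, "be_do": 70.0}
print(f"screener({probes['third_person_singular']:.0f}, {probes['past_tense']:.0f})"
      f" = {screener_score(probes):.0f}")
print(f"composite(..., be_do={probes['be_do']:.0f}) = {composite_score(probes):.0f}")

# Two timepoints: fine at age 4, below criterion at age 6 -> affected
records = [
    PhenotypeRecord("child_a", 48.0, {"third_person_singular": 95.0,
                                      "past_tense": 95.0, "be_do": 95.0}),
    PhenotypeRecord("child_a", 72.0, {"third_person_singular": 60.0,
                                      "past_tense": 60.0, "be_do": 60.0}),
]
status = assign_affectedness(records, criterion)
print(f"\nchild_a lowest-score rule: combined_affected={status.combined_affected}")

# Discordant: screener in the unaffected range, composite dragged below
rec = PhenotypeRecord("child_b", 60.0, {"third_person_singular": 90.0,
                                        "past_tense": 86.0, "be_do": 40.0},
                      nviq_ss=84.0)
status_b = assign_affectedness([rec], criterion)
print(f"child_b screener={status_b.screener_affected} "
      f"composite={status_b.composite_affected} "
      f"combined={status_b.combined_affected} discordant={status_b.discordant}")

# NV-IQ <= 85 flags the child as excluded from sharing/co-segregation counts
excluded = apply_nviq_exclusion({"child_b": status_b}, [rec])
print(f"child_b NV-IQ 84 -> excluded_low_nviq={excluded['child_b'].excluded_low_nviq}")
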