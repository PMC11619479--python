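"""Generate a synthetic UF-5000 cohort and look at its composition.

The generator draws culture outcomes (≈31.8% bacterial-positive among
non-yeast specimens, 88.5% of positives at >=10^5 CFU/mL, Gram-negative
predominance), lognormal BACT/WBC counts per stratum, Gram-class-specific
(B_FSC, B_FLH) channel features, and instrument flags gated on
WBC >= 10/µL and BACT >= 100/µL.
"""

from collections import Counter

from uroscreen import simulate
from uroscreen.records import CultureStatus

cfg = simulate.make_default_config(seed=42, n_samples=823)
cohort = simulate.generate_cohort(cfg)

statuses = Counter(c.status.value for c in cohort.cultures)
non_yeast = len(cohort) - statuses["yeast"]
positives = statuses["positive"]
print(f"cohort size:            {len(cohort)}")
print(f"culture status counts:  {dict(statuses)}")
print(f"bacterial positivity:   {positives}/{non_yeast} = {100 * positives / non_yeast:.1f}%"
      " of non-yeast specimens (generator target 31.8%)")

ge5 = sum(
    1 for c in cohort.cultures
    if c.status is CultureStatus.POSITIVE and c.cfu_category.value == "ge1e5"
)
print(f">=10^5 CFU/mL among positives: {ge5}/{positives} = {100 * ge5 / positives:.1f}%"
      " (target 88.5%)")

flags = Counter(s.flag.value for s in cohort.samples)
print(f"flag counts:            {dict(flags)}")
print("('No flag' dominates because flagging requires WBC >= 10/µL AND BACT >= 100/µL)")

simulate.write_cohort(cohort, "samples.csv", "cultures.csv")
print("wrote samples.csv and cultures.csv")
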