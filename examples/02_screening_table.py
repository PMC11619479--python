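"""Screening cut-off table: BACT count vs culture at fixed sensitivity floors.

For each nominal sensitivity, the largest BACT cut-off still achieving it is
selected (maximizing specificity under the sensitivity floor), and the
culture-workload economics of running only cut-off-positive urines are
reported: the fraction of cultures avoided and the false-negative rate among
the avoided ones.
"""

import numpy as np

from uroscreen import screening, simulate
from uroscreen.pipeline import threshold_table_frame
from uroscreen.records import CultureStatus

cohort = simulate.generate_cohort(simulate.make_default_config(seed=42, n_samples=823))
keep = [
    (s.bact_per_ul, int(c.status is CultureStatus.POSITIVE))
    for s, c in zip(cohort.samples, cohort.cultures)
    if c.status is not CultureStatus.YEAST
]
bact, labels = map(np.array, zip(*keep))

roc = screening.empirical_roc(bact, labels)
ci = screening.auc_ci(bact, labels)
print(f"BACT AUC vs culture (>=10^4 CFU/mL): {roc.auc:.3f} "
      f"(95% CI {ci[0]:.3f} to {ci[1]:.3f})")

rows = screening.sensitivity_table(bact, labels, [80, 85, 90, 95, 97.5, 99])
print(threshold_table_frame(rows).to_string(index=False))

sen95 = rows[3]
wl = screening.workload_reduction(sen95.counts)
red, fnr = wl.rounded()
print(f"\nAt the SEN-95 cut-off ({sen95.cutoff:.1f}/µL): culture workload "
      f"reduced by {red}%, with a false-negative rate of {fnr}% among "
      "specimens not cultured.")
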