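"""The scattergram-angle rule for predicting Gram-negative infection.

Each specimen's bacterial cloud lies on a ray of slope B_FSC/B_FLH on the
scattergram (fluorescence on the abscissa). Gram-negatives sit low (small,
brightly staining single cells); Gram-positives sit steep (large poorly
staining aggregates). A Youden-optimal ratio cut-off is fitted on
training-cohort positives, converted to an integer angle, and validated on
the held-out cohort with the "< angle predicts GN" rule.
"""

from uroscreen import gram, screening, simulate
from uroscreen.records import Cohort, CultureStatus, Gram

cohort = simulate.generate_cohort(simulate.make_default_config(seed=42, n_samples=3000))
positives = [
    (s, c) for s, c in zip(cohort.samples, cohort.cultures)
    if c.status is CultureStatus.POSITIVE
]

def gram_label(culture):
    return "GN" if Gram.NEGATIVE in culture.gram_classes else "GP"

train = [(s, c) for s, c in positives if s.cohort is Cohort.TRAINING]
ratios = [gram.fsc_flh_ratio(s.b_fsc_ch, s.b_flh_ch) for s, _ in train]
clf = gram.fit_ratio_cutoff(ratios, [gram_label(c) for _, c in train])
tm = clf.training_metrics.rounded()
print(f"fitted ratio cut-off: {clf.ratio_cutoff:.3f} "
      f"-> angle {clf.angle_deg:.2f}°, reported as {clf.angle_cutoff_deg}°")
print(f"training sensitivity {tm['sensitivity']}%, specificity {tm['specificity']}% "
      f"(Youden J = {clf.youden:.3f})")

valid = [(s, c) for s, c in positives if s.cohort is Cohort.VALIDATION]
preds, counts, skipped = gram.classify_by_angle(
    [s for s, _ in valid], clf.angle_cutoff_deg,
    [gram_label(c) for _, c in valid], bact_cutoff=42.2,
)
m = screening.diagnostic_metrics(counts).rounded()
print(f"\nvalidation (BACT >= 42.2/µL, n={counts.total}): "
      f"TP {counts.tp}, FN {counts.fn}, TN {counts.tn}, FP {counts.fp}")
print(f"PPV for Gram-negative culture: {m['ppv']}% "
      "(an angle below the cut-off strongly suggests Gram-negative infection)")
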