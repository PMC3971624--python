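"""Evaluate binary predictors of NEC: 2x2 tables, c-statistic, exact test.

For a binary marker the predictive value (c) is the area under its ROC
curve, (sensitivity + specificity)/2, and significance comes from the
two-sided Fisher exact test.  Here the six published criteria are
re-evaluated from their positivity counts, and a ROC scan picks the
optimal alanine:histidine cut-point on a synthetic cohort.
"""

from necbiome import CohortDesign, evaluate_binary, generate_cohort, roc_cutpoint
from necbiome.biomarkers import alanine_histidine_ratio

counts = {
    "High Firmicutes dysbiosis":  ((4, 9), (0, 18)),
    "No Propionibacterium":       ((9, 9), (8, 18)),
    "High Proteobacteria dysb.":  ((6, 9), (8, 19)),
    "Either dysbiosis":           ((7, 7), (8, 16)),
    "Combined (no Propi + dysb)": ((7, 7), (4, 16)),
    "Ala:His ratio > 4":          ((9, 11), (5, 20)),
}
print(f"{'criterion':28s} {'NEC':>6s} {'ctrl':>6s} {'c':>5s} {'sens':>5s} {'spec':>5s} {'p':>7s}")
for name, ((a, nc), (c, nk)) in counts.items():
    flags = {f"c{i}": i < a for i in range(nc)} | {f"k{i}": i < c for i in range(nk)}
    outcomes = {f"c{i}": "NEC" for i in range(nc)} | {f"k{i}": "control" for i in range(nk)}
    r = evaluate_binary(flags, outcomes, criterion=name)
    print(f"{name:28s} {a}/{nc:<4d} {c}/{nk:<4d} {100 * r.c_statistic:4.0f}% "
          f"{100 * r.sensitivity:4.0f}% {100 * r.specificity:4.0f}% {r.p_value:7.3f}")

cohort = generate_cohort(CohortDesign(seed=1))
ratios = {m.infant_id: alanine_histidine_ratio(m) for m in cohort.metabolites}
outcomes = {r.infant_id: r.group for r in cohort.records}
thr, res = roc_cutpoint(ratios, outcomes)
print(f"\nROC scan on synthetic urine ratios: cut-point {thr:.2f} "
      f"-> c = {100 * res.c_statistic:.0f}%")
# The combined microbial criterion reaches the highest predictive value
# (88%); the urinary ratio alone reaches 78% with a cut-point near 4.
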