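"""Alpha diversity: rarefy to 2,000 reads and compare Chao1 / Simpson.

Within-sample diversity is summarized after standardizing sequencing effort
by rarefaction; NEC-preceding communities are dominated by few taxa, so
they trend toward lower richness and evenness than controls.
"""

import numpy as np

from necbiome import CohortDesign, WINDOW_1, alpha_diversity_table, generate_cohort, select_analysis_samples

cohort = generate_cohort(CohortDesign(seed=1))
w1 = select_analysis_samples(cohort.records, WINDOW_1)
table = cohort.table.subset_samples([r.sample_id for r in w1])
alpha = alpha_diversity_table(table, depth=2000, seed=0).set_index("sample_id")

group_of = {r.sample_id: r.group for r in w1}
for group in ("NEC", "control"):
    ids = [s for s, g in group_of.items() if g == group]
    print(f"{group:8s} median Chao1 = {alpha.loc[ids, 'chao1'].median():5.1f}   "
          f"median Simpson = {alpha.loc[ids, 'simpson'].median():.3f}  (n={len(ids)})")
# Lower values in the NEC column reflect single-taxon dominance: fewer OTUs
# reach detectable counts and one taxon holds most of the reads.
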