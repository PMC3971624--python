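"""Beta diversity end to end: UniFrac -> NMDS -> Ward -> sub-type calls.

The weighted UniFrac matrix drives both the ordination (for visualization,
with Kruskal stress on the 0-100 scale) and the Ward clustering that
defines the community groups; dysbiosis sub-types are then read off the
clusters.
"""

from collections import Counter

from necbiome import CohortDesign, PipelineConfig, analyze_cohort, generate_cohort

design = CohortDesign(seed=1)
cohort = generate_cohort(design)
result = analyze_cohort(cohort, PipelineConfig(seed=1, design=design))

for tag, wa in result.windows.items():
    print(f"{wa.window_label}: n={len(wa.sample_ids)} samples, "
          f"NMDS stress={wa.ordination.stress:.2f}, Ward k={wa.k}")
    print(wa.diagnostics.round(2).to_string(index=False))

print("\nsub-type calls (group, subtype):")
for (group, subtype), n in sorted(Counter((c.group, c.subtype) for c in result.calls).items()):
    print(f"  {group:14s} {subtype:14s} {n}")
# Planted NEC-I infants land in the Firmicutes-dominated window-1 cluster,
# planted NEC-II infants in the dominant Enterobacteriaceae window-2 cluster;
# a low stress (< ~5 on the 0-100 scale) means the 3-D map is faithful.
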