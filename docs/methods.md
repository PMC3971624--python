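# Methods

This note documents the statistical procedures `necbiome` implements, the
defaults it ships, and the decisions taken where the underlying analysis
tradition leaves genuine freedom.

## Cohort model and sample selection

An infant belongs to one of three outcome groups: NEC case, control, or
non-NEC death (a competing outcome retained for ordination but excluded
from case/control biomarker evaluation).  Stool is analyzed in two
postnatal windows, days 4–9 and 10–16, both ends inclusive, with the birth
day counted as day 0 (the day-numbering convention is not universal; this
one is fixed here and documented rather than configurable per call).
Within a window, each infant contributes at most one sample: samples
collected on or after the infant's onset day (NEC diagnosis, or death) are
dropped first, then the earliest remaining in-window sample is kept, so
infants contribute statistically independent observations.  Selection is
idempotent and never produces more rows than there are infants.

## Alpha diversity

Counts are rarefied — subsampled without replacement, i.e. a multivariate
hypergeometric draw — to a common depth of 2,000 reads; shallower samples
are flagged and excluded rather than silently retained.  One draw per
sample is taken from a per-sample child stream of the stage seed (the
tradition this follows reports a single rarefaction, not an average over
draws).  Two indices are reported:

* **Chao1 richness**, bias-corrected: `S_obs + F1(F1−1)/(2(F2+1))` with F1,
  F2 the singleton/doubleton counts.  The bias-corrected form is defined
  even when F2 = 0; the classic `S_obs + F1²/(2F2)` form is available via
  `bias_corrected=False`.  Chao1 ≥ observed richness always, with equality
  iff F1 ≤ 1.
* **Simpson diversity** as `1 − Σ p_i²` (higher = more diverse), the
  orientation that makes "dysbiosis trends toward lower diversity" read
  naturally.  Both skbio-backed.

## Beta diversity

**Rare-OTU filter.** An OTU is retained iff detected (count > 0) in at
least 2 samples *and* carrying at least 5 reads overall.  The filter
precedes the distance computation; per-sample proportions are renormalized
over the retained OTUs.

**Weighted UniFrac** in the raw (unnormalized) form
`Σ_i b_i |p_i^A − p_i^B|`, where `b_i` is the branch length and `p_i^X`
the fraction of sample X's reads descending through branch i.  The
normalized variant is available behind a flag.  The computation is
delegated to scikit-bio; the test suite holds it to a per-branch
brute-force oracle and to the metric axioms on randomized instances.

**NMDS.** Kruskal non-metric scaling is implemented in-package: each start
alternates (a) isotonic (pool-adjacent-violators) regression of the
configuration distances on the rank order of the input dissimilarities —
primary tie handling, so tied dissimilarities may receive unequal fitted
values, implemented by pre-sorting ties by the current configuration
distance — with (b) a Guttman majorization update.  Stress is Kruskal
stress-1 on the 0–100 scale, `100·√(Σ(d̂−δ)²/Σδ²)`.  The recorded stress
trace is non-increasing by construction: an iteration that would raise
stress is rejected and that start terminates at its previous
configuration.  Defaults: k = 3 dimensions, 20 starts (19 random standard
normal + 1 deterministic start from classical metric scaling), 300
iterations, relative tolerance 1e−6.  The best start's configuration is
centered and rotated to principal axes (variance maximal on axis 1,
non-increasing thereafter), with a deterministic sign convention.  NMDS is
visualization/diagnostics only; clustering never consumes the ordination.

## Clustering and sub-typing

**Ward.** Agglomeration uses the Lance–Williams recurrence on squared
input distances (scipy's `ward` linkage), whose greedy step exactly
minimizes the increase in within-cluster sum of squares with
`SS(C) = Σ_{i<j∈C} d²_ij/|C|`, for Euclidean and non-Euclidean inputs
alike; the test suite verifies partition-for-every-k equality with an
explicit greedy SS oracle.  Reported per-merge heights are the SS
increases, which are non-decreasing along the merge sequence.

**Cluster-count diagnostics.** For each k, pseudo-F =
`[(T − W_k)/(k−1)] / [W_k/(n−k)]` with T the total SS; pseudo-T² for the
merge collapsing k+1 clusters into k is `B/[(SS_K+SS_L)/(n_K+n_L−2)]`
with B the merge's between-SS increase.  When both merging clusters are
singletons the denominator has zero degrees of freedom and pseudo-T² is
reported as B itself (a documented boundary contract).

**choose_k.** Scree-plot reading is human judgment; the package replaces
it with a stated deterministic rule: candidates are local maxima of
pseudo-F over the k grid (boundaries qualify one-sidedly); the largest
pseudo-F wins, ties broken toward the larger forming-merge pseudo-T², then
toward smaller k.  A monotone-decreasing scree yields k = 2.  An explicit
`k_override` always wins, per window.

**Dysbiosis flags** (unrarefied counts): Firmicutes ≥ 0.98 at phylum rank
in the window-1 sample; Proteobacteria ≥ 0.90 at phylum rank in the
window-2 sample; *Propionibacterium* absent = fewer than 1 read (the
detection floor is configurable) of that genus in the window-1 sample.
Flags whose window has no pre-onset sample are null, not false, and
combined flags (either-dysbiosis; no-Propionibacterium AND dysbiosis) are
null if any input is null — this is what produces the per-criterion
denominators.  Flags are monotone in their thresholds.

**Sub-type labels.** The window-1 cluster holding the majority of
Firmicutes-dysbiosis infants is the NEC-I-like community; the NEC-II-like
community is the *largest* window-2 cluster whose median
Enterobacteriaceae share reaches the Proteobacteria threshold (falling
back to the highest-median cluster if none reaches it) — size-weighting
keeps one or two extreme outlying samples from outranking the dominant
Enterobacteriaceae group, consistent with reporting tiny clusters as
outliers rather than communities.  An infant is NEC-I-like if its window-1
sample sits in the former (the early phenotype overrides), else
NEC-II-like if its window-2 sample sits in the latter, else unclassified.

## Biomarker evaluation

Every criterion reduces to a 2×2 table over evaluable infants (non-NEC
deaths never count).  Predictive value is the binary-predictor area under
the ROC curve, `c = (sensitivity + specificity)/2` — the definition that
reproduces all published predictive values from their counts, which
accuracy/PPV/NPV do not.  Significance is the two-sided Fisher exact test
with point-probability ordering (sum of hypergeometric probabilities of
all same-margin tables no more probable than the observed one), not the
doubled one-sided p.  Continuous markers are positive when *strictly
greater* than the threshold; the ROC scan searches midpoints between
consecutive sorted unique values, maximizing c with ties broken toward the
smallest threshold.  The ratio cut-point of 4 is evaluated in-sample, as
in the analysis it reproduces; no cross-validation is attempted and the
optimism that implies is acknowledged.  Report percentages are rounded to
whole percent alongside full-precision columns.

## Metabolite statistics

Kruskal–Wallis with tie correction and the chi-squared approximation
(appropriate at these group sizes; fully tied data returns H = 0, p = 1 by
convention); Spearman correlation as Pearson on mid-ranks with the t
approximation on n−2 degrees of freedom (constant inputs are an error, not
rho = 0); Welch t with Satterthwaite degrees of freedom; Benjamini–
Hochberg step-up adjustment preserving input order and capped at 1.  The
association table crosses {alanine, histidine, alanine:histidine ratio}
(first window-1 urine sample per infant) with three Spearman targets
(window-1 Firmicutes, Proteobacteria, *Propionibacterium* shares) and five
rank contrasts (Firmicutes-community membership, Enterobacteriaceae-
community membership, NEC vs controls, NEC-I vs rest, NEC-II vs rest,
deaths excluded from the NEC contrasts) — 24 rows, optional BH column.
The repeated-measures adjustment used alongside t-tests in the original
tradition (generalized estimating equations) is out of scope here; the
one-sample-per-infant restriction removes most of its motivation.

## Synthetic cohorts

The generator targets the statistical structure the analysis consumes —
not reads, chimeras, or primer bias.  Ten genera (Enterobacter,
Escherichia; Staphylococcus, Enterococcus, Leuconostoc, Lactococcus,
Streptococcus, Clostridium; Propionibacterium, Bifidobacterium) span three
phyla, with a ladderized genus/phylum tree whose within-phylum leaf pairs
are strictly closer than cross-phylum pairs.  Communities are
Dirichlet-multinomial: genus shares from a Dirichlet whose mean is the
archetype's weight vector and whose concentration controls infant-to-
infant overdispersion, split across 3 OTUs per genus, then a multinomial
at a uniform random depth in [2,000, 6,000] (the floor guarantees
rarefaction is always possible).

Archetypes and defaults:

* **control** — ~78/20 Proteobacteria/Firmicutes mean, concentration 3
  (overdispersed: median ~84% Proteobacteria and roughly 40% of draws
  ≥90%, so some controls are Proteobacteria-dysbiotic, as observed);
  *Propionibacterium* carried with probability 0.56.
* **firmicutes_dominant** (early-onset cases, window 1) — 99.3% Firmicutes
  (Bacilli) mean, concentration 250; onset uniform on days [7, 21].
* **proteo_leaning** (late-onset cases, window 1) — control genus mix at
  concentration 8: these infants sit in the Enterobacteriaceae-dominated
  community group before their dysbiosis develops.
* **proteobacteria_dominant** (late-onset cases, window 2) — 96%
  Enterobacteriaceae mean, concentration 200; onset uniform on [19, 39].
* **mixed** (early-onset cases, window 2) — ~35% Firmicutes,
  concentration 10 (the early phenotype disperses).
* **firmicutes_moderate** (non-NEC deaths) — ~80% Firmicutes,
  concentration 15; death day uniform on [9, 17].

*Propionibacterium* presence is a per-infant Bernoulli mask producing true
structural zeros (the absence criterion is presence/absence, not
abundance); when present its share is a tight Beta with mean 1.5%, so
detection at ≥1 read is reliable at these depths.  Cases never carry it.
Case samples are generated only on pre-onset days.

Metabolites are coupled at the infant level, in log space with log-normal
noise (sd 0.3, histidine 0.35): log-alanine = log 1.52 + 1.0·max(Firmicutes
share − 0.2, 0) − 0.15·(Propionibacterium carried); log-histidine =
log 0.53 − 0.5·max(days-to-onset − 8, 0)/10; pyridoxine tracks alanine
with slope 0.6.  Baselines are control medians in relative NMR units;
effect sizes were chosen so group medians land near the observed ones
(alanine ≈ 3.3 under full Firmicutes dominance, histidine ≈ 0.25 for
late-onset cases) and so association *signs and orderings* — not exact
medians — are recoverable.  Metabolite units are relative and
instrument-specific, so only signs/orderings are asserted anywhere.

What passing tests on synthetic cohorts do **not** show: recovery of
real-data absolute values (Chao1 medians, metabolite medians, printed
stress values), robustness to sequencing artifacts, or behavior under
taxa outside the ten-genus pool.  The generator has no sequencing error,
no chimeras, no compositional coupling beyond the Dirichlet, and
one-sample-per-window regularity that real cohorts lack.

## Pipeline, seeds, determinism

All randomness derives from one master seed through a fixed per-stage
offset table (`simulate`, `rarefaction`, `nmds_w1`, `nmds_w2`); offsets
are append-only, so adding a stage never shifts an existing stage's
stream.  Two runs from the same configuration are byte-identical, and the
manifest records the config, derived seeds, chosen k and stress per
window, and a sha256 checksum of every output file.

Problem sizes used in the shipped tests and the acceptance script — the
default design (4 early cases, 6 late cases, 18 controls, 3 deaths) over
20 seeds, 200 random UniFrac instances at 4–8 leaves, Ward oracles at
n ≤ 8, exact enumerations at n ≤ 7 — were chosen to exercise every code
path at the scale the statistics are designed for while keeping a full
run in the order of half a minute.

## Known limitations

* The c-statistic applies to binary predictors; for continuous markers the
  package dichotomizes rather than computing the rank-based AUC over raw
  values (the two coincide for the binary case).
* `choose_k` is a heuristic; on real data an analyst override per window
  is expected and supported.
* The Fisher test's point-probability tie tolerance (1e−7 relative) can,
  in principle, differ from other software at pathological near-ties.
* No confidence intervals for sensitivity/specificity are produced.
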