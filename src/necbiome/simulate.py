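"""Synthetic preterm-infant cohorts with planted dysbiosis structure.

The generator emulates the statistical structure the analysis consumes —
not raw sequence reads.  Each infant contributes one stool sample per
postnatal window (days 4-9 and 10-16), with pre-onset censoring for cases,
and one early-window urine sample.  Communities are drawn
Dirichlet-multinomial over a fixed pool of the dominant genera of the
preterm gut; four archetypes plant the study's phenotypes:

* controls: ~80/20 Proteobacteria/Firmicutes mixtures, stable across both
  windows, with Propionibacterium detectable in about half of infants;
* early-onset cases (NEC-I): >=98% Firmicutes (class Bacilli) communities in
  window 1, relaxing to mixed communities in window 2; onset days 7-21;
* late-onset cases (NEC-II): control-like window-1 communities but >=90%
  Proteobacteria (family Enterobacteriaceae) in window 2; onset days 19-39;
* non-NEC deaths: moderately Firmicutes-dominated (~80%) in both windows,
  dying days 9-17.

No case carries Propionibacterium.  Urinary metabolites are coupled at the
infant level: log-alanine rises with the window-1 Firmicutes share,
log-histidine falls with the planted days-to-onset, and pyridoxine tracks
alanine; the alanine:histidine ratio therefore separates cases from
controls the way the analysis expects to find.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skbio import TreeNode

from .io import Lineage, MetaboliteRecord, OtuTable, SampleRecord, TaxonomyMap

__all__ = [
    "GENUS_POOL",
    "GENUS_LINEAGES",
    "ArchetypeSpec",
    "CohortDesign",
    "Cohort",
    "default_archetypes",
    "generate_genus_tree",
    "generate_cohort",
]

GENUS_POOL = (
    "Enterobacter",
    "Escherichia",
    "Staphylococcus",
    "Enterococcus",
    "Leuconostoc",
    "Lactococcus",
    "Streptococcus",
    "Clostridium",
    "Propionibacterium",
    "Bifidobacterium",
)

_PROTEO = ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Enterobacteriales", "Enterobacteriaceae")
_BACILLI = ("Bacteria", "Firmicutes", "Bacilli")
_ACTINO = ("Bacteria", "Actinobacteria", "Actinobacteria")

GENUS_LINEAGES: dict[str, Lineage] = {
    "Enterobacter": Lineage(*_PROTEO, "Enterobacter"),
    "Escherichia": Lineage(*_PROTEO, "Escherichia"),
    "Staphylococcus": Lineage(*_BACILLI, "Bacillales", "Staphylococcaceae", "Staphylococcus"),
    "Enterococcus": Lineage(*_BACILLI, "Lactobacillales", "Enterococcaceae", "Enterococcus"),
    "Leuconostoc": Lineage(*_BACILLI, "Lactobacillales", "Leuconostocaceae", "Leuconostoc"),
    "Lactococcus": Lineage(*_BACILLI, "Lactobacillales", "Streptococcaceae", "Lactococcus"),
    "Streptococcus": Lineage(*_BACILLI, "Lactobacillales", "Streptococcaceae", "Streptococcus"),
    "Clostridium": Lineage("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Clostridiaceae", "Clostridium"),
    "Propionibacterium": Lineage(*_ACTINO, "Actinomycetales", "Propionibacteriaceae", "Propionibacterium"),
    "Bifidobacterium": Lineage(*_ACTINO, "Bifidobacteriales", "Bifidobacteriaceae", "Bifidobacterium"),
}

_PHYLUM_OF = {g: GENUS_LINEAGES[g].phylum for g in GENUS_POOL}


@dataclass(frozen=True)
class ArchetypeSpec:
    """A community archetype: Dirichlet weights over the genus pool.

    ``weights`` are relative genus means (Propionibacterium's weight is its
    target mean share when present); ``concentration`` scales the Dirichlet
    precision (small = overdispersed infant-to-infant composition);
    ``propionibacterium_presence_prob`` is the per-infant Bernoulli
    probability of carrying Propionibacterium at all (a structural zero
    otherwise).
    """

    name: str
    weights: dict[str, float]
    concentration: float = 10.0
    propionibacterium_presence_prob: float = 0.0

    def __post_init__(self) -> None:
        w = np.array([self.weights.get(g, 0.0) for g in GENUS_POOL])
        if np.any(w < 0) or not np.any(w > 0):
            raise ValueError(f"archetype {self.name!r}: weights must be >=0, not all 0")
        if not 0 <= self.propionibacterium_presence_prob <= 1:
            raise ValueError("presence probability must lie in [0, 1]")

    def mean_shares(self, propi_present: bool = True) -> dict[str, float]:
        """Expected genus shares under the archetype."""
        w = {g: self.weights.get(g, 0.0) for g in GENUS_POOL}
        if not propi_present:
            w["Propionibacterium"] = 0.0
        total = sum(w.values())
        return {g: v / total for g, v in w.items()}

    def mean_phylum_share(self, phylum: str, propi_present: bool = True) -> float:
        shares = self.mean_shares(propi_present)
        return sum(v for g, v in shares.items() if _PHYLUM_OF[g] == phylum)


def default_archetypes() -> dict[str, ArchetypeSpec]:
    """The four community archetypes the cohorts are built from."""
    return {
        "control": ArchetypeSpec(
            "control",
            weights={
                "Enterobacter": 0.50,
                "Escherichia": 0.28,
                "Staphylococcus": 0.09,
                "Enterococcus": 0.08,
                "Leuconostoc": 0.01,
                "Lactococcus": 0.005,
                "Streptococcus": 0.01,
                "Clostridium": 0.005,
                "Propionibacterium": 0.015,
                "Bifidobacterium": 0.005,
            },
            concentration=3.0,  # overdispersed: median ~84% Proteobacteria, ~40% of draws >=90%
            propionibacterium_presence_prob=0.56,
        ),
        "firmicutes_dominant": ArchetypeSpec(
            "firmicutes_dominant",
            weights={
                "Staphylococcus": 0.55,
                "Enterococcus": 0.435,
                "Leuconostoc": 0.002,
                "Lactococcus": 0.002,
                "Streptococcus": 0.002,
                "Clostridium": 0.002,
                "Enterobacter": 0.004,
                "Escherichia": 0.003,
            },
            concentration=250.0,
        ),
        # window-1 communities of late-onset cases: same genus mix as
        # controls but tighter around the ~80% Proteobacteria mode (these
        # infants sit squarely in the Enterobacteriaceae-dominated community
        # group in the early window, before their dysbiosis develops)
        "proteo_leaning": ArchetypeSpec(
            "proteo_leaning",
            weights={
                "Enterobacter": 0.50,
                "Escherichia": 0.28,
                "Staphylococcus": 0.09,
                "Enterococcus": 0.08,
                "Leuconostoc": 0.01,
                "Lactococcus": 0.005,
                "Streptococcus": 0.01,
                "Clostridium": 0.005,
                "Propionibacterium": 0.015,
                "Bifidobacterium": 0.005,
            },
            concentration=8.0,
        ),
        "proteobacteria_dominant": ArchetypeSpec(
            "proteobacteria_dominant",
            weights={
                "Enterobacter": 0.62,
                "Escherichia": 0.34,
                "Staphylococcus": 0.015,
                "Enterococcus": 0.015,
                "Leuconostoc": 0.002,
                "Streptococcus": 0.004,
                "Clostridium": 0.004,
            },
            concentration=200.0,
        ),
        "mixed": ArchetypeSpec(
            "mixed",
            weights={
                "Enterobacter": 0.35,
                "Escherichia": 0.25,
                "Staphylococcus": 0.20,
                "Enterococcus": 0.14,
                "Leuconostoc": 0.01,
                "Lactococcus": 0.01,
                "Streptococcus": 0.02,
                "Clostridium": 0.01,
                "Bifidobacterium": 0.005,
            },
            concentration=10.0,
        ),
        "firmicutes_moderate": ArchetypeSpec(
            "firmicutes_moderate",
            weights={
                "Staphylococcus": 0.45,
                "Enterococcus": 0.35,
                "Enterobacter": 0.12,
                "Escherichia": 0.06,
                "Streptococcus": 0.01,
                "Clostridium": 0.01,
            },
            concentration=15.0,
            propionibacterium_presence_prob=0.33,
        ),
    }


@dataclass(frozen=True)
class CohortDesign:
    """Cohort sizes, sequencing depths, and planted effect sizes.

    Defaults mirror the study scale: 4 early-dysbiosis cases, 6
    late-dysbiosis cases, 18 controls with stool in the first window, 3
    non-NEC deaths.  Depth never falls below 2,000 reads so rarefaction is
    always possible.  ``alanine_effect`` is the log-scale rise in alanine
    per unit window-1 Firmicutes share above the control baseline;
    ``histidine_effect`` the log-scale fall per 10 days-to-onset beyond 8
    days; ``noise_scale`` the log-normal sd of the metabolite noise.
    """

    n_nec1: int = 4
    n_nec2: int = 6
    n_controls: int = 18
    n_deaths: int = 3
    read_depth_range: tuple[int, int] = (2000, 6000)
    otus_per_genus: int = 3
    seed: int = 0
    alanine_effect: float = 1.0
    histidine_effect: float = 0.5
    noise_scale: float = 0.3
    couple_metabolites: bool = True

    def __post_init__(self) -> None:
        if min(self.n_nec1, self.n_nec2, self.n_controls, self.n_deaths) < 0:
            raise ValueError("cohort sizes must be non-negative")
        lo, hi = self.read_depth_range
        if lo < 2000 or hi < lo:
            raise ValueError("read depth range must satisfy 2000 <= lo <= hi")
        if self.otus_per_genus < 1:
            raise ValueError("otus_per_genus must be >= 1")
        for name in ("alanine_effect", "histidine_effect", "noise_scale"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class Cohort:
    """A generated cohort: everything the pipeline reads from disk."""

    table: OtuTable
    taxonomy: TaxonomyMap
    tree: TreeNode
    records: list[SampleRecord]
    metabolites: list[MetaboliteRecord]


def _otu_ids(otus_per_genus: int) -> dict[str, list[str]]:
    ids: dict[str, list[str]] = {}
    counter = 1
    for genus in GENUS_POOL:
        ids[genus] = [f"otu{counter + i:03d}" for i in range(otus_per_genus)]
        counter += otus_per_genus
    return ids


def generate_genus_tree(otus_per_genus: int = 3, seed: int = 0) -> TreeNode:
    """A rooted phylogeny grouping OTUs by genus and genera by phylum.

    Branch lengths are positive with small seeded jitter; any two leaves of
    one phylum are strictly closer (path length) than any cross-phylum pair.
    """
    if otus_per_genus < 1:
        raise ValueError("otus_per_genus must be >= 1")
    rng = np.random.default_rng(seed)
    ids = _otu_ids(otus_per_genus)
    phyla: dict[str, list[str]] = {}
    for genus in GENUS_POOL:
        phyla.setdefault(_PHYLUM_OF[genus], []).append(genus)

    def jitter(base: float) -> float:
        return base * (1 + 0.1 * rng.uniform(-1, 1))

    phylum_parts = []
    for phylum, genera in phyla.items():
        genus_parts = []
        for genus in genera:
            leaves = ",".join(f"{o}:{jitter(0.05):.6f}" for o in ids[genus])
            if otus_per_genus == 1:
                genus_parts.append(f"{ids[genus][0]}:{jitter(0.25):.6f}")
            else:
                genus_parts.append(f"({leaves}):{jitter(0.2):.6f}")
        phylum_parts.append(f"({','.join(genus_parts)}):{jitter(0.4):.6f}")
    # ladderize phylum subtrees so the root is strictly bifurcating
    combined = phylum_parts[0]
    for part in phylum_parts[1:]:
        combined = f"({combined},{part}):{jitter(0.1):.6f}"
    newick = f"{combined.rsplit(':', 1)[0]}:0;"
    return TreeNode.read([newick], format="newick")


def _taxonomy(otus_per_genus: int) -> TaxonomyMap:
    ids = _otu_ids(otus_per_genus)
    return TaxonomyMap(
        {otu: GENUS_LINEAGES[genus] for genus, otus in ids.items() for otu in otus}
    )


def _draw_sample_counts(
    rng: np.random.Generator,
    archetype: ArchetypeSpec,
    propi_present: bool,
    depth: int,
    otu_ids: dict[str, list[str]],
) -> np.ndarray:
    """One Dirichlet-multinomial community draw at the given depth.

    Propionibacterium, when present, gets a tightly-controlled small share
    (Beta with mean = its weight) so detection is reliable; when absent it
    is a structural zero.  Other genera share the remainder via a Dirichlet
    with the archetype's concentration; genus shares are split across the
    genus's OTUs by a mild within-genus Dirichlet.
    """
    weights = {g: archetype.weights.get(g, 0.0) for g in GENUS_POOL}
    propi_w = weights.pop("Propionibacterium")
    genera = [g for g, w in weights.items() if w > 0]
    w = np.array([weights[g] for g in genera])
    w = w / w.sum()

    propi_share = 0.0
    if propi_present and propi_w > 0:
        a0 = 3.0
        propi_share = float(rng.beta(a0, a0 * (1 - propi_w) / propi_w))
    genus_shares = rng.dirichlet(archetype.concentration * w) * (1 - propi_share)

    n_otus = sum(len(v) for v in otu_ids.values())
    otu_index = {o: j for j, o in enumerate(o for v in otu_ids.values() for o in v)}
    p = np.zeros(n_otus)
    for genus, share in [*zip(genera, genus_shares), ("Propionibacterium", propi_share)]:
        otus = otu_ids[genus]
        split = rng.dirichlet(np.full(len(otus), 2.0)) if len(otus) > 1 else np.array([1.0])
        for o, frac in zip(otus, split):
            p[otu_index[o]] = share * frac
    p = p / p.sum()
    return rng.multinomial(depth, p)


def generate_cohort(design: CohortDesign, archetypes: dict[str, ArchetypeSpec] | None = None) -> Cohort:
    """Generate a full cohort, reproducibly from ``design.seed``."""
    arch = archetypes or default_archetypes()
    rng = np.random.default_rng(design.seed)
    otu_ids = _otu_ids(design.otus_per_genus)
    tree = generate_genus_tree(design.otus_per_genus, seed=design.seed)
    tax = _taxonomy(design.otus_per_genus)

    # (infant prefix, count, group, w1 archetype, w2 archetype, onset range, presence prob)
    plan = [
        ("nec1", design.n_nec1, "NEC", "firmicutes_dominant", "mixed", (7, 21), 0.0),
        ("nec2", design.n_nec2, "NEC", "proteo_leaning", "proteobacteria_dominant", (19, 39), 0.0),
        ("ctrl", design.n_controls, "control", "control", "control", None,
         arch["control"].propionibacterium_presence_prob),
        ("death", design.n_deaths, "non_NEC_death", "firmicutes_moderate",
         "firmicutes_moderate", (9, 17),
         arch["firmicutes_moderate"].propionibacterium_presence_prob),
    ]

    records: list[SampleRecord] = []
    metabolites: list[MetaboliteRecord] = []
    all_counts: list[np.ndarray] = []
    sample_ids: list[str] = []
    flat_otus = [o for v in otu_ids.values() for o in v]

    for prefix, count, group, a1, a2, onset_range, propi_prob in plan:
        for i in range(count):
            infant = f"{prefix}_{i + 1:02d}"
            onset = None
            if onset_range is not None:
                onset = int(rng.integers(onset_range[0], onset_range[1] + 1))
            propi_present = bool(rng.random() < propi_prob)

            day_hi_1 = 9 if onset is None else min(9, onset - 1)
            day1 = int(rng.integers(4, day_hi_1 + 1))  # onset >= 7 guarantees day_hi_1 >= 4
            windows = [(day1, arch[a1], "w1")]
            if onset is None or onset - 1 >= 10:
                day_hi_2 = 16 if onset is None else min(16, onset - 1)
                day2 = int(rng.integers(10, day_hi_2 + 1))
                windows.append((day2, arch[a2], "w2"))

            firm_share_w1 = None
            for day, archetype, wtag in windows:
                depth = int(rng.integers(design.read_depth_range[0], design.read_depth_range[1] + 1))
                counts = _draw_sample_counts(rng, archetype, propi_present, depth, otu_ids)
                sid = f"{infant}_{wtag}"
                sample_ids.append(sid)
                all_counts.append(counts)
                records.append(SampleRecord(sid, infant, day, group, onset))
                if wtag == "w1":
                    firm = sum(
                        counts[j]
                        for j, o in enumerate(flat_otus)
                        if _PHYLUM_OF_OTU(o, otu_ids) == "Firmicutes"
                    )
                    firm_share_w1 = firm / counts.sum()

            metabolites.append(
                _draw_metabolites(rng, design, infant, day1, onset, firm_share_w1, propi_present)
            )

    table = OtuTable(sample_ids, flat_otus, np.vstack(all_counts))
    return Cohort(table=table, taxonomy=tax, tree=tree, records=records, metabolites=metabolites)


def _PHYLUM_OF_OTU(otu: str, otu_ids: dict[str, list[str]]) -> str:
    for genus, otus in otu_ids.items():
        if otu in otus:
            return _PHYLUM_OF[genus]
    raise KeyError(otu)


def _draw_metabolites(
    rng: np.random.Generator,
    design: CohortDesign,
    infant: str,
    urine_day: int,
    onset: int | None,
    firm_share_w1: float | None,
    propi_present: bool,
) -> MetaboliteRecord:
    """Infant-level metabolite draw (relative NMR units).

    Baselines: alanine 1.52, histidine 0.53, pyridoxine 1.0 (control
    medians).  Coupling: log-alanine rises with the window-1 Firmicutes
    share above the ~0.2 control baseline (and dips slightly when
    Propionibacterium is carried); log-histidine falls with days-to-onset
    beyond ~8 days, planting the inverse histidine/time-to-onset
    association of late-onset cases; pyridoxine tracks alanine.
    """
    s = design.noise_scale
    log_ala = np.log(1.52) + s * rng.standard_normal()
    if design.couple_metabolites:
        if firm_share_w1 is not None:
            log_ala += design.alanine_effect * max(firm_share_w1 - 0.2, 0.0)
        if propi_present:
            log_ala -= 0.15
    log_his = np.log(0.53) + (s + 0.05) * rng.standard_normal()
    if design.couple_metabolites and onset is not None:
        dto = onset - urine_day
        log_his -= design.histidine_effect * max(dto - 8, 0) / 10.0
    log_pyr = 0.6 * (log_ala - np.log(1.52)) + s * rng.standard_normal()
    return MetaboliteRecord(
        infant_id=infant,
        day_of_life=urine_day,
        alanine=float(np.exp(log_ala)),
        histidine=float(np.exp(log_his)),
        pyridoxine=float(np.exp(log_pyr)),
    )
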