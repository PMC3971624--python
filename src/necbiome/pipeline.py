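"""End-to-end orchestration: select -> filter -> alpha -> UniFrac -> NMDS ->
Ward/diagnostics -> dysbiosis calls -> biomarker and metabolite reports.

:func:`analyze_cohort` runs the whole analysis in memory;
:func:`run_pipeline` wraps it with file input/output and a reproducibility
manifest.  All randomness derives from one master seed through a fixed
per-stage offset table, so adding a stage never shifts another stage's
stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import alpha as _alpha
from . import beta as _beta
from . import cluster as _cluster
from . import biomarkers as _biomarkers
from . import stats as _stats
from .io import (
    WINDOW_1,
    WINDOW_2,
    OtuTable,
    read_metadata,
    read_metabolites,
    read_otu_table,
    read_taxonomy,
    read_tree,
    check_tree_consistency,
    select_analysis_samples,
    write_metadata,
    write_metabolites,
    write_otu_table,
    write_taxonomy,
    write_tree,
)
from .simulate import Cohort, CohortDesign, generate_cohort

__all__ = ["PipelineConfig", "RunManifest", "analyze_cohort", "run_pipeline", "load_cohort"]

# fixed stage -> offset table; append-only so streams never shift
_STAGE_OFFSETS = {
    "simulate": 1,
    "rarefaction": 2,
    "nmds_w1": 3,
    "nmds_w2": 4,
}


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a stage's integer seed from the master seed (stable scheme)."""
    ss = np.random.SeedSequence([int(master_seed), _STAGE_OFFSETS[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with the study's defaults."""

    # inputs: either a directory of the five files, or a synthetic design
    input_dir: str | None = None
    design: CohortDesign | None = None
    output_dir: str = "necbiome_out"
    seed: int = 0
    rarefaction_depth: int = 2000
    rare_otu_min_samples: int = 2
    rare_otu_min_total: int = 5
    unifrac_normalized: bool = False
    nmds_k: int = 3
    nmds_starts: int = 20
    nmds_max_iter: int = 300
    nmds_tol: float = 1e-6
    run_nmds: bool = True
    k_max: int = 6
    k_override_w1: int | None = None
    k_override_w2: int | None = None
    firmicutes_threshold: float = 0.98
    proteobacteria_threshold: float = 0.90
    ratio_mode: str = "fixed"  # "fixed" | "roc"
    ratio_threshold: float = 4.0

    def __post_init__(self) -> None:
        if not 0 < self.firmicutes_threshold <= 1 or not 0 < self.proteobacteria_threshold <= 1:
            raise ValueError("dysbiosis thresholds must lie in (0, 1]")
        if self.ratio_mode not in ("fixed", "roc"):
            raise ValueError("ratio_mode must be 'fixed' or 'roc'")
        if self.rarefaction_depth < 1:
            raise ValueError("rarefaction depth must be positive")


@dataclass
class RunManifest:
    """Reproducibility record: config, derived seeds, output checksums."""

    config: dict
    seeds: dict
    stress: dict
    chosen_k: dict
    checksums: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass
class WindowAnalysis:
    window_label: str
    sample_ids: list[str]
    filtered: OtuTable
    distances: object
    ordination: object | None
    tree: object
    diagnostics: pd.DataFrame
    k: int
    labels: dict[str, int]


@dataclass
class AnalysisResult:
    windows: dict[str, WindowAnalysis]
    alpha: pd.DataFrame
    calls: list
    table3: list
    table2: pd.DataFrame


def load_cohort(input_dir) -> Cohort:
    """Read the five input files from a directory."""
    d = Path(input_dir)
    for name in ("otu_table.tsv", "taxonomy.tsv", "tree.nwk", "metadata.tsv", "metabolites.tsv"):
        if not (d / name).exists():
            raise FileNotFoundError(f"missing input file {d / name}")
    table = read_otu_table(d / "otu_table.tsv")
    tax = read_taxonomy(d / "taxonomy.tsv")
    tax.check_covers(table)
    tree = read_tree(d / "tree.nwk")
    check_tree_consistency(table, tree)
    return Cohort(
        table=table,
        taxonomy=tax,
        tree=tree,
        records=read_metadata(d / "metadata.tsv"),
        metabolites=read_metabolites(d / "metabolites.tsv"),
    )


def write_cohort(cohort: Cohort, out_dir) -> None:
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    write_otu_table(cohort.table, d / "otu_table.tsv")
    write_taxonomy(cohort.taxonomy, d / "taxonomy.tsv")
    write_tree(cohort.tree, d / "tree.nwk")
    write_metadata(cohort.records, d / "metadata.tsv")
    write_metabolites(cohort.metabolites, d / "metabolites.tsv")


def _analyze_window(cohort: Cohort, window, config: PipelineConfig, nmds_seed: int):
    selected = select_analysis_samples(cohort.records, window)
    ids = [r.sample_id for r in selected if r.sample_id in cohort.table]
    if len(ids) < 2:
        raise ValueError(f"window {window.label}: fewer than two analysis samples")
    sub = cohort.table.subset_samples(ids)
    filtered = _beta.filter_rare_otus(
        sub, min_samples=config.rare_otu_min_samples, min_total=config.rare_otu_min_total
    )
    dm = _beta.unifrac_distance_matrix(
        filtered, cohort.tree, normalized=config.unifrac_normalized
    )
    ordination = None
    if config.run_nmds and len(ids) >= config.nmds_k + 1:
        ordination = _beta.nmds(
            dm,
            k=config.nmds_k,
            n_starts=config.nmds_starts,
            seed=nmds_seed,
            max_iter=config.nmds_max_iter,
            tol=config.nmds_tol,
        )
    ctree = _cluster.ward_cluster(dm)
    k_max = min(config.k_max, len(ids) - 1)
    diagnostics = _cluster.cluster_diagnostics(ctree, k_max=k_max)
    override = (
        config.k_override_w1 if window is WINDOW_1 or window.label == WINDOW_1.label
        else config.k_override_w2
    )
    k = _cluster.choose_k(diagnostics, k_override=override)
    labels = ctree.labels(k)
    return WindowAnalysis(
        window_label=window.label,
        sample_ids=ids,
        filtered=filtered,
        distances=dm,
        ordination=ordination,
        tree=ctree,
        diagnostics=diagnostics,
        k=k,
        labels=labels,
    )


def analyze_cohort(cohort: Cohort, config: PipelineConfig | None = None) -> AnalysisResult:
    """Run the full analysis on an in-memory cohort."""
    config = config or PipelineConfig()
    w1 = _analyze_window(cohort, WINDOW_1, config, stage_seed(config.seed, "nmds_w1"))
    w2 = _analyze_window(cohort, WINDOW_2, config, stage_seed(config.seed, "nmds_w2"))

    # alpha diversity on every selected (pre-onset, earliest-per-window) sample
    analysis_ids = w1.sample_ids + w2.sample_ids
    alpha_tbl = _alpha.alpha_diversity_table(
        cohort.table.subset_samples(analysis_ids),
        depth=config.rarefaction_depth,
        seed=stage_seed(config.seed, "rarefaction"),
    )

    calls = _cluster.classify_dysbiosis(
        cohort.table,
        cohort.taxonomy,
        cohort.records,
        firmicutes_threshold=config.firmicutes_threshold,
        proteobacteria_threshold=config.proteobacteria_threshold,
    )
    _cluster.assign_subtypes(calls, w1.labels, w2.labels)

    table3 = _biomarkers.table3_report(
        calls,
        cohort.metabolites,
        ratio_threshold=None if config.ratio_mode == "roc" else config.ratio_threshold,
    )
    table2 = _stats.table2_report(cohort.metabolites, calls, bh=True)
    return AnalysisResult(
        windows={"w1": w1, "w2": w2},
        alpha=alpha_tbl,
        calls=calls,
        table3=table3,
        table2=table2,
    )


def _calls_frame(calls) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {
            "infant_id": c.infant_id,
            "group": c.group,
            "subtype": c.subtype,
            "w1_sample_id": c.w1_sample_id or "",
            "w2_sample_id": c.w2_sample_id or "",
        }
        for flag in (
            "firmicutes_dysbiosis_w1",
            "proteobacteria_dysbiosis_w2",
            "propionibacterium_absent_w1",
            "either_dysbiosis",
            "combined_criterion",
        ):
            v = getattr(c, flag)
            row[flag] = "" if v is None else str(bool(v))
        for k, v in c.shares.items():
            row[f"share_{k}"] = "" if v is None else f"{v:.6f}"
        rows.append(row)
    return pd.DataFrame(rows)


def _table3_frame(results) -> pd.DataFrame:
    rows = []
    for r in results:
        t = r.table
        rows.append(
            {
                "criterion": r.criterion,
                "nec_positive": f"{t.a}/{t.n_cases}",
                "control_positive": f"{t.c}/{t.n_controls}",
                "p_value": round(r.p_value, 4),
                "predictive_value_pct": round(100 * r.c_statistic),
                "sensitivity_pct": round(100 * r.sensitivity),
                "specificity_pct": round(100 * r.specificity),
                "c_statistic": r.c_statistic,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "n_excluded": r.n_excluded,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages, writing every output under ``config.output_dir``."""
    if (config.input_dir is None) == (config.design is None):
        raise ValueError("provide exactly one of input_dir or a synthetic design")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.design is not None:
        design = dataclasses.replace(config.design, seed=stage_seed(config.seed, "simulate"))
        cohort = generate_cohort(design)
        write_cohort(cohort, out / "inputs")
    else:
        cohort = load_cohort(config.input_dir)

    result = analyze_cohort(cohort, config)

    result.alpha.to_csv(out / "alpha.tsv", sep="\t", index=False)
    stress = {}
    chosen_k = {}
    for tag, wa in result.windows.items():
        dm_df = pd.DataFrame(
            np.asarray(wa.distances.data), index=wa.sample_ids, columns=wa.sample_ids
        )
        dm_df.index.name = "sample_id"
        dm_df.to_csv(out / f"distance_{tag}.tsv", sep="\t")
        if wa.ordination is not None:
            ax_cols = [f"axis{i + 1}" for i in range(wa.ordination.configuration.shape[1])]
            pd.DataFrame(
                wa.ordination.configuration, index=wa.sample_ids, columns=ax_cols
            ).rename_axis("sample_id").to_csv(out / f"ordination_{tag}.tsv", sep="\t")
            stress[tag] = wa.ordination.stress
        wa.diagnostics.to_csv(out / f"diagnostics_{tag}.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"sample_id": wa.sample_ids, "cluster": [wa.labels[s] for s in wa.sample_ids]}
        ).to_csv(out / f"clusters_{tag}.tsv", sep="\t", index=False)
        pd.DataFrame(
            wa.tree.merges, columns=["node_a", "node_b", "height", "size"]
        ).assign(ss_increase=wa.tree.ss_increase).to_csv(
            out / f"merges_{tag}.tsv", sep="\t", index=False
        )
        chosen_k[tag] = wa.k

    _calls_frame(result.calls).to_csv(out / "dysbiosis_calls.tsv", sep="\t", index=False)
    t3 = _table3_frame(result.table3)
    t3.to_csv(out / "table3.tsv", sep="\t", index=False)
    (out / "table3.json").write_text(t3.to_json(orient="records", indent=2))
    result.table2.to_csv(out / "table2.tsv", sep="\t", index=False)
    (out / "table2.json").write_text(result.table2.to_json(orient="records", indent=2))

    checksums = {}
    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            checksums[str(f.relative_to(out))] = hashlib.sha256(f.read_bytes()).hexdigest()

    cfg_dict = dataclasses.asdict(config)
    if config.design is not None:
        cfg_dict["design"] = dataclasses.asdict(config.design)
    manifest = RunManifest(
        config=cfg_dict,
        seeds={s: stage_seed(config.seed, s) for s in _STAGE_OFFSETS},
        stress=stress,
        chosen_k=chosen_k,
        checksums=checksums,
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
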