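"""Ward clustering of UniFrac distances, cluster-count diagnostics, and
dysbiosis sub-typing.

Clustering operates directly on the weighted UniFrac distance matrix with
the Ward minimum-variance criterion: at each step the merge minimizing the
increase in within-cluster sum of squares is chosen, where the sum of
squares of a cluster C is computed from its pairwise squared distances,

    SS(C) = sum_{i<j in C} d_ij^2 / |C| .

The number of clusters is chosen from a scree of the pseudo-F statistic
(between/within variance ratio) supported by pseudo-T^2 (merge-specific
separation), with a mandatory override for analyst judgment.

Sub-typing mirrors the study's two dysbiosis phenotypes: early (days 4-9)
Firmicutes dominance at >=98% relative abundance, and later (days 10-16)
Proteobacteria dominance at >=90%, plus absence of Propionibacterium in the
early window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix

from .io import WINDOW_1, WINDOW_2, OtuTable, SampleRecord, TaxonomyMap, Window
from .io import select_analysis_samples

__all__ = [
    "ClusterTree",
    "DysbiosisCall",
    "ward_cluster",
    "cluster_diagnostics",
    "choose_k",
    "aggregate_relative_abundance",
    "classify_dysbiosis",
    "assign_subtypes",
]


@dataclass
class ClusterTree:
    """A Ward agglomeration over a distance matrix.

    ``merges`` is the scipy linkage matrix; ``ss_increase`` holds, per merge,
    the increase in within-cluster sum of squares it caused (the Ward
    objective; non-decreasing over the sequence).
    """

    sample_ids: list[str]
    merges: np.ndarray
    ss_increase: np.ndarray
    _d2: np.ndarray = field(repr=False, default=None)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def labels(self, k: int) -> dict[str, int]:
        """Cluster labels 1..k, renumbered by order of first appearance."""
        raw = fcluster(self.merges, t=k, criterion="maxclust")
        remap: dict[int, int] = {}
        out = {}
        for sid, lab in zip(self.sample_ids, raw):
            if lab not in remap:
                remap[lab] = len(remap) + 1
            out[sid] = remap[lab]
        return out


def _as_square(d) -> tuple[list[str], np.ndarray]:
    if isinstance(d, DistanceMatrix):
        return list(d.ids), np.asarray(d.data, dtype=float)
    full = np.asarray(d, dtype=float)
    if full.ndim != 2 or full.shape[0] != full.shape[1]:
        raise ValueError("distance input must be square")
    if not np.allclose(full, full.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    return [str(i) for i in range(full.shape[0])], full


def _cluster_ss(d2: np.ndarray, members: Sequence[int]) -> float:
    if len(members) < 2:
        return 0.0
    idx = np.asarray(members)
    sub = d2[np.ix_(idx, idx)]
    return float(sub.sum() / (2 * len(members)))


def ward_cluster(d) -> ClusterTree:
    """Agglomerate samples by Ward's minimum-variance criterion.

    Uses the Lance-Williams recurrence on squared input distances (the form
    whose greedy step exactly minimizes the within-SS increase, Euclidean or
    not), so the merge sequence matches a brute-force greedy SS oracle.
    """
    ids, full = _as_square(d)
    if len(ids) < 2:
        raise ValueError("need at least two samples to cluster")
    z = linkage(squareform(full, checks=False), method="ward")
    d2 = full**2

    # per-merge SS increase, from explicit member sets
    members: dict[int, list[int]] = {i: [i] for i in range(len(ids))}
    ss: dict[int, float] = {i: 0.0 for i in range(len(ids))}
    increases = np.empty(z.shape[0])
    for m, (a, b, _, _) in enumerate(z):
        a, b = int(a), int(b)
        merged = members[a] + members[b]
        new_ss = _cluster_ss(d2, merged)
        increases[m] = new_ss - ss[a] - ss[b]
        node = len(ids) + m
        members[node] = merged
        ss[node] = new_ss
    return ClusterTree(sample_ids=ids, merges=z, ss_increase=increases, _d2=d2)


def cluster_diagnostics(tree: ClusterTree, d=None, k_max: int | None = None) -> pd.DataFrame:
    """Scree table of (k, pseudo_F, pseudo_T2) for k = 2 .. k_max.

    pseudo-F(k) = [(T - W_k)/(k-1)] / [W_k/(n-k)] with W_k the total
    within-cluster SS of the k-cluster partition and T the one-cluster SS.
    pseudo-T2(k) belongs to the merge that collapses k+1 clusters into k:
    T2 = B / [(SS_K + SS_L)/(n_K + n_L - 2)] for merging clusters K, L with
    between-SS increase B; when both are singletons (zero denominator
    degrees of freedom) T2 is reported as B itself.
    """
    n = tree.n
    if d is not None:
        _, full = _as_square(d)
        d2 = full**2
    else:
        d2 = tree._d2
    if k_max is None:
        k_max = n - 1
    if not 2 <= k_max < n:
        raise ValueError(f"k_max must be in [2, {n - 1}]")
    total_ss = _cluster_ss(d2, list(range(n)))

    # reconstruct member sets once to evaluate every merge's T2
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    ss: dict[int, float] = {i: 0.0 for i in range(n)}
    t2_by_k: dict[int, float] = {}
    for m, (a, b, _, _) in enumerate(tree.merges):
        a, b = int(a), int(b)
        merged = members[a] + members[b]
        new_ss = _cluster_ss(d2, merged)
        between = new_ss - ss[a] - ss[b]
        df = len(members[a]) + len(members[b]) - 2
        denom = ss[a] + ss[b]
        if df == 0 or denom == 0:
            t2 = between
        else:
            t2 = between / (denom / df)
        k_after = n - m - 1  # this merge produces the k_after-cluster solution
        t2_by_k[k_after] = t2
        node = n + m
        members[node] = merged
        ss[node] = new_ss

    rows = []
    for k in range(2, k_max + 1):
        labels = tree.labels(k)
        w_k = 0.0
        for c in range(1, k + 1):
            idx = [i for i, s in enumerate(tree.sample_ids) if labels[s] == c]
            w_k += _cluster_ss(d2, idx)
        if w_k == 0:
            pf = np.inf if total_ss > 0 else 0.0
        else:
            pf = ((total_ss - w_k) / (k - 1)) / (w_k / (n - k))
        rows.append((k, pf, t2_by_k.get(k, np.nan)))
    return pd.DataFrame(rows, columns=["k", "pseudo_F", "pseudo_T2"])


def choose_k(diagnostics: pd.DataFrame, k_override: int | None = None) -> int:
    """Pick the cluster count from the pseudo-F scree, deterministically.

    Rule: candidates are local maxima of pseudo-F over the k grid (grid
    boundaries qualify one-sidedly); the candidate with the largest pseudo-F
    wins, ties broken toward the larger pseudo-T2 of the merge forming that
    solution, then toward smaller k.  A monotone-decreasing scree therefore
    yields k = 2.  ``k_override`` bypasses the rule entirely.
    """
    if k_override is not None:
        return int(k_override)
    if diagnostics.empty:
        raise ValueError("empty diagnostics")
    ks = diagnostics["k"].to_numpy()
    f = diagnostics["pseudo_F"].to_numpy(dtype=float)
    t2 = diagnostics["pseudo_T2"].to_numpy(dtype=float)
    candidates = []
    for i in range(len(ks)):
        left_ok = i == 0 or f[i] >= f[i - 1]
        right_ok = i == len(ks) - 1 or f[i] >= f[i + 1]
        if left_ok and right_ok:
            candidates.append(i)
    if not candidates:
        candidates = list(range(len(ks)))
    t2_key = np.where(np.isnan(t2), -np.inf, t2)
    best = max(candidates, key=lambda i: (f[i], t2_key[i], -ks[i]))
    return int(ks[best])


def aggregate_relative_abundance(
    table: OtuTable, tax: TaxonomyMap, rank: str, taxon: str, sample: str
) -> float:
    """Fraction of a sample's reads assigned to ``taxon`` at ``rank``.

    OTUs unassigned at that rank contribute to no taxon, so the shares of all
    taxa at a rank sum to the assigned-read fraction.
    """
    rel = table.relative_abundance(sample)
    share = 0.0
    for j, otu in enumerate(table.otu_ids):
        if rel[j] > 0 and tax[otu].at(rank) == taxon:
            share += float(rel[j])
    return share


@dataclass
class DysbiosisCall:
    """Per-infant dysbiosis flags and sub-type.

    Window-dependent flags are None (not False) when the infant lacks a
    pre-onset sample in that window; combined flags are None when any input
    flag is None.
    """

    infant_id: str
    group: str
    w1_sample_id: str | None
    w2_sample_id: str | None
    firmicutes_dysbiosis_w1: bool | None
    proteobacteria_dysbiosis_w2: bool | None
    propionibacterium_absent_w1: bool | None
    either_dysbiosis: bool | None
    combined_criterion: bool | None
    shares: dict[str, float | None]
    subtype: str = "unclassified"


def classify_dysbiosis(
    table: OtuTable,
    tax: TaxonomyMap,
    records: Sequence[SampleRecord],
    firmicutes_threshold: float = 0.98,
    proteobacteria_threshold: float = 0.90,
    propi_min_reads: int = 1,
    window1: Window = WINDOW_1,
    window2: Window = WINDOW_2,
) -> list[DysbiosisCall]:
    """Evaluate the three per-infant dysbiosis criteria on unrarefied counts.

    Firmicutes is evaluated at phylum rank in the window-1 sample against
    ``firmicutes_threshold`` (default 0.98); Proteobacteria at phylum rank in
    the window-2 sample against ``proteobacteria_threshold`` (default 0.90);
    Propionibacterium absence means fewer than ``propi_min_reads`` reads of
    that genus in the window-1 sample.
    """
    w1 = {r.infant_id: r for r in select_analysis_samples(records, window1)}
    w2 = {r.infant_id: r for r in select_analysis_samples(records, window2)}
    infants: list[str] = []
    groups: dict[str, str] = {}
    for r in records:
        if r.infant_id not in groups:
            infants.append(r.infant_id)
            groups[r.infant_id] = r.group

    propi_col = [
        j for j, o in enumerate(table.otu_ids) if tax[o].at("genus") == "Propionibacterium"
    ]

    calls = []
    for infant in infants:
        s1 = w1.get(infant)
        s2 = w2.get(infant)
        shares: dict[str, float | None] = {
            "firmicutes_w1": None,
            "bacilli_w1": None,
            "proteobacteria_w1": None,
            "propionibacterium_w1": None,
            "proteobacteria_w2": None,
            "enterobacteriaceae_w2": None,
        }
        firm = propi_absent = None
        if s1 is not None and s1.sample_id in table:
            sid = s1.sample_id
            shares["firmicutes_w1"] = aggregate_relative_abundance(
                table, tax, "phylum", "Firmicutes", sid
            )
            shares["bacilli_w1"] = aggregate_relative_abundance(
                table, tax, "class", "Bacilli", sid
            )
            shares["proteobacteria_w1"] = aggregate_relative_abundance(
                table, tax, "phylum", "Proteobacteria", sid
            )
            shares["propionibacterium_w1"] = aggregate_relative_abundance(
                table, tax, "genus", "Propionibacterium", sid
            )
            firm = shares["firmicutes_w1"] >= firmicutes_threshold
            propi_reads = int(table.sample_counts(sid)[propi_col].sum()) if propi_col else 0
            propi_absent = propi_reads < propi_min_reads
        proteo = None
        if s2 is not None and s2.sample_id in table:
            sid = s2.sample_id
            shares["proteobacteria_w2"] = aggregate_relative_abundance(
                table, tax, "phylum", "Proteobacteria", sid
            )
            shares["enterobacteriaceae_w2"] = aggregate_relative_abundance(
                table, tax, "family", "Enterobacteriaceae", sid
            )
            proteo = shares["proteobacteria_w2"] >= proteobacteria_threshold
        either = None if (firm is None or proteo is None) else (firm or proteo)
        combined = None if (propi_absent is None or either is None) else (propi_absent and either)
        calls.append(
            DysbiosisCall(
                infant_id=infant,
                group=groups[infant],
                w1_sample_id=s1.sample_id if s1 else None,
                w2_sample_id=s2.sample_id if s2 else None,
                firmicutes_dysbiosis_w1=firm,
                proteobacteria_dysbiosis_w2=proteo,
                propionibacterium_absent_w1=propi_absent,
                either_dysbiosis=either,
                combined_criterion=combined,
                shares=shares,
            )
        )
    return calls


def assign_subtypes(
    calls: Sequence[DysbiosisCall],
    w1_labels: dict[str, int] | None,
    w2_labels: dict[str, int] | None,
    entero_threshold: float = 0.90,
) -> list[DysbiosisCall]:
    """Attach cluster-derived sub-type labels to dysbiosis calls, in place.

    The window-1 cluster holding the majority of Firmicutes-dysbiosis
    infants is the NEC-I-like community.  The NEC-II-like community is the
    dominant Enterobacteriaceae group of window 2: the largest cluster whose
    median Enterobacteriaceae share reaches ``entero_threshold`` (small
    clusters of extreme outlying samples do not outrank it), falling back to
    the highest-median cluster when none reaches it.  An infant is
    NEC-I-like if its window-1 sample sits in the former (that phenotype is
    the earlier, overriding signature), else NEC-II-like if its window-2
    sample sits in the latter, else unclassified.
    """
    neci_cluster = None
    if w1_labels:
        votes: dict[int, int] = {}
        for c in calls:
            if c.firmicutes_dysbiosis_w1 and c.w1_sample_id in w1_labels:
                lab = w1_labels[c.w1_sample_id]
                votes[lab] = votes.get(lab, 0) + 1
        if votes:
            neci_cluster = max(sorted(votes), key=lambda k: votes[k])

    necii_cluster = None
    if w2_labels:
        shares_by_cluster: dict[int, list[float]] = {}
        for c in calls:
            if c.w2_sample_id in w2_labels and c.shares["enterobacteriaceae_w2"] is not None:
                shares_by_cluster.setdefault(w2_labels[c.w2_sample_id], []).append(
                    c.shares["enterobacteriaceae_w2"]
                )
        if shares_by_cluster:
            medians = {k: float(np.median(v)) for k, v in shares_by_cluster.items()}
            sizes = {k: len(v) for k, v in shares_by_cluster.items()}
            dominant = [k for k, m in medians.items() if m >= entero_threshold]
            if dominant:
                necii_cluster = max(sorted(dominant), key=lambda k: (sizes[k], medians[k]))
            else:
                necii_cluster = max(sorted(medians), key=lambda k: medians[k])

    for c in calls:
        if (
            neci_cluster is not None
            and c.w1_sample_id is not None
            and w1_labels.get(c.w1_sample_id) == neci_cluster
        ):
            c.subtype = "NEC-I-like"
        elif (
            necii_cluster is not None
            and c.w2_sample_id is not None
            and w2_labels.get(c.w2_sample_id) == necii_cluster
        ):
            c.subtype = "NEC-II-like"
        else:
            c.subtype = "unclassified"
    return list(calls)
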