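"""Univariate statistics for the metabolite analysis.

Kruskal-Wallis rank tests for group comparisons, Spearman rank
correlations of urinary metabolites with community features, Welch t-tests,
and Benjamini-Hochberg control of the false discovery rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st
from statsmodels.stats.multitest import multipletests

from .biomarkers import alanine_histidine_ratio
from .cluster import DysbiosisCall
from .io import MetaboliteRecord

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "kruskal_wallis",
    "spearman",
    "bh_adjust",
    "welch_t",
    "table2_report",
]


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    group_names: tuple[str, ...]
    statistic: float
    p_value: float
    medians: dict


@dataclass(frozen=True)
class CorrelationResult:
    var_x: str
    var_y: str
    rho: float
    p_value: float


def kruskal_wallis(groups: Mapping[str, Sequence[float]], variable: str = "") -> GroupComparison:
    """Tie-corrected Kruskal-Wallis H with chi-squared p on len(groups)-1 df.

    Fully tied data (every value identical) has no separation by convention:
    H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, arr in arrays.items():
        if arr.size == 0:
            raise ValueError(f"group {name!r} is empty")
    values = np.concatenate(list(arrays.values()))
    if values.size < 3:
        raise ValueError("need at least three observations in total")
    if np.all(values == values[0]):
        h, p = 0.0, 1.0
    else:
        h, p = _st.kruskal(*arrays.values())
    return GroupComparison(
        variable=variable,
        group_names=tuple(arrays),
        statistic=float(h),
        p_value=float(p),
        medians={k: float(np.median(v)) for k, v in arrays.items()},
    )


def spearman(x: Sequence[float], y: Sequence[float], names=("x", "y")) -> CorrelationResult:
    """Spearman rank correlation: Pearson on mid-ranks, t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired inputs of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation undefined for a constant input")
    res = _st.spearmanr(x, y)
    return CorrelationResult(names[0], names[1], float(res.statistic), float(res.pvalue))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def welch_t(
    group_a: Sequence[float], group_b: Sequence[float], variable: str = ""
) -> GroupComparison:
    """Welch two-sample t-test with Satterthwaite degrees of freedom."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("zero variance in both groups")
    t, p = _st.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        variable=variable,
        group_names=("a", "b"),
        statistic=float(t),
        p_value=float(p),
        medians={"a": float(np.median(a)), "b": float(np.median(b))},
    )


_METABOLITES = ("alanine", "histidine", "alanine_histidine_ratio")
_FEATURES = ("firmicutes_w1", "proteobacteria_w1", "propionibacterium_w1")


def table2_report(
    metabolites: Sequence[MetaboliteRecord],
    calls: Sequence[DysbiosisCall],
    bh: bool = False,
) -> pd.DataFrame:
    """Metabolite-community association table.

    For each of alanine, histidine, and their ratio: Spearman correlations
    against the window-1 Firmicutes, Proteobacteria, and Propionibacterium
    relative-abundance shares, and Kruskal-Wallis contrasts of the metabolite
    across five groupings (Firmicutes-community cluster membership vs rest;
    Enterobacteriaceae-community membership vs rest; NEC vs controls; NEC-I
    vs rest excluding deaths; NEC-II vs rest excluding deaths).  Cluster
    membership is read from each call's cluster-derived ``subtype``, so
    :func:`necbiome.cluster.assign_subtypes` must have run.  One metabolite
    record per infant: the first window-1 urine sample.

    Returns 3 x (3 + 5) = 24 rows; ``bh=True`` appends a BH-adjusted p
    column over all rows.
    """
    first: dict[str, MetaboliteRecord] = {}
    for m in sorted(metabolites, key=lambda m: (m.infant_id, m.day_of_life)):
        first.setdefault(m.infant_id, m)
    by_infant = {c.infant_id: c for c in calls}

    met_values: dict[str, dict[str, float]] = {name: {} for name in _METABOLITES}
    for infant, m in first.items():
        met_values["alanine"][infant] = m.alanine
        met_values["histidine"][infant] = m.histidine
        met_values["alanine_histidine_ratio"][infant] = alanine_histidine_ratio(m)

    def contrast_members(c: DysbiosisCall, which: str) -> bool | None:
        # None -> infant excluded from this contrast entirely
        if which == "cluster_I":
            return c.subtype == "NEC-I-like"
        if which == "cluster_II":
            return c.subtype == "NEC-II-like"
        if which == "NEC_vs_rest":
            return None if c.group == "non_NEC_death" else c.group == "NEC"
        if which == "NEC_I_vs_rest":
            if c.group == "non_NEC_death":
                return None
            return c.group == "NEC" and c.subtype == "NEC-I-like"
        if which == "NEC_II_vs_rest":
            if c.group == "non_NEC_death":
                return None
            return c.group == "NEC" and c.subtype == "NEC-II-like"
        raise ValueError(which)

    rows = []
    for met in _METABOLITES:
        vals = met_values[met]
        for feat in _FEATURES:
            pairs = [
                (vals[i], by_infant[i].shares[feat])
                for i in vals
                if i in by_infant and by_infant[i].shares[feat] is not None
            ]
            x = [p[0] for p in pairs]
            y = [p[1] for p in pairs]
            try:
                res = spearman(x, y, names=(met, feat))
                rho, p = res.rho, res.p_value
            except ValueError:
                rho, p = np.nan, np.nan
            rows.append(
                {
                    "metabolite": met,
                    "kind": "spearman",
                    "against": feat,
                    "n": len(pairs),
                    "rho": rho,
                    "median_in": np.nan,
                    "median_rest": np.nan,
                    "p_value": p,
                }
            )
        for which in ("cluster_I", "cluster_II", "NEC_vs_rest", "NEC_I_vs_rest", "NEC_II_vs_rest"):
            inside, outside = [], []
            for infant, v in vals.items():
                c = by_infant.get(infant)
                if c is None:
                    continue
                member = contrast_members(c, which)
                if member is None:
                    continue
                (inside if member else outside).append(v)
            if inside and outside:
                gc = kruskal_wallis({"in": inside, "rest": outside}, variable=met)
                stat_p = gc.p_value
                med_in, med_rest = gc.medians["in"], gc.medians["rest"]
            else:
                stat_p, med_in, med_rest = np.nan, np.nan, np.nan
            rows.append(
                {
                    "metabolite": met,
                    "kind": "kruskal_wallis",
                    "against": which,
                    "n": len(inside) + len(outside),
                    "rho": np.nan,
                    "median_in": med_in,
                    "median_rest": med_rest,
                    "p_value": stat_p,
                }
            )
    df = pd.DataFrame(rows)
    if bh:
        mask = df["p_value"].notna()
        adjusted = np.full(len(df), np.nan)
        if mask.any():
            adjusted[mask.to_numpy()] = bh_adjust(df.loc[mask, "p_value"].to_numpy())
        df["p_bh"] = adjusted
    return df
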