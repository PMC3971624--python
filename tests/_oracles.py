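"""Independent brute-force oracles used to cross-check the implementation.

Each oracle recomputes a quantity from first principles (enumeration,
closed form, or exhaustive search) without touching the code path it
checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# Weighted UniFrac: enumerate every branch and its descendant leaf set


def unifrac_bruteforce(tree, counts_a: dict[str, int], counts_b: dict[str, int]) -> float:
    total_a = sum(counts_a.values())
    total_b = sum(counts_b.values())
    dist = 0.0
    for node in tree.traverse(include_self=False):
        tips = [t.name for t in node.tips()] or [node.name]
        pa = sum(counts_a.get(t, 0) for t in tips) / total_a
        pb = sum(counts_b.get(t, 0) for t in tips) / total_b
        dist += (node.length or 0.0) * abs(pa - pb)
    return dist


def random_tree_newick(rng: np.random.Generator, n_leaves: int) -> str:
    """Random rooted binary topology with uniform branch lengths."""
    parts = [f"L{i}:{rng.uniform(0.1, 2.0):.6f}" for i in range(n_leaves)]
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        b = parts.pop(j)
        a = parts.pop(i)
        parts.append(f"({a},{b}):{rng.uniform(0.1, 2.0):.6f}")
    inner = parts[0].rsplit(":", 1)[0]
    return f"{inner}:0;"


# ---------------------------------------------------------------------------
# Ward: greedy minimization of the within-cluster sum-of-squares increase


def _ss(d2: np.ndarray, cluster: frozenset[int]) -> float:
    if len(cluster) < 2:
        return 0.0
    idx = sorted(cluster)
    return sum(d2[i, j] for a, i in enumerate(idx) for j in idx[a + 1:]) / len(cluster)


def ward_greedy_partitions(d: np.ndarray) -> dict[int, list[frozenset[int]]]:
    """Greedy SS-increase-minimizing agglomeration; partitions for every k.

    Ties on the SS increase break toward the lexicographically smallest
    cluster pair, matching scipy's ordering on distinct input distances
    (random continuous distances make exact ties measure-zero).
    """
    n = d.shape[0]
    d2 = d**2
    clusters: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    partitions = {n: list(clusters)}
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            merged = clusters[i] | clusters[j]
            inc = _ss(d2, merged) - _ss(d2, clusters[i]) - _ss(d2, clusters[j])
            key = (inc, tuple(sorted(clusters[i])), tuple(sorted(clusters[j])))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        merged = clusters[i] | clusters[j]
        clusters = [c for m, c in enumerate(clusters) if m not in (i, j)] + [merged]
        partitions[len(clusters)] = list(clusters)
    return partitions


# ---------------------------------------------------------------------------
# Fisher's exact test: enumerate all tables with the observed margins


def fisher_enumeration(a: int, b: int, c: int, d: int) -> float:
    row1, col1, n = a + b, a + c, a + b + c + d

    def logp(x: int) -> float:
        return (
            math.lgamma(row1 + 1) - math.lgamma(x + 1) - math.lgamma(row1 - x + 1)
            + math.lgamma(n - row1 + 1) - math.lgamma(col1 - x + 1)
            - math.lgamma(n - row1 - col1 + x + 1)
            - (math.lgamma(n + 1) - math.lgamma(col1 + 1) - math.lgamma(n - col1 + 1))
        )

    lo, hi = max(0, col1 - (n - row1)), min(row1, col1)
    p_obs = math.exp(logp(a))
    total = 0.0
    for x in range(lo, hi + 1):
        p = math.exp(logp(x))
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(total, 1.0)


# ---------------------------------------------------------------------------
# Rank statistics: exact permutation enumeration (tiny n)


def _midranks(values) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    i = 0
    sorted_vals = values[order]
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def kw_statistic(groups: list[list[float]]) -> float:
    """Tie-corrected Kruskal-Wallis H from the rank formula."""
    values = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n = len(values)
    ranks = _midranks(values)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    correction = 1 - sum(c**3 - c for c in counts) / (n**3 - n)
    return h / correction if correction > 0 else 0.0


def kw_permutation_p(groups: list[list[float]]) -> float:
    """Exact p by enumerating all assignments of values to group slots."""
    values = list(np.concatenate([np.asarray(g, dtype=float) for g in groups]))
    sizes = [len(g) for g in groups]
    h_obs = kw_statistic(groups)
    n_extreme = total = 0
    for perm in itertools.permutations(range(len(values))):
        regrouped, start = [], 0
        for s in sizes:
            regrouped.append([values[i] for i in perm[start:start + s]])
            start += s
        total += 1
        if kw_statistic(regrouped) >= h_obs - 1e-12:
            n_extreme += 1
    return n_extreme / total


def spearman_rho_formula(x, y) -> float:
    """Pearson correlation of mid-ranks, computed from the definition."""
    rx, ry = _midranks(x), _midranks(y)
    rx, ry = rx - rx.mean(), ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def spearman_permutation_p(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho_obs = abs(spearman_rho_formula(x, y))
    n_extreme = total = 0
    for perm in itertools.permutations(range(len(y))):
        total += 1
        if abs(spearman_rho_formula(x, y[list(perm)])) >= rho_obs - 1e-12:
            n_extreme += 1
    return n_extreme / total


# ---------------------------------------------------------------------------
# ROC: exhaustive threshold scan


def roc_scan_best_c(case_vals, ctrl_vals) -> float:
    values = np.unique(np.concatenate([case_vals, ctrl_vals]))
    best = -np.inf
    for thr in (values[:-1] + values[1:]) / 2:
        sens = np.mean(np.asarray(case_vals) > thr)
        spec = np.mean(np.asarray(ctrl_vals) <= thr)
        best = max(best, (sens + spec) / 2)
    return float(best)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg: the step-up rule, evaluated by hand


def bh_stepup(p_values) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adjusted[i] = running
    return adjusted
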