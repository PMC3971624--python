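"""Beta diversity: rare-OTU filtering, weighted UniFrac, and NMDS ordination.

Weighted UniFrac weighs each branch of the phylogeny by its length times the
difference between the two samples' fractions of reads descending through it
(the raw, unnormalized form):

    d(A, B) = sum_i  b_i * | p_i^A - p_i^B |

Non-metric multidimensional scaling (NMDS) embeds the samples in k
dimensions by minimizing Kruskal stress-1,

    stress = 100 * sqrt( sum (dhat_ij - delta_ij)^2 / sum delta_ij^2 ),

where delta are configuration distances and dhat is the monotone (isotonic)
regression of delta on the rank order of the input dissimilarities.  Several
random starts guard against local optima; the reported configuration is
centered and rotated so variance is maximized along the first axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity

from .io import OtuTable

__all__ = [
    "filter_rare_otus",
    "weighted_unifrac",
    "unifrac_distance_matrix",
    "nmds",
    "OrdinationResult",
]


def filter_rare_otus(
    table: OtuTable, min_samples: int = 2, min_total: int = 5
) -> OtuTable:
    """Drop rare OTUs before beta diversity, to improve signal to noise.

    An OTU is kept iff it is detected (count > 0) in at least ``min_samples``
    samples AND its overall read total is at least ``min_total``.  The sample
    set is unchanged.
    """
    present_in = (table.counts > 0).sum(axis=0)
    totals = table.counts.sum(axis=0)
    keep = [
        o
        for o, n, t in zip(table.otu_ids, present_in, totals)
        if n >= min_samples and t >= min_total
    ]
    if not keep:
        raise ValueError("rare-OTU filter removed every OTU; ordination impossible")
    return table.subset_otus(keep)


def _check_tree_covers(table: OtuTable, tree: TreeNode) -> None:
    leaves = {t.name for t in tree.tips()}
    nonzero = table.counts.sum(axis=0) > 0
    for otu, nz in zip(table.otu_ids, nonzero):
        if nz and otu not in leaves:
            raise ValueError(f"OTU {otu!r} has reads but is absent from the tree")


def weighted_unifrac(
    table: OtuTable, tree: TreeNode, a: str, b: str, normalized: bool = False
) -> float:
    """Weighted UniFrac distance between two samples of ``table``."""
    pair = table.subset_samples([a, b]) if a != b else table.subset_samples([a])
    _check_tree_covers(pair, tree)
    if a == b:
        return 0.0
    dm = beta_diversity(
        "weighted_unifrac",
        pair.counts,
        ids=[a, b],
        taxa=pair.otu_ids,
        tree=tree,
        normalized=normalized,
    )
    return float(dm[a, b])


def unifrac_distance_matrix(
    table: OtuTable, tree: TreeNode, normalized: bool = False
) -> DistanceMatrix:
    """All-pairs weighted UniFrac over a table's samples.

    Per-sample proportions are taken over the table as given, so filtering
    (rare-OTU removal) must happen before this call for the renormalized
    convention.
    """
    _check_tree_covers(table, tree)
    return beta_diversity(
        "weighted_unifrac",
        table.counts,
        ids=table.sample_ids,
        taxa=table.otu_ids,
        tree=tree,
        normalized=normalized,
    )


# ---------------------------------------------------------------------------
# NMDS


@dataclass
class OrdinationResult:
    """The best-of-starts NMDS solution.

    ``configuration`` is centered and rotated to principal axes (coordinate
    variance non-increasing across columns).  ``stress`` is Kruskal stress-1
    on the 0-100 scale.  ``stress_traces`` holds the per-iteration stress of
    every start; each trace is non-increasing by construction.
    """

    sample_ids: list[str]
    configuration: np.ndarray
    stress: float
    n_starts: int
    best_start: int
    converged: list[bool]
    stress_traces: list[np.ndarray]


def _stress1(delta: np.ndarray, dhat: np.ndarray) -> float:
    denom = float(np.sum(delta**2))
    if denom == 0:
        return np.inf
    return 100.0 * np.sqrt(float(np.sum((dhat - delta) ** 2)) / denom)


def _monotone_fit(d: np.ndarray, delta: np.ndarray) -> np.ndarray:
    # Kruskal's primary approach to ties: order by (dissimilarity, current
    # configuration distance), so tied dissimilarities are free to receive
    # unequal fitted values.
    order = np.lexsort((delta, d))
    fit = isotonic_regression(delta[order], increasing=True).x
    dhat = np.empty_like(delta)
    dhat[order] = fit
    return dhat


def _guttman_update(x: np.ndarray, delta: np.ndarray, dhat: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(delta > 0, dhat / np.where(delta > 0, delta, 1.0), 0.0)
    b = -squareform(ratio)
    np.fill_diagonal(b, -b.sum(axis=1))
    return b @ x / n


def _classical_mds(d_full: np.ndarray, k: int) -> np.ndarray:
    n = d_full.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d_full**2) @ j
    w, v = np.linalg.eigh(g)
    idx = np.argsort(w)[::-1][:k]
    scale = np.sqrt(np.clip(w[idx], 0, None))
    return v[:, idx] * scale


def _principal_axis_rotate(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rot = u * s
    # deterministic sign: largest-magnitude coordinate of each axis positive
    for j in range(rot.shape[1]):
        i = int(np.argmax(np.abs(rot[:, j])))
        if rot[i, j] < 0:
            rot[:, j] = -rot[:, j]
    return rot


def nmds(
    d: DistanceMatrix,
    k: int = 3,
    n_starts: int = 20,
    seed=0,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> OrdinationResult:
    """Kruskal NMDS of a distance matrix by iterated monotone regression.

    Each start alternates an isotonic fit of configuration distances on the
    dissimilarity ranks with a Guttman majorization step; the recorded stress
    trace is forced non-increasing (an iteration that would raise stress is
    rejected and the start stops).  One extra deterministic start is seeded
    from classical metric scaling of ``d``.  The lowest-stress start wins.
    """
    if isinstance(d, DistanceMatrix):
        ids = list(d.ids)
        full = np.asarray(d.data, dtype=float)
    else:
        full = np.asarray(d, dtype=float)
        if full.ndim != 2 or full.shape[0] != full.shape[1]:
            raise ValueError("distance input must be square")
        if not np.allclose(full, full.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        ids = [str(i) for i in range(full.shape[0])]
    n = full.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} samples, got {n}")
    dvec = squareform(full, checks=False)
    if np.all(dvec == 0):
        raise ValueError("all distances are zero; ordination undefined")

    rng = np.random.default_rng(seed)
    starts: list[np.ndarray] = [_classical_mds(full, k)]
    starts += [rng.standard_normal((n, k)) for _ in range(max(n_starts - 1, 0))]

    best_x, best_stress, best_i = None, np.inf, -1
    converged: list[bool] = []
    traces: list[np.ndarray] = []
    for i, x0 in enumerate(starts):
        x = x0.copy()
        trace: list[float] = []
        conv = False
        prev_x = x
        prev_stress = np.inf
        for _ in range(max_iter):
            delta = pdist(x)
            if np.all(delta == 0):  # collapsed configuration
                break
            dhat = _monotone_fit(dvec, delta)
            stress = _stress1(delta, dhat)
            if stress > prev_stress:  # reject uphill step, keep previous
                x = prev_x
                conv = True
                break
            trace.append(stress)
            if prev_stress - stress < tol * max(prev_stress, 1e-300):
                conv = True
                break
            prev_x, prev_stress = x, stress
            x = _guttman_update(x, delta, dhat)
        if not conv and trace:
            x = prev_x  # report the configuration whose stress was last recorded
        final = trace[-1] if trace else np.inf
        converged.append(conv)
        traces.append(np.asarray(trace))
        if final < best_stress:
            best_x, best_stress, best_i = x, final, i

    if best_x is None:
        raise ValueError("no NMDS start produced a valid configuration")
    return OrdinationResult(
        sample_ids=ids,
        configuration=_principal_axis_rotate(best_x),
        stress=float(best_stress),
        n_starts=len(starts),
        best_start=best_i,
        converged=converged,
        stress_traces=traces,
    )
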