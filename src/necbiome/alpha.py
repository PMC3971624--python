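"""Rarefaction and alpha (within-sample) diversity.

Per-sample counts are standardized by rarefying — subsampling reads without
replacement — to a common depth (2,000 reads in the primary analysis), then
summarized by the Chao1 richness estimator and the Simpson diversity index.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio.diversity import alpha as _skbio_alpha

from .io import OtuTable

__all__ = ["rarefy", "chao1", "simpson", "alpha_diversity_table", "DepthError"]


class DepthError(ValueError):
    """Requested rarefaction depth exceeds the sample's read count."""


def rarefy(counts, depth: int, seed) -> np.ndarray:
    """Subsample a count vector without replacement to ``depth`` reads.

    Equivalent to drawing ``depth`` reads from the sample's read pool: the
    result is multivariate-hypergeometric and reproducible from ``seed``
    (an int or ``numpy.random.Generator``).
    """
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    if depth > total:
        raise DepthError(f"depth {depth} exceeds sample total {total}")
    if depth == total:
        return counts.copy()
    rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts, depth)


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness: S_obs + F1*(F1-1)/(2*(F2+1)) (bias-corrected form).

    F1 and F2 are the singleton and doubleton counts.  The classic
    F1^2/(2*F2) form (undefined at F2=0) is available with
    ``bias_corrected=False``.  Always >= observed richness.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if counts.sum() <= 0:
        raise ValueError("chao1 requires a non-empty sample")
    return float(_skbio_alpha.chao1(counts, bias_corrected=bias_corrected))


def simpson(counts) -> float:
    """Simpson diversity, 1 - sum(p_i^2): the chance two reads differ in OTU.

    Depends on proportions only; in [0, 1), 0 for a single-OTU sample.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if counts.sum() <= 0:
        raise ValueError("simpson requires a non-empty sample")
    return float(_skbio_alpha.simpson(counts))


def alpha_diversity_table(
    table: OtuTable, depth: int = 2000, seed=0
) -> pd.DataFrame:
    """Per-sample alpha diversity on one rarefaction draw at ``depth``.

    Samples shallower than ``depth`` are flagged (``depth_ok=False``) and get
    NaN indices rather than being silently kept at native depth.  Each sample
    gets an independent child stream of ``seed`` so the draw for one sample
    does not depend on table ordering of the others.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(table.sample_ids))
    rows = []
    for sid, child in zip(table.sample_ids, children):
        v = table.sample_counts(sid)
        ok = int(v.sum()) >= depth
        if ok:
            r = rarefy(v, depth, np.random.default_rng(child))
            rows.append((sid, True, chao1(r), simpson(r)))
        else:
            rows.append((sid, False, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["sample_id", "depth_ok", "chao1", "simpson"])
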