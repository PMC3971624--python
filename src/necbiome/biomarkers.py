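"""Binary biomarker evaluation: 2x2 tables, exact tests, and ROC cut-points.

Every biomarker here reduces to a 2x2 table of cases/controls versus
positive/negative.  Its predictive value is the binary-predictor area under
the ROC curve,

    c = (sensitivity + specificity) / 2,

its significance the two-sided Fisher exact test (point-probability
ordering).  Continuous markers (the urinary alanine:histidine ratio) are
dichotomized at a threshold, either fixed or chosen by exhaustive ROC scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import fisher_exact as _scipy_fisher

from .cluster import DysbiosisCall
from .io import MetaboliteRecord

__all__ = [
    "TwoByTwo",
    "BiomarkerResult",
    "fisher_exact",
    "evaluate_binary",
    "alanine_histidine_ratio",
    "roc_cutpoint",
    "table3_report",
    "TABLE3_CRITERIA",
]


@dataclass(frozen=True)
class TwoByTwo:
    """Counts: a = cases positive, b = cases negative, c = controls positive,
    d = controls negative."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("2x2 counts must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d


@dataclass(frozen=True)
class BiomarkerResult:
    """One evaluated criterion: counts, operating characteristics, exact p."""

    criterion: str
    table: TwoByTwo
    sensitivity: float
    specificity: float
    c_statistic: float
    p_value: float
    n_excluded: int = 0


def fisher_exact(t: TwoByTwo) -> float:
    """Two-sided Fisher exact p: with margins fixed, sum the hypergeometric
    probabilities of every table whose point probability is <= the observed
    table's (ties within relative tolerance)."""
    return float(_scipy_fisher([[t.a, t.b], [t.c, t.d]], alternative="two-sided").pvalue)


def evaluate_binary(
    flags: Mapping[str, bool | None],
    outcomes: Mapping[str, str],
    criterion: str = "",
) -> BiomarkerResult:
    """Evaluate a binary per-infant predictor of NEC versus control.

    ``outcomes`` maps infant -> "NEC" | "control" (other groups are ignored);
    infants with a None flag, or with a flag but no outcome, are excluded and
    counted in ``n_excluded``.
    """
    a = b = c = d = 0
    excluded = 0
    for infant, outcome in outcomes.items():
        if outcome not in ("NEC", "control"):
            continue
        flag = flags.get(infant)
        if flag is None:
            excluded += 1
            continue
        if outcome == "NEC":
            a, b = (a + 1, b) if flag else (a, b + 1)
        else:
            c, d = (c + 1, d) if flag else (c, d + 1)
    t = TwoByTwo(a, b, c, d)
    if t.n_cases == 0 or t.n_controls == 0:
        raise ValueError(f"criterion {criterion!r}: no evaluable cases or controls")
    sens = a / t.n_cases
    spec = d / t.n_controls
    return BiomarkerResult(
        criterion=criterion,
        table=t,
        sensitivity=sens,
        specificity=spec,
        c_statistic=(sens + spec) / 2,
        p_value=fisher_exact(t),
        n_excluded=excluded,
    )


def alanine_histidine_ratio(m: MetaboliteRecord) -> float:
    """Urinary alanine:histidine ratio (relative NMR units cancel)."""
    if not m.histidine > 0:
        raise ValueError(f"non-positive histidine for infant {m.infant_id!r}")
    return m.alanine / m.histidine


def roc_cutpoint(
    values: Mapping[str, float],
    outcomes: Mapping[str, str],
    criterion: str = "ROC cut-point",
) -> tuple[float, BiomarkerResult]:
    """Exhaustive ROC scan for the threshold maximizing the c-statistic.

    Candidate thresholds are midpoints between consecutive sorted unique
    values; a subject is positive when its value is strictly greater than the
    threshold.  Ties on c break toward the smallest threshold.
    """
    case_vals = [v for i, v in values.items() if outcomes.get(i) == "NEC"]
    ctrl_vals = [v for i, v in values.items() if outcomes.get(i) == "control"]
    if not case_vals or not ctrl_vals:
        raise ValueError("need at least one case and one control with values")
    uniq = np.unique(np.asarray(case_vals + ctrl_vals, dtype=float))
    if uniq.size < 2:
        raise ValueError("all marker values identical; no discriminating cut-point")
    midpoints = (uniq[:-1] + uniq[1:]) / 2
    best_thr, best_c = None, -np.inf
    for thr in midpoints:  # ascending, so first max wins -> smallest threshold
        sens = float(np.mean(np.asarray(case_vals) > thr))
        spec = float(np.mean(np.asarray(ctrl_vals) <= thr))
        c = (sens + spec) / 2
        if c > best_c:
            best_thr, best_c = float(thr), c
    flags = {i: v > best_thr for i, v in values.items()}
    return best_thr, evaluate_binary(flags, outcomes, criterion=criterion)


TABLE3_CRITERIA = (
    "High Firmicutes dysbiosis (>=98%, days 4 to 9)",
    "No Propionibacterium (days 4 to 9)",
    "High Proteobacteria dysbiosis (>=90%, days 10 to 16)",
    "Dysbiosis (criterion 1 or 3)",
    "Combined criteria 2 and 4 (no Propionibacterium + dysbiosis)",
    "Urinary alanine:histidine ratio >4 (days 4 to 9)",
)


def table3_report(
    calls: Sequence[DysbiosisCall],
    metabolites: Sequence[MetaboliteRecord] = (),
    ratio_threshold: float | None = 4.0,
) -> list[BiomarkerResult]:
    """The six predictive criteria, evaluated on their per-criterion
    evaluable sets.

    Criteria 1-3 use the single flags (infants lacking the needed window are
    excluded); 4 and 5 are restricted to infants with pre-onset samples in
    both windows; 6 dichotomizes the first window-1 urine sample's
    alanine:histidine ratio at ``ratio_threshold`` (pass None to pick the
    threshold by ROC scan instead).  Non-NEC deaths are never evaluable.
    """
    outcomes = {c.infant_id: c.group for c in calls}
    results = [
        evaluate_binary(
            {c.infant_id: c.firmicutes_dysbiosis_w1 for c in calls},
            outcomes,
            TABLE3_CRITERIA[0],
        ),
        evaluate_binary(
            {c.infant_id: c.propionibacterium_absent_w1 for c in calls},
            outcomes,
            TABLE3_CRITERIA[1],
        ),
        evaluate_binary(
            {c.infant_id: c.proteobacteria_dysbiosis_w2 for c in calls},
            outcomes,
            TABLE3_CRITERIA[2],
        ),
        evaluate_binary(
            {c.infant_id: c.either_dysbiosis for c in calls},
            outcomes,
            TABLE3_CRITERIA[3],
        ),
        evaluate_binary(
            {c.infant_id: c.combined_criterion for c in calls},
            outcomes,
            TABLE3_CRITERIA[4],
        ),
    ]
    # first urine sample per infant in the early window
    first: dict[str, MetaboliteRecord] = {}
    for m in sorted(metabolites, key=lambda m: (m.infant_id, m.day_of_life)):
        first.setdefault(m.infant_id, m)
    ratios = {i: alanine_histidine_ratio(m) for i, m in first.items()}
    if ratios:
        if ratio_threshold is None:
            _, res = roc_cutpoint(ratios, outcomes, criterion=TABLE3_CRITERIA[5])
        else:
            flags = {i: r > ratio_threshold for i, r in ratios.items()}
            res = evaluate_binary(flags, outcomes, criterion=TABLE3_CRITERIA[5])
        results.append(res)
    return results
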