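"""Wilcoxon rank-sum comparison battery with reciprocal-count cutoffs.

Every (population, timepoint, cohort-pair) cell of a comparison design gets a
two-sided Wilcoxon rank-sum (Mann-Whitney) test. Significance uses a fixed
per-comparison cutoff equal to the reciprocal of the total number of
comparisons in the design, rounded to a stated precision — the rule printed
alongside the original designs:

* 18 populations x 3 timepoints x 3 cohort pairs = 162 comparisons,
  cutoff round(1/162, 3) = 0.006;
* 100 populations x 3 timepoints x 1 pair = 300 comparisons,
  cutoff round(1/300, 4) = 0.0033;
* 18 populations x 3 timepoints x 1 pair = 54 comparisons,
  cutoff round(1/54, 4) = 0.0185.

Effect size is reported as the fold ratio of medians, case/control (values
below 1 indicate depression in the first cohort of the pair); the heatmap
export masks non-significant cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .profiles import Cohort, CohortSet, TIMEPOINTS, ValidationError

__all__ = [
    "BatteryRecord",
    "significance_threshold",
    "rank_sum_battery",
    "fold_heatmap",
]


@dataclass(frozen=True)
class BatteryRecord:
    """One population x timepoint x cohort-pair rank-sum result."""

    population: str
    timepoint_days: int
    cohort_a: str
    cohort_b: str
    measure: str
    statistic: float
    p_value: float
    threshold: float
    significant: bool
    fold_ratio: float  # median(a)/median(b); NaN flags a zero denominator


def significance_threshold(n_comparisons: int, decimals: int = 4) -> float:
    """Per-comparison cutoff 1/n, rounded to the requested decimals."""
    if n_comparisons < 1:
        raise ValidationError("n_comparisons must be a positive integer")
    return round(1.0 / n_comparisons, decimals)


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided rank-sum p-value: exact for small tie-free samples,
    normal approximation with continuity correction otherwise (mid-ranks
    for ties)."""
    small = max(len(x), len(y)) <= 25
    no_ties = np.unique(np.concatenate([x, y])).size == len(x) + len(y)
    method = "exact" if (small and no_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def rank_sum_battery(
    cs: CohortSet,
    cohort_pairs: list[tuple[str, str]],
    timepoints: tuple[int, ...] = TIMEPOINTS,
    measure: str = "counts",
    decimals: int = 4,
    min_per_side: int = 3,
) -> list[BatteryRecord]:
    """Run the full design; every record is emitted, significant or not.

    The threshold is ``significance_threshold`` of the design's total cell
    count (populations x timepoints x pairs); empty cells (fewer than
    ``min_per_side`` subjects on either side) are skipped with a warning and
    do not reduce the design count. Controls carry no timepoint and enter
    every visit's comparison as the full single-sample control set.
    """
    panel = cs.panel
    n_comparisons = panel.size * len(timepoints) * len(cohort_pairs)
    threshold = significance_threshold(n_comparisons, decimals)

    def side(cohort: str, tp: int) -> np.ndarray:
        if Cohort(cohort) is Cohort.CONTROL:
            profs = cs.controls()
        else:
            profs = cs.select(cohort, tp)
        if not profs:
            return np.empty((0, panel.size))
        return cs.matrix(measure, profs)

    records: list[BatteryRecord] = []
    for a, b in cohort_pairs:
        for tp in timepoints:
            Xa, Xb = side(a, tp), side(b, tp)
            if Xa.shape[0] < min_per_side or Xb.shape[0] < min_per_side:
                import logging

                logging.getLogger(__name__).warning(
                    "skipping empty design cell %s vs %s at day %s", a, b, tp
                )
                continue
            for k, pop in enumerate(panel.ids):
                stat, p = _rank_sum_p(Xa[:, k], Xb[:, k])
                med_a, med_b = float(np.median(Xa[:, k])), float(np.median(Xb[:, k]))
                fold = med_a / med_b if med_b > 0 else float("nan")
                records.append(
                    BatteryRecord(
                        population=pop,
                        timepoint_days=tp,
                        cohort_a=a,
                        cohort_b=b,
                        measure=measure,
                        statistic=stat,
                        p_value=p,
                        threshold=threshold,
                        significant=bool(p < threshold),
                        fold_ratio=fold,
                    )
                )
    return records


def battery_frame(records: list[BatteryRecord]) -> pd.DataFrame:
    """Tidy DataFrame view of battery records."""
    return pd.DataFrame([r.__dict__ for r in records])


def fold_heatmap(
    records: list[BatteryRecord],
    populations: Sequence[str] | None = None,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Population x timepoint fold-ratio matrices, one per cohort pair.

    Non-significant cells are masked to NaN (rendered blank), mirroring
    heatmaps where a blank cell means no significant difference.
    ``populations`` restricts the rows displayed — the usual pipeline shows
    only the populations pre-selected by the FIS stage, whose FDR control is
    what keeps false discoveries out of the displayed matrix.
    """
    df = battery_frame(records)
    if populations is not None:
        df = df[df["population"].isin(set(populations))]
    if df.empty:
        return {}
    out: dict[tuple[str, str], pd.DataFrame] = {}
    for (a, b), sub in df.groupby(["cohort_a", "cohort_b"], sort=False):
        masked = sub.assign(
            fold=np.where(sub["significant"], sub["fold_ratio"], np.nan)
        )
        mat = masked.pivot(index="population", columns="timepoint_days", values="fold")
        # keep panel order rather than alphabetical
        mat = mat.reindex([r for r in dict.fromkeys(sub["population"])])
        out[(a, b)] = mat
    return out
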