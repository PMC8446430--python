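"""The I-index overlap measure between composition profiles, and distances.

The I-index used here is a normalized generalized Jensen-Shannon overlap.
Given n profiles restricted to a common feature set and renormalised to
probability distributions P_1..P_n, the generalized Jensen-Shannon divergence
with uniform weights is

    JSD(P_1..P_n) = H(mean_i P_i) - mean_i H(P_i),

where H is Shannon entropy. JSD is bounded by log n, so

    I = 1 - JSD / log n

lies in [0, 1], equals 1 for identical distributions and 0 for pairwise
disjoint supports. The definition is base-invariant: both JSD and log n scale
by the same factor under a change of logarithm base.

The overlap functional sits behind a single interface so an alternative
estimator (e.g. Morisita-Horn) can be swapped without touching the feature
importance or clustering layers.

A case's divergence from a control set is measured as the overlap *lost* by
adding the case:

    d(case; controls) = I(controls) - I(controls ∪ {case}),

so that larger d = more divergent, and a feature's positive contribution to d
reads as "contributes to the case-control difference". The per-subject
trajectory statistic is ``1 - I({case} ∪ controls)`` over the full panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .profiles import CohortSet, ImmuneProfile, ValidationError

__all__ = [
    "OverlapConfig",
    "SimilarityMatrix",
    "i_index",
    "i_index_matrix",
    "set_distance",
    "trajectory_distance",
    "trajectory_table",
    "similarity_matrix",
]


@dataclass(frozen=True)
class OverlapConfig:
    """Numerical conventions for the overlap functional.

    pseudocount
        Small non-negative value added to every category *after* restriction
        to the analysed feature set and *before* normalisation. The default
        0.5 is on the counts scale (half a cell/µL) and keeps
        disjoint-support profiles at finite divergence in realistic runs;
        pseudocount 0 is reserved for analytic tests. When the measure is
        proportions, pass a proportion-scale value (e.g. 1e-4).
    """

    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if self.pseudocount < 0:
            raise ValidationError("pseudocount must be non-negative")


def _as_distributions(X: np.ndarray, pseudocount: float) -> np.ndarray:
    """Rows of X (non-negative) -> probability distributions after pseudocount."""
    X = np.asarray(X, dtype=float) + pseudocount
    totals = X.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise ValidationError("each profile must have positive total on the analysed features")
    return X / totals


def i_index_matrix(X: np.ndarray, pseudocount: float = 0.5) -> float:
    """I-index of the rows of an (n, K) non-negative matrix.

    Rows are renormalised (after pseudocount) and compared via the
    generalized Jensen-Shannon overlap defined in the module docstring.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n < 2:
        raise ValidationError("i_index needs at least 2 profiles")
    D = _as_distributions(X, pseudocount)
    h_rows = -xlogy(D, D).sum(axis=1)          # per-profile entropies
    mix = D.mean(axis=0)
    h_mix = -xlogy(mix, mix).sum()
    jsd = h_mix - h_rows.mean()
    val = 1.0 - jsd / np.log(n)
    # guard against |eps|-scale excursions from floating point
    return float(min(1.0, max(0.0, val)))


def _stack(
    profiles: Sequence[ImmuneProfile],
    measure: str,
    feature_idx: np.ndarray | None = None,
) -> np.ndarray:
    if len(profiles) < 2:
        raise ValidationError("need at least 2 profiles")
    k = profiles[0].counts.shape[0]
    if any(p.counts.shape[0] != k for p in profiles):
        raise ValidationError("profiles must share one panel")
    X = np.vstack([p.values(measure) for p in profiles])
    if feature_idx is not None:
        if feature_idx.size == 0:
            raise ValidationError("feature subset must be non-empty")
        X = X[:, feature_idx]
    return X


def i_index(
    profiles: Sequence[ImmuneProfile],
    measure: str = "counts",
    cfg: OverlapConfig = OverlapConfig(),
) -> float:
    """I-index overlap of two or more profiles (1 identical .. 0 disjoint)."""
    return i_index_matrix(_stack(profiles, measure), cfg.pseudocount)


def set_distance(
    case: ImmuneProfile,
    controls: Sequence[ImmuneProfile],
    feature_subset: Sequence[str] | np.ndarray | None = None,
    measure: str = "counts",
    cfg: OverlapConfig = OverlapConfig(),
    panel=None,
) -> float:
    """Overlap lost by adding ``case`` to the control set.

    ``d = I(controls) - I(controls ∪ {case})``, computed after restriction to
    ``feature_subset`` (panel ids, or integer positions) and renormalisation.
    ``feature_subset=None`` uses the full panel.
    """
    if len(controls) < 2:
        raise ValidationError("need at least 2 controls")
    idx = None
    if feature_subset is not None:
        fs = np.asarray(feature_subset)
        if fs.size == 0:
            raise ValidationError("feature subset must be non-empty")
        if fs.dtype.kind in "iu":
            idx = fs.astype(np.intp)
        else:
            if panel is None:
                raise ValidationError("panel required to resolve feature ids")
            idx = panel.indexer(list(fs))
    ctrl = _stack(list(controls), measure, idx)
    case_row = case.values(measure)
    if idx is not None:
        case_row = case_row[idx]
    i_ctrl = i_index_matrix(ctrl, cfg.pseudocount)
    i_all = i_index_matrix(np.vstack([ctrl, case_row]), cfg.pseudocount)
    return i_ctrl - i_all


def trajectory_distance(
    case: ImmuneProfile,
    controls: Sequence[ImmuneProfile],
    measure: str = "counts",
    cfg: OverlapConfig = OverlapConfig(),
) -> float:
    """Distance of one case from the compound control set, ``1 - I``.

    The I-index is taken over ``{case} ∪ controls`` on the full panel; the
    per-subject time course of this quantity tracks convergence toward the
    control population.
    """
    if len(controls) < 2:
        raise ValidationError("need at least 2 controls")
    X = _stack([case] + list(controls), measure)
    return 1.0 - i_index_matrix(X, cfg.pseudocount)


def trajectory_table(
    cs: CohortSet,
    case_cohorts: Iterable[str] = ("HIV_POS", "HIV_NEG"),
    measure: str = "counts",
    cfg: OverlapConfig = OverlapConfig(),
) -> pd.DataFrame:
    """Tidy per-(subject, visit) trajectory distances versus the controls.

    Columns: ``subject_id, cohort, timepoint_days, distance``.
    """
    controls = cs.controls()
    rows = []
    for cohort in case_cohorts:
        for p in cs.select(cohort):
            if p.timepoint_days is None:
                continue
            rows.append(
                {
                    "subject_id": p.subject_id,
                    "cohort": p.cohort.value,
                    "timepoint_days": p.timepoint_days,
                    "distance": trajectory_distance(p, controls, measure, cfg),
                }
            )
    return pd.DataFrame(rows, columns=["subject_id", "cohort", "timepoint_days", "distance"])


@dataclass
class SimilarityMatrix:
    """Pairwise I-index values over a profile set (symmetric, unit diagonal)."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        V = np.asarray(self.values, dtype=float)
        self.values = V
        n = len(self.labels)
        if V.shape != (n, n):
            raise ValidationError("similarity matrix must be square and match labels")
        if not np.allclose(V, V.T, atol=1e-12):
            raise ValidationError("similarity matrix must be symmetric")
        if np.any(V < -1e-12) or np.any(V > 1 + 1e-12):
            raise ValidationError("similarities must lie in [0, 1]")
        if not np.allclose(np.diag(V), 1.0, atol=1e-12):
            raise ValidationError("similarity diagonal must be 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="label")


def similarity_matrix(
    cs: CohortSet,
    measure: str = "counts",
    cfg: OverlapConfig = OverlapConfig(),
    profiles: Sequence[ImmuneProfile] | None = None,
) -> SimilarityMatrix:
    """Pairwise I-index matrix over the profiles of a cohort set."""
    profs = list(profiles) if profiles is not None else list(cs.profiles)
    if len(profs) < 2:
        raise ValidationError("need at least 2 profiles")
    X = cs.matrix(measure, profs)
    D = _as_distributions(X, cfg.pseudocount)
    n = D.shape[0]
    V = np.eye(n)
    log2 = np.log(2.0)
    h_rows = -xlogy(D, D).sum(axis=1)
    for i in range(n):
        for j in range(i + 1, n):
            mix = 0.5 * (D[i] + D[j])
            h_mix = -xlogy(mix, mix).sum()
            jsd = h_mix - 0.5 * (h_rows[i] + h_rows[j])
            V[i, j] = V[j, i] = min(1.0, max(0.0, 1.0 - jsd / log2))
    return SimilarityMatrix(labels=[p.label for p in profs], values=V)
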