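"""Per-visit PCA of composition profiles and cohort convergence summaries.

Each post-transplant visit is fitted independently: the case profiles at that
visit are pooled with the full (visit-less) control set, columns are
standardised (z-scored) — counts span orders of magnitude across populations —
and a PCA is fitted on the pooled matrix. Cohort structure is summarised by
the centroid of each cohort's scores and the pairwise distances between
centroids in PC space; shrinking case-versus-control centroid distance across
visits quantifies convergence of the reconstituting immune compartment toward
the healthy-control configuration.

For proportion-scale input an optional centered log-ratio (clr) transform is
available (with the overlap module's pseudocount guarding zeros), the
standard compositional-data preparation before PCA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .profiles import Cohort, CohortSet, TIMEPOINTS, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["PcaResult", "pca_by_visit"]


@dataclass
class PcaResult:
    """Per-visit PCA scores and cohort-convergence summaries."""

    scores: dict[int, pd.DataFrame] = field(default_factory=dict)
    explained_variance: dict[int, np.ndarray] = field(default_factory=dict)
    centroids: dict[int, pd.DataFrame] = field(default_factory=dict)
    centroid_distances: pd.DataFrame = field(default_factory=pd.DataFrame)

    def distance_series(self, cohort_a: str, cohort_b: str) -> pd.Series:
        """Centroid distance of one cohort pair indexed by visit day."""
        df = self.centroid_distances
        mask = ((df["cohort_a"] == cohort_a) & (df["cohort_b"] == cohort_b)) | (
            (df["cohort_a"] == cohort_b) & (df["cohort_b"] == cohort_a)
        )
        return df.loc[mask].set_index("timepoint_days")["distance"].sort_index()


def _clr(X: np.ndarray, pseudocount: float) -> np.ndarray:
    L = np.log(X + pseudocount)
    return L - L.mean(axis=1, keepdims=True)


def pca_by_visit(
    cs: CohortSet,
    measure: str = "proportions",
    n_components: int = 2,
    scale: bool = True,
    clr: bool = False,
    clr_pseudocount: float = 1e-6,
    timepoints: tuple[int, ...] = TIMEPOINTS,
) -> PcaResult:
    """Fit one PCA per visit on cases-at-visit pooled with all controls.

    Constant columns are dropped (with a warning) when scaling is on, since
    a zero-variance column cannot be z-scored. Explained-variance fractions
    are non-increasing by construction; centroid distances are Euclidean in
    the ``n_components``-dimensional score space.
    """
    if n_components > cs.panel.size:
        raise ValidationError("n_components exceeds panel size")
    result = PcaResult()
    dist_rows = []
    for tp in timepoints:
        cases = [p for p in cs.profiles if p.timepoint_days == tp]
        controls = cs.controls()
        profs = cases + controls
        cohorts = [p.cohort.value for p in profs]
        for cohort in set(cohorts):
            if cohorts.count(cohort) < 3:
                raise ValidationError(
                    f"need at least 3 subjects per cohort per visit ({cohort} at day {tp})"
                )
        X = cs.matrix(measure, profs)
        cols = np.array(cs.panel.ids)
        if clr:
            X = _clr(X, clr_pseudocount)
        if scale:
            keep = X.std(axis=0) > 0
            if not keep.all():
                logger.warning(
                    "day %d: dropping constant columns %s", tp, cols[~keep].tolist()
                )
                X, cols = X[:, keep], cols[keep]
            X = StandardScaler().fit_transform(X)
        pca = PCA(n_components=n_components, svd_solver="full")
        S = pca.fit_transform(X)
        comp_names = [f"PC{i+1}" for i in range(n_components)]
        scores = pd.DataFrame(S, columns=comp_names)
        scores.insert(0, "subject_id", [p.subject_id for p in profs])
        scores.insert(1, "cohort", cohorts)
        result.scores[tp] = scores
        result.explained_variance[tp] = pca.explained_variance_ratio_
        cent = scores.groupby("cohort")[comp_names].mean()
        result.centroids[tp] = cent
        present = list(cent.index)
        for i, a in enumerate(present):
            for b in present[i + 1 :]:
                d = float(np.linalg.norm(cent.loc[a] - cent.loc[b]))
                dist_rows.append(
                    {"cohort_a": a, "cohort_b": b, "timepoint_days": tp, "distance": d}
                )
    result.centroid_distances = pd.DataFrame(dist_rows)
    return result
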