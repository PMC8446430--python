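"""Data model and I/O for immunophenotype panels and longitudinal cohorts.

The unit of observation is one subject at one post-transplant visit, summarised
as a vector of lymphocyte-subset quantities over a fixed *panel* of
immune-marker combinations (e.g. ``CD3+/HLA-DR+`` = activated T cells).
Quantities are carried on two scales:

* ``counts`` — absolute cells per microliter of blood, obtained from percent of
  gated lymphocytes times the absolute lymphocyte count;
* ``proportions`` — the composition of the panel, i.e. counts renormalised to
  sum to one over the K selected populations.

Proportions are defined over the panel under analysis (not over all
lymphocytes) because the overlap index downstream requires probability
distributions on a common support; the marker panels are not exhaustive,
mutually exclusive partitions of the lymphocyte pool, and overlapping gate
definitions are deliberately kept as separate features.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Post-transplant sampling days for the two transplant cohorts.
TIMEPOINTS: tuple[int, ...] = (56, 180, 365)

#: Tolerance on the sum of a normalised composition.
PROPORTION_TOL = 1e-9

_META_COLUMNS = ("subject_id", "cohort", "timepoint_days")


class Cohort(str, enum.Enum):
    """Study arm of a profile."""

    HIV_POS = "HIV_POS"   # HIV(+) transplant recipients (lymphoma, BEAM)
    HIV_NEG = "HIV_NEG"   # HIV(-) transplant recipients (myeloma, melphalan)
    CONTROL = "CONTROL"   # healthy controls, sampled once

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class ValidationError(ValueError):
    """An input violates a profile/panel invariant."""


class FormatError(ValueError):
    """A delimited-text file does not have the expected layout."""


@dataclass(frozen=True)
class PopulationPanel:
    """Ordered set of immune-marker-combination identifiers under study.

    Parameters
    ----------
    ids
        Unique, non-empty marker-combination strings; order fixes the column
        order of every profile vector.
    annotations
        Optional map from id to a short functional description
        (e.g. ``"CD4+/CD45RA+" -> "Naive T helper cells"``).
    """

    ids: tuple[str, ...]
    annotations: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = tuple(self.ids)
        object.__setattr__(self, "ids", ids)
        if len(ids) < 2:
            raise ValidationError("a panel needs at least 2 populations")
        if any(not i for i in ids):
            raise ValidationError("population ids must be non-empty")
        if len(set(ids)) != len(ids):
            raise ValidationError("population ids must be unique")
        unknown = set(self.annotations) - set(ids)
        if unknown:
            raise ValidationError(f"annotations for unknown ids: {sorted(unknown)}")

    @property
    def size(self) -> int:
        return len(self.ids)

    # len() mirrors .size; both appear in downstream code.
    def __len__(self) -> int:
        return len(self.ids)

    def indexer(self, subset: Sequence[str]) -> np.ndarray:
        """Integer positions of ``subset`` ids, in the given order."""
        pos = {p: k for k, p in enumerate(self.ids)}
        try:
            return np.asarray([pos[s] for s in subset], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - message path
            raise ValidationError(f"unknown population id {exc.args[0]!r}") from exc


def normalize(values: np.ndarray) -> np.ndarray:
    """Renormalise a non-negative vector to a composition summing to 1."""
    values = np.asarray(values, dtype=float)
    total = values.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValidationError("cannot normalise a vector with non-positive total")
    return values / total


def to_absolute(percentages: np.ndarray, total_lymphocytes: float) -> np.ndarray:
    """Convert percent-of-gated-lymphocytes to absolute cells per µL.

    ``counts[i] = percentages[i] / 100 * total_lymphocytes``, the standard
    derivation from an absolute lymphocyte count on a hematology analyzer.
    """
    pct = np.asarray(percentages, dtype=float)
    if np.any(pct < 0) or np.any(pct > 100):
        raise ValidationError("percentages must lie in [0, 100]")
    if total_lymphocytes < 0:
        raise ValidationError("total lymphocyte count must be non-negative")
    return pct / 100.0 * float(total_lymphocytes)


@dataclass(frozen=True)
class ImmuneProfile:
    """One subject x timepoint composition vector over a panel.

    ``counts`` are absolute cells/µL; ``proportions`` are the counts
    renormalised over the panel. Controls carry ``timepoint_days=None``
    (sampled once); transplant recipients carry one of :data:`TIMEPOINTS`.
    """

    subject_id: str
    cohort: Cohort
    timepoint_days: int | None
    counts: np.ndarray
    proportions: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        props = np.asarray(self.proportions, dtype=float)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "proportions", props)
        if not self.subject_id:
            raise ValidationError("subject_id must be non-empty")
        if counts.ndim != 1 or props.shape != counts.shape:
            raise ValidationError("counts and proportions must be aligned 1-d vectors")
        if np.any(~np.isfinite(counts)) or np.any(counts < 0):
            raise ValidationError(f"negative or non-finite count for subject {self.subject_id!r}")
        if counts.sum() <= 0:
            raise ValidationError(f"all-zero profile for subject {self.subject_id!r}")
        if np.any(props < 0) or abs(props.sum() - 1.0) > PROPORTION_TOL:
            raise ValidationError(
                f"proportions must be a composition summing to 1 (subject {self.subject_id!r})"
            )
        if self.timepoint_days is not None and self.timepoint_days not in TIMEPOINTS:
            raise ValidationError(
                f"timepoint_days must be one of {TIMEPOINTS} or None, got {self.timepoint_days}"
            )

    @classmethod
    def from_counts(
        cls,
        subject_id: str,
        cohort: Cohort | str,
        timepoint_days: int | None,
        counts: np.ndarray,
    ) -> "ImmuneProfile":
        counts = np.asarray(counts, dtype=float)
        return cls(
            subject_id=subject_id,
            cohort=Cohort(cohort),
            timepoint_days=timepoint_days,
            counts=counts,
            proportions=normalize(counts),
        )

    @property
    def key(self) -> tuple[str, int | None]:
        return (self.subject_id, self.timepoint_days)

    @property
    def label(self) -> str:
        """Unique display label, ``subject`` or ``subject@day``."""
        if self.timepoint_days is None:
            return self.subject_id
        return f"{self.subject_id}@{self.timepoint_days}"

    def values(self, measure: str) -> np.ndarray:
        """Return the vector on the requested scale (``counts``|``proportions``)."""
        if measure == "counts":
            return self.counts
        if measure == "proportions":
            return self.proportions
        raise ValueError(f"measure must be 'counts' or 'proportions', got {measure!r}")


@dataclass
class CohortSet:
    """A panel plus a collection of profiles sharing it."""

    panel: PopulationPanel
    profiles: list[ImmuneProfile]

    def __post_init__(self) -> None:
        keys = set()
        for p in self.profiles:
            if p.counts.shape[0] != self.panel.size:
                raise ValidationError(
                    f"profile {p.label} has {p.counts.shape[0]} entries; panel has {self.panel.size}"
                )
            if p.key in keys:
                raise ValidationError(f"duplicate subject x timepoint: {p.key}")
            keys.add(p.key)

    def __len__(self) -> int:
        return len(self.profiles)

    def select(
        self,
        cohort: Cohort | str | None = None,
        timepoint_days: int | None | str = "any",
    ) -> list[ImmuneProfile]:
        """Profiles filtered by cohort and/or visit.

        ``timepoint_days="any"`` keeps all visits; ``None`` selects visit-less
        profiles (controls).
        """
        cohort = Cohort(cohort) if cohort is not None else None
        out = []
        for p in self.profiles:
            if cohort is not None and p.cohort is not cohort:
                continue
            if timepoint_days != "any" and p.timepoint_days != timepoint_days:
                continue
            out.append(p)
        return out

    def controls(self) -> list[ImmuneProfile]:
        return self.select(Cohort.CONTROL)

    def matrix(self, measure: str, profiles: Iterable[ImmuneProfile] | None = None) -> np.ndarray:
        """Stack profiles into an (n, K) array on the requested scale."""
        profs = list(profiles) if profiles is not None else self.profiles
        return np.vstack([p.values(measure) for p in profs])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.profiles:
            row: dict[str, object] = {
                "subject_id": p.subject_id,
                "cohort": p.cohort.value,
                "timepoint_days": "" if p.timepoint_days is None else p.timepoint_days,
            }
            row.update(zip(self.panel.ids, p.counts))
            rows.append(row)
        return pd.DataFrame(rows, columns=list(_META_COLUMNS) + list(self.panel.ids))


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def write_cohort(cs: CohortSet, path: str | Path) -> Path:
    """Write a cohort as delimited text (TSV by default, CSV for ``.csv``).

    Columns: ``subject_id, cohort, timepoint_days`` then one count column per
    population, so a cohort of n subjects-visits yields n rows x (K+3) columns.
    Counts round-trip exactly through :func:`read_cohort` (written as repr).
    """
    path = Path(path)
    df = cs.to_frame()
    df.to_csv(path, sep=_sep_for(path), index=False)
    return path


def read_cohort(
    path: str | Path,
    panel: PopulationPanel | None = None,
    value_kind: str = "counts",
) -> CohortSet:
    """Read a delimited cohort file into a validated :class:`CohortSet`.

    Parameters
    ----------
    path
        TSV/CSV with header ``subject_id, cohort, timepoint_days, <ids...>``.
    panel
        Expected panel; when omitted a panel is built from the data columns
        in file order (no annotations).
    value_kind
        ``"counts"`` (cells/µL, the writer's format) or ``"proportions"``
        (compositions; rows not summing to 1 are renormalised with a warning,
        and counts are set equal to the raw values for lack of a total).

    Raises
    ------
    FormatError
        Missing required columns.
    ValidationError
        A row violates profile invariants; the message names the row index
        and the offending population.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    value_cols = [c for c in df.columns if c not in _META_COLUMNS]
    if panel is None:
        panel = PopulationPanel(tuple(value_cols))
    else:
        missing = [c for c in panel.ids if c not in value_cols]
        if missing:
            raise FormatError(f"{path}: missing population columns {missing}")
    if value_kind not in ("counts", "proportions"):
        raise ValueError(f"value_kind must be 'counts' or 'proportions', got {value_kind!r}")

    profiles = []
    for idx, row in df.iterrows():
        values = row[list(panel.ids)].to_numpy(dtype=float)
        bad = np.flatnonzero(values < 0)
        if bad.size:
            raise ValidationError(
                f"{path} row {idx}: negative value for population "
                f"{panel.ids[bad[0]]!r} ({values[bad[0]]})"
            )
        if value_kind == "proportions":
            total = values.sum()
            if abs(total - 1.0) > PROPORTION_TOL:
                logger.warning(
                    "%s row %d: proportions sum to %.6g; renormalising", path, idx, total
                )
        tp = row["timepoint_days"]
        tp = None if (pd.isna(tp) or tp == "") else int(tp)
        profiles.append(
            ImmuneProfile.from_counts(
                subject_id=str(row["subject_id"]),
                cohort=Cohort(row["cohort"]),
                timepoint_days=tp,
                counts=values,
            )
        )
    return CohortSet(panel=panel, profiles=profiles)
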