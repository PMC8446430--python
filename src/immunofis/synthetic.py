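"""Seeded generator of three-cohort longitudinal immunophenotype datasets.

The generator emulates the structure of a post-transplant immune-
reconstitution study: two transplant cohorts sampled at days 56, 180 and 365
(defaults: 37 HIV(+) and 30 HIV(-) recipients) and a healthy-control cohort
sampled once (default 71 subjects). Per subject-visit it

1. draws an absolute lymphocyte count (cells/µL) log-normally;
2. builds the cohort-visit mean composition by applying decayed
   multiplicative effects to the control baseline and renormalising;
3. draws the composition Dirichlet-multinomially (a Dirichlet draw around the
   mean followed by a multinomial split of the total), so populations compete
   compositionally, as percent-of-lymphocyte measurements do.

Effects are specified as log2 fold changes versus the control mean on the
proportion scale, with a per-visit decay multiplier sequence in [0, 1]
encoding convergence toward controls over the post-transplant year. Because
effects act before renormalisation, a large single-population effect slightly
perturbs the remaining populations — the compositional analogue of real
percent-of-total measurements.

Default effect directions follow the reconstitution phenotype repeatedly
reported after transplant in chronic HIV infection: activated and
memory/effector CD8 T cells elevated, naive/memory CD4 helper subsets,
activated B cells and NK subsets depressed, decaying toward controls over
visits; the HIV(-) template carries transient early effects (late-activated
T cells and NK activation high at day 56) that resolve by day 365.

Baseline proportions are an order-of-magnitude-plausible fixture; they are
not calibrated to any particular cohort's medians — the generator validates
the inferential machinery on known ground truth, not absolute realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .panels import panel_18, preset
from .profiles import (
    Cohort,
    CohortSet,
    ImmuneProfile,
    PopulationPanel,
    TIMEPOINTS,
    ValidationError,
)

__all__ = ["EffectTemplate", "SimConfig", "default_baseline", "default_templates", "generate"]


@dataclass(frozen=True)
class EffectTemplate:
    """One population's cohort effect versus the control mean.

    ``log2_fc`` is the full-strength effect on the proportion scale
    (pre-renormalisation); ``decay`` multiplies it per visit over
    (day 56, 180, 365) and must be non-increasing within [0, 1] — effects
    shrink toward control over time.
    """

    feature: str
    log2_fc: float
    decay: tuple[float, float, float] = (1.0, 0.6, 0.35)

    def __post_init__(self) -> None:
        d = self.decay
        if len(d) != len(TIMEPOINTS):
            raise ValidationError("decay needs one multiplier per visit")
        if any(not (0.0 <= x <= 1.0) for x in d):
            raise ValidationError("decay values must lie in [0, 1]")
        if any(d[i + 1] > d[i] for i in range(len(d) - 1)):
            raise ValidationError("decay must be non-increasing")

    def log2_fc_at(self, timepoint_days: int) -> float:
        return self.log2_fc * self.decay[TIMEPOINTS.index(timepoint_days)]


# Order-of-magnitude-plausible panel shares for the 18-population preset
# (panel-relative, renormalised below; big lineage gates large, fine subsets
# small). Overlapping gates are independent features, not a partition.
_BASELINE_18 = {
    "CD3+": 0.24,
    "CD3+/HLA-DR+": 0.030,
    "CD3+/HLA-DR+/CD69+/CD134-": 0.012,
    "CD3+/HLA-DR+/CD134+/CD69-": 0.010,
    "CD4+": 0.15,
    "CD4+/CD45RA+": 0.070,
    "CD4+/CD45RO+": 0.075,
    "CD8+": 0.095,
    "CD8+/CD45RA-": 0.045,
    "CD8+/CD27-": 0.028,
    "CD8+/CD25-": 0.080,
    "CD19+": 0.055,
    "CD19+/CD80+": 0.016,
    "CD19+/CD86+": 0.014,
    "CD3-/CD56+": 0.050,
    "CD3-/CD56+/CD16+/CD134+": 0.012,
    "CD3-/CD56+/CD16+/CD107a/b+": 0.004,
    "CD3-/CD56+/CD16+/CD314+": 0.014,
}


def default_baseline(panel: PopulationPanel) -> np.ndarray:
    """Control mean composition for a panel (sums to 1).

    The 18-population preset uses the hand-set fixture above; other panels
    get fixture values where ids match and deterministic log-uniform shares
    (fixed internal seed — a fixture, not subject to the run seed) elsewhere.
    """
    rng = np.random.default_rng(180365)  # fixture stream, independent of run seed
    vals = np.empty(panel.size)
    for k, pid in enumerate(panel.ids):
        vals[k] = _BASELINE_18.get(pid, math.nan)
    missing = np.isnan(vals)
    if missing.any():
        vals[missing] = np.exp(rng.uniform(np.log(0.001), np.log(0.02), missing.sum()))
    return vals / vals.sum()


def default_templates(panel: PopulationPanel) -> dict[Cohort, list[EffectTemplate]]:
    """Shipped effect directionality for the two transplant cohorts.

    HIV(+) versus control: activated T cells and memory/effector CD8 subsets
    up; naive/memory CD4 helpers, activated B cells and NK subsets down;
    effects decay toward control over visits but persist at day 365.
    HIV(-) versus control: transient early elevation of late-activated
    (CD134+) T cells and of activated/degranulating NK subsets, fully
    resolved by day 365.
    """
    slow = (1.0, 0.6, 0.35)
    transient = (1.0, 0.5, 0.0)
    hiv_pos = [
        EffectTemplate("CD3+/HLA-DR+", +1.5, slow),
        EffectTemplate("CD3+/HLA-DR+/CD69+/CD134-", +1.2, slow),
        EffectTemplate("CD8+/CD45RA-", +1.0, slow),
        EffectTemplate("CD8+/CD27-", +0.8, slow),
        EffectTemplate("CD4+/CD45RA+", -1.2, slow),
        EffectTemplate("CD4+/CD45RO+", -0.8, slow),
        EffectTemplate("CD19+/CD80+", -1.0, slow),
        EffectTemplate("CD3-/CD56+/CD16+/CD134+", -1.0, slow),
        EffectTemplate("CD3-/CD56+/CD16+/CD314+", -0.8, slow),
    ]
    hiv_neg = [
        EffectTemplate("CD3+/HLA-DR+/CD134+/CD69-", +1.2, transient),
        EffectTemplate("CD3-/CD56+/CD16+/CD107a/b+", +1.0, transient),
        EffectTemplate("CD3-/CD56+/CD16+/CD134+", +0.8, transient),
    ]
    known = set(panel.ids)
    out = {
        Cohort.HIV_POS: [t for t in hiv_pos if t.feature in known],
        Cohort.HIV_NEG: [t for t in hiv_neg if t.feature in known],
    }
    if not out[Cohort.HIV_POS]:
        raise ValidationError("panel shares no features with the default templates")
    return out


@dataclass(frozen=True)
class SimConfig:
    """Study-design and noise parameters of one simulated dataset.

    Defaults encode the emulated study: cohort sizes 37/30/71, visits at days
    56/180/365 for transplant recipients, one visit-less sample per control.
    ``concentration`` is the Dirichlet precision around the cohort-visit mean
    composition (larger = less compositional overdispersion).
    ``lymph_median``/``lymph_sigma`` parameterise the log-normal absolute
    lymphocyte count (cells/µL); ``case_total_factor`` scales case totals per
    visit (incomplete numeric recovery early post-transplant).
    """

    panel: PopulationPanel = field(default_factory=panel_18)
    n_hiv_pos: int = 37
    n_hiv_neg: int = 30
    n_control: int = 71
    baseline: np.ndarray | None = None
    concentration: float = 300.0
    lymph_median: float = 1500.0
    lymph_sigma: float = 0.3
    case_total_factor: tuple[float, float, float] = (0.7, 0.85, 1.0)
    effects: dict[Cohort, list[EffectTemplate]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for n in (self.n_hiv_pos, self.n_hiv_neg, self.n_control):
            if n < 3:
                raise ValidationError("cohort sizes must be at least 3")
        if self.concentration <= 0:
            raise ValidationError("concentration must be positive")

    def resolved_baseline(self) -> np.ndarray:
        base = self.baseline if self.baseline is not None else default_baseline(self.panel)
        base = np.asarray(base, dtype=float)
        if base.shape != (self.panel.size,):
            raise ValidationError("baseline length must match the panel")
        if np.any(base <= 0):
            raise ValidationError("baseline proportions must be positive")
        return base / base.sum()

    def resolved_effects(self) -> dict[Cohort, list[EffectTemplate]]:
        eff = self.effects if self.effects is not None else default_templates(self.panel)
        known = set(self.panel.ids)
        for templates in eff.values():
            for t in templates:
                if t.feature not in known:
                    raise ValidationError(f"effect on unknown feature {t.feature!r}")
        return eff


def mean_composition(cfg: SimConfig, cohort: Cohort, timepoint_days: int | None) -> np.ndarray:
    """Cohort-visit mean composition: decayed effects applied to baseline."""
    base = cfg.resolved_baseline()
    if cohort is Cohort.CONTROL or timepoint_days is None:
        return base
    mult = np.ones_like(base)
    for t in cfg.resolved_effects().get(cohort, []):
        k = cfg.panel.indexer([t.feature])[0]
        mult[k] = 2.0 ** t.log2_fc_at(timepoint_days)
    mean = base * mult
    return mean / mean.sum()


def _draw_profile(
    rng: np.random.Generator,
    cfg: SimConfig,
    subject_id: str,
    cohort: Cohort,
    timepoint_days: int | None,
) -> ImmuneProfile:
    mean = mean_composition(cfg, cohort, timepoint_days)
    total = rng.lognormal(math.log(cfg.lymph_median), cfg.lymph_sigma)
    if cohort is not Cohort.CONTROL and timepoint_days is not None:
        total *= cfg.case_total_factor[TIMEPOINTS.index(timepoint_days)]
    n_cells = max(int(round(total)), 1)
    p = rng.dirichlet(cfg.concentration * mean)
    counts = rng.multinomial(n_cells, p).astype(float)
    if counts.sum() == 0:  # pragma: no cover - n_cells >= 1 forbids this
        counts[0] = 1.0
    return ImmuneProfile.from_counts(subject_id, cohort, timepoint_days, counts)


def generate(cfg: SimConfig) -> CohortSet:
    """Generate a full three-cohort longitudinal dataset (seed-deterministic).

    Transplant subjects get one profile per visit day; controls get a single
    visit-less profile. The same config (including seed) always yields an
    identical cohort set.
    """
    rng = np.random.default_rng(cfg.seed)
    cfg.resolved_effects()  # fail fast on unknown features
    profiles: list[ImmuneProfile] = []
    for i in range(cfg.n_hiv_pos):
        for tp in TIMEPOINTS:
            profiles.append(_draw_profile(rng, cfg, f"HIVPOS{i:03d}", Cohort.HIV_POS, tp))
    for i in range(cfg.n_hiv_neg):
        for tp in TIMEPOINTS:
            profiles.append(_draw_profile(rng, cfg, f"HIVNEG{i:03d}", Cohort.HIV_NEG, tp))
    for i in range(cfg.n_control):
        profiles.append(_draw_profile(rng, cfg, f"CTRL{i:03d}", Cohort.CONTROL, None))
    return CohortSet(panel=cfg.panel, profiles=profiles)


def null_config(cfg: SimConfig | None = None, **overrides) -> SimConfig:
    """A config with all cohort effects removed (cases ≡ control distribution).

    Case totals are also left unscaled so the null is exact on both scales.
    """
    base = cfg if cfg is not None else SimConfig()
    return replace(
        base,
        effects={Cohort.HIV_POS: [], Cohort.HIV_NEG: []},
        case_total_factor=(1.0, 1.0, 1.0),
        **overrides,
    )
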