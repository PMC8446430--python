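import numpy as np
import pytest

from immunofis import Cohort, CohortSet, ImmuneProfile, PopulationPanel
from scipy.stats import entropy


def make_profile(counts, subject="s", cohort=Cohort.CONTROL, tp=None):
    return ImmuneProfile.from_counts(subject, cohort, tp, np.asarray(counts, dtype=float))


def make_cohort(panel_ids, rows):
    """rows: list of (subject, cohort, tp, counts)."""
    panel = PopulationPanel(tuple(panel_ids))
    profiles = [make_profile(c, s, co, tp) for s, co, tp, c in rows]
    return CohortSet(panel=panel, profiles=profiles)


def oracle_i_index(X, pseudocount=0.0):
    """Independent direct-entropy I-index: scipy.stats.entropy arithmetic only."""
    X = np.asarray(X, dtype=float) + pseudocount
    D = X / X.sum(axis=1, keepdims=True)
    jsd = entropy(D.mean(axis=0)) - np.mean([entropy(d) for d in D])
    return 1.0 - jsd / np.log(D.shape[0])


def oracle_set_distance(case_row, ctrl_rows, pseudocount=0.5):
    """Independent overlap-lost distance from two direct I-index evaluations."""
    ctrl = np.asarray(ctrl_rows, dtype=float)
    both = np.vstack([ctrl, case_row])
    return oracle_i_index(ctrl, pseudocount) - oracle_i_index(both, pseudocount)


@pytest.fixture
def rng():
    return np.random.default_rng(20210903)


@pytest.fixture
def small_panel():
    return PopulationPanel(("A", "B", "C", "D"))


@pytest.fixture
def toy_cohort():
    """3 controls + 2 HIV(+) case-visits on a 4-population panel."""
    rows = [
        ("c1", Cohort.CONTROL, None, [100, 200, 300, 400]),
        ("c2", Cohort.CONTROL, None, [110, 190, 310, 390]),
        ("c3", Cohort.CONTROL, None, [90, 210, 290, 410]),
        ("p1", Cohort.HIV_POS, 56, [400, 100, 300, 200]),
        ("p1", Cohort.HIV_POS, 180, [300, 150, 300, 250]),
    ]
    return make_cohort(("A", "B", "C", "D"), rows)
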