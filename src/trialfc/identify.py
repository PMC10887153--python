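"""Marker-based task identification from trial FC maps.

One FC map is drawn from each task category and the three serve as class
prototypes ("markers"); every remaining trial is assigned the label of the
marker with the largest spatial correlation R to it.  With 8 trials per
category there are 8^3 = 512 marker triples and 21 test trials each, i.e.
10,752 tests per subject.  The per-category correct rate pooled over all
tests quantifies how reliably a subject's whole-brain activity identifies
the task, against a chance level of 33.3% for three categories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .fcmap import FCMap
from .hrf import TASK_ORDER
from .preprocess import BrainMask
from .similarity import SCMatrix, sc_matrix, spatial_correlation

__all__ = [
    "MarkerTriple",
    "Classification",
    "IdentificationResult",
    "AssociationResult",
    "classify_trial",
    "run_identification",
    "chance_rate",
    "test_vs_chance",
    "associate_R_with_CR",
]


@dataclass(frozen=True)
class MarkerTriple:
    """One marker trial index (1..n_per_task) per task category."""

    marker_indices: tuple[int, int, int]  # order follows TASK_ORDER

    def __post_init__(self) -> None:
        if len(self.marker_indices) != len(TASK_ORDER):
            raise ValueError("exactly one marker per category")
        if any(i < 1 for i in self.marker_indices):
            raise ValueError("marker indices are 1-based")


class Classification(NamedTuple):
    label: str
    tied: bool
    scores: dict[str, float]


@dataclass
class IdentificationResult:
    """Pooled outcome of the exhaustive marker-combination experiment."""

    subject_id: str
    n_combinations: int
    n_tests: int
    per_category_correct_rate: dict[str, float]  # percent
    n_ties: int
    sc: SCMatrix | None = None

    def __post_init__(self) -> None:
        for rate in self.per_category_correct_rate.values():
            if not (0 <= rate <= 100):
                raise ValueError("correct rates are percentages in [0, 100]")


@dataclass(frozen=True)
class AssociationResult:
    """Pearson association of mean within-category R with correct rate."""

    pearson_r: float
    p_value: float
    n_points: int


def classify_trial(
    test_map: FCMap,
    markers: Mapping[str, FCMap],
    mask: BrainMask | None = None,
) -> Classification:
    """Nearest-prototype label: the marker with maximal spatial R.

    Ties (a measure-zero event in floating point) break to the first label
    in canonical category order and are flagged.
    """
    order = [t for t in TASK_ORDER if t in markers]
    order += [t for t in markers if t not in order]
    scores = {t: spatial_correlation(test_map, markers[t], mask=mask)
              for t in order}
    best = max(scores.values())
    winners = [t for t in order if scores[t] == best]
    return Classification(label=winners[0], tied=len(winners) > 1,
                          scores=scores)


def run_identification(
    maps: Sequence[FCMap],
    subject_id: str = "",
    n_per_task: int = 8,
    sc: SCMatrix | None = None,
) -> IdentificationResult:
    """Exhaustive marker-triple identification for one subject.

    All pairwise spatial correlations are computed once (the SC matrix);
    each of the n^3 marker triples then classifies the remaining
    3n - 3 trials by argmax R.  Correct rates are micro-averaged per true
    category over all tests; with this balanced design every combination
    tests n - 1 trials of each category, so micro and macro averages
    coincide.
    """
    if sc is None:
        sc = sc_matrix(list(maps), subject_id=subject_id)
    labels = [t for t, _ in sc.trial_meta]
    cat_idx = []
    for t in TASK_ORDER:
        rows = [i for i, lab in enumerate(labels) if lab == t]
        if len(rows) != n_per_task:
            raise ValueError(f"need {n_per_task} maps for category {t}")
        cat_idx.append(rows)
    n_trials = len(labels)
    n_cat = len(TASK_ORDER)
    true_cat = np.array([TASK_ORDER.index(t) for t in labels])

    combos = np.indices((n_per_task,) * n_cat).reshape(n_cat, -1)  # (3, 512)
    n_comb = combos.shape[1]
    marker_rows = np.stack(
        [np.asarray(cat_idx[c])[combos[c]] for c in range(n_cat)]
    )  # global trial index of each marker, (3, n_comb)

    # scores[c, t, k]: R between trial t and combination k's category-c marker
    scores = np.stack([sc.R[:, marker_rows[c]] for c in range(n_cat)])
    pred = scores.argmax(axis=0)  # first max = canonical-order tie-break
    ties = (scores == scores.max(axis=0)).sum(axis=0) > 1

    is_test = np.ones((n_trials, n_comb), dtype=bool)
    comb_cols = np.arange(n_comb)
    for c in range(n_cat):
        is_test[marker_rows[c], comb_cols] = False

    correct = pred == true_cat[:, None]
    rates: dict[str, float] = {}
    for c, t in enumerate(TASK_ORDER):
        cell = is_test & (true_cat == c)[:, None]
        rates[t] = 100.0 * correct[cell].mean()
    return IdentificationResult(
        subject_id=subject_id,
        n_combinations=n_comb,
        n_tests=int(is_test.sum()),
        per_category_correct_rate=rates,
        n_ties=int(ties[is_test].sum()),
        sc=sc,
    )


def chance_rate(n_categories: int) -> float:
    """Random-selection correct rate in percent (33.3% for 3 categories)."""
    if n_categories < 2:
        raise ValueError("need at least 2 categories")
    return 100.0 / n_categories


def test_vs_chance(
    per_subject_rates: Sequence[float], chance: float
) -> tuple[float, float]:
    """One-sample t test of per-subject rates against the chance level.

    Pairing each subject's rate with the constant chance level degenerates
    to a one-sample t on the differences; the alternative is one-sided
    (rate > chance) since the claim is directional.
    """
    rates = np.asarray(per_subject_rates, dtype=float)
    if rates.size < 2:
        raise ValueError("need at least 2 subjects")
    if rates.std(ddof=1) == 0:
        raise ValueError("zero variance across subjects: t test undefined")
    res = stats.ttest_1samp(rates, popmean=chance, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def associate_R_with_CR(
    mean_within_R: Sequence[float], correct_rate: Sequence[float]
) -> AssociationResult:
    """Pearson association between mean within-category R and correct rate.

    One point per subject per category (27 points for 9 subjects x 3
    tasks); two-sided p value.
    """
    x = np.asarray(mean_within_R, dtype=float)
    y = np.asarray(correct_rate, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired 1D inputs required")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return AssociationResult(pearson_r=float(r), p_value=float(p),
                             n_points=int(x.size))
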