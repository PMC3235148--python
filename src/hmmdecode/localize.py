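"""Attributing classification power to recording sites and parameter sets.

Three complementary analyses:

* **Leave-one-array-out** — drop the selected couple of contacts of each
  electrode array in turn, retrain the whole pipeline on the reduced
  montage, and test whether the cross-validated ROC area drops
  significantly relative to the all-contacts baseline.
* **Contact replacement** — within one target array, substitute a single
  selected contact by another contact of the same array (keeping the total
  contact count), retrain, and test the area change.
* **Parameter swap** — exchange one named parameter set (priors, means,
  covariances or transitions) between the two trained session models, over
  all state matchings, and measure the accuracy drop; the set whose swap
  destroys the accuracy is the one carrying the discriminative information.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .classify import (
    CvReport,
    HmmPairClassifier,
    compare_area_distributions,
    cross_validate_pair,
    fixed_prior_accuracy,
    roc_area,
    select_q_pair,
)
from .io import ChannelLayout, EpochSet, select_contacts

__all__ = [
    "ArrayDropResult",
    "LocalizationReport",
    "leave_one_array_out",
    "replace_contact",
    "SwapReport",
    "swap_parameters",
    "PARAMETER_SETS",
]

PARAMETER_SETS = ("priors", "means", "covariances", "transitions")


# ---------------------------------------------------------------------------
# leave-one-array-out
# ---------------------------------------------------------------------------

@dataclass
class ArrayDropResult:
    array_id: str
    report: CvReport | None
    p_value: float
    significant: bool
    failed: bool = False


@dataclass
class LocalizationReport:
    baseline: CvReport
    drops: list[ArrayDropResult]
    alpha: float

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "array_id": d.array_id,
                "mean_area": d.report.mean_area if d.report else np.nan,
                "sd_area": d.report.sd_area if d.report else np.nan,
                "p_value": d.p_value,
                "significant": d.significant,
                "failed": d.failed,
            }
            for d in self.drops
        ]
        df = pd.DataFrame(rows)
        df.attrs["baseline_mean_area"] = self.baseline.mean_area
        return df


def _cv_on_contacts(
    es: EpochSet,
    contact_ids: list[str],
    *,
    q1: int,
    q2: int,
    q_grid,
    n_splits: int,
    seed: int | None,
    test_size: float,
    **fit_kwargs,
) -> CvReport:
    sub = es.restrict(contact_ids)
    X = sub.data_list()
    y = sub.days()
    if q_grid is not None:
        reports, best = select_q_pair(
            X, y, q_grid, n_splits=n_splits, seed=seed, test_size=test_size,
            **fit_kwargs,
        )
        return reports[best]
    return cross_validate_pair(
        X, y, q1, q2, n_splits=n_splits, seed=seed, test_size=test_size,
        **fit_kwargs,
    )


def leave_one_array_out(
    es: EpochSet,
    layout: ChannelLayout,
    *,
    q1: int = 3,
    q2: int = 4,
    q_grid=None,
    n_splits: int = 10,
    test_size: float = 0.1,
    seed: int | None = 0,
    alpha: float = 0.01,
    baseline: CvReport | None = None,
    **fit_kwargs,
) -> LocalizationReport:
    """Drop each electrode array's selected contact couple in turn and
    retrain.

    ``es`` must carry the full montage (its columns matching
    ``layout.contact_ids``); the selection is taken from the layout (the
    most-distant couple per array is selected if nothing is marked yet).
    When ``q_grid`` is given, the state counts are re-selected for every
    reduced montage (the default ``None`` reuses ``q1``/``q2``).  Each
    dropped-array area distribution is compared with the all-contacts
    baseline by a Welch t-test at ``alpha``; a significant entry means the
    area *dropped* (one-sided interpretation of the mean ordering plus the
    two-sided p).
    """
    if layout.n_arrays < 2:
        raise ValueError("leave-one-array-out requires at least two arrays")
    if not layout.selected_ids:
        layout = select_contacts(layout)
    selected = layout.selected_ids
    common = dict(n_splits=n_splits, seed=seed, test_size=test_size, **fit_kwargs)
    if baseline is None:
        baseline = _cv_on_contacts(
            es, selected, q1=q1, q2=q2, q_grid=q_grid, **common
        )
    drops: list[ArrayDropResult] = []
    for arr in layout.array_ids:
        arr_contacts = set(layout.contacts_of(arr))
        kept = [c for c in selected if c not in arr_contacts]
        try:
            rep = _cv_on_contacts(es, kept, q1=q1, q2=q2, q_grid=q_grid, **common)
        except Exception as exc:  # noqa: BLE001 - flagged, run continues
            warnings.warn(f"array {arr!r} pipeline failed: {exc}", stacklevel=2)
            drops.append(
                ArrayDropResult(arr, None, np.nan, significant=False, failed=True)
            )
            continue
        _, p = compare_area_distributions(baseline.areas, rep.areas)
        sig = bool(p < alpha and rep.mean_area < baseline.mean_area)
        drops.append(ArrayDropResult(arr, rep, float(p), sig))
    return LocalizationReport(baseline=baseline, drops=drops, alpha=alpha)


def replace_contact(
    es: EpochSet,
    layout: ChannelLayout,
    target_array: str,
    contact_out: str,
    contact_in: str,
    *,
    q1: int = 3,
    q2: int = 4,
    q_grid=None,
    n_splits: int = 10,
    test_size: float = 0.1,
    seed: int | None = 0,
    alpha: float = 0.05,
    baseline: CvReport | None = None,
    **fit_kwargs,
) -> tuple[CvReport, float]:
    """Swap one selected contact of the target array for another contact of
    the *same* array (total contact count unchanged), retrain, and compare
    the area distribution with the baseline (Welch t, default alpha 0.05).
    """
    if not layout.selected_ids:
        layout = select_contacts(layout)
    arr_contacts = layout.contacts_of(target_array)
    if contact_out not in arr_contacts or contact_in not in arr_contacts:
        raise ValueError(
            f"replacement must stay on array {target_array!r}: "
            f"{contact_out!r} -> {contact_in!r}"
        )
    selected = layout.selected_ids
    if contact_out not in selected:
        raise ValueError(f"{contact_out!r} is not among the selected contacts")
    if contact_in in selected and contact_in != contact_out:
        raise ValueError(f"{contact_in!r} is already selected")
    new_sel = [contact_in if c == contact_out else c for c in selected]
    assert len(new_sel) == len(selected)
    common = dict(n_splits=n_splits, seed=seed, test_size=test_size, **fit_kwargs)
    if baseline is None:
        baseline = _cv_on_contacts(es, selected, q1=q1, q2=q2, q_grid=q_grid, **common)
    rep = _cv_on_contacts(es, new_sel, q1=q1, q2=q2, q_grid=q_grid, **common)
    if new_sel == selected:
        return rep, 1.0
    _, p = compare_area_distributions(baseline.areas, rep.areas)
    return rep, float(p)


# ---------------------------------------------------------------------------
# parameter swapping
# ---------------------------------------------------------------------------

@dataclass
class SwapReport:
    """Accuracy/area of every swap configuration of one parameter set."""

    parameter_set: str
    matchings: list[tuple[int, ...]]
    areas: list[float]
    accuracies: list[float]
    baseline_area: float
    baseline_accuracy: float
    p_accuracy: float = np.nan

    @property
    def mean_accuracy_drop(self) -> float:
        return self.baseline_accuracy - float(np.mean(self.accuracies))

    @property
    def mean_area_drop(self) -> float:
        return self.baseline_area - float(np.mean(self.areas))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "matching": [",".join(map(str, m)) for m in self.matchings],
                "area": self.areas,
                "accuracy": self.accuracies,
            }
        )


def _swapped_pair(
    clf: HmmPairClassifier, which: str, matching: tuple[int, ...]
) -> HmmPairClassifier:
    """Clone the classifier with the named parameter set exchanged between
    its two models under the given state matching.

    ``matching[i] = j`` pairs state ``i`` of the smaller-Q model with state
    ``j`` of the larger-Q model.  With equal Q and a full permutation this
    exchanges the whole parameter set (so swapping *all* sets is exactly a
    model exchange); with unequal Q the matched entries are exchanged and
    stochastic vectors/rows renormalized.
    """
    import copy

    m1, m2 = clf.models_
    q1, q2 = m1.means_.shape[0], m2.means_.shape[0]
    swap_1_into_2 = q1 <= q2
    small, large = (m1, m2) if swap_1_into_2 else (m2, m1)
    ns, nl = (q1, q2) if swap_1_into_2 else (q2, q1)
    s_new = copy.deepcopy(small)
    l_new = copy.deepcopy(large)
    idx_s = np.arange(ns)
    idx_l = np.asarray(matching, dtype=int)
    if which == "means":
        s_new.means_[idx_s], l_new.means_[idx_l] = (
            large.means_[idx_l].copy(),
            small.means_[idx_s].copy(),
        )
    elif which == "covariances":
        s_new.covars_[idx_s], l_new.covars_[idx_l] = (
            large.covars_[idx_l].copy(),
            small.covars_[idx_s].copy(),
        )
    elif which == "priors":
        s_pi, l_pi = s_new.startprob_.copy(), l_new.startprob_.copy()
        s_pi[idx_s], l_pi[idx_l] = large.startprob_[idx_l], small.startprob_[idx_s]
        s_new.startprob_ = s_pi / s_pi.sum()
        l_new.startprob_ = l_pi / l_pi.sum()
    elif which == "transitions":
        sA, lA = s_new.transmat_.copy(), l_new.transmat_.copy()
        sA[np.ix_(idx_s, idx_s)] = large.transmat_[np.ix_(idx_l, idx_l)]
        lA[np.ix_(idx_l, idx_l)] = small.transmat_[np.ix_(idx_s, idx_s)]
        s_new.transmat_ = sA / sA.sum(axis=1, keepdims=True)
        l_new.transmat_ = lA / lA.sum(axis=1, keepdims=True)
    else:
        raise ValueError(
            f"unknown parameter set {which!r}; expected one of {PARAMETER_SETS}"
        )
    out = copy.copy(clf)
    out.models_ = [s_new, l_new] if swap_1_into_2 else [l_new, s_new]
    return out


def swap_parameters(
    clf: HmmPairClassifier,
    which: str | tuple[str, ...],
    X,
    y,
    *,
    max_matchings: int = 5040,
    seed: int | None = 0,
) -> SwapReport:
    """Exchange a parameter set between the two session models and measure
    the damage on held-out trials.

    All injective matchings of the smaller model's states into the larger's
    are enumerated (all permutations for equal Q), capped at
    ``max_matchings`` by uniform seeded subsampling.  Each swapped pair is
    scored by fixed-prior accuracy and ROC area; the report compares them
    with the unmodified pair and carries a one-sample t-test of the swap
    accuracies against the baseline accuracy.
    """
    y = np.asarray(y)
    X = list(X)
    which_sets = (which,) if isinstance(which, str) else tuple(which)
    for w in which_sets:
        if w not in PARAMETER_SETS:
            raise ValueError(
                f"unknown parameter set {w!r}; expected one of {PARAMETER_SETS}"
            )
    q1, q2 = (m.means_.shape[0] for m in clf.models_)
    ns, nl = min(q1, q2), max(q1, q2)
    matchings = list(itertools.permutations(range(nl), ns))
    if len(matchings) > max_matchings:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(matchings), size=max_matchings, replace=False)
        matchings = [matchings[i] for i in sorted(keep)]

    base_scores = clf.decision_function(X)
    baseline_area = roc_area(base_scores, y, pos_label=clf.classes_[1]).area
    baseline_acc = fixed_prior_accuracy(clf, X, y)

    areas, accs = [], []
    for m in matchings:
        mod = clf
        for w in which_sets:
            mod = _swapped_pair(mod, w, m)
        s = mod.decision_function(X)
        areas.append(roc_area(s, y, pos_label=mod.classes_[1]).area)
        accs.append(fixed_prior_accuracy(mod, X, y))

    accs_arr = np.asarray(accs)
    if np.var(accs_arr) == 0:
        p = 1.0 if np.allclose(accs_arr, baseline_acc) else 0.0
    else:
        _, p = stats.ttest_1samp(accs_arr, baseline_acc)
    return SwapReport(
        parameter_set="+".join(which_sets),
        matchings=matchings,
        areas=areas,
        accuracies=accs,
        baseline_area=float(baseline_area),
        baseline_accuracy=float(baseline_acc),
        p_accuracy=float(p),
    )
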