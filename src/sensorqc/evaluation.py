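"""Metrics, cross-validation and the randomised-classifier control.

The TP/TN rates here follow the framework's printed definition: both
are normalised by *predicted* counts,

    TP = #{pred = pos and truth = pos} / #{pred = pos}
    TN = #{pred != pos and truth != pos} / #{pred != pos}
    BA = (TP + TN) / 2,

i.e. they are predictive values rather than sensitivity/specificity.
The conventional truth-normalised variant is available behind
``convention="sensitivity"``.  A useful property of the predicted-count
form: for a classifier independent of the truth both rates converge to
the class prevalences, so BA converges to exactly 50%.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np

from sensorqc.core_io import (
    ADHERENCE,
    DataError,
    LabelSeries,
    StateSeries,
    VIOLATION,
)
from sensorqc.context_classifier import (
    fit_multinomial_nb,
    predict_adherence_series,
    states_to_vectors,
)


class UndefinedRateError(ValueError):
    """A rate's denominator (a predicted-class count) is empty."""


@dataclasses.dataclass(frozen=True)
class MetricsReport:
    """TP/TN rates and balanced accuracy, stored as fractions in [0, 1]."""

    tp_rate: float
    tn_rate: float
    ba: float
    n_pred_pos: int
    n_pred_neg: int

    def __post_init__(self) -> None:
        if not np.isclose(self.ba, (self.tp_rate + self.tn_rate) / 2.0):
            raise DataError("BA must equal (TP + TN) / 2")

    def as_percent(self) -> dict:
        return {"BA": round(100.0 * self.ba),
                "TP": round(100.0 * self.tp_rate),
                "TN": round(100.0 * self.tn_rate)}


def _seq(x) -> np.ndarray:
    if isinstance(x, LabelSeries):
        return x.u
    return np.asarray(x).ravel()


def qc_metrics(pred, truth, positive_label=ADHERENCE,
               convention: str = "predictive") -> MetricsReport:
    """Compute TP, TN and balanced accuracy for one label sequence.

    With ``convention="predictive"`` (default) rates are normalised by
    predicted counts as described in the module docstring; with
    ``"sensitivity"`` they are normalised by truth counts instead.  An
    empty denominator raises :class:`UndefinedRateError`.
    """
    p, t = _seq(pred), _seq(truth)
    if p.size != t.size:
        raise DataError("pred and truth lengths differ")
    pred_pos = p == positive_label
    truth_pos = t == positive_label
    if convention == "predictive":
        denom_pos, denom_neg = pred_pos, ~pred_pos
    elif convention == "sensitivity":
        denom_pos, denom_neg = truth_pos, ~truth_pos
    else:
        raise DataError(f"unknown convention {convention!r}")
    n_pos, n_neg = int(denom_pos.sum()), int(denom_neg.sum())
    if n_pos == 0:
        raise UndefinedRateError(
            "no predicted-positive points: TP rate undefined")
    if n_neg == 0:
        raise UndefinedRateError(
            "no predicted-negative points: TN rate undefined")
    tp = float(np.sum(pred_pos & truth_pos)) / n_pos
    tn = float(np.sum(~pred_pos & ~truth_pos)) / n_neg
    return MetricsReport(tp, tn, (tp + tn) / 2.0,
                         int(pred_pos.sum()), int((~pred_pos).sum()))


def pooled_metrics(pairs: Sequence[tuple], positive_label=ADHERENCE,
                   convention: str = "predictive") -> MetricsReport:
    """Metrics over the pooled time points of several (pred, truth) pairs."""
    p = np.concatenate([_seq(a) for a, _ in pairs])
    t = np.concatenate([_seq(b) for _, b in pairs])
    return qc_metrics(p, t, positive_label, convention)


def make_folds(n_groups: int, k: int, seed: int) -> list:
    """Random partition of group indices into k near-equal folds."""
    if k > n_groups:
        raise DataError(f"k={k} folds but only {n_groups} groups")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_groups)
    return [np.sort(perm[i::k]) for i in range(k)]


def kfold_cv(groups: Sequence[tuple], k: int = 10, seed: int = 0,
             fit_fn: Callable = None, predict_fn: Callable = None,
             positive_label=ADHERENCE, convention: str = "predictive"
             ) -> dict:
    """k-fold cross-validation over test recordings.

    ``groups`` is a sequence of (vectors, labels) pairs, one per
    recording: ``vectors`` a T_i x K count matrix and ``labels`` a
    LabelSeries (or int array).  Folds partition *recordings*, never
    time points, because points within a recording are strongly
    dependent.  Per fold, the model is trained on the pooled points of
    the other k-1 folds and evaluated on the pooled points of the
    held-out fold.

    ``fit_fn(vectors, labels)`` and ``predict_fn(vectors, model)``
    default to the multinomial naive Bayes.
    """
    if fit_fn is None:
        fit_fn = fit_multinomial_nb
    if predict_fn is None:
        predict_fn = predict_adherence_series
    folds = make_folds(len(groups), k, seed)
    reports = []
    for held_out in folds:
        train_idx = [i for i in range(len(groups))
                     if i not in set(held_out.tolist())]
        Vtr = np.vstack([np.asarray(groups[i][0]) for i in train_idx])
        utr = np.concatenate([_seq(groups[i][1]) for i in train_idx])
        model = fit_fn(Vtr, utr)
        Vte = np.vstack([np.asarray(groups[i][0]) for i in held_out])
        ute = np.concatenate([_seq(groups[i][1]) for i in held_out])
        pred = predict_fn(Vte, model)
        reports.append(qc_metrics(pred, ute, positive_label, convention))
    def stat(field):
        vals = np.array([getattr(r, field) for r in reports])
        return float(vals.mean()), float(vals.std(ddof=0))
    return {
        "folds": reports,
        "ba_mean": stat("ba")[0], "ba_sd": stat("ba")[1],
        "tp_mean": stat("tp_rate")[0], "tp_sd": stat("tp_rate")[1],
        "tn_mean": stat("tn_rate")[0], "tn_sd": stat("tn_rate")[1],
    }


def shuffled_indicator_null(z: StateSeries, u: LabelSeries, seed: int = 0,
                            k: int = 10, mode: str = "modal",
                            n_states: int | None = None) -> dict:
    """Randomised-classifier control: permute z, keep u fixed, re-train.

    The state indicators are uniformly permuted while the labels stay in
    place, destroying any true association; the naive Bayes is then
    trained and scored exactly as in the real protocol (k-fold CV over
    contiguous blocks of the permuted sequence).  A classifier scoring
    well here would indicate leakage; the expected balanced accuracy is
    50%.

    The naive Bayes is trained with uniform class priors here.  With
    empirical priors a classifier holding no information collapses to a
    constant majority-class predictor, whose predicted-count rates are
    undefined; uniform priors keep the control on the same 50% chance
    level while leaving both predicted classes populated.
    """
    if len(z) != len(u):
        raise DataError("z and u must align")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(z))
    z_shuf = StateSeries(z.z[perm])
    vectors = states_to_vectors(z_shuf, n_states=n_states, mode="modal")
    # contiguous blocks stand in for recordings in this synthetic control
    edges = np.linspace(0, len(z), k + 1).astype(int)
    groups = [(vectors[a:b], u.u[a:b]) for a, b in zip(edges, edges[1:])]

    def fit_uniform(V, labels):
        return fit_multinomial_nb(V, labels, class_priors=(0.5, 0.5))

    return kfold_cv(groups, k=k, seed=seed, fit_fn=fit_uniform)
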