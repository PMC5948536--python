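"""Mapping unsupervised AR states to meaning.

Two mappings are provided.  For controlled recordings with behavior
tags, each occupied state k is named after the modal behavior among the
points it claims (b_k = mode{b_t : z_t = k}).  For adherence/violation
QC, per-point state-probability rows are rescaled to integer frequency
vectors and a multinomial naive Bayes classifier is trained on them: the
predicted class is

    argmax_c  log P(u = c) + sum_k p_k log pibar_{k,c}

(the multinomial normalisation factorials cancel in the argmax).  A
point whose vector puts mass on a state never seen in training is
classified as a violation -- the test protocol's instructions are
finite, but the space of possible violations is not.
"""

from __future__ import annotations

import dataclasses
from collections import Counter

import numpy as np

from sensorqc.core_io import (
    ADHERENCE,
    VIOLATION,
    BehaviorSeries,
    DataError,
    LabelSeries,
    StateSeries,
)


@dataclasses.dataclass(frozen=True)
class FrequencyVector:
    """Nonnegative integer counts over the K+ states (total = scale)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int).ravel()
        object.__setattr__(self, "counts", c)
        if np.any(c < 0):
            raise DataError("counts must be nonnegative")


@dataclasses.dataclass(frozen=True)
class NbModel:
    """Fitted multinomial naive Bayes over state-frequency vectors.

    attr_log_probs has shape (2, K) -- rows are the adherence and
    violation class simplexes in log space; seen_states holds the
    0-based state columns with any training mass.
    """

    attr_log_probs: np.ndarray
    class_log_priors: np.ndarray
    seen_states: frozenset

    def __post_init__(self) -> None:
        if not np.isclose(np.exp(self.class_log_priors).sum(), 1.0):
            raise DataError("class priors must form a simplex")


BehaviorMap = dict


def map_states_to_behaviors(z: StateSeries, b: BehaviorSeries) -> BehaviorMap:
    """Name each occupied state by its modal behavior tag.

    Ties are broken lexicographically so the mapping is deterministic.
    """
    if len(z) != len(b):
        raise DataError("state and behavior sequences must align")
    out: BehaviorMap = {}
    for k in np.unique(z.z):
        tags = b.b[z.z == k]
        counts = Counter(tags.tolist())
        top = max(counts.values())
        out[int(k)] = sorted(t for t, c in counts.items() if c == top)[0]
    return out


def probs_to_frequency_vector(row: np.ndarray, scale: int = 100
                              ) -> FrequencyVector:
    """Rescale a probability row to integer counts totalling ``scale``.

    Uses largest-remainder rounding so the total is preserved exactly.
    With scale = 1 this is a one-hot vector at the argmax (the "modal"
    representation).
    """
    row = np.asarray(row, dtype=float).ravel()
    if scale < 1:
        raise DataError("scale must be a positive integer")
    if not np.isclose(row.sum(), 1.0, atol=1e-6):
        raise DataError("probability row must sum to 1")
    raw = row * scale
    base = np.floor(raw).astype(int)
    short = scale - int(base.sum())
    if short > 0:
        remainders = raw - base
        # stable ranking: largest remainder first, earlier index on ties
        order = np.lexsort((np.arange(row.size), -remainders))
        base[order[:short]] += 1
    return FrequencyVector(base)


def states_to_vectors(states: StateSeries, n_states: int | None = None,
                      mode: str = "modal", scale: int = 100) -> np.ndarray:
    """Per-point frequency vectors (T x K int matrix) from a StateSeries.

    ``mode="modal"`` one-hot encodes the modal indicator (scale 1);
    ``mode="posterior"`` applies largest-remainder rescaling of each
    posterior row to ``scale`` counts.
    """
    K = n_states or (int(states.z.max()) if len(states) else 1)
    if mode == "modal":
        out = np.zeros((len(states), K), dtype=int)
        out[np.arange(len(states)), states.z - 1] = 1
        return out
    if mode == "posterior":
        if states.probs is None:
            raise DataError("posterior mode needs state probabilities")
        K = max(K, states.probs.shape[1])
        return np.stack([probs_to_frequency_vector(r, scale).counts
                         for r in states.probs])
    raise DataError(f"unknown vector mode {mode!r}")


def fit_multinomial_nb(vectors: np.ndarray, u, laplace: float = 1.0,
                       class_priors=None) -> NbModel:
    """Train the multinomial naive Bayes on frequency vectors.

    pibar_{k,c} = (laplace + sum of class-c counts on state k) /
    (sum over states of the same).  Priors default to the empirical
    class frequencies; pass ``class_priors`` to override them.
    """
    V = np.asarray(vectors, dtype=float)
    labels = u.u if isinstance(u, LabelSeries) else np.asarray(u, int)
    if V.shape[0] != labels.size:
        raise DataError("vectors and labels must align")
    classes = np.unique(labels)
    if not np.array_equal(classes, np.array([ADHERENCE, VIOLATION])):
        raise DataError("training data must contain both classes")
    K = V.shape[1]
    attr = np.empty((2, K))
    for i, c in enumerate((ADHERENCE, VIOLATION)):
        tot = V[labels == c].sum(axis=0) + laplace
        attr[i] = tot / tot.sum()
    if class_priors is None:
        priors = np.array([(labels == ADHERENCE).mean(),
                           (labels == VIOLATION).mean()])
    else:
        priors = np.asarray(class_priors, dtype=float)
        priors = priors / priors.sum()
    with np.errstate(divide="ignore"):
        log_attr = np.log(attr)
        log_priors = np.log(priors)
    seen = frozenset(np.flatnonzero(V.sum(axis=0) > 0).tolist())
    return NbModel(log_attr, log_priors, seen)


def predict_adherence(vec, model: NbModel) -> int:
    """Classify one frequency vector as adherence (1) or violation (2).

    Positive counts on states unseen during training force a violation
    verdict regardless of the scores; an exact score tie also predicts
    violation (the conservative choice for quality control).
    """
    counts = vec.counts if isinstance(vec, FrequencyVector) else \
        np.asarray(vec, dtype=float).ravel()
    K = model.attr_log_probs.shape[1]
    if counts.size > K:
        if np.any(counts[K:] > 0):
            return VIOLATION
        counts = counts[:K]
    active = np.flatnonzero(counts > 0)
    if any(int(k) not in model.seen_states for k in active):
        return VIOLATION
    scores = model.class_log_priors + model.attr_log_probs @ counts
    if scores[0] > scores[1]:
        return ADHERENCE
    return VIOLATION


def predict_adherence_series(vectors: np.ndarray, model: NbModel
                             ) -> LabelSeries:
    """Vectorised prediction over a T x K count matrix."""
    V = np.asarray(vectors, dtype=float)
    K = model.attr_log_probs.shape[1]
    extra = np.zeros(V.shape[0], dtype=bool)
    if V.shape[1] > K:
        extra = V[:, K:].sum(axis=1) > 0
        V = V[:, :K]
    unseen_cols = np.array([k for k in range(K)
                            if k not in model.seen_states], dtype=int)
    unseen = extra
    if unseen_cols.size:
        unseen = unseen | (V[:, unseen_cols].sum(axis=1) > 0)
    scores = V @ model.attr_log_probs.T + model.class_log_priors
    pred = np.where(scores[:, 0] > scores[:, 1], ADHERENCE, VIOLATION)
    pred[unseen] = VIOLATION
    return LabelSeries(pred)
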