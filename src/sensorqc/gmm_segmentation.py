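"""Unsupervised QC via a two-component Gaussian mixture.

The assumption: feature values recorded while the user adheres to the
test protocol cluster into one Gaussian component and violations into
the other.  For walking and voice tests adherence produces the *larger*
mean (vigorous movement / loud phonation); for balance tests adherence
(standing still) produces the *smaller* mean.  Because the mixture
ignores time order, the raw MAP component indicators can flicker
unrealistically; a running median applied repeatedly until it reaches a
fixed point (a "root signal") removes sub-window flicker.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import median_filter

from sensorqc.core_io import (
    ADHERENCE,
    VIOLATION,
    DataError,
    FeatureSeries,
    LabelSeries,
)

_HIGH_MEAN_CLASS = {"walking": ADHERENCE, "voice": ADHERENCE,
                    "balance": VIOLATION}


@dataclasses.dataclass(frozen=True)
class GmmFit:
    """Fitted univariate two-component mixture.

    ``z`` holds MAP component indicators in {1, 2}; ``loglik_trace`` is
    the per-EM-iteration log-likelihood (non-decreasing).  ``degenerate``
    flags fits where the data could not support two components.
    """

    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    z: np.ndarray
    loglik_trace: np.ndarray
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not np.isclose(self.weights.sum(), 1.0):
            raise DataError("mixture weights must sum to 1")
        if np.any(self.variances <= 0):
            raise DataError("variances must be positive")


def _log_gauss(x: np.ndarray, mean: float, var: float) -> np.ndarray:
    return -0.5 * np.log(2.0 * np.pi * var) - (x - mean) ** 2 / (2.0 * var)


def fit_gmm2(fs: FeatureSeries, seed: int = 0, tol: float = 1e-8,
             max_iter: int = 500, var_floor: float = 1e-6,
             n_restarts: int = 1) -> GmmFit:
    """Fit a K=2 univariate Gaussian mixture by expectation-maximisation.

    Initialisation is deterministic (components at the 25th and 75th
    percentiles, equal weights, pooled variance); ``seed`` only controls
    optional random restarts beyond the first.  Points are assigned to
    components by the MAP rule after convergence.
    """
    x = fs.values
    if x.size < 10:
        raise DataError("need at least 10 points to fit the mixture")
    if np.ptp(x) == 0.0:
        if var_floor <= 0:
            raise DataError("constant input and no variance floor")
        z = np.ones(x.size, dtype=int)
        means = np.array([x[0], x[0]])
        variances = np.array([var_floor, var_floor])
        return GmmFit(means, variances, np.array([1.0, 0.0]), z,
                      np.array([np.sum(_log_gauss(x, x[0], var_floor))]),
                      degenerate=True)

    rng = np.random.default_rng(seed)
    best = None
    for restart in range(max(1, n_restarts)):
        if restart == 0:
            mu = np.percentile(x, [75.0, 25.0]).astype(float)
        else:
            mu = rng.choice(x, size=2, replace=False).astype(float)
        var = np.full(2, max(np.var(x), var_floor))
        w = np.array([0.5, 0.5])
        trace = []
        for _ in range(max_iter):
            logp = np.stack([np.log(w[k]) + _log_gauss(x, mu[k], var[k])
                             for k in range(2)])
            norm = np.logaddexp(logp[0], logp[1])
            trace.append(float(norm.sum()))
            resp = np.exp(logp - norm)
            nk = resp.sum(axis=1)
            nk = np.maximum(nk, 1e-300)
            w = nk / x.size
            mu = resp @ x / nk
            var = np.maximum(
                np.array([resp[k] @ (x - mu[k]) ** 2 / nk[k]
                          for k in range(2)]), var_floor)
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol * abs(trace[-1]):
                break
        if best is None or trace[-1] > best[-1][-1]:
            best = (mu, var, w, np.array(trace))
    mu, var, w, trace = best
    logp = np.stack([np.log(np.maximum(w[k], 1e-300))
                     + _log_gauss(x, mu[k], var[k]) for k in range(2)])
    z = np.argmax(logp, axis=0) + 1
    return GmmFit(mu, var, w, z, trace)


def assign_protocol_classes(fit: GmmFit, test_type: str) -> LabelSeries:
    """Map mixture components to adherence/violation by their means.

    Walking and voice: the higher-mean component is adherence (u=1).
    Balance: the higher-mean component is violation (u=2).  An exact
    mean tie treats component 1 as the higher-mean component.
    """
    if test_type not in _HIGH_MEAN_CLASS:
        raise DataError(f"unknown test_type {test_type!r}")
    high_class = _HIGH_MEAN_CLASS[test_type]
    low_class = VIOLATION if high_class == ADHERENCE else ADHERENCE
    # tie -> component 1 counted as the higher mean
    high_comp = 1 if fit.means[0] >= fit.means[1] else 2
    u = np.where(fit.z == high_comp, high_class, low_class)
    meta = {"tie": bool(fit.means[0] == fit.means[1]),
            "degenerate": fit.degenerate}
    return LabelSeries(u, meta=meta)


def running_median_pass(u: np.ndarray, window: int) -> np.ndarray:
    """One edge-replicated running-median pass over an integer sequence."""
    return median_filter(u, size=window, mode="nearest")


def repeated_running_median(labels: LabelSeries, window: int) -> LabelSeries:
    """Apply a running median repeatedly until a fixed point (root signal).

    The window must be odd so the median of {1,2} values is always 1 or
    2.  Edges are handled by replication.  The iteration terminates in at
    most T passes; a guard asserts this.
    """
    if window % 2 == 0 or window < 3:
        raise DataError("window must be odd and >= 3")
    u = labels.u.copy()
    for _ in range(max(1, u.size)):
        nxt = running_median_pass(u, window)
        if np.array_equal(nxt, u):
            return LabelSeries(u, meta=dict(labels.meta))
        u = nxt
    raise AssertionError("running median failed to reach a fixed point "
                         "within T passes")


def default_window(rate: float, window_s: float = 0.5) -> int:
    """Smoothing window: ~0.5 s of samples, rounded up to an odd count."""
    w = max(3, int(np.ceil(rate * window_s)))
    return w if w % 2 == 1 else w + 1


def gmm_qc(fs: FeatureSeries, test_type: str, window: int | None = None,
           seed: int = 0) -> LabelSeries:
    """Full unsupervised GMM route: fit, class mapping, median smoothing."""
    fit = fit_gmm2(fs, seed=seed)
    labels = assign_protocol_classes(fit, test_type)
    if window is None:
        window = default_window(fs.rate)
    return repeated_running_median(labels, window)
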