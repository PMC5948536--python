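"""Bayesian-nonparametric switching autoregressive segmentation.

Each hidden state k carries an order-r autoregressive model

    x_t = sum_{j=1..r} A_j^{(k)} x_{t-j} + e_t,   e_t ~ N(mu_k, sigma_k^2)

and a Markov chain z_1..z_T selects which state generates each point.
Rather than fixing the number of states, the transition matrix carries a
hierarchical Dirichlet process prior (an infinite HMM): a global weight
vector beta ~ stick-breaking(gamma) is shared across rows, and row j is
Dirichlet(alpha * beta [+ kappa * e_j]) distributed.  gamma (global
concentration) governs how readily new effective states arise; alpha
(local concentration) governs how sparse the transition matrix is.  The
number of *effective* states K+ (states with at least one assigned
point) is inferred from the data.

Inference is a truncated blocked Gibbs sampler: the infinite state set
is truncated at L, the full state sequence is drawn jointly by forward
filtering / backward sampling, and AR parameters, transition rows and
global weights are drawn from their (conditionally) conjugate
posteriors.  With r = 0 and a free noise mean the model reduces exactly
to a Gaussian-emission HMM.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from sensorqc.core_io import DataError, FeatureSeries, StateSeries


@dataclasses.dataclass(frozen=True)
class ARState:
    """One autoregressive regime: coefficients, noise variance and mean."""

    coeffs: np.ndarray
    noise_var: float
    noise_mean: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "coeffs",
                           np.asarray(self.coeffs, dtype=float).ravel())
        if not self.noise_var > 0:
            raise DataError("noise_var must be positive")

    @property
    def order(self) -> int:
        return self.coeffs.size


@dataclasses.dataclass
class HdpArModel:
    """Truncated HDP switching-AR model parameters.

    trans is L x L row-stochastic; beta is the global L-simplex used both
    as the shared Dirichlet base measure of the rows and as the initial
    state distribution.  kappa > 0 adds a sticky self-transition bias.
    """

    L: int
    states: list
    trans: np.ndarray
    beta: np.ndarray
    alpha: float = 1.0
    gamma: float = 1.0
    kappa: float = 0.0
    order: int = 4

    def __post_init__(self) -> None:
        self.trans = np.asarray(self.trans, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        if len(self.states) != self.L:
            raise DataError("need one ARState per truncated state")
        if self.trans.shape != (self.L, self.L):
            raise DataError("trans must be L x L")
        if not np.allclose(self.trans.sum(axis=1), 1.0, atol=1e-9):
            raise DataError("trans rows must sum to 1")
        if not np.isclose(self.beta.sum(), 1.0, atol=1e-9):
            raise DataError("beta must sum to 1")
        if self.alpha <= 0 or self.gamma <= 0 or self.kappa < 0:
            raise DataError("need alpha > 0, gamma > 0, kappa >= 0")


@dataclasses.dataclass(frozen=True)
class ArPrior:
    """Conditionally conjugate prior for one AR state.

    Coefficients (and the optional free mean) are zero-mean Gaussian with
    variance coef_scale^2 per entry; the noise variance is
    inverse-gamma(sigma_a, sigma_b).
    """

    coef_scale: float = 1.0
    sigma_a: float = 1.0
    sigma_b: float = 1.0
    sample_mean: bool = False


@dataclasses.dataclass(frozen=True)
class GibbsConfig:
    """Sampler settings.

    ``init`` chooses the starting state assignment: ``single_state``
    (everything in state 1), ``random`` (uniform over the truncation),
    or ``quantile`` (``init_states`` groups by feature-value quantile --
    a small fixed number of level-separated starting states, which mixes
    far better when regimes differ mainly in level).
    """

    n_iter: int = 500
    burn_in: int = 250
    seed: int = 0
    init: str = "single_state"
    init_states: int = 6
    hyper_resample: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.burn_in < self.n_iter):
            raise DataError("need 0 < burn_in < n_iter")
        if self.init not in ("single_state", "random", "quantile"):
            raise DataError(f"unknown init {self.init!r}")


@dataclasses.dataclass
class FitResult:
    """Post-burn-in draws of the state sequence.

    z_samples has one row per retained Gibbs sweep; k_effective holds the
    number of occupied states K+ in each sweep; z_mode summarises the
    per-time-point posterior over states by relative frequency.
    """

    z_samples: np.ndarray
    z_mode: StateSeries
    k_effective: np.ndarray
    model: HdpArModel
    boundaries: tuple = ()


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _values(x) -> np.ndarray:
    return x.values if isinstance(x, FeatureSeries) else np.asarray(x, float)


def ar_loglik(x, t: int, state: ARState) -> float:
    """Gaussian log density of x_t given its r lagged values."""
    xv = _values(x)
    r = state.order
    if t < r:
        raise DataError(f"t={t} has fewer than r={r} lagged values")
    lags = xv[t - r:t][::-1] if r else np.empty(0)
    mean = float(lags @ state.coeffs) + state.noise_mean
    v = state.noise_var
    return float(-0.5 * np.log(2.0 * np.pi * v)
                 - (xv[t] - mean) ** 2 / (2.0 * v))


def _lag_matrix(xv: np.ndarray, r: int) -> np.ndarray:
    """T x r matrix with row t = (x_{t-1}, ..., x_{t-r}); zeros where t < r."""
    T = xv.size
    X = np.zeros((T, r))
    for j in range(1, r + 1):
        X[j:, j - 1] = xv[:-j] if j else xv
    return X


def _loglik_matrix(xv: np.ndarray, model: HdpArModel,
                   valid: np.ndarray) -> np.ndarray:
    """T x L log-likelihood table; zero where the point is conditioned on."""
    r = model.order
    T = xv.size
    A = np.stack([s.coeffs for s in model.states])          # L x r
    mu = np.array([s.noise_mean for s in model.states])
    var = np.array([s.noise_var for s in model.states])
    X = _lag_matrix(xv, r) if r else np.zeros((T, 0))
    pred = X @ A.T + mu                                      # T x L
    ll = (-0.5 * np.log(2.0 * np.pi * var)
          - (xv[:, None] - pred) ** 2 / (2.0 * var))
    ll[~valid] = 0.0
    return ll


def _segment_valid(T: int, r: int, boundaries: Sequence[int]) -> np.ndarray:
    """Mask of points with a full set of in-segment lags.

    The first r points of every segment are conditioned on as fixed
    history and contribute no likelihood.
    """
    valid = np.ones(T, dtype=bool)
    for start in boundaries:
        valid[start:start + r] = False
    return valid


def _norm_boundaries(T: int, boundaries) -> tuple:
    bs = tuple(sorted(set([0] + list(boundaries or []))))
    if any(b < 0 or b >= T for b in bs):
        raise DataError("segment boundaries out of range")
    return bs


# ---------------------------------------------------------------------------
# Blocked state sampling (forward filter, backward sample)
# ---------------------------------------------------------------------------

def _forward_pass(lik: np.ndarray, model: HdpArModel,
                  starts: set) -> tuple[np.ndarray, float]:
    """Scaled forward recursion; returns filtered alphas and log marginal."""
    T, L = lik.shape
    alpha = np.empty((T, L))
    piT = model.trans
    logZ = 0.0
    prev = None
    for t in range(T):
        a = model.beta * lik[t] if t in starts else (prev @ piT) * lik[t]
        s = a.sum()
        if not s > 0 or not np.isfinite(s):
            raise FloatingPointError(
                f"forward pass underflow at t={t}")
        logZ += np.log(s)
        prev = alpha[t] = a / s
    return alpha, logZ


def forward_loglik(x, model: HdpArModel, boundaries=None) -> float:
    """Marginal log-likelihood log p(x | model) with states summed out.

    The likelihoods are scaled per step, so the result is exact up to
    floating point; the first r points of each segment are conditioned
    on and contribute no factor.
    """
    xv = _values(x)
    bs = _norm_boundaries(xv.size, boundaries)
    valid = _segment_valid(xv.size, model.order, bs)
    lik = np.exp(_loglik_matrix(xv, model, valid))
    # conditioned points have lik row == 1 (log 0), which is exactly the
    # "no likelihood contribution" convention
    _, logZ = _forward_pass(lik, model, set(bs))
    return logZ


def block_sample_states(x, model: HdpArModel, rng,
                        boundaries=None, compute_probs: bool = True
                        ) -> StateSeries:
    """Draw z_1..z_T jointly by forward filtering / backward sampling.

    Returns a StateSeries whose ``probs`` (when requested) are the
    forward-backward smoothed per-point state probabilities under the
    current model parameters.  The chain restarts from the global
    weights at every segment boundary.
    """
    xv = _values(x)
    T = xv.size
    if T <= model.order:
        raise DataError("series shorter than the AR order")
    bs = _norm_boundaries(T, boundaries)
    starts = set(bs)
    valid = _segment_valid(T, model.order, bs)
    ll = _loglik_matrix(xv, model, valid)
    ll -= ll.max(axis=1, keepdims=True)
    lik = np.exp(ll)
    alpha, _ = _forward_pass(lik, model, starts)

    L = model.L
    z = np.empty(T, dtype=np.int32)
    u = rng.random(T)
    ends = [b - 1 for b in bs[1:]] + [T - 1]
    end_set = set(ends)
    for t in range(T - 1, -1, -1):
        if t in end_set:
            p = alpha[t]
        else:
            p = alpha[t] * model.trans[:, z[t + 1] - 1]
        c = np.cumsum(p)
        z[t] = int(np.searchsorted(c, u[t] * c[-1])) + 1

    probs = None
    if compute_probs:
        back = np.empty((T, L))
        for t in range(T - 1, -1, -1):
            if t in end_set:
                back[t] = 1.0
            else:
                b = model.trans @ (lik[t + 1] * back[t + 1])
                back[t] = b / b.max()
        gam = alpha * back
        gam /= gam.sum(axis=1, keepdims=True)
        return StateSeries(z, probs=_one_consistent(gam, z))
    return StateSeries(z)


def _one_consistent(probs: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Nudge smoothed rows so their argmax matches the sampled indicator.

    StateSeries requires argmax(probs) == z when both are present; the
    sampled draw can disagree with the smoothed mode at genuinely
    ambiguous points, so the sampled state's probability is raised to the
    row maximum there and the row renormalised.
    """
    out = probs.copy()
    rows = np.flatnonzero(out.argmax(axis=1) + 1 != z)
    for t in rows:
        k = z[t] - 1
        out[t, k] = out[t].max() + 1e-12
        out[t] /= out[t].sum()
    return out


# ---------------------------------------------------------------------------
# Parameter conditionals
# ---------------------------------------------------------------------------

def coef_posterior(X: np.ndarray, y: np.ndarray, sigma2: float,
                   prior: ArPrior) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian posterior (mean, covariance) of the coefficient vector.

    Conditional on the noise variance this is the ridge-style formula
    mean = (X'X + sigma2/s^2 I)^-1 X'y with s = prior.coef_scale.
    """
    p = X.shape[1]
    prec = X.T @ X / sigma2 + np.eye(p) / prior.coef_scale ** 2
    cov = np.linalg.inv(prec)
    mean = cov @ (X.T @ y) / sigma2
    return mean, cov


def sample_ar_params(x, z: np.ndarray, prior: ArPrior, rng,
                     L: int, r: int, boundaries=None,
                     states: Optional[list] = None) -> list:
    """Draw each state's AR parameters from its conditional posterior.

    States with no assigned points draw from the prior.  The update is a
    two-stage conditionally conjugate draw: coefficients given the noise
    variance (Gaussian), then the noise variance given the coefficients
    (inverse-gamma).
    """
    xv = _values(x)
    T = xv.size
    bs = _norm_boundaries(T, boundaries)
    valid = _segment_valid(T, r, bs)
    z = np.asarray(z, dtype=int)
    Xfull = _lag_matrix(xv, r)
    if prior.sample_mean:
        Xfull = np.hstack([Xfull, np.ones((T, 1))])
    p = Xfull.shape[1]
    new_states = []
    for k in range(1, L + 1):
        idx = np.flatnonzero((z == k) & valid)
        cur_var = states[k - 1].noise_var if states else 1.0
        if idx.size == 0:
            coef = rng.normal(0.0, prior.coef_scale, size=p)
            var = 1.0 / rng.gamma(prior.sigma_a, 1.0 / prior.sigma_b)
        else:
            X, y = Xfull[idx], xv[idx]
            mean, cov = coef_posterior(X, y, cur_var, prior)
            coef = rng.multivariate_normal(mean, cov) if p else np.empty(0)
            resid = y - X @ coef
            a_post = prior.sigma_a + idx.size / 2.0
            b_post = prior.sigma_b + 0.5 * float(resid @ resid)
            var = 1.0 / rng.gamma(a_post, 1.0 / b_post)
        if prior.sample_mean:
            new_states.append(ARState(coef[:r], var, noise_mean=coef[r]))
        else:
            new_states.append(ARState(coef[:r], var))
    return new_states


def transition_counts(z: np.ndarray, L: int, boundaries=None) -> np.ndarray:
    """L x L counts of consecutive transitions, excluding segment breaks."""
    z = np.asarray(z, dtype=int)
    bs = _norm_boundaries(z.size, boundaries)
    n = np.zeros((L, L))
    if z.size < 2:
        return n
    keep = np.ones(z.size - 1, dtype=bool)
    for b in bs:
        if b > 0:
            keep[b - 1] = False
    np.add.at(n, (z[:-1][keep] - 1, z[1:][keep] - 1), 1.0)
    return n


def sample_transitions(z: np.ndarray, beta: np.ndarray, alpha: float,
                       kappa: float, rng, boundaries=None,
                       counts: Optional[np.ndarray] = None) -> np.ndarray:
    """Draw transition rows: pi_j ~ Dirichlet(alpha*beta + kappa*e_j + n_j)."""
    L = beta.size
    if counts is None:
        counts = transition_counts(z, L, boundaries)
    conc = alpha * beta[None, :] + kappa * np.eye(L) + counts
    draws = rng.gamma(np.maximum(conc, 1e-12))
    draws = np.maximum(draws, 1e-300)
    return draws / draws.sum(axis=1, keepdims=True)


def _table_counts(counts: np.ndarray, beta: np.ndarray, alpha: float,
                  kappa: float, rng) -> np.ndarray:
    """Chinese-restaurant-franchise auxiliary table counts m_jk (L x L)."""
    L = beta.size
    m = np.zeros((L, L))
    for j in range(L):
        for k in range(L):
            n = int(counts[j, k])
            if n == 0:
                continue
            c = alpha * beta[k] + (kappa if j == k else 0.0)
            probs = c / (c + np.arange(n))
            m[j, k] = int(np.sum(rng.random(n) < probs))
    return m


def sample_concentrations(counts: np.ndarray, m: np.ndarray,
                          beta: np.ndarray, alpha: float, gamma: float,
                          rng, a: float = 1.0, b: float = 1.0
                          ) -> tuple[float, float]:
    """Resample alpha and gamma under Gamma(a, b) hyperpriors.

    alpha uses the usual beta/Bernoulli auxiliary-variable scheme per
    transition row (rows with data only); gamma's conditional is exact
    under the truncated stick-breaking construction of beta:
    gamma ~ Gamma(a + L - 1, b - sum_k log(1 - v_k)).
    """
    n_rows = counts.sum(axis=1)
    used = n_rows > 0
    total_tables = float(m.sum())
    if used.any():
        w = rng.beta(alpha + 1.0, n_rows[used])
        s = rng.random(used.sum()) < n_rows[used] / (n_rows[used] + alpha)
        alpha = float(rng.gamma(a + total_tables - s.sum(),
                                1.0 / (b - np.sum(np.log(w)))))
        alpha = max(alpha, 1e-6)
    L = beta.size
    stick_left = 1.0 - np.concatenate([[0.0], np.cumsum(beta[:-1])])
    v = np.clip(beta[:-1] / np.maximum(stick_left[:-1], 1e-300),
                1e-12, 1.0 - 1e-12)
    gamma = float(rng.gamma(a + L - 1.0, 1.0 / (b - np.sum(np.log1p(-v)))))
    return alpha, max(gamma, 1e-6)


def sample_global_weights(counts: np.ndarray, gamma: float, alpha: float,
                          rng, beta: Optional[np.ndarray] = None,
                          kappa: float = 0.0) -> np.ndarray:
    """Draw the global state weights beta via the auxiliary-table scheme.

    Table counts m_k are simulated from the transition counts, then beta
    follows the truncated stick-breaking posterior
    v_k ~ Beta(1 + m_k, gamma + sum_{l>k} m_l), with the last stick
    taking the remainder.  With no counts this is a plain truncated
    stick-breaking draw with parameter gamma (E[beta_1] = 1/(1+gamma)).
    """
    counts = np.asarray(counts, dtype=float)
    L = counts.shape[0]
    if beta is None:
        beta = np.full(L, 1.0 / L)
    m = _table_counts(counts, beta, alpha, kappa, rng).sum(axis=0)
    rest = np.concatenate([np.cumsum(m[::-1])[::-1][1:], [0.0]])
    new_beta = np.empty(L)
    stick = 1.0
    for k in range(L - 1):
        v = rng.beta(1.0 + m[k], gamma + rest[k])
        new_beta[k] = stick * v
        stick *= 1.0 - v
    new_beta[L - 1] = stick
    new_beta = np.maximum(new_beta, 1e-300)
    return new_beta / new_beta.sum()


# ---------------------------------------------------------------------------
# Gibbs driver
# ---------------------------------------------------------------------------

def _init_model(L: int, r: int, alpha: float, gamma: float, kappa: float,
                prior: ArPrior, rng) -> HdpArModel:
    states = [ARState(rng.normal(0.0, 0.1, size=r), 1.0) for _ in range(L)]
    beta = np.full(L, 1.0 / L)
    trans = np.full((L, L), 1.0 / L)
    return HdpArModel(L, states, trans, beta, alpha, gamma, kappa, r)


def fit_switching_ar(fs, cfg: GibbsConfig,
                     model_init: Optional[HdpArModel] = None,
                     prior: ArPrior = ArPrior(), L: int = 20,
                     order: int = 4, alpha: float = 1.0, gamma: float = 1.0,
                     kappa: float = 0.0) -> FitResult:
    """Fit the truncated HDP switching-AR model by blocked Gibbs sampling.

    ``fs`` may be a single FeatureSeries (or array) or a list of them; a
    list is concatenated with segment boundaries so that no AR lag or
    Markov transition crosses a recording boundary, and all recordings
    share one state space.

    Each sweep cycles: global weights -> transition rows -> per-state AR
    parameters -> blocked state sequence.  Post-burn-in state sequences
    are retained; K+ counts the occupied states in each sweep.
    """
    if isinstance(fs, (list, tuple)):
        arrays = [_values(f) for f in fs]
        xv = np.concatenate(arrays)
        boundaries = tuple(np.cumsum([0] + [a.size for a in arrays])[:-1])
    else:
        xv = _values(fs)
        boundaries = (0,)
    T = xv.size
    if T <= 10 * order:
        raise DataError("series too short for the requested AR order")
    rng = np.random.default_rng(cfg.seed)
    model = model_init or _init_model(L, order, alpha, gamma, kappa,
                                      prior, rng)
    L = model.L

    if cfg.init == "single_state":
        z = np.ones(T, dtype=np.int32)
    elif cfg.init == "random":
        z = rng.integers(1, L + 1, size=T).astype(np.int32)
    else:
        nb = min(cfg.init_states, L)
        qs = np.quantile(xv, np.linspace(0.0, 1.0, nb + 1)[1:-1])
        z = (np.searchsorted(qs, xv) + 1).astype(np.int32)

    keep = []
    k_eff = []
    for it in range(cfg.n_iter):
        counts = transition_counts(z, L, boundaries)
        model.beta = sample_global_weights(counts, model.gamma, model.alpha,
                                           rng, beta=model.beta,
                                           kappa=model.kappa)
        if cfg.hyper_resample:
            m = _table_counts(counts, model.beta, model.alpha,
                              model.kappa, rng)
            model.alpha, model.gamma = sample_concentrations(
                counts, m, model.beta, model.alpha, model.gamma, rng)
        model.trans = sample_transitions(z, model.beta, model.alpha,
                                         model.kappa, rng, counts=counts)
        model.states = sample_ar_params(xv, z, prior, rng, L, model.order,
                                        boundaries, states=model.states)
        ss = block_sample_states(xv, model, rng, boundaries,
                                 compute_probs=False)
        z = ss.z.astype(np.int32)
        if it >= cfg.burn_in:
            keep.append(z.copy())
            k_eff.append(int(np.unique(z).size))

    z_samples = np.stack(keep)
    z_mode = _mode_series(z_samples, L)
    return FitResult(z_samples, z_mode, np.asarray(k_eff, dtype=int),
                     model, boundaries)


def _mode_series(z_samples: np.ndarray, L: int) -> StateSeries:
    freq = np.stack([(z_samples == k).mean(axis=0)
                     for k in range(1, L + 1)], axis=1)
    z = freq.argmax(axis=1) + 1
    return StateSeries(z, probs=freq)


def posterior_state_probs(result: FitResult) -> StateSeries:
    """Per-point posterior state frequencies across retained sweeps."""
    return _mode_series(result.z_samples, result.model.L)
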