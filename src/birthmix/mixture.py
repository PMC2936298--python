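"""Stage 1: the k-component normal mixture model of a birthweight
distribution.

The density is ``sum_j w_j f(x; mu_j, sigma_j)`` with ``f`` a normal
density, ``w_j`` the fraction of births in component j, and ``mu_j``,
``sigma_j`` the component mean and standard deviation in grams.
Components are always stored and reported in increasing order of mean so
that "component j" refers to the same subpopulation across repeated fits
— the labeling convention the multi-sample combination step relies on.

Fitting is by EM with a deterministic seeded initialization; the number
of components can be chosen by an information criterion (BIC by default)
or forced by the user.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .records import BIRTHWEIGHT, RecordsLike, as_frame

#: smallest admissible component standard deviation, grams.  Guards EM
#: against degenerate zero-variance spikes on repeated birthweights.
SIGMA_FLOOR = 1.0

#: slack allowed in user-supplied weights before renormalization is
#: refused (printed tables often carry weights summing to e.g. 0.999).
WEIGHT_SUM_SLACK = 0.01

ArrayLike = Union[Sequence[float], np.ndarray]


@dataclass(frozen=True)
class MixtureModel:
    """A k-component normal mixture over birthweight (grams).

    Weights within ``WEIGHT_SUM_SLACK`` of 1 are renormalized on
    construction; components are sorted by mean.
    """

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: Optional[float] = None
    converged: bool = True
    n_iter: int = 0
    loglik_trace: Optional[tuple] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        m = np.asarray(self.means, dtype=float)
        s = np.asarray(self.sds, dtype=float)
        if not (w.shape == m.shape == s.shape) or w.ndim != 1 or w.size < 1:
            raise ValueError("weights, means, sds must be 1-d arrays of equal length >= 1")
        if np.any(w <= 0) or np.any(w > 1):
            raise ValueError("weights must lie in (0, 1]")
        total = w.sum()
        if abs(total - 1.0) > WEIGHT_SUM_SLACK:
            raise ValueError(f"weights sum to {total:.4f}, not within {WEIGHT_SUM_SLACK} of 1")
        w = w / total
        if np.any(s <= 0):
            raise ValueError("component standard deviations must be strictly positive")
        order = np.argsort(m, kind="stable")
        for name, arr in (("weights", w[order]), ("means", m[order]), ("sds", s[order])):
            arr = np.ascontiguousarray(arr)
            arr.flags.writeable = False
            object.__setattr__(self, name, arr)

    @property
    def k(self) -> int:
        return self.weights.size

    def component_log_density(self, x: ArrayLike) -> np.ndarray:
        """log of w_j f(x; mu_j, sigma_j), shape (n, k)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        z = (x[:, None] - self.means[None, :]) / self.sds[None, :]
        return (
            np.log(self.weights)[None, :]
            - np.log(self.sds)[None, :]
            - 0.5 * np.log(2 * np.pi)
            - 0.5 * z**2
        )

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n birthweights; nonpositive draws are rejected and redrawn."""
        comp = rng.choice(self.k, size=n, p=self.weights)
        x = rng.normal(self.means[comp], self.sds[comp])
        bad = x <= 0
        while bad.any():
            x[bad] = rng.normal(self.means[comp[bad]], self.sds[comp[bad]])
            bad = x <= 0
        return x


def mixture_density(x: ArrayLike, model: MixtureModel) -> Union[float, np.ndarray]:
    """Mixture density sum_j w_j f(x; mu_j, sigma_j), per gram."""
    scalar = np.isscalar(x) or np.ndim(x) == 0
    dens = np.exp(logsumexp(model.component_log_density(x), axis=1))
    return float(dens[0]) if scalar else dens


def posterior_weights(x: ArrayLike, model: MixtureModel) -> np.ndarray:
    """Posterior component membership probabilities at birthweight x.

    Entry j is ``w_j f(x;mu_j,sigma_j) / sum_l w_l f(x;mu_l,sigma_l)``,
    computed on the log scale so that far-tail x does not underflow.
    Returns shape (k,) for scalar x, else (n, k).
    """
    scalar = np.isscalar(x) or np.ndim(x) == 0
    xv = np.atleast_1d(np.asarray(x, dtype=float))
    if not np.all(np.isfinite(xv)):
        raise ValueError("birthweight must be finite")
    logd = model.component_log_density(xv)
    tau = np.exp(logd - logsumexp(logd, axis=1, keepdims=True))
    return tau[0] if scalar else tau


def _observed_loglik(x: np.ndarray, model: MixtureModel) -> float:
    return float(logsumexp(model.component_log_density(x), axis=1).sum())


def _kmeans_init(x: np.ndarray, k: int, rng: np.random.Generator) -> MixtureModel:
    """Seeded k-means++ seeding plus Lloyd iterations on (a subsample
    of) the birthweights.  Unlike a quantile-based start, this places a
    center on small well-separated components, which matters for
    birthweight data where a sub-1% low-weight component is typical."""
    sub = x if x.size <= 20_000 else rng.choice(x, 20_000, replace=False)
    centers = np.empty(k)
    centers[0] = sub[rng.integers(sub.size)]
    d2 = (sub - centers[0]) ** 2
    for j in range(1, k):
        p = d2 / d2.sum()
        centers[j] = sub[rng.choice(sub.size, p=p)]
        d2 = np.minimum(d2, (sub - centers[j]) ** 2)
    for _ in range(25):
        assign = np.argmin(np.abs(sub[:, None] - centers[None, :]), axis=1)
        new = np.array(
            [sub[assign == j].mean() if (assign == j).any() else centers[j] for j in range(k)]
        )
        if np.allclose(new, centers):
            break
        centers = new
    assign = np.argmin(np.abs(sub[:, None] - centers[None, :]), axis=1)
    w = np.maximum(np.bincount(assign, minlength=k), 1) / sub.size
    sds = np.array(
        [
            max(sub[assign == j].std(), SIGMA_FLOOR) if (assign == j).sum() > 1 else SIGMA_FLOOR
            for j in range(k)
        ]
    )
    order = np.argsort(centers)
    return MixtureModel(w[order] / w.sum(), centers[order], sds[order])


_HALF_LOG2PI = 0.5 * np.log(2 * np.pi)


def _em_e_step(x: np.ndarray, w, m, s):
    """Responsibilities and observed log-likelihood at (w, m, s)."""
    z = (x[:, None] - m[None, :]) / s[None, :]
    logd = np.log(w)[None, :] - np.log(s)[None, :] - _HALF_LOG2PI - 0.5 * z * z
    amax = logd.max(axis=1, keepdims=True)
    expd = np.exp(logd - amax)
    denom = expd.sum(axis=1, keepdims=True)
    ll = float((amax.ravel() + np.log(denom.ravel())).sum())
    return expd / denom, ll


def _em_m_step(x: np.ndarray, tau: np.ndarray):
    nk = np.maximum(tau.sum(axis=0), 1e-12)
    w = nk / x.size
    m = tau.T @ x / nk
    var = (tau * (x[:, None] - m[None, :]) ** 2).sum(axis=0) / nk
    s = np.maximum(np.sqrt(var), SIGMA_FLOOR)
    return w, m, s


def _em_once(
    x: np.ndarray, init: MixtureModel, tol: float, max_iter: int
) -> MixtureModel:
    """EM with guarded SQUAREM acceleration.

    Plain EM crawls on the near-flat likelihood ridges typical of
    heavily overlapping components; the squared-extrapolation step
    (Varadhan & Roland) jumps along the ridge.  An accelerated proposal
    is accepted only if it does not decrease the observed
    log-likelihood, so the recorded trace stays non-decreasing.
    """
    k = init.k

    def pack(w, m, s):
        return np.concatenate([np.log(w), m, np.log(s)])

    def unpack(t):
        lw = t[:k]
        w = np.exp(lw - logsumexp(lw))
        m = t[k : 2 * k]
        s = np.maximum(np.exp(t[2 * k :]), SIGMA_FLOOR)
        return w, m, s

    def em_map(t):
        tau, ll = _em_e_step(x, *unpack(t))
        return pack(*_em_m_step(x, tau)), ll

    theta = pack(init.weights, init.means, init.sds)
    trace = []
    ll_prev = -np.inf
    converged = False
    n_steps = 0
    while n_steps < max_iter:
        theta1, ll0 = em_map(theta)
        theta2, ll1 = em_map(theta1)
        n_steps += 2
        trace.extend([ll0, ll1])
        r = theta1 - theta
        v = (theta2 - theta1) - r
        vnorm = np.linalg.norm(v)
        if vnorm > 0:
            alpha = max(-np.linalg.norm(r) / vnorm, -64.0)
            accel = theta - 2.0 * alpha * r + alpha * alpha * v
            theta_new, ll_accel = em_map(accel)
            n_steps += 1
            if np.isfinite(ll_accel) and ll_accel >= ll1:
                trace.append(ll_accel)
            else:
                theta_new = theta2
        else:
            theta_new = theta2
        ll_now = trace[-1]
        if ll_now - ll_prev < tol * max(1.0, abs(ll_now)) and ll_prev > -np.inf:
            converged = True
            theta = theta_new
            break
        ll_prev = ll_now
        theta = theta_new
    w, m, s = unpack(theta)
    final_ll = _observed_loglik(x, MixtureModel(w, m, s))
    trace.append(final_ll)
    return MixtureModel(
        w, m, s,
        loglik=final_ll,
        converged=converged,
        n_iter=n_steps,
        loglik_trace=tuple(trace),
    )


def fit_mixture_em(
    records: RecordsLike,
    k: int,
    init: Optional[MixtureModel] = None,
    tol: float = 1e-10,
    max_iter: int = 2000,
    seed: int = 0,
    n_starts: int = 1,
) -> MixtureModel:
    """Fit a k-component normal mixture to birthweights by EM.

    Each start initializes from seeded k-means++/Lloyd clustering of the
    birthweights (cluster proportions, centers and spreads); the best
    final log-likelihood over ``n_starts`` wins.  ``init`` overrides the
    first start.  The observed-data log-likelihood is non-decreasing
    across iterations (available as ``loglik_trace``).
    """
    frame = as_frame(records)
    x = frame[BIRTHWEIGHT].to_numpy(dtype=float)
    n = x.size
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < 10 * k:
        raise ValueError(f"need at least {10 * k} records to fit k={k}, got {n}")
    if np.unique(x).size < k:
        raise ValueError("k exceeds the number of distinct birthweights")
    if k == 1:
        # closed form: sample mean, population-style sd
        m = float(np.mean(x))
        s = max(float(np.std(x)), SIGMA_FLOOR)
        model = MixtureModel(np.array([1.0]), np.array([m]), np.array([s]))
        return MixtureModel(
            model.weights, model.means, model.sds,
            loglik=_observed_loglik(x, model), converged=True, n_iter=0,
        )

    rng = np.random.default_rng(seed)
    best: Optional[MixtureModel] = None
    for start in range(max(1, n_starts)):
        if init is not None and start == 0:
            start_model = init
        else:
            start_model = _kmeans_init(x, k, rng)
        fitted = _em_once(x, start_model, tol, max_iter)
        if best is None or (fitted.loglik or -np.inf) > (best.loglik or -np.inf):
            best = fitted
    assert best is not None
    if not best.converged:
        warnings.warn(
            f"EM did not converge in {max_iter} iterations (k={k})", RuntimeWarning
        )
    return best


_CRITERIA = ("bic", "aic", "icl")


def _criterion_value(
    name: str, loglik: float, k: int, n: int, entropy: float
) -> float:
    npar = 3 * k - 1
    if name == "aic":
        return -2.0 * loglik + 2.0 * npar
    bic = -2.0 * loglik + npar * np.log(n)
    if name == "bic":
        return bic
    if name == "icl":
        return bic + 2.0 * entropy
    raise ValueError(f"unknown criterion {name!r}; choose from {_CRITERIA}")


@dataclass(frozen=True)
class KSelection:
    """Result of component-count selection: chosen k plus the criterion
    value (and any fit failure) for every candidate."""

    k: int
    criterion: str
    table: pd.DataFrame
    models: dict

    def __int__(self) -> int:
        return self.k


def select_k(
    records: RecordsLike,
    k_min: int,
    k_max: int,
    criterion: str = "bic",
    **fit_kwargs,
) -> KSelection:
    """Choose the number of mixture components in [k_min, k_max] by
    minimizing an information criterion (``bic``, ``aic`` or ``icl``).

    All candidate values are reported in ``table``; per-k fit failures
    are recorded there and only raise if every candidate fails.
    """
    if k_min > k_max or k_min < 1:
        raise ValueError("require 1 <= k_min <= k_max")
    if criterion not in _CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}; choose from {_CRITERIA}")
    frame = as_frame(records)
    x = frame[BIRTHWEIGHT].to_numpy(dtype=float)
    n = x.size
    rows = []
    models: dict = {}
    for k in range(k_min, k_max + 1):
        try:
            model = fit_mixture_em(frame, k, **fit_kwargs)
        except ValueError as exc:
            rows.append({"k": k, "loglik": np.nan, "value": np.nan, "error": str(exc)})
            continue
        tau = posterior_weights(x, model)
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = float(-np.nansum(np.where(tau > 0, tau * np.log(tau), 0.0)))
        value = _criterion_value(criterion, model.loglik, k, n, ent)
        models[k] = model
        rows.append({"k": k, "loglik": model.loglik, "value": value, "error": ""})
    table = pd.DataFrame(rows)
    if table["value"].isna().all():
        raise RuntimeError("mixture fitting failed for every candidate k")
    k_best = int(table.loc[table["value"].idxmin(), "k"])
    return KSelection(k=k_best, criterion=criterion, table=table, models=models)
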