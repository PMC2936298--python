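"""Stage 2: component-specific birthweight-mortality curves (PMLR).

Within mixture component j the mortality risk at birthweight x is
``r_j(x) = logit^-1[q_j(z_j)]`` where ``q_j`` is a polynomial (degree 4
by default, allowing up to two changes of convexity) in the
component-standardized birthweight ``z_j = (x - mu_j) / sigma_j``.

The curves are estimated by maximum likelihood conditional on the fitted
mixture: the marginal death probability of a record at birthweight x is,
by the law of total probability, the posterior-weighted average
``R(x) = sum_j tau_j(x) r_j(x)`` with ``tau_j`` the posterior component
membership probabilities, giving a Bernoulli likelihood in the risk
polynomial coefficients.  Components carrying too few expected deaths to
support a five-parameter curve are reported as unestimated rather than
fitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .mixture import MixtureModel, posterior_weights
from .records import BIRTHWEIGHT, DEATH, RecordsLike, as_frame

#: components whose posterior-expected death count falls below this are
#: reported as unestimated (their coefficient row is NaN).
MIN_EXPECTED_DEATHS = 5.0

#: box bound on polynomial coefficients during optimization; generous on
#: the logit scale, prevents runaway drift in data-free tail regions.
COEF_BOUND = 50.0

_PCLIP = 1e-12


@dataclass(frozen=True)
class RiskModel:
    """Per-component degree-``degree`` risk polynomials on the
    component-standardized birthweight scale, tied to the mixture they
    were conditioned on.

    ``coeffs`` has shape (k, degree+1), ascending powers of z; a row of
    NaN marks a component whose curve was not estimated.
    """

    mixture: MixtureModel
    coeffs: np.ndarray
    degree: int = 4
    loglik: Optional[float] = None
    converged: bool = True

    def __post_init__(self) -> None:
        c = np.asarray(self.coeffs, dtype=float)
        if c.ndim != 2 or c.shape != (self.mixture.k, self.degree + 1):
            raise ValueError(
                f"coeffs must have shape (k={self.mixture.k}, degree+1={self.degree + 1})"
            )
        row_ok = np.isfinite(c).all(axis=1)
        row_nan = np.isnan(c).all(axis=1)
        if not np.all(row_ok | row_nan):
            raise ValueError("each coefficient row must be all finite or all NaN")
        c = np.ascontiguousarray(c)
        c.flags.writeable = False
        object.__setattr__(self, "coeffs", c)

    @property
    def k(self) -> int:
        return self.mixture.k

    @property
    def estimable(self) -> np.ndarray:
        """Boolean mask over components whose curve was estimated."""
        return np.isfinite(self.coeffs).all(axis=1)

    def component_logit(self, j: int, x) -> Union[float, np.ndarray]:
        """Risk polynomial q_j(z_j) at birthweight x; j is 1-based."""
        _check_j(j, self.k)
        if not self.estimable[j - 1]:
            raise ValueError(f"component {j} was not estimated")
        z = (np.asarray(x, dtype=float) - self.mixture.means[j - 1]) / self.mixture.sds[j - 1]
        val = np.polynomial.polynomial.polyval(z, self.coeffs[j - 1])
        return float(val) if np.ndim(x) == 0 else val

    def component_risk(self, j: int, x) -> Union[float, np.ndarray]:
        """r_j(x) = logit^-1[q_j(z_j)], strictly inside (0, 1); j is
        1-based.  Logits are clamped so the inverse logit never rounds
        to exactly 0 or 1 in floating point."""
        out = expit(np.clip(self.component_logit(j, x), -700.0, 36.7))
        return float(out) if np.ndim(x) == 0 else out


def _check_j(j: int, k: int) -> None:
    if not 1 <= j <= k:
        raise ValueError(f"component index must satisfy 1 <= j <= {k}, got {j}")


def risk_eval(risk: RiskModel, j: int, x) -> Union[float, np.ndarray]:
    """Birthweight-specific mortality risk in component j (1-based) at x,
    strictly inside (0, 1)."""
    return risk.component_risk(j, x)


def population_risk(risk: RiskModel, x) -> Union[float, np.ndarray]:
    """Model-implied population mortality risk at birthweight x: the
    posterior-weighted average of the component curves (law of total
    probability).  Posterior mass on unestimated components is
    renormalized over the estimated ones."""
    scalar = np.ndim(x) == 0
    xv = np.atleast_1d(np.asarray(x, dtype=float))
    tau = posterior_weights(xv, risk.mixture)
    est = risk.estimable
    if not est.any():
        raise ValueError("no component curve was estimated")
    tau = tau[:, est]
    tau = tau / np.maximum(tau.sum(axis=1, keepdims=True), 1e-300)
    r = np.column_stack(
        [expit(np.atleast_1d(risk.component_logit(j + 1, xv))) for j in np.flatnonzero(est)]
    )
    out = (tau * r).sum(axis=1)
    return float(out[0]) if scalar else out


def _design_tensor(
    x: np.ndarray, mixture: MixtureModel, degree: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Posterior weights tau (n, k) and per-component Vandermonde in z
    (k, n, degree+1)."""
    tau = posterior_weights(x, mixture)
    z = (x[:, None] - mixture.means[None, :]) / mixture.sds[None, :]
    zp = np.stack(
        [np.vander(z[:, j], degree + 1, increasing=True) for j in range(mixture.k)]
    )
    return tau, zp


def _marginal_risk(
    coeffs: np.ndarray, tau: np.ndarray, zp: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """R(x_i) = sum_j tau_ij r_j(x_i) and the per-component risks."""
    # coeffs (k, d+1), zp (k, n, d+1) -> logits (n, k)
    logits = np.einsum("knd,kd->nk", zp, coeffs)
    r = expit(logits)
    return (tau * r).sum(axis=1), r


def pmlr_loglik(
    coeffs: Union[Sequence[Sequence[float]], np.ndarray],
    records: RecordsLike,
    mixture: MixtureModel,
) -> float:
    """Bernoulli log-likelihood of the candidate risk polynomials given
    the records, conditional on the mixture:
    ``sum_i d_i log R(x_i) + (1 - d_i) log(1 - R(x_i))``."""
    frame = as_frame(records)
    x = frame[BIRTHWEIGHT].to_numpy(dtype=float)
    d = frame[DEATH].to_numpy(dtype=float)
    c = np.asarray(coeffs, dtype=float)
    if c.ndim != 2 or c.shape[0] != mixture.k:
        raise ValueError(f"coeffs must be (k={mixture.k}, degree+1)")
    tau, zp = _design_tensor(x, mixture, c.shape[1] - 1)
    big_r, _ = _marginal_risk(c, tau, zp)
    big_r = np.clip(big_r, _PCLIP, 1 - _PCLIP)
    return float(np.sum(d * np.log(big_r) + (1 - d) * np.log1p(-big_r)))


def _neg_loglik_and_grad(
    theta: np.ndarray,
    tau: np.ndarray,
    zp: np.ndarray,
    d: np.ndarray,
    n_comp: int,
    ncoef: int,
) -> Tuple[float, np.ndarray]:
    c = theta.reshape(n_comp, ncoef)
    big_r, r = _marginal_risk(c, tau, zp)
    big_r = np.clip(big_r, _PCLIP, 1 - _PCLIP)
    ll = np.sum(d * np.log(big_r) + (1 - d) * np.log1p(-big_r))
    # dll/dR_i, then chain through R = sum_j tau_j r_j, r_j = expit(q_j)
    w = d / big_r - (1 - d) / (1 - big_r)
    core = w[:, None] * tau * r * (1 - r)  # (n, k_est)
    grad = np.einsum("nk,knd->kd", core, zp).ravel()
    return -ll, -grad


def _weighted_logistic_irls(
    X: np.ndarray, d: np.ndarray, w: np.ndarray, max_iter: int = 50
) -> np.ndarray:
    """Weighted polynomial-logistic fit by Newton/IRLS with step halving
    and a small ridge for separation-proof conditioning."""
    beta = np.zeros(X.shape[1])
    rate = np.clip((w * d).sum() / max(w.sum(), 1e-300), 1e-6, 1 - 1e-6)
    beta[0] = logit(rate)

    def surrogate(b: np.ndarray) -> float:
        p = np.clip(expit(X @ b), _PCLIP, 1 - _PCLIP)
        return float(np.sum(w * (d * np.log(p) + (1 - d) * np.log1p(-p))))

    ll = surrogate(beta)
    ridge = 1e-6 * np.eye(X.shape[1])
    for _ in range(max_iter):
        p = expit(X @ beta)
        score = X.T @ (w * (d - p))
        H = (X * (w * p * (1 - p))[:, None]).T @ X + ridge
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        for _ in range(20):
            cand = beta + scale * step
            ll_new = surrogate(cand)
            if ll_new >= ll:
                break
            scale *= 0.5
        else:
            break
        if ll_new - ll < 1e-10 * max(1.0, abs(ll_new)):
            beta = cand
            break
        beta, ll = cand, ll_new
    return np.clip(beta, -COEF_BOUND, COEF_BOUND)


def fit_pmlr(
    records: RecordsLike,
    mixture: MixtureModel,
    degree: int = 4,
    seed: int = 0,
    min_expected_deaths: float = MIN_EXPECTED_DEATHS,
    max_eval: int = 5000,
) -> RiskModel:
    """Fit the component-specific risk polynomials by maximum likelihood
    conditional on ``mixture``.

    The marginal Bernoulli likelihood in the quartic coefficients is
    ridge-shaped wherever posterior membership columns are nearly
    collinear, so the procedure anchors at a stable initialization and
    polishes rather than chasing the ridge: each component is first fit
    by a posterior-weighted polynomial-logistic regression (a concave
    surrogate whose maximizer is unique), then all coefficients are
    refined jointly on the marginal likelihood with a bounded
    derivative-free simplex search (at most ``max_eval`` evaluations).
    The reported log-likelihood never falls below the initialization's.

    Components with posterior-expected death count below
    ``min_expected_deaths`` are left unestimated (NaN row), and posterior
    mass is renormalized over the rest for the likelihood.
    """
    frame = as_frame(records)
    x = frame[BIRTHWEIGHT].to_numpy(dtype=float)
    d = frame[DEATH].to_numpy(dtype=float)
    deaths = d.sum()
    if deaths == 0 or deaths == d.size:
        raise ValueError("records must contain at least one death and one survival")

    ncoef = degree + 1
    tau_full, zp_full = _design_tensor(x, mixture, degree)
    expected_deaths = tau_full.T @ d
    est = expected_deaths >= min_expected_deaths
    if not est.any():
        raise ValueError(
            "no component has enough expected deaths to estimate a risk curve"
        )
    if not est.all():
        warnings.warn(
            f"components {list(np.flatnonzero(~est) + 1)} carry fewer than "
            f"{min_expected_deaths} expected deaths; their curves are unestimated",
            RuntimeWarning,
        )
    tau = tau_full[:, est]
    tau = tau / np.maximum(tau.sum(axis=1, keepdims=True), 1e-300)
    zp = zp_full[est]
    n_comp = int(est.sum())

    theta0 = np.concatenate(
        [
            _weighted_logistic_irls(zp[jj], d, tau[:, jj])
            for jj in range(n_comp)
        ]
    )
    f0, _ = _neg_loglik_and_grad(theta0, tau, zp, d, n_comp, ncoef)

    def neg_ll(t: np.ndarray) -> float:
        return _neg_loglik_and_grad(t, tau, zp, d, n_comp, ncoef)[0]

    res = minimize(
        neg_ll,
        theta0,
        method="Nelder-Mead",
        options={
            "maxfev": max_eval,
            "xatol": 1e-6,
            "fatol": 1e-8,
            "adaptive": True,
        },
    )
    if res.fun <= f0:
        best_theta, best_fun = res.x, res.fun
    else:
        best_theta, best_fun = theta0, f0
    ok = bool(res.success) or best_fun <= f0
    if not ok:
        warnings.warn(
            f"PMLR polish flagged non-convergence: {res.message}", RuntimeWarning
        )
    best_theta = np.clip(best_theta, -COEF_BOUND, COEF_BOUND)

    coeffs = np.full((mixture.k, ncoef), np.nan)
    coeffs[est] = best_theta.reshape(n_comp, ncoef)
    return RiskModel(
        mixture=mixture,
        coeffs=coeffs,
        degree=degree,
        loglik=float(-best_fun),
        converged=ok,
    )


@dataclass(frozen=True)
class BinnedMortality:
    """Crude mortality rates in fixed-width birthweight bins.

    Bins are half-open ``[a, a + width)`` anchored at 0 g.  Rates are NaN
    (undefined, not zero) in bins without births.
    """

    edges: np.ndarray  # (n_bins + 1,)
    births: np.ndarray
    deaths: np.ndarray
    bin_width: float

    @property
    def rates(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.births > 0, self.deaths / np.maximum(self.births, 1), np.nan)

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left_g": self.edges[:-1],
                "bin_right_g": self.edges[1:],
                "births": self.births,
                "deaths": self.deaths,
                "crude_rate": self.rates,
            }
        )


def empirical_mortality(records: RecordsLike, bin_width: float = 100.0) -> BinnedMortality:
    """Crude mortality rates (deaths/births) in ``bin_width``-gram bins
    anchored at 0; totals are conserved."""
    frame = as_frame(records)
    x = frame[BIRTHWEIGHT].to_numpy(dtype=float)
    d = frame[DEATH].to_numpy(dtype=float)
    n_bins = int(np.floor(x.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    idx = np.floor(x / bin_width).astype(int)
    births = np.bincount(idx, minlength=n_bins).astype(float)
    deaths = np.bincount(idx, weights=d, minlength=n_bins)
    return BinnedMortality(edges=edges, births=births, deaths=deaths, bin_width=bin_width)


def curve_support(
    mixture: MixtureModel, j: int, c: float = 3.0
) -> Tuple[float, float]:
    """Birthweight interval over which the component-j curve is reported:
    ``mu_j +/- c sigma_j`` clipped to positive birthweights."""
    _check_j(j, mixture.k)
    mu = mixture.means[j - 1]
    sd = mixture.sds[j - 1]
    return (max(0.0, mu - c * sd), mu + c * sd)
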