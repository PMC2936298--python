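"""Multi-sample ("meta-sample") inference for component risk curves.

Per-sample PMLR fits from N_rep samples of the same population are
combined on the logit scale: the overall estimate of r_j(x) is the
inverse logit of the mean of the per-sample logits, and the spread of
those logits drives confidence intervals

    theta_bar +/- (B_theta +) C * S_theta / sqrt(N_rep)

where B_theta is a simulation-based bias adjustment (mean absolute
deviation between refitted simulated estimates and the overall estimate)
and C is a calibration constant.  When the N_rep samples overlap because
the population is finite, C is inflated from its infinite-population
value C_0 to

    C_phi = C_0 * phi * N_rep / (1 - (1 - phi)^N_rep),

phi being the fraction of the population each sample constitutes.  Odds
ratios between components of one population, or between the same
component of two populations, are handled as logit differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.special import expit, logit
from scipy.stats import norm

from .mixture import MixtureModel
from .risk import RiskModel, _check_j


@dataclass(frozen=True)
class RiskTarget:
    """Scalar target theta = logit r_j(x0): component j (1-based) at
    birthweight x0 in grams."""

    j: int
    x0: float

    def describe(self) -> str:
        return f"logit r_{self.j}({self.x0:g})"


@dataclass(frozen=True)
class OddsRatioTarget:
    """Scalar target theta = logit r_j1(x0) - logit r_j2(x0): the log
    odds ratio between components j1 and j2 at birthweight x0."""

    j1: int
    j2: int
    x0: float

    def describe(self) -> str:
        return f"logit r_{self.j1}({self.x0:g}) - logit r_{self.j2}({self.x0:g})"


Target = Union[RiskTarget, OddsRatioTarget]


@dataclass(frozen=True)
class MetaEstimate:
    """The N_rep per-sample logit-scale estimates of one scalar target,
    with their mean, sample standard deviation and bias adjustment."""

    target: Target
    per_sample_thetas: np.ndarray
    bias: float = 0.0
    n_excluded: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.per_sample_thetas, dtype=float)
        if t.ndim != 1 or t.size < 1:
            raise ValueError("per_sample_thetas must be a nonempty 1-d array")
        if not np.all(np.isfinite(t)):
            raise ValueError("per-sample logit estimates must be finite")
        if self.bias < 0:
            raise ValueError("bias adjustment must be nonnegative")
        t = np.ascontiguousarray(t)
        t.flags.writeable = False
        object.__setattr__(self, "per_sample_thetas", t)

    @property
    def n_rep(self) -> int:
        return self.per_sample_thetas.size

    @property
    def theta_bar(self) -> float:
        return float(np.mean(self.per_sample_thetas))

    @property
    def s_theta(self) -> float:
        if self.n_rep < 2 or np.ptp(self.per_sample_thetas) == 0.0:
            return 0.0  # identical estimates: exactly zero spread
        return float(np.std(self.per_sample_thetas, ddof=1))

    def with_bias(self, bias: float) -> "MetaEstimate":
        return MetaEstimate(self.target, self.per_sample_thetas, bias, self.n_excluded)


@dataclass(frozen=True)
class IntervalEstimate:
    """A point estimate with symmetric-on-the-logit-scale confidence
    limits, reported on one of three scales."""

    point: float
    lower: float
    upper: float
    scale: str  # "logit" | "probability" | "odds_ratio"
    c_used: float
    phi_used: float = 0.0
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.scale not in ("logit", "probability", "odds_ratio"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if not self.lower <= self.point <= self.upper:
            raise ValueError("require lower <= point <= upper")
        if self.scale == "probability" and not (0 < self.lower and self.upper < 1):
            raise ValueError("probability-scale bounds must lie in (0, 1)")
        if self.scale == "odds_ratio" and self.lower <= 0:
            raise ValueError("odds-ratio-scale bounds must be positive")


class CombinedRiskCurve:
    """Overall risk curves from N_rep per-sample PMLR fits: at every x,
    r_j(x) is the inverse logit of the mean per-sample logit over the
    samples where component j was estimated."""

    def __init__(self, fits: Sequence[RiskModel]):
        fits = list(fits)
        if not fits:
            raise ValueError("need at least one fitted risk model")
        k = fits[0].k
        if any(f.k != k for f in fits):
            raise ValueError("all fits must share the same component count")
        self.fits = fits
        self.k = k

    def component_estimable(self, j: int) -> bool:
        _check_j(j, self.k)
        return any(f.estimable[j - 1] for f in self.fits)

    def component_logit(self, j: int, x) -> Union[float, np.ndarray]:
        _check_j(j, self.k)
        use = [f for f in self.fits if f.estimable[j - 1]]
        if not use:
            raise ValueError(f"component {j} estimated in no sample")
        vals = np.stack([np.atleast_1d(np.asarray(f.component_logit(j, x))) for f in use])
        out = vals.mean(axis=0)
        return float(out[0]) if np.ndim(x) == 0 else out

    def component_risk(self, j: int, x) -> Union[float, np.ndarray]:
        out = expit(np.clip(self.component_logit(j, x), -700.0, 36.7))
        return float(out) if np.ndim(x) == 0 else out


def average_mixture(models: Sequence[MixtureModel]) -> MixtureModel:
    """Overall mixture estimate: the mean of per-sample weights
    (renormalized), means and sds, components aligned by mean order."""
    models = list(models)
    if not models:
        raise ValueError("need at least one mixture model")
    k = models[0].k
    if any(m.k != k for m in models):
        raise ValueError("all models must share the same k")
    w = np.mean([m.weights for m in models], axis=0)
    mu = np.mean([m.means for m in models], axis=0)
    sd = np.mean([m.sds for m in models], axis=0)
    return MixtureModel(w / w.sum(), mu, sd)


def combine_risk_estimates(
    fits: Sequence[RiskModel], j: int, x: float
) -> MetaEstimate:
    """Combine per-sample estimates of r_j(x) on the logit scale.

    Samples where component j was unestimated are excluded with a
    warning; at least two must remain.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits supplied")
    _check_j(j, fits[0].k)
    thetas = []
    excluded = 0
    for f in fits:
        if f.estimable[j - 1]:
            thetas.append(logit(f.component_risk(j, float(x))))
        else:
            excluded += 1
    if excluded:
        warnings.warn(
            f"component {j} unestimated in {excluded} of {len(fits)} samples; "
            "those samples are excluded from the combination",
            RuntimeWarning,
        )
    if len(thetas) == 0:
        raise ValueError(f"component {j} estimated in no sample")
    if len(fits) > 1 and len(thetas) < 2:
        raise ValueError(
            f"fewer than 2 samples retain component {j}; cannot combine"
        )
    return MetaEstimate(
        target=RiskTarget(j=j, x0=float(x)),
        per_sample_thetas=np.array(thetas),
        n_excluded=excluded,
    )


def overlap_constant(c0: float, phi: float, n_rep: int) -> float:
    """Overlap-corrected calibration constant
    ``C_phi = C_0 phi N_rep / {1 - (1 - phi)^N_rep}``.

    phi is the fraction of the population each of the N_rep samples
    constitutes; phi -> 0 (non-overlapping samples) recovers C_0.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    if phi == 0:
        return float(c0)
    if not 0 < phi < 1:
        raise ValueError(f"phi must lie in (0, 1), got {phi}")
    return float(c0 * phi * n_rep / (1.0 - (1.0 - phi) ** n_rep))


def ci_theta(meta: MetaEstimate, c: float, use_bias: bool = True) -> IntervalEstimate:
    """Logit-scale confidence interval
    ``theta_bar +/- {B_theta + C S_theta / sqrt(N_rep)}`` (the bias term
    is dropped when ``use_bias`` is false).

    A zero half-width is flagged as degenerate, not an error.
    """
    if c <= 0:
        raise ValueError("c must be positive")
    half = (meta.bias if use_bias else 0.0) + c * meta.s_theta / np.sqrt(meta.n_rep)
    tb = meta.theta_bar
    return IntervalEstimate(
        point=tb,
        lower=tb - half,
        upper=tb + half,
        scale="logit",
        c_used=c,
        degenerate=(half == 0.0),
    )


def risk_interval(
    meta: MetaEstimate, c: float, use_bias: bool = True
) -> IntervalEstimate:
    """Probability-scale confidence interval for r_j(x0): the inverse
    logit of both endpoints of the logit-scale interval (monotone, so
    ordering is preserved)."""
    li = ci_theta(meta, c, use_bias)
    return IntervalEstimate(
        point=float(expit(li.point)),
        lower=float(expit(li.lower)),
        upper=float(expit(li.upper)),
        scale="probability",
        c_used=c,
        degenerate=li.degenerate,
    )


def confidence_bounds(
    fits: Sequence[RiskModel],
    j: int,
    grid: Sequence[float],
    c: float,
    bias: Union[float, Sequence[float]] = 0.0,
    use_bias: bool = True,
) -> pd.DataFrame:
    """Pointwise confidence bounds for the component-j curve along a
    birthweight grid; connecting the per-point limits yields the lower
    and upper bound curves.

    ``bias`` may be a scalar applied at every grid point or a per-point
    sequence.  Returns columns birthweight_g, risk, lower, upper,
    n_rep_effective.
    """
    grid = np.asarray(list(grid), dtype=float)
    biases = np.broadcast_to(np.asarray(bias, dtype=float), grid.shape)
    rows = []
    for x0, b in zip(grid, biases):
        meta = combine_risk_estimates(fits, j, x0).with_bias(float(b))
        iv = risk_interval(meta, c, use_bias)
        rows.append(
            {
                "birthweight_g": x0,
                "risk": iv.point,
                "lower": iv.lower,
                "upper": iv.upper,
                "n_rep_effective": meta.n_rep,
            }
        )
    return pd.DataFrame(rows)


def odds_ratio_within(
    fits: Sequence[RiskModel],
    j1: int,
    j2: int,
    x0: float,
    c: float,
    bias: float = 0.0,
    use_bias: bool = True,
) -> Tuple[IntervalEstimate, MetaEstimate]:
    """Odds ratio comparing components j1 and j2 of one population at
    birthweight x0: per-sample thetas are the logit differences, the
    point estimate is exp(theta_bar), and the interval is the
    exponentiated logit-scale interval."""
    fits = list(fits)
    if not fits:
        raise ValueError("no fits supplied")
    _check_j(j1, fits[0].k)
    _check_j(j2, fits[0].k)
    thetas = []
    excluded = 0
    for f in fits:
        if f.estimable[j1 - 1] and f.estimable[j2 - 1]:
            thetas.append(
                logit(f.component_risk(j1, float(x0)))
                - logit(f.component_risk(j2, float(x0)))
            )
        else:
            excluded += 1
    if excluded:
        warnings.warn(
            f"components ({j1},{j2}) unestimated in {excluded} of {len(fits)} "
            "samples; those samples are excluded",
            RuntimeWarning,
        )
    if len(thetas) == 0 or (len(fits) > 1 and len(thetas) < 2):
        raise ValueError("fewer than 2 samples retain both components")
    meta = MetaEstimate(
        target=OddsRatioTarget(j1=j1, j2=j2, x0=float(x0)),
        per_sample_thetas=np.array(thetas),
        bias=float(bias),
        n_excluded=excluded,
    )
    li = ci_theta(meta, c, use_bias)
    interval = IntervalEstimate(
        point=float(np.exp(li.point)),
        lower=float(np.exp(li.lower)),
        upper=float(np.exp(li.upper)),
        scale="odds_ratio",
        c_used=c,
        degenerate=li.degenerate,
    )
    return interval, meta


def odds_ratio_between(
    meta1: MetaEstimate, meta2: MetaEstimate, c: float
) -> IntervalEstimate:
    """Odds ratio comparing the same component of two populations at the
    same birthweight: point estimate exp(theta_bar_1 - theta_bar_2),
    log-scale half-width ``B_1 + B_2 + C sqrt(S_1^2/N_rep_1 +
    S_2^2/N_rep_2)``."""
    t1, t2 = meta1.target, meta2.target
    if not (isinstance(t1, RiskTarget) and isinstance(t2, RiskTarget)):
        raise ValueError("between-population odds ratios require risk targets")
    if t1.j != t2.j or t1.x0 != t2.x0:
        raise ValueError(
            f"mismatched targets: {t1.describe()} vs {t2.describe()}"
        )
    diff = meta1.theta_bar - meta2.theta_bar
    half = meta1.bias + meta2.bias + c * np.sqrt(
        meta1.s_theta**2 / meta1.n_rep + meta2.s_theta**2 / meta2.n_rep
    )
    return IntervalEstimate(
        point=float(np.exp(diff)),
        lower=float(np.exp(diff - half)),
        upper=float(np.exp(diff + half)),
        scale="odds_ratio",
        c_used=c,
        degenerate=(half == 0.0),
    )


def _theta_of(risk_like, target: Target) -> float:
    """Evaluate a scalar logit-scale target on a RiskModel or
    CombinedRiskCurve; raises if a needed component is unestimated."""
    if isinstance(target, RiskTarget):
        return float(logit(risk_like.component_risk(target.j, target.x0)))
    return float(
        logit(risk_like.component_risk(target.j1, target.x0))
        - logit(risk_like.component_risk(target.j2, target.x0))
    )


def bias_adjustment(
    overall_mixture: MixtureModel,
    overall_risk,
    targets: Sequence[Target],
    n: int,
    n_sim: int = 5,
    seed: int = 0,
    fit_mixture_kwargs: Optional[dict] = None,
    fit_pmlr_kwargs: Optional[dict] = None,
    fallback_rate: Optional[float] = None,
) -> Dict[Target, float]:
    """Simulation-based bias adjustment B_theta for each target.

    Generates ``n_sim`` data sets of size n from the overall mixture with
    outcomes from the overall risk curves, refits the k-component mixture
    and PMLR on each, and returns the mean absolute deviation
    ``|theta_sim - theta_hat|`` per target.  One shared bank of
    simulations serves all targets.  Simulated sets on which the refit
    fails, or a target's component is unestimated, are dropped for the
    affected targets with a warning.
    """
    from .mixture import fit_mixture_em
    from .risk import fit_pmlr
    from .simulate import simulate_records

    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    fit_mixture_kwargs = dict(fit_mixture_kwargs or {})
    fit_pmlr_kwargs = dict(fit_pmlr_kwargs or {})
    theta_hat = {t: _theta_of(overall_risk, t) for t in targets}
    devs: Dict[Target, List[float]] = {t: [] for t in targets}
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(2 * n_sim) % (2**31 - 1)
    n_failed = 0
    for s in range(n_sim):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                sim = simulate_records(
                    overall_mixture,
                    overall_risk,
                    n,
                    seed=int(child_seeds[2 * s]),
                    fallback_rate=fallback_rate,
                )
                mix_sim = fit_mixture_em(
                    sim, overall_mixture.k, seed=int(child_seeds[2 * s + 1]),
                    **fit_mixture_kwargs,
                )
                risk_sim = fit_pmlr(
                    sim, mix_sim, seed=int(child_seeds[2 * s + 1]), **fit_pmlr_kwargs
                )
        except (ValueError, RuntimeError) as exc:
            n_failed += 1
            warnings.warn(f"bias simulation {s} failed and was dropped: {exc}", RuntimeWarning)
            continue
        for t in targets:
            try:
                theta_sim = _theta_of(risk_sim, t)
            except ValueError:
                continue
            devs[t].append(abs(theta_sim - theta_hat[t]))
    if n_failed == n_sim:
        raise RuntimeError("all bias simulations failed")
    out: Dict[Target, float] = {}
    for t in targets:
        if devs[t]:
            out[t] = float(np.mean(devs[t]))
        else:
            warnings.warn(
                f"target {t.describe()} unestimable in every bias simulation; "
                "bias set to 0",
                RuntimeWarning,
            )
            out[t] = 0.0
    return out


def covariate_component_probability(cov_risk, j: int) -> float:
    """Overall probability of a binary covariate (e.g. preterm birth)
    within component j: the integral of r_j(x) f(x; mu_j, sigma_j) over
    birthweight, where r_j was fitted by PMLR with the covariate as the
    outcome.

    Integrates over mu_j +/- 8 sigma_j by adaptive quadrature.
    """
    mixture = cov_risk.mixture if isinstance(cov_risk, RiskModel) else cov_risk.fits[0].mixture
    _check_j(j, mixture.k)
    mu = mixture.means[j - 1]
    sd = mixture.sds[j - 1]

    def integrand(x: float) -> float:
        return cov_risk.component_risk(j, x) * norm.pdf(x, mu, sd)

    value, abserr = quad(integrand, mu - 8 * sd, mu + 8 * sd, limit=200)
    if abserr > max(1e-8, 1e-6 * abs(value)):
        raise RuntimeError(
            f"quadrature did not converge: value={value:.6g}, abserr={abserr:.2g}"
        )
    return float(np.clip(value, 1e-15, 1 - 1e-15))
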