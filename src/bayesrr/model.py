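"""Poisson log-link relative-risk model.

The 30-day mortality indicator is modelled as a Poisson count with log link
("modified Poisson regression"), so the exposure coefficient is the log
relative risk of death for nonagenarians vs octogenarians.  The module
provides design construction, the IRLS maximum-likelihood fit with both
model-based and sandwich (robust) covariances, the log-posterior targeted by
MCMC, and a closed-form conjugate normal approximation for the two-group case
used as an independent testing oracle.

A note on variances: for a binary outcome the Poisson likelihood overstates
the variance (residual variance mu instead of mu(1-mu)).  The frequentist
report therefore attaches the sandwich SE; the Bayesian posterior uses the
Poisson likelihood itself, which is what reproduces the published posterior
spreads.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import NONAGENARIAN, CohortTable, TwoByTwoTable
from .errors import (
    DegenerateDesignError,
    NonConvergenceError,
    OracleInapplicableError,
)
from .priors import PriorSpec

logger = logging.getLogger(__name__)

#: covariate set of the fully adjusted model
MODEL2_COVARIATES: tuple[str, ...] = (
    "sex",
    "sofa",
    "cfs",
    "niv",
    "mech_vent",
    "rrt",
    "admission_dx",
    "withhold",
    "withdraw",
)

CONTINUOUS = ("sofa", "cfs")
CATEGORICAL = ("sex", "admission_dx")

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ModelSpec:
    """Which covariates enter the model; the exposure is always the
    nonagenarian indicator."""

    adjusted: bool
    covariates: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.adjusted and self.covariates:
            raise ValueError("unadjusted spec must have an empty covariate list")


def unadjusted_spec() -> ModelSpec:
    return ModelSpec(adjusted=False)


def adjusted_spec(covariates: tuple[str, ...] = MODEL2_COVARIATES) -> ModelSpec:
    return ModelSpec(adjusted=True, covariates=tuple(covariates))


@dataclass
class Design:
    """Design matrix with outcome and optional row multiplicities."""

    X: np.ndarray
    y: np.ndarray
    names: list[str]
    weights: np.ndarray
    n_dropped_missing: int = 0
    exposure_index: int = 1


@dataclass
class PoissonFit:
    beta: np.ndarray
    cov_model: np.ndarray
    cov_robust: np.ndarray
    converged: bool
    n_iter: int
    names: list[str] = field(default_factory=list)

    def se_model(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_model))

    def se_robust(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_robust))


@dataclass(frozen=True)
class NormalPosteriorApprox:
    """Normal approximation to the two-group posterior of the log RR."""

    mean_log_rr: float
    sd_log_rr: float

    def p_rr_greater(self, threshold_rr: float) -> float:
        from scipy.stats import norm

        return float(norm.sf((math.log(threshold_rr) - self.mean_log_rr) / self.sd_log_rr))


# ---------------------------------------------------------------------------
# design construction


def build_design(cohort: CohortTable, spec: ModelSpec) -> Design:
    """Intercept, nonagenarian indicator, then covariate columns.

    Continuous scores enter linearly; categoricals are reference-coded with
    the most frequent level as reference.  Rows missing any required covariate
    are dropped and counted.
    """
    df = cohort.df
    missing_cols = [c for c in spec.covariates if c not in df.columns]
    if missing_cols:
        raise DegenerateDesignError(f"covariates absent from cohort: {missing_cols}")
    needed = list(spec.covariates)
    mask = np.ones(len(df), dtype=bool)
    for c in needed:
        mask &= df[c].notna().to_numpy()
    n_dropped = int((~mask).sum())
    if n_dropped:
        logger.info("build_design: dropped %d rows with missing covariates", n_dropped)
    sub = df[mask]
    if len(sub) == 0:
        raise DegenerateDesignError("no complete-case rows for this model")

    cols = [np.ones(len(sub))]
    names = ["intercept"]
    exposure = (sub["age_group"] == NONAGENARIAN).to_numpy(dtype=float)
    if exposure.min() == exposure.max():
        raise DegenerateDesignError("exposure column is constant")
    cols.append(exposure)
    names.append("nonagenarian")

    for c in spec.covariates:
        if c in CONTINUOUS:
            cols.append(sub[c].to_numpy(dtype=float))
            names.append(c)
        elif c in CATEGORICAL:
            counts = sub[c].value_counts()
            ref = counts.index[0]
            for level in counts.index[1:]:
                cols.append((sub[c] == level).to_numpy(dtype=float))
                names.append(f"{c}[{level}]")
        else:  # boolean flags
            cols.append(sub[c].to_numpy(dtype=float))
            names.append(c)

    X = np.column_stack(cols)
    y = sub["mortality_30d"].to_numpy(dtype=float)
    return Design(
        X=X,
        y=y,
        names=names,
        weights=np.ones(len(sub)),
        n_dropped_missing=n_dropped,
        exposure_index=1,
    )


def design_from_two_by_two(table: TwoByTwoTable) -> Design:
    """Aggregated 4-row design for the unadjusted model.

    The Poisson likelihood depends on the data only through the group death
    and total counts, so aggregation with row multiplicities is exact (this
    sufficiency is tested against the expanded-record design).
    """
    X = np.array([[1.0, 1.0], [1.0, 1.0], [1.0, 0.0], [1.0, 0.0]])
    y = np.array([1.0, 0.0, 1.0, 0.0])
    w = np.array(
        [table.d1, table.n1 - table.d1, table.d0, table.n0 - table.d0], dtype=float
    )
    return Design(X=X, y=y, names=["intercept", "nonagenarian"], weights=w)


# ---------------------------------------------------------------------------
# likelihood, MLE, sandwich


def poisson_loglik(beta: np.ndarray, design: Design) -> float:
    """Sum over records of y*eta - exp(eta) (the y! term vanishes for 0/1 y)."""
    eta = design.X @ beta
    if not np.all(np.isfinite(eta)) or eta.max() > 700:
        return -math.inf
    return float(design.weights @ (design.y * eta - np.exp(eta)))


def poisson_mle(
    design: Design, tol: float = 1e-10, max_iter: int = 100
) -> PoissonFit:
    """Newton/IRLS maximisation of the Poisson log-likelihood.

    Convergence when the score norm falls below ``tol`` relative to the norm
    of X'Wy (an absolute 1e-10 is below floating-point rounding noise for
    cohort-sized data).
    """
    X, y, w = design.X, design.y, design.weights
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateDesignError("design matrix is rank deficient")
    beta = np.zeros(X.shape[1])
    mean_y = float(np.clip((w * y).sum() / w.sum(), 1e-10, None))
    beta[0] = math.log(mean_y)
    scale = max(1.0, float(np.linalg.norm(X.T @ (w * y))))
    trace = []
    ll = poisson_loglik(beta, design)
    converged = False
    A = None
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -500, 500)
        mu = np.exp(eta)
        grad = X.T @ (w * (y - mu))
        gnorm = float(np.linalg.norm(grad))
        trace.append((it, ll, gnorm))
        if gnorm < tol * scale:
            converged = True
            break
        A = (X * (w * mu)[:, None]).T @ X
        try:
            step = np.linalg.solve(A, grad)
        except np.linalg.LinAlgError as exc:
            raise NonConvergenceError(f"singular information matrix: {exc}", trace)
        # step halving keeps the ascent monotone
        alpha = 1.0
        for _ in range(30):
            cand = beta + alpha * step
            ll_new = poisson_loglik(cand, design)
            if ll_new >= ll - 1e-12:
                break
            alpha *= 0.5
        else:
            raise NonConvergenceError("step halving failed to improve", trace)
        beta = beta + alpha * step
        ll = ll_new
    if not converged:
        raise NonConvergenceError(
            f"IRLS did not converge in {max_iter} iterations", trace
        )
    eta = np.clip(X @ beta, -500, 500)
    mu = np.exp(eta)
    A = (X * (w * mu)[:, None]).T @ X
    cov_model = np.linalg.inv(A)
    cov_model = 0.5 * (cov_model + cov_model.T)
    fit = PoissonFit(
        beta=beta,
        cov_model=cov_model,
        cov_robust=np.full_like(cov_model, np.nan),
        converged=True,
        n_iter=it,
        names=list(design.names),
    )
    fit.cov_robust = sandwich_cov(fit, design)
    return fit


def sandwich_cov(fit: PoissonFit, design: Design) -> np.ndarray:
    """Robust covariance A^-1 B A^-1 with A = sum mu xx', B = sum (y-mu)^2 xx'."""
    X, y, w = design.X, design.y, design.weights
    mu = np.exp(np.clip(X @ fit.beta, -500, 500))
    A = (X * (w * mu)[:, None]).T @ X
    B = (X * (w * (y - mu) ** 2)[:, None]).T @ X
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise DegenerateDesignError(f"singular bread matrix: {exc}")
    cov = Ainv @ B @ Ainv
    return 0.5 * (cov + cov.T)


# ---------------------------------------------------------------------------
# Bayesian pieces


def _normal_logpdf(x: float, mean: float, sd: float) -> float:
    z = (x - mean) / sd
    return -0.5 * (_LOG_2PI + z * z) - math.log(sd)


def log_posterior(
    beta: np.ndarray,
    design: Design,
    prior: PriorSpec,
    nuisance_sd: float = 10.0,
    exposure_index: int | None = None,
) -> float:
    """Poisson log-likelihood plus normal log-priors (full densities kept).

    The elicited prior applies to the exposure coefficient; the intercept and
    any covariate coefficients get independent N(0, nuisance_sd^2) priors.
    Non-finite linear predictors yield -inf rather than an exception.
    """
    if nuisance_sd <= 0:
        raise ValueError("nuisance_sd must be > 0")
    beta = np.asarray(beta, dtype=float)
    if beta.shape[0] != design.X.shape[1]:
        raise ValueError("beta dimension does not match design")
    if not np.all(np.isfinite(beta)):
        return -math.inf
    j = design.exposure_index if exposure_index is None else exposure_index
    ll = poisson_loglik(beta, design)
    if not math.isfinite(ll):
        return -math.inf
    lp = _normal_logpdf(beta[j], prior.mean_log_rr, prior.sd_log_rr)
    for k in range(beta.shape[0]):
        if k != j:
            lp += _normal_logpdf(beta[k], 0.0, nuisance_sd)
    return ll + lp


def make_log_posterior(
    design: Design, prior: PriorSpec, nuisance_sd: float = 10.0
):
    """Closure suitable for the MCMC engine."""

    def logpost(beta: np.ndarray) -> float:
        return log_posterior(beta, design, prior, nuisance_sd=nuisance_sd)

    return logpost


def conjugate_two_group_posterior(
    table: TwoByTwoTable, prior: PriorSpec
) -> NormalPosteriorApprox:
    """Precision-weighted normal combination of prior and two-group likelihood.

    The likelihood is approximated as normal on the log-RR scale with mean
    ln((d1/n1)/(d0/n0)) and variance 1/d1 + 1/d0 (the model-based Poisson
    variance of the saturated two-group fit).  Used as an independent oracle
    for the MCMC posterior.
    """
    if table.d1 == 0 or table.d0 == 0:
        raise OracleInapplicableError("zero deaths in a group: oracle inapplicable")
    mean_lik = math.log((table.d1 / table.n1) / (table.d0 / table.n0))
    var_lik = 1.0 / table.d1 + 1.0 / table.d0
    prec = 1.0 / var_lik + 1.0 / prior.sd_log_rr**2
    mean = (mean_lik / var_lik + prior.mean_log_rr / prior.sd_log_rr**2) / prec
    return NormalPosteriorApprox(mean_log_rr=mean, sd_log_rr=math.sqrt(1.0 / prec))
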