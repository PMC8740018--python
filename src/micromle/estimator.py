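"""Maximum-likelihood fitting of the censored lognormal concentration model.

``fit_mle`` maximizes the censored-data log-likelihood over (mu, log sigma)
with a Nelder-Mead simplex refined by BFGS, so sigma > 0 is structural and
no randomness enters: a fixed dataset always yields the same fit.
``wald_confidence`` derives standard errors and confidence intervals from
the observed information (numerical Hessian at the MLE), and
``summarize_uncensored`` is the shortcut path for datasets without ND
records, where the MLE has the closed form (sample mean, n-denominator SD)
of the log values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import optimize
from scipy.stats import norm

from .data_model import (
    EnumerationDataset,
    FullyCensoredError,
    ValidationError,
    to_fitting_convention,
)
from .likelihood import (
    LognormalParams,
    CompiledDataset,
    compile_dataset,
    loglik_compiled,
)

__all__ = [
    "FitResult",
    "WaldInterval",
    "initialize",
    "fit_mle",
    "wald_confidence",
    "summarize_uncensored",
    "Z_90",
]

#: standard-normal 95th-percentile multiplier (5th/95th distribution percentiles)
Z_90 = 1.6448536269514722

_SIGMA_FLOOR = 0.05  # starting-value floor for degenerate spread


@dataclass(frozen=True)
class FitResult:
    """Point estimates, uncertainty, and diagnostics of one fit.

    ``ci95_mu``/``ci95_sigma`` are Wald intervals at the requested level
    (95% by default) for the *parameters*; ``percentile_05``/``percentile_95``
    are the 5th/95th percentiles of the fitted concentration *distribution*
    (mu -/+ 1.644854 sigma) — two different things, both reported.
    """

    params: LognormalParams
    se_mu: float | None
    se_sigma: float | None
    ci95_mu: tuple[float, float] | None
    ci95_sigma: tuple[float, float] | None
    loglik: float
    converged: bool
    n_detected: int
    m_censored: int
    percentile_05: float
    percentile_95: float
    loq_log10: float
    n_iter: int = 0
    message: str = ""


class WaldInterval(NamedTuple):
    se_mu: float | None
    se_sigma: float | None
    ci_mu: tuple[float, float] | None
    ci_sigma: tuple[float, float] | None
    message: str


def _representatives(dataset: EnumerationDataset) -> tuple[np.ndarray, np.ndarray]:
    """Substitution representatives: exact as-is, ND -> log10(LOQ/2),
    interval -> log-midpoint."""
    half_loq = math.log10(dataset.loq / 2.0)
    ys, ws = [], []
    for o in dataset.observations:
        if o.kind == "exact":
            ys.append(o.value)
        elif o.kind == "left_censored":
            ys.append(half_loq)
        else:
            ys.append(0.5 * (o.lower + o.upper))
        ws.append(o.weight)
    return np.asarray(ys, dtype=float), np.asarray(ws, dtype=float)


def initialize(dataset: EnumerationDataset) -> LognormalParams:
    """Substitution starting point for the optimizer.

    The weighted mean and n-denominator SD of the representative values,
    with the SD floored at 0.05 so a degenerate spread still yields a
    usable simplex.
    """
    if dataset.n_detected < 1:
        raise FullyCensoredError("cannot initialize from a fully censored dataset")
    if dataset.total_weight < 2:
        raise ValidationError("initialization requires total weight >= 2")
    y, w = _representatives(dataset)
    mu0 = float(np.average(y, weights=w))
    sd0 = float(math.sqrt(np.average((y - mu0) ** 2, weights=w)))
    return LognormalParams(mu0, max(sd0, _SIGMA_FLOOR))


def _closed_form_exact(c: CompiledDataset) -> tuple[float, float]:
    mu = float(np.average(c.exact_y, weights=c.exact_w))
    sd = float(math.sqrt(np.average((c.exact_y - mu) ** 2, weights=c.exact_w)))
    return mu, sd


def _guard_identifiable(dataset: EnumerationDataset) -> None:
    if dataset.n_detected < 1:
        raise FullyCensoredError(
            "all observations are below the LOQ (100% censored); the lognormal "
            "MLE is not identifiable from fully censored data — such "
            "presence/absence-type results need different methods")
    if dataset.total_weight < 2:
        raise ValidationError("fitting requires at least two samples in total")


def fit_mle(dataset: EnumerationDataset, tol: float = 1e-10, max_iter: int = 2000,
            *, interval_method: str = "midpoint", nd_bound: str = "integer",
            level: float = 0.95) -> FitResult:
    """Maximize the censored log-likelihood; deterministic for fixed input.

    Parameters
    ----------
    dataset
        Must contain at least one quantified observation and total weight
        >= 2; a fully censored dataset raises :class:`FullyCensoredError`.
    tol
        Relative tolerance on the objective for the simplex stage.
    max_iter
        Iteration cap for the simplex stage.
    interval_method, nd_bound
        Data-representation conventions, see
        :func:`micromle.data_model.to_fitting_convention`.  The defaults
        (bin midpoints, ND bounded at LOQ - 1 CFU/g) match how
        semi-quantitative plate-count tables are conventionally read; use
        ``interval_method="likelihood", nd_bound="loq"`` for exact
        continuous-scale censoring, e.g. on simulated data.
    """
    _guard_identifiable(dataset)
    work = to_fitting_convention(dataset, interval_method, nd_bound)
    c = compile_dataset(work)

    # degenerate: exact-only data with zero spread has no interior maximum
    if not c.cens_b.size and not c.int_lo.size and float(np.ptp(c.exact_y)) == 0.0:
        warnings.warn("all observations identical: sigma is degenerate (0); "
                      "standard errors unavailable", stacklevel=2)
        return _degenerate_result(dataset, float(c.exact_y[0]))

    p0 = initialize(dataset)
    x0 = np.array([p0.mu, math.log(p0.sigma)])

    def nll(x: np.ndarray) -> float:
        logsig = min(max(x[1], -30.0), 30.0)
        return -loglik_compiled(c, x[0], math.exp(logsig))

    f0 = nll(x0)
    nm = optimize.minimize(
        nll, x0, method="Nelder-Mead",
        options={"maxiter": max_iter, "xatol": 1e-9,
                 "fatol": tol * max(1.0, abs(f0)), "adaptive": False})
    best_x, best_f, n_iter = nm.x, nm.fun, nm.nit
    bfgs = optimize.minimize(nll, best_x, method="BFGS",
                             options={"gtol": 1e-9, "maxiter": 500})
    if np.isfinite(bfgs.fun) and bfgs.fun <= best_f:
        best_x, best_f = bfgs.x, bfgs.fun
    converged = bool(nm.success or bfgs.success)
    if not converged:
        warnings.warn(f"optimizer did not meet tolerance: {nm.message}", stacklevel=2)

    params = LognormalParams(float(best_x[0]), float(math.exp(best_x[1])))
    wald = wald_confidence(dataset, params, level,
                           interval_method=interval_method, nd_bound=nd_bound)
    return FitResult(
        params=params, se_mu=wald.se_mu, se_sigma=wald.se_sigma,
        ci95_mu=wald.ci_mu, ci95_sigma=wald.ci_sigma,
        loglik=float(-best_f), converged=converged,
        n_detected=dataset.n_detected, m_censored=dataset.m_censored,
        percentile_05=params.mu - Z_90 * params.sigma,
        percentile_95=params.mu + Z_90 * params.sigma,
        loq_log10=dataset.loq_log10, n_iter=int(n_iter),
        message=wald.message or str(nm.message))


def _degenerate_result(dataset: EnumerationDataset, mu: float) -> FitResult:
    return FitResult(
        params=LognormalParams(mu, 0.0), se_mu=None, se_sigma=None,
        ci95_mu=None, ci95_sigma=None, loglik=math.inf, converged=True,
        n_detected=dataset.n_detected, m_censored=dataset.m_censored,
        percentile_05=mu, percentile_95=mu, loq_log10=dataset.loq_log10,
        message="degenerate fit: zero spread")


def wald_confidence(dataset: EnumerationDataset, params: LognormalParams,
                    level: float = 0.95, *, interval_method: str = "midpoint",
                    nd_bound: str = "integer") -> WaldInterval:
    """Standard errors and Wald CIs from the observed information.

    The Hessian of the log-likelihood at the MLE is computed in the
    (mu, sigma) parametrization by central finite differences with step
    1e-5 * max(1, |theta|); the covariance is the inverse of its negation.
    If that matrix is not positive definite the SEs are reported as
    unavailable with a diagnostic message.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    c = compile_dataset(to_fitting_convention(dataset, interval_method, nd_bound))
    f = lambda mu, s: loglik_compiled(c, mu, s)
    mu, sig = params.mu, params.sigma
    h1 = 1e-5 * max(1.0, abs(mu))
    h2 = min(1e-5 * max(1.0, abs(sig)), 0.4 * sig)  # keep sigma - h2 > 0
    f00 = f(mu, sig)
    d2mu = (f(mu + h1, sig) - 2 * f00 + f(mu - h1, sig)) / h1 ** 2
    d2sig = (f(mu, sig + h2) - 2 * f00 + f(mu, sig - h2)) / h2 ** 2
    dcross = (f(mu + h1, sig + h2) - f(mu + h1, sig - h2)
              - f(mu - h1, sig + h2) + f(mu - h1, sig - h2)) / (4 * h1 * h2)
    H = np.array([[d2mu, dcross], [dcross, d2sig]])
    if not np.all(np.isfinite(H)):
        raise ValidationError("non-finite Hessian entries at the supplied parameters")
    info = -H
    try:
        eigvals = np.linalg.eigvalsh(info)
        if np.any(eigvals <= 0):
            return WaldInterval(None, None, None, None,
                                "observed information not positive definite; "
                                "Wald standard errors unavailable")
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return WaldInterval(None, None, None, None,
                            "singular observed information; SEs unavailable")
    se_mu = float(math.sqrt(cov[0, 0]))
    se_sigma = float(math.sqrt(cov[1, 1]))
    z = float(norm.ppf(0.5 + level / 2.0))
    return WaldInterval(se_mu, se_sigma,
                        (mu - z * se_mu, mu + z * se_mu),
                        (sig - z * se_sigma, sig + z * se_sigma), "")


def summarize_uncensored(dataset: EnumerationDataset, *, level: float = 0.95) -> FitResult:
    """Direct summary for datasets without ND records (QN_1/QN_2 path).

    For exact data no optimization is needed: the MLE is the sample mean
    and n-denominator SD of the log values (the same limit ``fit_mle``
    converges to).  Interval-only data still routes through
    :func:`fit_mle`.
    """
    if dataset.has_censored:
        raise ValidationError(
            "dataset contains censored (ND) observations; use fit_mle")
    if dataset.has_interval:
        return fit_mle(dataset, level=level)
    _guard_identifiable(dataset)
    c = compile_dataset(dataset)
    mu, sd = _closed_form_exact(c)
    if sd == 0.0:
        warnings.warn("all observations identical: sigma is degenerate (0)",
                      stacklevel=2)
        return _degenerate_result(dataset, mu)
    params = LognormalParams(mu, sd)
    wald = wald_confidence(dataset, params, level)
    return FitResult(
        params=params, se_mu=wald.se_mu, se_sigma=wald.se_sigma,
        ci95_mu=wald.ci_mu, ci95_sigma=wald.ci_sigma,
        loglik=loglik_compiled(c, mu, sd), converged=True,
        n_detected=dataset.n_detected, m_censored=0,
        percentile_05=mu - Z_90 * sd, percentile_95=mu + Z_90 * sd,
        loq_log10=dataset.loq_log10, message=wald.message or "closed form")
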