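"""Censored-data log-likelihood of the lognormal concentration model.

The model: log10 concentrations Y are Normal(mu, sigma).  A dataset mixes
three contribution types,

* exact observations -> the normal log-density at y,
* left-censored (ND) observations -> log Phi((b - mu)/sigma) for the
  censoring bound b, raised to the number of ND samples (a weight),
* interval observations -> log of the band probability
  Phi((u - mu)/sigma) - Phi((l - mu)/sigma).

Everything is computed in log space: the product form of the censored
likelihood underflows double precision for about a thousand ND samples,
which real surveys reach.  Tail probabilities use ``scipy.special.log_ndtr``
(stable far beyond z = -30), and band probabilities are evaluated as a
difference of CDFs mirrored into the nearer tail so neither tail
catastrophically cancels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.special import log_ndtr

__all__ = [
    "LognormalParams",
    "log_density",
    "log_prob_below",
    "log_prob_interval",
    "total_log_likelihood",
    "LOGLIK_FLOOR",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)

#: log of (roughly) the smallest positive double; per-observation
#: contributions below this are numerically indistinguishable from
#: "impossible" and are flagged in diagnostics, but remain legal values
#: during optimization.
LOGLIK_FLOOR = -745.0


@dataclass(frozen=True)
class LognormalParams:
    """Mean and SD of the log10-normal concentration model (log10 CFU/g).

    ``sigma == 0`` is admitted only to represent the degenerate summary of
    identical observations; likelihood evaluation requires ``sigma > 0``.
    """

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.mu):
            raise ValueError(f"mu must be finite, got {self.mu!r}")
        if not (math.isfinite(self.sigma) and self.sigma >= 0):
            raise ValueError(f"sigma must be finite and >= 0, got {self.sigma!r}")


def _require_positive_sigma(params: LognormalParams) -> None:
    if params.sigma <= 0:
        raise ValueError("likelihood evaluation requires sigma > 0")


def log_density(y, params: LognormalParams):
    """Normal log-density of a log10 concentration (scalar or ndarray)."""
    _require_positive_sigma(params)
    z = (np.asarray(y, dtype=float) - params.mu) / params.sigma
    out = -_LOG_SQRT_2PI - math.log(params.sigma) - 0.5 * z * z
    return float(out) if np.isscalar(y) or out.ndim == 0 else out


def log_prob_below(threshold, params: LognormalParams):
    """log P(Y < threshold): stable log of the normal CDF on the log scale."""
    _require_positive_sigma(params)
    z = (np.asarray(threshold, dtype=float) - params.mu) / params.sigma
    out = log_ndtr(z)
    return float(out) if out.ndim == 0 else out


def _log_ndtr_diff(a, b):
    """log(Phi(b) - Phi(a)) elementwise for a < b, stable in both tails.

    Pairs whose midpoint lies above zero are mirrored (Phi(b) - Phi(a) =
    Phi(-a) - Phi(-b)) so the difference is always taken in the lower
    tail, where log_ndtr keeps full precision and the subtraction is
    performed as log1p(-exp(.)) on well-scaled logs.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    swap = (a + b) > 0
    lo = np.where(swap, -b, a)
    hi = np.where(swap, -a, b)
    log_hi = log_ndtr(hi)
    log_lo = log_ndtr(lo)
    with np.errstate(divide="ignore"):
        out = log_hi + np.log1p(-np.exp(log_lo - log_hi))
    return out


def log_prob_interval(lower: float, upper: float, params: LognormalParams) -> float:
    """log P(lower <= Y < upper) for one concentration band."""
    _require_positive_sigma(params)
    if not lower < upper:
        raise ValueError(f"interval requires lower < upper, got [{lower}, {upper}]")
    a = (lower - params.mu) / params.sigma
    b = (upper - params.mu) / params.sigma
    return float(_log_ndtr_diff(a, b))


# ---------------------------------------------------------------------------
# whole-dataset evaluation


class CompiledDataset(NamedTuple):
    """Observation arrays extracted once so repeated evaluation is cheap."""

    exact_y: np.ndarray
    exact_w: np.ndarray
    cens_b: np.ndarray
    cens_w: np.ndarray
    int_lo: np.ndarray
    int_hi: np.ndarray
    int_w: np.ndarray


def compile_dataset(dataset) -> CompiledDataset:
    ey, ew, cb, cw, il, ih, iw = [], [], [], [], [], [], []
    for o in dataset.observations:
        if o.kind == "exact":
            ey.append(o.value)
            ew.append(o.weight)
        elif o.kind == "left_censored":
            cb.append(o.upper)
            cw.append(o.weight)
        else:
            il.append(o.lower)
            ih.append(o.upper)
            iw.append(o.weight)
    arr = lambda x: np.asarray(x, dtype=float)
    return CompiledDataset(arr(ey), arr(ew), arr(cb), arr(cw), arr(il), arr(ih), arr(iw))


def loglik_compiled(c: CompiledDataset, mu: float, sigma: float) -> float:
    """Weighted total log-likelihood from pre-compiled arrays."""
    if sigma <= 0:
        raise ValueError("likelihood evaluation requires sigma > 0")
    ll = 0.0
    if c.exact_y.size:
        z = (c.exact_y - mu) / sigma
        ll += float(np.dot(c.exact_w, -_LOG_SQRT_2PI - math.log(sigma) - 0.5 * z * z))
    if c.cens_b.size:
        ll += float(np.dot(c.cens_w, log_ndtr((c.cens_b - mu) / sigma)))
    if c.int_lo.size:
        a = (c.int_lo - mu) / sigma
        b = (c.int_hi - mu) / sigma
        ll += float(np.dot(c.int_w, _log_ndtr_diff(a, b)))
    return ll


def total_log_likelihood(dataset, params: LognormalParams) -> float:
    """Sum of weighted observation contributions for a whole dataset.

    A left-censored observation of weight m contributes exactly m times
    the single-sample censored term, matching the censored probability
    raised to the m-th power in the product form of the likelihood.
    """
    _require_positive_sigma(params)
    if dataset.total_weight < 1:
        raise ValueError("empty dataset")
    return loglik_compiled(compile_dataset(dataset), params.mu, params.sigma)
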