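"""Generalised-sigmoid (simplified Richards) curves for transcript-abundance trends.

Two equivalent parameterisations of a logistic-type curve with lower plateau 0
and arbitrary positive upper plateau are provided:

* the *standard* form ``GL(x) = kappa / (1 + exp(-(alpha + x @ beta)))``, and
* a *robust* re-parameterisation ``GLA(x) = y0 * (1 + exp(eta * beta1)) /
  (1 + exp(eta * beta1 - x @ beta))`` in terms of the curve value at the
  covariate origin (``y0``), the slope vector ``beta`` and the inflection
  location ``eta`` on the scaled covariate axis.

The robust form avoids the non-identifiability of the upper plateau when the
slope of interest is near zero or the data only support an exponential-like
rise.  All exponentials are evaluated through guarded log-space primitives so
the curve stays finite and positive for exponents up to +-700.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InvalidArgumentError",
    "UndefinedInflectionError",
    "StandardSigmoidParams",
    "GeneCurveParams",
    "gla",
    "gl",
    "log_gla",
    "upper_plateau",
    "to_standard",
    "adjusted_inflection",
]


class InvalidArgumentError(ValueError):
    """Raised when an argument violates a documented precondition."""


class UndefinedInflectionError(ValueError):
    """Raised when the adjusted inflection point does not exist.

    The log-scale inflection (with the lower plateau forced to 1) is undefined
    for a flat curve (``beta1 == 0``) and for curves whose upper plateau does
    not exceed 1.
    """


def _softplus(x):
    # log(1 + e^x), stable over the whole double range
    return np.logaddexp(0.0, x)


def _log_expm1(x):
    """log(e^x - 1) for x > 0, stable for both tiny and huge x."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = x < 30.0
    # below 30, expm1 is exactly representable; above, e^-x underflows the log1p
    out[small] = np.log(np.expm1(x[small]))
    out[~small] = x[~small] + np.log1p(-np.exp(-x[~small]))
    return out


@dataclass(frozen=True)
class StandardSigmoidParams:
    """Parameters of the standard generalised sigmoid ``GL``.

    ``alpha`` is the horizontal offset, ``beta`` the slope coefficients
    (column 1 is the covariate of interest) and ``kappa`` the upper plateau.
    """

    alpha: float
    beta: np.ndarray
    kappa: float

    def __post_init__(self):
        object.__setattr__(self, "beta", np.atleast_1d(np.asarray(self.beta, dtype=float)))
        if not np.isfinite(self.alpha):
            raise InvalidArgumentError("alpha must be finite")
        if not np.all(np.isfinite(self.beta)):
            raise InvalidArgumentError("beta must be finite")
        if not (self.kappa > 0 and np.isfinite(self.kappa)):
            raise InvalidArgumentError(f"kappa must be a positive real, got {self.kappa}")


@dataclass(frozen=True)
class GeneCurveParams:
    """Robust parameterisation of one gene's abundance curve.

    ``y0`` is the (positive) curve value at the covariate origin, ``beta`` the
    slope vector whose first entry is the slope along the covariate of
    interest, and ``eta`` the inflection location on the scaled covariate axis.
    """

    y0: float
    beta: np.ndarray
    eta: float

    def __post_init__(self):
        object.__setattr__(self, "beta", np.atleast_1d(np.asarray(self.beta, dtype=float)))
        if not (self.y0 > 0 and np.isfinite(self.y0)):
            raise InvalidArgumentError(f"y0 must be a positive real, got {self.y0}")
        if not np.all(np.isfinite(self.beta)):
            raise InvalidArgumentError("beta must be finite")
        if not np.isfinite(self.eta):
            raise InvalidArgumentError("eta must be finite")

    @property
    def beta1(self) -> float:
        """Slope on the covariate of interest (first column of the design)."""
        return float(self.beta[0])


def log_gla(xb, eta_beta1, log_y0):
    """``log GLA`` from pre-computed linear predictors.

    Parameters are broadcastable arrays: ``xb = x @ beta``, ``eta_beta1 =
    eta * beta1`` and ``log_y0 = log(y0)``.  This is the stable work-horse the
    likelihood uses; the exponent never leaves log space.
    """
    return log_y0 + _softplus(eta_beta1) - _softplus(eta_beta1 - xb)


def gla(x_row: np.ndarray, params: GeneCurveParams) -> float:
    """Evaluate the robust generalised sigmoid at one covariate row.

    Returns ``y0 * (1 + e^{eta*beta1}) / (1 + e^{eta*beta1 - x@beta})``,
    strictly positive and finite for exponents up to +-700.
    """
    x_row = np.atleast_1d(np.asarray(x_row, dtype=float))
    if not np.all(np.isfinite(x_row)):
        raise InvalidArgumentError("x_row must be finite")
    if x_row.shape[-1] != params.beta.shape[0]:
        raise InvalidArgumentError(
            f"x_row has {x_row.shape[-1]} covariates, params.beta has {params.beta.shape[0]}"
        )
    xb = x_row @ params.beta
    val = np.exp(log_gla(xb, params.eta * params.beta1, np.log(params.y0)))
    return float(val) if np.ndim(val) == 0 else val


def gl(x_row: np.ndarray, params: StandardSigmoidParams) -> float:
    """Evaluate the standard generalised sigmoid ``kappa / (1 + e^{-(alpha + x@beta)})``."""
    x_row = np.atleast_1d(np.asarray(x_row, dtype=float))
    if not np.all(np.isfinite(x_row)):
        raise InvalidArgumentError("x_row must be finite")
    xb = x_row @ params.beta
    # kappa * sigmoid(alpha + xb), in log space for symmetry with gla
    val = np.exp(np.log(params.kappa) - _softplus(-(params.alpha + xb)))
    return float(val) if np.ndim(val) == 0 else val


def upper_plateau(params: GeneCurveParams) -> float:
    """Upper plateau ``k = y0 * (1 + e^{eta*beta1})``, the limit of gla as x@beta -> +inf."""
    return float(np.exp(np.log(params.y0) + _softplus(params.eta * params.beta1)))


def to_standard(params: GeneCurveParams) -> StandardSigmoidParams:
    """Map the robust parameterisation onto the standard one.

    The mapping ``alpha = -eta * beta1``, ``kappa = upper_plateau`` leaves the
    curve unchanged pointwise.
    """
    return StandardSigmoidParams(
        alpha=-params.eta * params.beta1,
        beta=params.beta.copy(),
        kappa=upper_plateau(params),
    )


def adjusted_inflection(params: GeneCurveParams) -> float:
    """Covariate value of fastest change of the log-scale curve, plateau forced to 1.

    Because the curve's lower plateau is 0, the log-transformed curve has no
    inflection; forcing a lower plateau of 1 gives the covariate value where
    the curve crosses the geometric midpoint ``sqrt(k)`` between 1 and the
    upper plateau ``k``.  Closed form (nuisance covariates at 0):

        x_dot = eta - log(sqrt(k) - 1) / beta1,   k = y0 * (1 + e^{eta*beta1})

    Raises :class:`UndefinedInflectionError` when ``beta1 == 0`` (flat curve)
    or ``k <= 1`` (the curve never exceeds the forced lower plateau).
    """
    b1 = params.beta1
    if b1 == 0.0:
        raise UndefinedInflectionError("adjusted inflection undefined for beta1 = 0")
    log_k = np.log(params.y0) + _softplus(params.eta * b1)
    if log_k <= 0.0:
        raise UndefinedInflectionError(
            f"adjusted inflection undefined: upper plateau {np.exp(log_k):.4g} <= 1"
        )
    # log(sqrt(k) - 1) = log(expm1(log_k / 2))
    return float(params.eta - _log_expm1(0.5 * log_k) / b1)


def adjusted_inflection_draws(beta1, eta, log_y0):
    """Vectorised adjusted inflection over posterior draws.

    Arrays broadcast together; entries where the inflection is undefined
    (``beta1 == 0`` or plateau <= 1) come back NaN rather than raising, which
    is the convention posterior summaries need.
    """
    beta1 = np.asarray(beta1, dtype=float)
    eta = np.asarray(eta, dtype=float)
    log_y0 = np.asarray(log_y0, dtype=float)
    log_k = log_y0 + _softplus(eta * beta1)
    defined = (beta1 != 0.0) & (log_k > 0.0)
    out = np.full(np.broadcast_shapes(beta1.shape, eta.shape, log_y0.shape), np.nan)
    lk = np.where(defined, log_k, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        val = eta - _log_expm1(0.5 * lk) / beta1
    out[defined] = np.broadcast_to(val, out.shape)[defined]
    return out
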