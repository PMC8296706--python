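"""Gene-level outputs: posterior predictive filtering, differential calls, inflections.

A gene is *well fitted* when at most ``max_outliers`` (default 3) of its
samples fall outside the central 95% posterior-predictive interval of the
fitted NB model.  Among well-fitted genes, those whose central 95% credible
interval for the slope of interest excludes zero are called differentially
transcribed — with no multiplicity adjustment, following standard Bayesian
reporting.  Each differential call is mapped to a covariate value through the
posterior of the log-scale adjusted inflection point, back-transformed to the
raw covariate axis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .inference import FitResult
from .sigmoid import InvalidArgumentError, adjusted_inflection_draws, log_gla

__all__ = [
    "posterior_predictive_check",
    "call_differential",
    "summarize_inflection",
    "generate_report",
    "REPORT_COLUMNS",
]

REPORT_COLUMNS = [
    "gene_id",
    "well_fitted",
    "n_ppc_outliers",
    "de_call",
    "direction",
    "beta1_median",
    "beta1_ci_low",
    "beta1_ci_high",
    "y0_median",
    "inflection_median",
    "inflection_ci_low",
    "inflection_ci_high",
    "frac_inflection_defined",
]


def _posterior_log_mu(fit: FitResult, thin_idx: np.ndarray) -> np.ndarray:
    """Expected log abundance per draw: (draws, samples, genes)."""
    X = fit.design.values
    beta1 = fit.flat("beta1")[thin_idx]  # (n, G)
    beta_nuis = fit.flat("beta_nuis")[thin_idx]  # (n, G, K)
    eta = fit.flat("eta")[thin_idx]
    log_y0 = np.log(fit.flat("y0")[thin_idx])
    delta = fit.gene_delta()[thin_idx]  # (n, T, G)
    beta = np.concatenate([beta1[:, :, None], beta_nuis], axis=2)  # (n, G, R)
    xb = np.einsum("tr,ngr->ntg", X, beta)
    return delta + log_gla(xb, (eta * beta1)[:, None, :], log_y0[:, None, :])


def posterior_predictive_check(
    fit: FitResult,
    counts: pd.DataFrame,
    max_outliers: int = 3,
    level: float = 0.95,
    max_draws: int = 500,
) -> pd.DataFrame:
    """Flag genes the fitted model fails to reproduce.

    For every gene and sample the observed count is compared with the pooled
    posterior-predictive distribution (the NB mixture over posterior draws of
    the expected abundance and overdispersion); a sample is an outlier when it
    falls outside the central ``level`` interval of that mixture, and a gene
    is well fitted when at most ``max_outliers`` of its samples are outliers.

    Returns a frame with columns gene_id, well_fitted, n_ppc_outliers.
    """
    if list(counts.index) != list(fit.gene_ids) or list(counts.columns) != list(fit.sample_ids):
        raise InvalidArgumentError("counts do not match the fitted gene/sample universe")
    n_total = fit.n_chains * fit.n_draws
    thin_idx = np.unique(np.linspace(0, n_total - 1, min(max_draws, n_total)).astype(int))

    log_mu = _posterior_log_mu(fit, thin_idx)  # (n, T, G)
    omega = fit.gene_omega()[thin_idx][:, None, :]  # (n, 1, G)
    mu = np.exp(log_mu)
    p = omega / (omega + mu)
    y_obs = counts.to_numpy().T[None, :, :]  # (1, T, G)

    # mixture CDF at the observed count and just below it
    cdf_at = stats.nbinom.cdf(y_obs, omega, p).mean(axis=0)
    cdf_below = np.where(
        y_obs > 0, stats.nbinom.cdf(y_obs - 1, omega, p), 0.0
    ).mean(axis=0)
    tail = (1.0 - level) / 2.0
    outlier = (cdf_at < tail) | (1.0 - cdf_below < tail)  # T x G
    n_out = outlier.sum(axis=0)
    return pd.DataFrame(
        {
            "gene_id": fit.gene_ids,
            "well_fitted": n_out <= max_outliers,
            "n_ppc_outliers": n_out,
        }
    )


def call_differential(fit: FitResult, level: float = 0.95) -> pd.DataFrame:
    """Central credible interval of the slope of interest and the resulting call.

    ``de_call`` is true iff the equal-tailed ``level`` interval of beta1
    excludes zero; ``direction`` is 'up'/'down' by the interval's sign, 'none'
    otherwise.  No multiple-testing adjustment is applied.
    """
    if not 0.0 < level < 1.0:
        raise InvalidArgumentError("level must lie in (0, 1)")
    beta1 = fit.flat("beta1")  # (n, G)
    tail = (1.0 - level) / 2.0
    low, med, high = np.quantile(beta1, [tail, 0.5, 1.0 - tail], axis=0)
    de = (low > 0.0) | (high < 0.0)
    direction = np.where(low > 0.0, "up", np.where(high < 0.0, "down", "none"))
    return pd.DataFrame(
        {
            "gene_id": fit.gene_ids,
            "de_call": de,
            "direction": direction,
            "beta1_median": med,
            "beta1_ci_low": low,
            "beta1_ci_high": high,
        }
    )


def summarize_inflection(
    fit: FitResult,
    level: float = 0.95,
    min_defined: float = 0.5,
) -> pd.DataFrame:
    """Posterior of the adjusted inflection point on the raw covariate scale.

    The adjusted inflection (log-scale curve, lower plateau forced to 1) is
    computed per posterior draw where it exists (nonzero slope, upper plateau
    above 1), back-transformed with the design's interest-column scaling, and
    summarised by the median and the equal-tailed ``level`` interval over the
    defined draws.  Genes with fewer than ``min_defined`` defined draws get
    NaN summaries.  Back-transformed values may legitimately fall outside the
    observed covariate range, flagging changes before or after it.
    """
    beta1 = fit.flat("beta1")
    eta = fit.flat("eta")
    log_y0 = np.log(fit.flat("y0"))
    infl_scaled = adjusted_inflection_draws(beta1, eta, log_y0)  # (n, G), NaN undefined
    infl_raw = fit.design.to_raw_interest(infl_scaled)
    frac_defined = np.mean(~np.isnan(infl_scaled), axis=0)
    tail = (1.0 - level) / 2.0
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        q = np.nanquantile(infl_raw, [tail, 0.5, 1.0 - tail], axis=0)
    summarised = frac_defined >= min_defined
    q = np.where(summarised[None, :], q, np.nan)
    return pd.DataFrame(
        {
            "gene_id": fit.gene_ids,
            "inflection_median": q[1],
            "inflection_ci_low": q[0],
            "inflection_ci_high": q[2],
            "frac_inflection_defined": frac_defined,
        }
    )


def generate_report(
    fit: FitResult,
    ppc: pd.DataFrame,
    de: pd.DataFrame,
    inflection: pd.DataFrame,
) -> pd.DataFrame:
    """Join the per-gene results into the fixed-order report table."""
    for frame in (ppc, de, inflection):
        if list(frame["gene_id"]) != list(fit.gene_ids):
            raise InvalidArgumentError("component results disagree on the gene universe")
    y0_median = np.median(fit.flat("y0"), axis=0)
    report = (
        ppc.merge(de, on="gene_id")
        .merge(inflection, on="gene_id")
        .assign(y0_median=y0_median)
    )
    return report[REPORT_COLUMNS]
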