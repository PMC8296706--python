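"""Data preparation (filtering, design scaling, gene blocking) and posterior sampling.

The fitting pipeline is: remove genes with zero counts in more than half the
samples, build a scaled no-intercept design matrix with the covariate of
interest in column one, partition genes into blocks (default 5000) and run
NUTS on the joint model independently per block.  Draws come back in a
:class:`FitResult` holding constrained-space posterior draws for every model
parameter, equal-tailed summaries and sampler diagnostics.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .model import HorseshoeConfig, UnconstrainedModel, regularized_scales
from .nuts import sample_nuts
from .sigmoid import InvalidArgumentError

__all__ = [
    "FitError",
    "DesignMatrix",
    "FitConfig",
    "FitResult",
    "filter_zero_genes",
    "build_design",
    "partition_genes",
    "fit",
]

logger = logging.getLogger("sigtrend")

GENE_PARAMS = ("beta1", "y0", "eta", "beta_nuis", "hs_local")
BLOCK_PARAMS = ("delta", "omega", "sigma", "hs_tau", "hs_c2", "gamma1", "gamma2")

# a block whose divergent-transition fraction exceeds this fails the fit
MAX_DIVERGENT_FRACTION = 0.10


class FitError(RuntimeError):
    """Sampler failure; carries the diagnostics gathered before the failure."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


def filter_zero_genes(counts: pd.DataFrame):
    """Drop genes with zero counts in strictly more than half of the samples.

    Returns ``(kept_counts, removed_gene_ids)``; gene order is preserved.
    """
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise InvalidArgumentError("count matrix is empty")
    values = counts.to_numpy()
    if np.any(values < 0) or not np.all(np.equal(np.mod(values, 1), 0)):
        raise InvalidArgumentError("counts must be non-negative integers")
    n_samples = counts.shape[1]
    n_zero = (values == 0).sum(axis=1)
    keep = n_zero <= n_samples / 2.0
    removed = list(counts.index[~keep])
    return counts.loc[keep], removed


@dataclass
class DesignMatrix:
    """Scaled no-intercept design; column 0 is the covariate of interest.

    ``center``/``scale`` hold the per-column scaling applied to the raw
    covariates so inflection points can be mapped back to the original axis:
    ``raw = scaled * scale[0] + center[0]``.
    """

    values: np.ndarray
    column_names: list
    center: np.ndarray
    scale: np.ndarray
    interest_column: int = 0

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.values.shape[1]

    def to_raw_interest(self, x_scaled):
        """Back-transform a value on the scaled interest axis to the raw scale."""
        return np.asarray(x_scaled) * self.scale[self.interest_column] + self.center[
            self.interest_column
        ]


def _encode_column(col: pd.Series) -> np.ndarray:
    if pd.api.types.is_numeric_dtype(col):
        return col.to_numpy(dtype=float)
    levels = sorted(col.astype(str).unique())
    if len(levels) != 2:
        raise InvalidArgumentError(
            f"factor covariate '{col.name}' must have exactly two levels, got {levels}"
        )
    return np.where(col.astype(str) == levels[1], 0.5, -0.5)


def build_design(
    metadata: pd.DataFrame,
    interest: str,
    nuisance: list | None = None,
    sample_ids: list | None = None,
) -> DesignMatrix:
    """Build the scaled design matrix from a sample metadata table.

    Continuous covariates are centred and scaled to unit standard deviation;
    two-level factors are coded -0.5/+0.5 and then centred and scaled the same
    way.  The covariate of interest is placed first and there is no intercept
    column.  ``sample_ids`` (e.g. the count-matrix columns) fixes the row
    order; every id must be present in the metadata.
    """
    nuisance = list(nuisance or [])
    names = [interest, *nuisance]
    for name in names:
        if name not in metadata.columns:
            raise InvalidArgumentError(f"covariate column '{name}' missing from metadata")
        if metadata[name].isna().any():
            raise InvalidArgumentError(f"covariate column '{name}' has missing values")
    if sample_ids is not None:
        index = metadata.index.astype(str)
        missing = [s for s in map(str, sample_ids) if s not in set(index)]
        if missing:
            raise InvalidArgumentError(f"samples missing from metadata: {missing}")
        metadata = metadata.loc[[str(s) for s in sample_ids]]

    columns, centers, scales = [], [], []
    for name in names:
        raw = _encode_column(metadata[name])
        sd = np.std(raw, ddof=1)
        if not sd > 0:
            raise InvalidArgumentError(f"covariate '{name}' is constant")
        centers.append(raw.mean())
        scales.append(sd)
        columns.append((raw - raw.mean()) / sd)
    return DesignMatrix(
        values=np.column_stack(columns),
        column_names=names,
        center=np.array(centers),
        scale=np.array(scales),
    )


def partition_genes(counts: pd.DataFrame, block_size: int) -> list:
    """Split genes into contiguous blocks of at most ``block_size``."""
    if block_size < 1:
        raise InvalidArgumentError("block_size must be >= 1")
    return [counts.iloc[i : i + block_size] for i in range(0, counts.shape[0], block_size)]


@dataclass
class FitConfig:
    """Sampler and blocking configuration.

    Defaults are 4 chains of 1000 warmup + 1000 sampling draws at target
    acceptance 0.95 (the heavy-tailed horseshoe geometry needs a conservative
    step size), genes fit in input-order blocks of 5000.
    """

    seed: int
    chains: int = 4
    warmup_draws: int = 1000
    sampling_draws: int = 1000
    block_size: int = 5000
    target_accept: float = 0.95
    max_treedepth: int = 10
    shuffle_genes: bool = False
    horseshoe: HorseshoeConfig = field(default_factory=HorseshoeConfig)

    def __post_init__(self):
        if self.chains < 1 or self.warmup_draws < 0 or self.sampling_draws < 1:
            raise InvalidArgumentError("chains and draw counts must be positive")
        if self.block_size < 1:
            raise InvalidArgumentError("block_size must be >= 1")
        if not 0.0 < self.target_accept < 1.0:
            raise InvalidArgumentError("target_accept must lie in (0, 1)")


@dataclass
class FitResult:
    """Posterior draws, summaries and diagnostics for one fit.

    Gene-level draw arrays are (chains, draws, genes[, nuisance]); block-level
    arrays carry an extra leading block axis after the draw axes, e.g.
    ``delta`` is (chains, draws, blocks, samples).  ``summaries`` is an
    equal-tailed quantile table with split-Rhat and effective sample size.
    """

    gene_ids: list
    sample_ids: list
    gene_block: np.ndarray
    draws: dict
    summaries: pd.DataFrame
    diagnostics: dict
    design: DesignMatrix
    config: FitConfig
    data_digest: str

    @property
    def n_chains(self) -> int:
        return self.draws["beta1"].shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws["beta1"].shape[1]

    def flat(self, name: str) -> np.ndarray:
        """Draws for ``name`` with chain and draw axes merged."""
        arr = self.draws[name]
        return arr.reshape(arr.shape[0] * arr.shape[1], *arr.shape[2:])

    def gene_delta(self) -> np.ndarray:
        """Exposure draws aligned per gene: (chain*draw, samples, genes)."""
        delta = self.flat("delta")  # (n, blocks, T)
        return delta[:, self.gene_block, :].transpose(0, 2, 1)

    def gene_omega(self) -> np.ndarray:
        """Overdispersion draws aligned per gene: (chain*draw, genes)."""
        return self.flat("omega")[:, self.gene_block]

    def save(self, outdir) -> None:
        from . import io as _io

        _io.save_fit(self, outdir)


def _constrain_block(model: UnconstrainedModel, draws: np.ndarray) -> dict:
    """Vectorised unconstrained -> natural-space transform for a draw matrix."""
    z1 = draws[:, model._z1]
    lam = np.exp(draws[:, model._u])
    tau = np.exp(draws[:, model._v][:, 0])
    c = np.sqrt(np.exp(draws[:, model._w][:, 0]))
    sigma = np.exp(draws[:, model._ls])
    out = {
        "beta1": z1 * regularized_scales(lam, tau[:, None], c[:, None]),
        "y0": np.exp(draws[:, model._q]),
        "eta": draws[:, model._eta],
        "beta_nuis": draws[:, model._zn].reshape(-1, model.G, model.K)
        * sigma[:, None, :],
        "hs_local": lam,
        "delta": draws[:, model._d],
        "omega": np.exp(draws[:, model._lo][:, 0]),
        "sigma": sigma,
        "hs_tau": tau,
        "hs_c2": np.exp(draws[:, model._w][:, 0]),
        "gamma1": np.exp(draws[:, model._g1][:, 0]),
        "gamma2": np.exp(draws[:, model._g2][:, 0]),
    }
    return out


def _summarise(draws: dict, gene_ids, sample_ids, column_names, gene_block) -> pd.DataFrame:
    import warnings

    names, labels, mats = [], [], []

    def add(name, arr, label):
        names.append(name)
        labels.append(label)
        mats.append(arr)

    for g, gid in enumerate(gene_ids):
        add("beta1", draws["beta1"][:, :, g], str(gid))
        add("y0", draws["y0"][:, :, g], str(gid))
        add("eta", draws["eta"][:, :, g], str(gid))
        for k in range(draws["beta_nuis"].shape[-1]):
            add("beta_nuis", draws["beta_nuis"][:, :, g, k], f"{gid}:{column_names[k + 1]}")
    n_blocks = draws["delta"].shape[2]
    for b in range(n_blocks):
        tag = f"block{b}:" if n_blocks > 1 else ""
        for t, sid in enumerate(sample_ids):
            add("delta", draws["delta"][:, :, b, t], f"{tag}{sid}")
        add("omega", draws["omega"][:, :, b], f"{tag}omega")
        for k in range(draws["sigma"].shape[-1]):
            add("sigma", draws["sigma"][:, :, b, k], f"{tag}{column_names[k + 1]}")
        add("hs_tau", draws["hs_tau"][:, :, b], f"{tag}tau")
        add("hs_c2", draws["hs_c2"][:, :, b], f"{tag}c2")

    stacked = np.stack(mats, axis=-1)  # (C, S, P)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import arviz as az

        data = az.convert_to_dataset(stacked)
        rhat = az.rhat(data)["x"].values.ravel()
        ess = az.ess(data)["x"].values.ravel()
    flat = stacked.reshape(-1, stacked.shape[-1])
    q = np.quantile(flat, [0.025, 0.5, 0.975], axis=0)
    return pd.DataFrame(
        {
            "parameter": names,
            "label": labels,
            "mean": flat.mean(axis=0),
            "q2.5": q[0],
            "q50": q[1],
            "q97.5": q[2],
            "rhat": rhat,
            "ess_bulk": ess,
        }
    )


def _digest(counts: pd.DataFrame, design: DesignMatrix) -> str:
    h = hashlib.sha256()
    h.update(counts.to_csv(sep="\t").encode())
    h.update(np.ascontiguousarray(design.values).tobytes())
    return h.hexdigest()[:16]


def fit(counts: pd.DataFrame, design: DesignMatrix, cfg: FitConfig) -> FitResult:
    """Sample the posterior of the joint model; blocks are fit independently.

    ``counts`` is genes x samples (already zero-filtered); ``design`` the
    scaled design matrix with matching sample order.  Identical seed, config
    and data give identical draws.  Raises :class:`FitError` when any block
    has more than 10% divergent transitions or a chain cannot be initialised.
    """
    if counts.shape[1] != design.n_samples:
        raise InvalidArgumentError("counts and design disagree on sample count")
    values = counts.to_numpy()
    if np.any(values < 0) or not np.all(np.equal(np.mod(values, 1), 0)):
        raise InvalidArgumentError("counts must be non-negative integers")

    order = np.arange(counts.shape[0])
    if cfg.shuffle_genes:
        order = np.random.default_rng(
            np.random.SeedSequence(entropy=cfg.seed, spawn_key=(999,))
        ).permutation(order)
    ordered = counts.iloc[order]
    blocks = partition_genes(ordered, cfg.block_size)
    logger.info(
        "fitting %d genes x %d samples in %d block(s)",
        counts.shape[0], counts.shape[1], len(blocks),
    )

    per_block = []
    diagnostics = {"blocks": []}
    for b, block in enumerate(blocks):
        model = UnconstrainedModel(block, design, cfg.horseshoe)
        chain_draws, block_diag = [], {"chains": []}
        for c in range(cfg.chains):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=cfg.seed, spawn_key=(b, c))
            )
            theta0 = model.initial_point(rng)
            try:
                draws, stats = sample_nuts(
                    model.logp_grad,
                    theta0,
                    cfg.warmup_draws,
                    cfg.sampling_draws,
                    rng,
                    target_accept=cfg.target_accept,
                    max_treedepth=cfg.max_treedepth,
                )
            except ValueError as exc:
                raise FitError(f"block {b} chain {c}: {exc}", diagnostics) from exc
            chain_draws.append(draws)
            block_diag["chains"].append(
                {
                    "divergences": stats.divergences,
                    "step_size": stats.step_size,
                    "mean_accept": stats.mean_accept,
                    "max_treedepth_hits": stats.max_treedepth_hits,
                }
            )
            logger.info(
                "block %d chain %d: %d divergence(s), step size %.3g, accept %.2f",
                b, c, stats.divergences, stats.step_size, stats.mean_accept,
            )
        n_div = sum(ch["divergences"] for ch in block_diag["chains"])
        frac_div = n_div / (cfg.chains * cfg.sampling_draws)
        block_diag["divergent_fraction"] = frac_div
        diagnostics["blocks"].append(block_diag)
        if frac_div > MAX_DIVERGENT_FRACTION:
            raise FitError(
                f"block {b}: {frac_div:.0%} divergent transitions exceeds "
                f"{MAX_DIVERGENT_FRACTION:.0%}",
                diagnostics,
            )
        constrained = [_constrain_block(model, ch) for ch in chain_draws]
        per_block.append(
            {k: np.stack([c[k] for c in constrained]) for k in GENE_PARAMS + BLOCK_PARAMS}
        )

    # concatenate gene-level draws over blocks, stack block-level draws
    draws = {}
    for name in GENE_PARAMS:
        draws[name] = np.concatenate([pb[name] for pb in per_block], axis=2)
    for name in BLOCK_PARAMS:
        arrs = [pb[name] for pb in per_block]
        arrs = [a[..., None] if a.ndim == 2 else a for a in arrs]  # scalars -> (C,S,1)
        draws[name] = np.stack(arrs, axis=2)
        if name in ("omega", "hs_tau", "hs_c2", "gamma1", "gamma2"):
            draws[name] = draws[name][..., 0]

    # undo the (optional) shuffle so genes come back in input order
    inverse = np.argsort(order)
    for name in GENE_PARAMS:
        draws[name] = np.ascontiguousarray(draws[name][:, :, inverse])
    block_of_gene = np.concatenate(
        [np.full(len(b), i) for i, b in enumerate(blocks)]
    )[inverse]

    gene_ids = list(counts.index)
    sample_ids = list(counts.columns)
    summaries = _summarise(draws, gene_ids, sample_ids, design.column_names, block_of_gene)
    diagnostics["divergent_fraction"] = max(
        bd["divergent_fraction"] for bd in diagnostics["blocks"]
    )
    diagnostics["max_rhat"] = float(summaries["rhat"].max())
    logger.info(
        "fit complete: max divergent fraction %.3f, max rhat %.3f",
        diagnostics["divergent_fraction"], diagnostics["max_rhat"],
    )
    return FitResult(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        gene_block=block_of_gene,
        draws=draws,
        summaries=summaries,
        diagnostics=diagnostics,
        design=design,
        config=cfg,
        data_digest=_digest(counts, design),
    )
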