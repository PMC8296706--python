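"""Reading and writing the tool's on-disk formats.

Count matrices are TSV/CSV (first column gene id, remaining columns sample
ids, integer cells) or MatrixMarket triplets with ``.rows``/``.cols`` sidecar
name files.  Fit results serialise to a directory: draws as a compressed
columnar archive, summaries as TSV, the configuration echoed as YAML and a
manifest with provenance (seed, digests, versions).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .inference import DesignMatrix, FitConfig, FitResult
from .model import HorseshoeConfig
from .sigmoid import InvalidArgumentError

__all__ = [
    "read_counts",
    "write_counts",
    "read_metadata",
    "save_fit",
    "load_fit",
]


def read_counts(path) -> pd.DataFrame:
    """Read a genes x samples count matrix (TSV/CSV or MatrixMarket)."""
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy import io as spio

        mat = spio.mmread(path)
        rows = Path(str(path) + ".rows")
        cols = Path(str(path) + ".cols")
        if not rows.exists() or not cols.exists():
            raise InvalidArgumentError(
                f"MatrixMarket input needs sidecar files {rows.name} and {cols.name}"
            )
        gene_ids = rows.read_text().split()
        sample_ids = cols.read_text().split()
        counts = pd.DataFrame(
            np.asarray(mat.todense()), index=gene_ids, columns=sample_ids
        )
    else:
        sep = "," if path.suffix == ".csv" else "\t"
        counts = pd.read_csv(path, sep=sep, index_col=0)
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise InvalidArgumentError("count matrix has non-numeric cells")
    if np.any(values < 0) or not np.all(np.equal(np.mod(values, 1), 0)):
        raise InvalidArgumentError("count matrix must contain non-negative integers")
    return counts.astype(np.int64)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_metadata(path) -> pd.DataFrame:
    """Read the sample metadata table; first column is the sample id."""
    path = Path(path)
    sep = "," if path.suffix == ".csv" else "\t"
    meta = pd.read_csv(path, sep=sep, index_col=0)
    meta.index = meta.index.astype(str)
    if meta.index.duplicated().any():
        raise InvalidArgumentError("metadata contains duplicated sample ids")
    return meta


def _config_dict(cfg: FitConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d


def save_fit(fit: FitResult, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(outdir / "draws.npz", **fit.draws)
    fit.summaries.to_csv(outdir / "summaries.tsv", sep="\t", index=False)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(_config_dict(fit.config), fh, sort_keys=True)
    manifest = {
        "gene_ids": list(map(str, fit.gene_ids)),
        "sample_ids": list(map(str, fit.sample_ids)),
        "gene_block": fit.gene_block.tolist(),
        "diagnostics": fit.diagnostics,
        "data_digest": fit.data_digest,
        "design": {
            "values": fit.design.values.tolist(),
            "column_names": list(fit.design.column_names),
            "center": fit.design.center.tolist(),
            "scale": fit.design.scale.tolist(),
            "interest_column": fit.design.interest_column,
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def load_fit(indir) -> FitResult:
    indir = Path(indir)
    for name in ("draws.npz", "summaries.tsv", "config.yaml", "manifest.json"):
        if not (indir / name).exists():
            raise InvalidArgumentError(f"fit directory is incomplete: missing {name}")
    with np.load(indir / "draws.npz") as npz:
        draws = {k: npz[k] for k in npz.files}
    summaries = pd.read_csv(indir / "summaries.tsv", sep="\t")
    with open(indir / "config.yaml") as fh:
        raw_cfg = yaml.safe_load(fh)
    hs = raw_cfg.pop("horseshoe", {})
    cfg = FitConfig(horseshoe=HorseshoeConfig(**hs), **raw_cfg)
    with open(indir / "manifest.json") as fh:
        manifest = json.load(fh)
    design = DesignMatrix(
        values=np.array(manifest["design"]["values"]),
        column_names=manifest["design"]["column_names"],
        center=np.array(manifest["design"]["center"]),
        scale=np.array(manifest["design"]["scale"]),
        interest_column=manifest["design"]["interest_column"],
    )
    return FitResult(
        gene_ids=manifest["gene_ids"],
        sample_ids=manifest["sample_ids"],
        gene_block=np.array(manifest["gene_block"]),
        draws=draws,
        summaries=summaries,
        diagnostics=manifest["diagnostics"],
        design=design,
        config=cfg,
        data_digest=manifest["data_digest"],
    )
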