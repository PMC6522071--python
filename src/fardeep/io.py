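"""Readers and writers for signature/mixture tables and run outputs.

Inputs are delimited text with a header row: the first column holds gene
ids, remaining columns are cell types (signature) or sample ids (mixture).
The delimiter is chosen by extension (``.csv`` comma, anything else tab)
unless overridden.  Outputs are tab-separated with a JSON run manifest.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .deconvolve import DeconvolutionResult, collapse_duplicate_genes, results_to_frames

logger = logging.getLogger(__name__)

__all__ = ["read_signature", "read_mixture", "write_results"]


def _detect_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_matrix(path: str | Path, delimiter: str | None, what: str) -> pd.DataFrame:
    path = Path(path)
    sep = _detect_delimiter(path, delimiter)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:
        raise ValueError(f"cannot parse {what} file {path}: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{what} file {path} is empty")
    df = df.apply(pd.to_numeric, errors="coerce")
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)][:5].tolist()
        raise ValueError(
            f"{what} file {path} has non-numeric or missing entries (e.g. rows {bad})"
        )
    if not np.isfinite(df.to_numpy()).all():
        raise ValueError(f"{what} file {path} contains non-finite values")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return collapse_duplicate_genes(df)


def read_signature(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Load a genes-x-cell-types signature matrix.

    Values must be finite and non-negative (linear-scale expression) with at
    least two cell types.
    """
    df = _read_matrix(path, delimiter, "signature")
    if df.shape[1] < 2:
        raise ValueError("signature matrix needs at least 2 cell types")
    if (df.to_numpy() < 0).any():
        raise ValueError("signature matrix has negative entries; linear-scale expression expected")
    return df


def read_mixture(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Load a genes-x-samples mixture matrix (finite values, unique samples)."""
    df = _read_matrix(path, delimiter, "mixture")
    if df.columns.duplicated().any():
        raise ValueError("mixture matrix has duplicate sample ids")
    return df


def write_results(
    results: list[DeconvolutionResult],
    outdir: str | Path,
    *,
    manifest_extra: dict | None = None,
) -> dict[str, Path]:
    """Write the three output tables plus a machine-readable manifest.

    ``scores.tsv`` (sample, cell_type, score, relative — 6 significant
    digits), ``samples.tsv`` (chosen k, outlier and iteration counts),
    ``outlier_genes.tsv`` (sample, gene, residual), and ``manifest.json``
    carrying every parameter and the full-precision scores.  Nothing is
    written when ``results`` is empty.
    """
    if not results:
        raise ValueError("no results to write")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scores, summary, outliers = results_to_frames(results)
    paths = {
        "scores": outdir / "scores.tsv",
        "samples": outdir / "samples.tsv",
        "outliers": outdir / "outlier_genes.tsv",
        "manifest": outdir / "manifest.json",
    }
    scores.to_csv(paths["scores"], sep="\t", index=False, float_format="%.6g")
    summary.to_csv(paths["samples"], sep="\t", index=False, float_format="%.6g")
    outliers.to_csv(paths["outliers"], sep="\t", index=False, float_format="%.6g")

    from . import __version__

    manifest = {
        "tool": "fardeep",
        "version": __version__,
        "python": platform.python_version(),
        "samples": {
            res.sample_id: {
                "chosen_k": res.chosen_k,
                "n_outliers": res.n_outliers,
                "n_iter": res.n_iter,
                "n_genes_used": res.n_genes_used,
                "error": res.error,
                "cell_types": res.cell_types,
                "subset_scores": [float(s) for s in res.subset_scores],
                "relative": None if res.relative is None else [float(r) for r in res.relative],
            }
            for res in results
        },
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    logger.info("wrote %d sample result(s) to %s", len(results), outdir)
    return paths
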