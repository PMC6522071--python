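"""End-to-end robust deconvolution of bulk expression mixtures.

Given a signature matrix (genes x cell types, linear-scale reference
expression) and a mixture matrix (genes x samples), each sample is modeled
as a non-negative combination of the cell-type signatures plus a sparse
outlier vector.  Per sample, the trimming sensitivity ``k`` is tuned by
BIC*, the adaptive trimmed NNLS is fit, and the coefficient vector is
reported as an absolute "subset score" per cell type alongside its
normalization to relative abundances.

No global rescaling or Z-normalization is ever applied to mixture columns;
the absolute scale of the scores is meaningful.  Optional quantile
normalization across samples is available for microarray-style mixtures and
is off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alts import ALTSParams, alts_fit
from .tuning import default_k_grid, tune_k

logger = logging.getLogger(__name__)

__all__ = [
    "DeconvolutionResult",
    "collapse_duplicate_genes",
    "intersect_genes",
    "quantile_normalize",
    "relative_abundance",
    "score_summation",
    "fardeep",
    "results_to_frames",
]


@dataclass
class DeconvolutionResult:
    """Per-sample deconvolution output.

    ``relative`` is ``None`` (not NaNs) when every score is zero.  A failed
    sample carries the failure message in ``error`` and NaN scores; other
    samples are unaffected.
    """

    sample_id: str
    cell_types: list[str]
    subset_scores: np.ndarray
    relative: np.ndarray | None
    chosen_k: float
    n_outliers: int
    outlier_genes: list[str]
    n_iter: int
    n_genes_used: int
    outlier_residuals: list[float] = field(default_factory=list)
    error: str | None = None


def collapse_duplicate_genes(mat: pd.DataFrame) -> pd.DataFrame:
    """Average rows sharing a gene id (case-insensitively).

    The first-seen spelling of each id is kept verbatim; row order follows
    first occurrence.
    """
    keys = mat.index.astype(str).str.upper()
    if keys.is_unique:
        return mat
    n_dups = int(keys.duplicated().sum())
    logger.warning("collapsing %d duplicate gene id(s) by mean", n_dups)
    first_spelling = {}
    for orig, key in zip(mat.index.astype(str), keys):
        first_spelling.setdefault(key, orig)
    out = mat.groupby(keys, sort=False).mean()
    out.index = [first_spelling[k] for k in out.index]
    return out


def intersect_genes(
    sig: pd.DataFrame, mix: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Align signature and mixture on shared gene ids.

    Matching is exact after case folding; duplicate ids on either side are
    collapsed by mean first.  Row order follows the signature matrix.
    Fails hard when fewer than ``2 p`` genes are shared (underdetermined)
    and warns when less than a quarter of the signature is matched.
    """
    sig = collapse_duplicate_genes(sig)
    mix = collapse_duplicate_genes(mix)
    mix_by_key = {k: i for i, k in enumerate(mix.index.astype(str).str.upper())}
    sig_keys = sig.index.astype(str).str.upper()
    rows_sig, rows_mix = [], []
    for i, key in enumerate(sig_keys):
        j = mix_by_key.get(key)
        if j is not None:
            rows_sig.append(i)
            rows_mix.append(j)
    p = sig.shape[1]
    if len(rows_sig) < 2 * p:
        raise ValueError(
            f"only {len(rows_sig)} genes shared between signature and mixture; "
            f"need at least 2 x p = {2 * p}"
        )
    if len(rows_sig) < 0.25 * sig.shape[0]:
        logger.warning(
            "only %d of %d signature genes matched the mixture (<25%%)",
            len(rows_sig), sig.shape[0],
        )
    sig_a = sig.iloc[rows_sig]
    mix_a = mix.iloc[rows_mix]
    genes = list(sig_a.index.astype(str))
    logger.info("%d shared genes used for deconvolution", len(genes))
    return sig_a, mix_a, genes


def quantile_normalize(mat: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Classic quantile normalization of a genes-x-samples matrix.

    Every column's sorted values are replaced by the across-column mean of
    sorted values, mapped back through each column's ranks; tied ranks
    receive the average of the tied reference values.  A single-column input
    is returned unchanged.
    """
    vals = np.asarray(mat, dtype=float) if not isinstance(mat, pd.DataFrame) else mat.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("non-finite entries in matrix")
    n, s = vals.shape
    if s < 2:
        return mat.copy() if isinstance(mat, pd.DataFrame) else vals.copy()
    reference = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    positions = np.arange(1, n + 1, dtype=float)
    from scipy.stats import rankdata

    for j in range(s):
        ranks = rankdata(vals[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, reference)
    if isinstance(mat, pd.DataFrame):
        return pd.DataFrame(out, index=mat.index, columns=mat.columns)
    return out


def relative_abundance(scores: np.ndarray) -> np.ndarray | None:
    """Rescale non-negative subset scores to sum to one.

    Returns ``None`` when every score is zero — relative composition is
    undefined there, and NaNs would silently propagate.
    """
    scores = np.asarray(scores, dtype=float)
    if np.any(scores < 0):
        raise ValueError("subset scores must be non-negative")
    total = scores.sum()
    if total == 0.0:
        return None
    return scores / total


def score_summation(result: DeconvolutionResult, subset: list[str]) -> float:
    """Sum the scores of the named cell types (e.g. an anti-tumor panel).

    With ``subset`` equal to all cell types this is the total infiltration
    score.
    """
    lookup = {ct: s for ct, s in zip(result.cell_types, result.subset_scores)}
    unknown = [name for name in subset if name not in lookup]
    if unknown:
        raise KeyError(
            f"unknown cell type(s) {unknown}; valid names: {result.cell_types}"
        )
    return float(sum(lookup[name] for name in subset))


def fardeep(
    sig: pd.DataFrame,
    mix: pd.DataFrame,
    *,
    params: ALTSParams | None = None,
    fixed_k: float | None = None,
    k_grid: np.ndarray | None = None,
    bic_variant: str = "log_scale",
    quantile_normalization: bool = False,
) -> list[DeconvolutionResult]:
    """Deconvolve every mixture sample against the signature matrix.

    Samples are processed independently: optional quantile normalization is
    computed across all mixture columns up front (before gene intersection),
    then per sample ``k`` is tuned by BIC* (unless ``fixed_k`` is given) and
    the trimmed NNLS is fit.  Detected outlier rows are mapped back to gene
    ids.  A failure in one sample is recorded in its result and does not
    abort the others.
    """
    if params is None:
        params = ALTSParams()
    if not params.nonneg:
        raise ValueError("deconvolution requires the non-negative solver")
    if k_grid is None:
        k_grid = default_k_grid()
    if float(np.nanmax(mix.to_numpy(dtype=float))) < 50:
        logger.warning(
            "mixture maximum is below 50; data may be log-transformed, but "
            "linear-scale expression is expected"
        )
    if quantile_normalization:
        mix = quantile_normalize(mix)
    sig_a, mix_a, genes = intersect_genes(sig, mix)
    X = sig_a.to_numpy(dtype=float)
    cell_types = list(sig_a.columns.astype(str))
    gene_arr = np.asarray(genes)

    results: list[DeconvolutionResult] = []
    for sample in mix_a.columns:
        y = mix_a[sample].to_numpy(dtype=float)
        try:
            if fixed_k is not None:
                fit = alts_fit(X, y, ALTSParams(
                    k=fixed_k, alpha1=params.alpha1, alpha2=params.alpha2,
                    nonneg=True, intercept=params.intercept,
                    max_outlier_frac=params.max_outlier_frac,
                    median_floor=params.median_floor,
                ))
                chosen_k = fixed_k
            else:
                tuned = tune_k(X, y, k_grid, params, variant=bic_variant, label=str(sample))
                fit = tuned.best_fit
                chosen_k = tuned.best_k
            scores = fit.beta
            results.append(DeconvolutionResult(
                sample_id=str(sample),
                cell_types=cell_types,
                subset_scores=scores,
                relative=relative_abundance(scores),
                chosen_k=float(chosen_k),
                n_outliers=fit.n_outliers,
                outlier_genes=[str(g) for g in gene_arr[fit.outlier_index]],
                n_iter=fit.n_iter,
                n_genes_used=len(genes),
                outlier_residuals=[float(r) for r in fit.residuals[fit.outlier_index]],
            ))
            logger.info(
                "sample %s: k=%.3g, %d outlier gene(s), %d iteration(s)",
                sample, chosen_k, fit.n_outliers, fit.n_iter,
            )
        except Exception as exc:  # per-sample isolation
            logger.error("sample %s failed: %s", sample, exc)
            results.append(DeconvolutionResult(
                sample_id=str(sample),
                cell_types=cell_types,
                subset_scores=np.full(len(cell_types), np.nan),
                relative=None,
                chosen_k=float("nan"),
                n_outliers=0,
                outlier_genes=[],
                n_iter=0,
                n_genes_used=len(genes),
                error=str(exc),
            ))
    return results


def results_to_frames(
    results: list[DeconvolutionResult],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Tidy tables: (scores, per-sample summary, outlier genes)."""
    score_rows, summary_rows, outlier_rows = [], [], []
    for res in results:
        for ct, sc in zip(res.cell_types, res.subset_scores):
            rel = np.nan
            if res.relative is not None:
                rel = res.relative[res.cell_types.index(ct)]
            score_rows.append({
                "sample": res.sample_id, "cell_type": ct,
                "score": sc, "relative": rel,
            })
        summary_rows.append({
            "sample": res.sample_id, "chosen_k": res.chosen_k,
            "n_outliers": res.n_outliers, "n_iter": res.n_iter,
            "n_genes_used": res.n_genes_used,
            "error": res.error if res.error else "",
        })
        residuals = res.outlier_residuals or [np.nan] * len(res.outlier_genes)
        for g, r in zip(res.outlier_genes, residuals):
            outlier_rows.append({"sample": res.sample_id, "gene": g, "residual": r})
    cols_out = ["sample", "gene", "residual"]
    return (
        pd.DataFrame(score_rows),
        pd.DataFrame(summary_rows),
        pd.DataFrame(outlier_rows, columns=cols_out),
    )
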