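"""Sample-level PCA on log-CPM for quality control.

Projects samples onto principal components of the gene space to check that
replicates cluster, pools separate, and treatments structure the variance —
the standard first diagnostic on a polysome-profiling count matrix. Runs on
log2-CPM (prior 0.5), centered per gene, optionally unit-variance scaled;
zero-variance genes are dropped with a log note. A deterministic sign
convention (the largest-magnitude loading of each component is positive)
keeps coordinates reproducible across runs and BLAS builds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .normalization import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["PCAResult", "PCAError", "pca"]


class PCAError(ValueError):
    pass


@dataclass(frozen=True)
class PCAResult:
    """Sample coordinates, per-component variance fractions and gene loadings."""

    coordinates: pd.DataFrame        # samples x components
    variance_fraction: np.ndarray    # length k, non-increasing
    loadings: pd.DataFrame           # genes x components, orthonormal columns
    centered: bool
    scaled: bool


def pca(
    expr: ExpressionMatrix,
    center: bool = True,
    scale: bool = False,
    k: int | None = None,
    subset=None,
) -> PCAResult:
    """PCA of samples in gene space via SVD of the (centered) data.

    Parameters
    ----------
    expr
        A log-scale expression matrix (genes x samples).
    k
        Number of components; defaults to full rank.
    subset
        Optional predicate on sample id restricting which samples enter.
    """
    if not expr.log_scale:
        raise PCAError("pca expects a log-scale expression matrix")
    df = expr.values
    if subset is not None:
        keep = [s for s in df.columns if subset(s)]
        df = df[keep]
    x = df.to_numpy().T.astype(float)  # samples x genes
    n_samples = x.shape[0]
    if n_samples < 2:
        raise PCAError("pca needs at least 2 samples")

    gene_var = x.var(axis=0)
    nz = gene_var > 0
    if scale and not nz.any():
        raise PCAError("all genes have zero variance; cannot scale")
    if (~nz).any():
        logger.info("dropping %d zero-variance genes before PCA", int((~nz).sum()))
        x = x[:, nz]
        gene_var = gene_var[nz]
    gene_ids = df.index[nz]

    if center:
        x = x - x.mean(axis=0)
    if scale:
        x = x / np.sqrt(x.var(axis=0, ddof=1))

    max_rank = min(x.shape[0] - (1 if center else 0), x.shape[1])
    if k is None:
        k = max_rank
    if not 1 <= k <= max_rank:
        raise PCAError(f"k must be in [1, {max_rank}], got {k}")

    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # deterministic orientation: largest-magnitude loading entry positive
    for j in range(vt.shape[0]):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0

    total_var = float((s ** 2).sum())
    var_frac = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    coords = u[:, :k] * s[:k]
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        coordinates=pd.DataFrame(coords, index=df.columns, columns=comp_names),
        variance_fraction=var_frac,
        loadings=pd.DataFrame(vt[:k].T, index=gene_ids, columns=comp_names),
        centered=bool(center),
        scaled=bool(scale),
    )
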