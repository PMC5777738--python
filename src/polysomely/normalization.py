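"""Between-sample normalization: TMM scaling factors and (log-)CPM.

TMM (trimmed mean of M-values) computes, for each sample against a reference
sample, precision-weighted mean log2 expression ratios over genes surviving a
double trim — 30% on the log-ratio (M) and 5% on absolute expression (A) by
default. The resulting factors correct for composition bias: a few highly
expressed genes inflating one library's total would otherwise depress the
apparent expression of everything else in that sample. Factors are rescaled
to geometric mean 1 so they are comparable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counts_io import CountMatrix

__all__ = ["NormFactors", "ExpressionMatrix", "tmm_factors", "cpm", "NormalizationError"]


class NormalizationError(ValueError):
    pass


@dataclass(frozen=True)
class NormFactors:
    """Per-sample TMM scaling factors and library sizes.

    ``factors`` have geometric mean 1; ``factors * library_sizes`` are the
    effective library sizes used everywhere downstream.
    """

    sample_ids: tuple[str, ...]
    factors: np.ndarray
    library_sizes: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.factors, dtype=float)
        if not np.all(np.isfinite(f)) or np.any(f <= 0):
            raise NormalizationError("normalization factors must be finite and positive")

    @property
    def effective_library_sizes(self) -> np.ndarray:
        return self.factors * self.library_sizes

    def for_samples(self, sample_ids) -> "NormFactors":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return NormFactors(
            tuple(sample_ids), self.factors[idx].copy(), self.library_sizes[idx].copy()
        )


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene-by-sample CPM or log2-CPM values with provenance flags."""

    values: pd.DataFrame
    log_scale: bool
    prior: float


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """Log2 TMM factor of one sample against the reference.

    Uses genes positive in both libraries; drops the most extreme trim_m
    fraction of M-values and trim_a fraction of A-values on each side; returns
    the weighted mean M with inverse asymptotic (delta-method binomial)
    variance weights.
    """
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        raise NormalizationError(
            "sample shares no positively expressed gene with the reference; "
            "filter low-expression genes or choose another reference"
        )
    y_s = obs[pos].astype(float)
    y_r = ref[pos].astype(float)
    p_s = y_s / lib_obs
    p_r = y_r / lib_ref
    m = np.log2(p_s / p_r)
    a = 0.5 * np.log2(p_s * p_r)
    w = 1.0 / ((lib_obs - y_s) / (lib_obs * y_s) + (lib_ref - y_r) / (lib_ref * y_r))

    n = m.size
    lo_m, hi_m = int(np.floor(n * trim_m)) + 1, n - int(np.floor(n * trim_m))
    lo_a, hi_a = int(np.floor(n * trim_a)) + 1, n - int(np.floor(n * trim_a))
    # rank-based double trim; ranks are 1-based, ties broken by first occurrence
    rank_m = m.argsort(kind="stable").argsort(kind="stable") + 1
    rank_a = a.argsort(kind="stable").argsort(kind="stable") + 1
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 0.0
    f = float(np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
    return 0.0 if not np.isfinite(f) else f


def _auto_reference(arr: np.ndarray, lib: np.ndarray) -> int:
    """Sample whose upper-quartile proportion is closest to the mean across samples."""
    q75 = np.array([np.quantile(arr[:, j] / lib[j], 0.75) for j in range(arr.shape[1])])
    return int(np.argmin(np.abs(q75 - q75.mean())))


def tmm_factors(
    counts: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    reference: str | None = None,
) -> NormFactors:
    """TMM normalization factors for every sample of a count matrix.

    Parameters
    ----------
    trim_m, trim_a
        Two-sided trim fractions on the log-ratio and average-expression
        scales (published defaults 0.30 and 0.05).
    reference
        Sample id to normalize against; by default the sample whose 75th
        percentile of count proportions is closest to the across-sample mean.
    """
    arr = counts.values.to_numpy().astype(float)
    n_samples = arr.shape[1]
    if n_samples < 2:
        raise NormalizationError("TMM requires at least 2 samples")
    lib = arr.sum(axis=0)
    if np.any(lib <= 0):
        bad = counts.sample_ids[np.flatnonzero(lib <= 0)[0]]
        raise NormalizationError(f"sample {bad!r} has zero library size")
    if reference is None:
        ref_idx = _auto_reference(arr, lib)
    else:
        try:
            ref_idx = list(counts.sample_ids).index(reference)
        except ValueError:
            raise NormalizationError(f"unknown reference sample {reference!r}") from None

    log_f = np.zeros(n_samples)
    for j in range(n_samples):
        if j == ref_idx:
            continue
        log_f[j] = _tmm_pair(arr[:, j], arr[:, ref_idx], lib[j], lib[ref_idx], trim_m, trim_a)
    factors = 2.0 ** log_f
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean 1
    return NormFactors(tuple(map(str, counts.sample_ids)), factors, lib)


def cpm(
    counts: CountMatrix,
    factors: NormFactors | None = None,
    prior: float = 0.5,
    log_scale: bool = False,
) -> ExpressionMatrix:
    """Counts per million on TMM-effective library sizes.

    Linear scale with ``prior == 0`` is the plain definition
    ``y / (f * L) * 1e6``. On the log scale the prior count is rescaled per
    sample in proportion to its effective library size relative to the mean,
    and added to both numerator and (doubled, to the) denominator, keeping
    log2 values finite at zero counts while preserving cross-sample
    comparability.
    """
    if prior < 0:
        raise NormalizationError("prior count must be non-negative")
    arr = counts.values.to_numpy().astype(float)
    if factors is None:
        eff = arr.sum(axis=0)
    else:
        got = tuple(map(str, counts.sample_ids))
        if got != factors.sample_ids:
            factors = factors.for_samples(got)
        eff = factors.effective_library_sizes
    if log_scale:
        # prior scaled per sample as in standard log-CPM practice
        scaled_prior = prior * eff / eff.mean()
        vals = np.log2((arr + scaled_prior) / (eff + 2.0 * scaled_prior) * 1e6)
    else:
        if prior == 0:
            vals = arr / eff * 1e6
        else:
            scaled_prior = prior * eff / eff.mean()
            vals = (arr + scaled_prior) / (eff + 2.0 * scaled_prior) * 1e6
    df = pd.DataFrame(vals, index=counts.gene_ids, columns=counts.sample_ids)
    return ExpressionMatrix(df, log_scale=log_scale, prior=float(prior))
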