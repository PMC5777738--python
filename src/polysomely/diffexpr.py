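"""Negative-binomial differential expression for two-group contrasts.

Each contrast compares one treatment with the control (normoxia) within one
cell line and one RNA pool (total T or polysomal P). The model is the standard
RNA-seq negative binomial with variance = mean + phi * mean^2; phi = 0
recovers Poisson. Dispersion is estimated per gene by method of moments on
the normalized scale and shrunk toward the common value; significance comes
from an exact-style conditional test: libraries are equalized to a common
effective size, and the conditional distribution of the treatment-group sum
given the pooled total is enumerated under the null of equal means.

The design is deliberately a collection of two-group comparisons rather than
a GLM: every contrast in the study is treatment-vs-control within one
(cell line, pool) stratum, so the simpler exact test applies directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .counts_io import CountMatrix, SampleDesign
from .normalization import NormFactors

__all__ = [
    "DispersionEstimates",
    "DEResult",
    "DiffExprError",
    "filter_low_expression",
    "estimate_dispersions",
    "test_contrast",
    "bh_adjust",
]


class DiffExprError(ValueError):
    pass


@dataclass(frozen=True)
class DispersionEstimates:
    """Per-gene NB dispersions, their common value, and the shrinkage prior."""

    gene_ids: tuple[str, ...]
    common: float
    per_gene: np.ndarray
    prior_df: float

    def __post_init__(self) -> None:
        d = np.asarray(self.per_gene)
        if (d < 0).any() or not np.all(np.isfinite(d)):
            raise DiffExprError("dispersions must be finite and non-negative")


@dataclass(frozen=True)
class DEResult:
    """Per-gene log2 fold change, p-value and BH FDR for one contrast.

    ``table`` columns: gene_id, log2FC, pvalue, fdr, mean_abundance.
    Genes removed upstream by filtering are simply absent.
    """

    table: pd.DataFrame
    cell_line: str
    pool: str
    treatment: str
    control: str

    def gene_ids(self) -> pd.Index:
        return pd.Index(self.table["gene_id"])

    def to_frame(self) -> pd.DataFrame:
        df = self.table.copy()
        df["cell_line"] = self.cell_line
        df["pool"] = self.pool
        df["treatment"] = self.treatment
        df["control"] = self.control
        return df


# ---------------------------------------------------------------------------
# expression filter


def filter_low_expression(
    counts: CountMatrix,
    design: SampleDesign | None = None,
    min_cpm: float = 1.0,
    min_samples: int | None = None,
) -> CountMatrix:
    """Keep genes reaching ``min_cpm`` (plain library-size CPM, factor 1) in at
    least ``min_samples`` samples; gene order is preserved.

    ``min_samples`` defaults to the smallest experimental group size in the
    design (or 1 without a design).
    """
    if design is not None:
        design.check_matches(counts)
    n_total = counts.shape[1]
    if min_samples is None:
        if design is not None:
            sizes = design.table.groupby(
                ["cell_line", "treatment", "pool"], sort=False
            ).size()
            min_samples = int(sizes.min())
        else:
            min_samples = 1
    if min_samples > n_total:
        raise DiffExprError(
            f"min_samples={min_samples} exceeds total sample count {n_total}"
        )
    if min_cpm <= 0:
        return counts
    arr = counts.values.to_numpy().astype(float)
    lib = arr.sum(axis=0)
    cpm = arr / lib * 1e6
    keep = (cpm >= min_cpm).sum(axis=1) >= min_samples
    return CountMatrix(counts.values.loc[keep])


# ---------------------------------------------------------------------------
# dispersion estimation


def estimate_dispersions(
    counts: CountMatrix,
    design: SampleDesign,
    factors: NormFactors,
    prior_df: float = 10.0,
) -> DispersionEstimates:
    """Method-of-moments NB dispersions with shrinkage toward the common value.

    Within each (cell line, treatment, pool) group with >= 2 replicates,
    counts are put on a common scale by dividing by relative effective
    library sizes; the MoM estimate per gene pools the group-wise statistic
    phi = (s^2 - mbar) / mbar^2, floored at zero. The final per-gene value is
    a precision-weighted compromise ``(prior_df * common + df_g * phi_g) /
    (prior_df + df_g)`` — genes with little replication stay near the common
    dispersion, well-replicated genes keep their own.
    """
    design.check_matches(counts)
    factors = factors.for_samples(tuple(map(str, counts.sample_ids)))
    arr = counts.values.to_numpy().astype(float)
    eff = factors.effective_library_sizes
    scaled = arr / (eff / eff.mean())  # counts on a common library scale

    sample_pos = {s: i for i, s in enumerate(counts.sample_ids)}
    groups = []
    for _, sub in design.table.groupby(["cell_line", "treatment", "pool"], sort=False):
        idx = [sample_pos[s] for s in sub["sample_id"]]
        if len(idx) >= 2:
            groups.append(idx)
    if not groups:
        raise DiffExprError(
            "no experimental group has >= 2 replicates; supply a fixed dispersion"
        )

    n_genes = arr.shape[0]
    num = np.zeros(n_genes)  # pooled (s2 - m) estimates weighted by df
    den = np.zeros(n_genes)
    df_g = np.zeros(n_genes)
    for idx in groups:
        sub = scaled[:, idx]
        m = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        ok = m > 0
        contrib = np.zeros(n_genes)
        contrib[ok] = (s2[ok] - m[ok]) / m[ok] ** 2
        w = float(len(idx) - 1)
        num += np.where(ok, contrib * w, 0.0)
        den += np.where(ok, w, 0.0)
        df_g += np.where(ok, w, 0.0)
    phi_mom = np.zeros(n_genes)
    nz = den > 0
    phi_mom[nz] = np.maximum(0.0, num[nz] / den[nz])

    common = float(np.average(phi_mom[nz], weights=den[nz])) if nz.any() else 0.0
    common = max(0.0, common)
    shrunk = (prior_df * common + df_g * phi_mom) / np.maximum(prior_df + df_g, 1e-12)
    shrunk = np.maximum(shrunk, 0.0)
    return DispersionEstimates(
        tuple(map(str, counts.gene_ids)), common, shrunk, float(prior_df)
    )


# ---------------------------------------------------------------------------
# exact-style conditional test


def _round_half_even(x: np.ndarray) -> np.ndarray:
    return np.rint(x)


def _nb_logpmf(x: np.ndarray, mean: float, phi: float) -> np.ndarray:
    """log PMF of NB with variance mean + phi*mean^2; Poisson at phi == 0."""
    if phi <= 0:
        return stats.poisson.logpmf(x, mean)
    r = 1.0 / phi
    p = r / (r + mean)
    return stats.nbinom.logpmf(x, r, p)


def _exact_pvalue(s1: int, s2: int, n1: int, n2: int, phi: float) -> float:
    """Two-sided conditional test of equal NB means.

    Group sums of n iid NB(mu, phi) are NB(n*mu, phi/n). Conditioning on the
    pooled total removes the nuisance mean; the p-value sums the conditional
    probabilities of all outcomes no more probable than the observed one
    (with 1e-12 slack for probability ties).
    """
    total = s1 + s2
    if total == 0:
        return 1.0
    mu = total / (n1 + n2)  # per-sample null mean
    x = np.arange(total + 1)
    lp = _nb_logpmf(x, n1 * mu, phi / n1) + _nb_logpmf(total - x, n2 * mu, phi / n2)
    lp -= np.max(lp)
    p = np.exp(lp)
    p /= p.sum()
    p_obs = p[s1]
    return float(min(1.0, p[p <= p_obs + 1e-12].sum()))


def test_contrast(
    counts: CountMatrix,
    design: SampleDesign,
    factors: NormFactors,
    dispersions: DispersionEstimates,
    cell_line: str,
    pool: str,
    treatment: str,
    control: str = "N",
    prior_count: float = 0.5,
) -> DEResult:
    """Differential expression of ``treatment`` vs ``control`` within one
    cell line and RNA pool.

    log2FC uses prior-count-moderated normalized group means; the p-value is
    the exact conditional NB test on counts rescaled (half-to-even) to the
    mean effective library size of the contrast's samples; FDR is BH over all
    genes of the contrast.
    """
    design.check_matches(counts)
    if tuple(map(str, counts.gene_ids)) != dispersions.gene_ids:
        raise DiffExprError("gene universe mismatch between counts and dispersions")
    treat_ids = design.samples_for(cell_line, treatment, pool)
    ctrl_ids = design.samples_for(cell_line, control, pool)
    if not treat_ids or not ctrl_ids:
        raise DiffExprError(
            f"contrast ({cell_line}, {pool}, {treatment} vs {control}) has an empty group"
        )
    factors = factors.for_samples(tuple(map(str, counts.sample_ids)))
    sample_pos = {s: i for i, s in enumerate(counts.sample_ids)}
    it = [sample_pos[s] for s in treat_ids]
    ic = [sample_pos[s] for s in ctrl_ids]
    arr = counts.values.to_numpy().astype(float)
    eff = factors.effective_library_sizes
    sel = it + ic
    common_lib = eff[sel].mean()
    # equalize libraries: proportional rescale to the common size, half-to-even
    eq = _round_half_even(arr[:, sel] * (common_lib / eff[sel])).astype(np.int64)
    n1 = len(it)
    n2 = len(ic)
    s1 = eq[:, :n1].sum(axis=1)
    s2 = eq[:, n1:].sum(axis=1)

    phi = dispersions.per_gene
    pvals = np.array(
        [_exact_pvalue(int(a), int(b), n1, n2, float(f)) for a, b, f in zip(s1, s2, phi)]
    )

    # moderated log2 fold change on normalized means
    norm = arr / (eff / eff.mean())
    mean_t = norm[:, it].mean(axis=1)
    mean_c = norm[:, ic].mean(axis=1)
    log2fc = np.log2(mean_t + prior_count) - np.log2(mean_c + prior_count)
    mean_ab = norm[:, sel].mean(axis=1)

    table = pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "log2FC": log2fc,
            "pvalue": pvals,
            "fdr": bh_adjust(pvals),
            "mean_abundance": mean_ab,
        }
    ).reset_index(drop=True)
    return DEResult(table, cell_line, pool, treatment, control)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in the input order.

    adjusted_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise DiffExprError("bh_adjust expects a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise DiffExprError("p-values must lie in [0, 1] and not be NaN")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out
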