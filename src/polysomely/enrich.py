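"""Gene-set over-representation by the hypergeometric upper tail.

Given a query gene list (e.g. translationally activated genes of one
contrast), a background universe (by default all genes surviving the
expression filter — the statistically defensible background, since only
those genes could have entered the query), and a GMT collection, each set is
tested with the one-sided hypergeometric test P(X >= k | N, K, n). Raw-p
significance flags at the classic presentation thresholds (0.03 GO-style,
0.1 pathway-style) are reported alongside a BH FDR at 0.05, which is the
recommended criterion.

This replaces web-service enrichment (DAVID-style) with an explicit,
reproducible statistic; note DAVID's EASE score is a more conservative
modified Fisher test, so borderline sets can differ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .counts_io import GeneSetCollection
from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)

__all__ = ["EnrichmentTable", "EnrichError", "hypergeom_tail", "overrepresentation"]


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k | N, K, n).

    The probability that a size-n draw from a universe of N genes, K of
    which belong to the set, contains at least k set members.
    """
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 0.0), 1.0)


class EnrichError(ValueError):
    pass


@dataclass(frozen=True)
class EnrichmentTable:
    """Per-set overlap statistics, hypergeometric p and BH FDR.

    ``table`` columns: set_name, overlap (k), set_size (K), query_size (n),
    universe_size (N), pvalue, fdr, significant_raw, significant_fdr,
    overlap_genes (comma-joined ids).
    """

    table: pd.DataFrame
    p_threshold: float
    fdr_threshold: float


def overrepresentation(
    query: set[str],
    universe: set[str],
    sets: GeneSetCollection,
    p_threshold: float = 0.03,
    fdr_threshold: float = 0.05,
) -> EnrichmentTable:
    """Test every gene set for over-representation in the query.

    Sets are intersected with the universe before testing; sets left empty by
    the intersection are skipped with a log note. The query must be a subset
    of the universe.
    """
    query = set(query)
    universe = set(universe)
    stray = query - universe
    if stray:
        raise EnrichError(f"query genes outside the universe: {sorted(stray)}")
    n_univ = len(universe)
    n_query = len(query)

    rows = []
    for name, members in sets:
        in_univ = set(members) & universe
        if not in_univ:
            logger.info("gene set %r has no overlap with the universe; skipped", name)
            continue
        overlap = sorted(query & in_univ)
        k, K = len(overlap), len(in_univ)
        p = hypergeom_tail(k, n_univ, K, n_query)
        rows.append(
            {
                "set_name": name,
                "overlap": k,
                "set_size": K,
                "query_size": n_query,
                "universe_size": n_univ,
                "pvalue": p,
                "overlap_genes": ",".join(overlap),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "set_name", "overlap", "set_size", "query_size",
            "universe_size", "pvalue", "overlap_genes",
        ],
    )
    if len(df):
        df["fdr"] = bh_adjust(df["pvalue"].to_numpy())
    else:
        df["fdr"] = pd.Series(dtype=float)
    df["significant_raw"] = df["pvalue"] < p_threshold
    df["significant_fdr"] = df["fdr"] < fdr_threshold
    df = df[
        [
            "set_name", "overlap", "set_size", "query_size", "universe_size",
            "pvalue", "fdr", "significant_raw", "significant_fdr", "overlap_genes",
        ]
    ].sort_values("pvalue", kind="stable").reset_index(drop=True)
    return EnrichmentTable(df, float(p_threshold), float(fdr_threshold))
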