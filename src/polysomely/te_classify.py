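"""Translational-efficiency scoring and transcriptional/translational
classification of genes.

For each treatment-vs-control contrast the polysomal (P) and total (T)
fold changes of the same gene are combined into a per-gene translational
efficiency statistic Te. Two modes exist:

* ``ratio`` — Te = log2FC_P / log2FC_T, the literal published formula.
  Genes whose total fold change is numerically near zero are excluded (the
  ratio is undefined), and |Te| is winsorized before z-scoring so single
  near-zero denominators cannot dominate the spread.
* ``difference`` — Te = log2FC_P - log2FC_T (delta-TE), the numerically
  stable alternative: no exclusions, no sign confounding when both fold
  changes are negative.

Te values are z-scored across the selected gene set of the contrast; genes
with z above / below ±1.5 (default) are called translationally activated /
inactivated. The four-way gene classification layers the translational call
over transcriptional significance in both pools.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexpr import DEResult

__all__ = [
    "TeTable",
    "GeneClassTable",
    "VennCounts",
    "TeError",
    "select_polysome_significant",
    "compute_te",
    "zscore_te",
    "classify_translational",
    "classify_four_way",
    "intersect_sets",
]


class TeError(ValueError):
    pass


@dataclass(frozen=True)
class TeTable:
    """Per-gene Te, z-score and translational call for one contrast.

    ``table`` columns: gene_id, log2FC_P, log2FC_T, te, zscore, call,
    exclusion_reason. ``call`` is one of activated / inactivated / unchanged /
    excluded; z-scores are NaN until :func:`zscore_te` runs.
    """

    table: pd.DataFrame
    mode: str
    cell_line: str
    treatment: str
    z_threshold: float | None = None


@dataclass(frozen=True)
class GeneClassTable:
    """Four-way class per gene with the evidence used.

    ``table`` columns: gene_id, gene_class, fdr_T, fdr_P, log2FC_T, log2FC_P,
    zscore. Classes: transcriptional, transcriptional_no_translation,
    translational, non_significant — a partition of the tested universe.
    """

    table: pd.DataFrame
    cell_line: str
    treatment: str


@dataclass(frozen=True)
class VennCounts:
    """Exact intersection-region counts and members for 2-4 named sets."""

    set_names: tuple[str, ...]
    regions: dict[tuple[bool, ...], frozenset[str]]

    @property
    def union_size(self) -> int:
        return sum(len(m) for m in self.regions.values())

    def count(self, *names: str) -> int:
        """Size of the region belonging to exactly the given sets."""
        mask = tuple(n in names for n in self.set_names)
        return len(self.regions.get(mask, frozenset()))

    def members(self, *names: str) -> frozenset[str]:
        mask = tuple(n in names for n in self.set_names)
        return self.regions.get(mask, frozenset())

    def report(self) -> str:
        lines = [f"sets: {', '.join(self.set_names)}", f"union: {self.union_size}"]
        for mask in sorted(self.regions, reverse=True):
            names = [n for n, m in zip(self.set_names, mask) if m]
            members = sorted(self.regions[mask])
            lines.append(f"[{' & '.join(names)}] n={len(members)}: {' '.join(members)}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------


def select_polysome_significant(de_p: DEResult, fdr_threshold: float) -> set[str]:
    """Genes significant in the polysomal pool at FDR strictly below the
    threshold (0.05 for the non-tumoural line, 0.10 for the tumoural line in
    the original study)."""
    if not 0 < fdr_threshold <= 1:
        raise TeError(f"fdr_threshold must be in (0, 1], got {fdr_threshold}")
    if de_p.pool != "P":
        raise TeError(f"expected a polysomal (P) result, got pool {de_p.pool!r}")
    t = de_p.table
    return set(t.loc[t["fdr"] < fdr_threshold, "gene_id"])


def compute_te(
    de_p: DEResult,
    de_t: DEResult,
    genes,
    mode: str = "ratio",
    denom_tolerance: float = 1e-8,
    te_cap: float = 50.0,
) -> TeTable:
    """Translational efficiency for the given genes of one contrast.

    Ratio mode divides the polysomal by the total log2 fold change and
    excludes genes with |log2FC_T| < ``denom_tolerance``; |Te| is capped at
    ``te_cap`` (winsorized) ahead of z-scoring. Difference mode subtracts and
    never excludes.
    """
    if mode not in ("ratio", "difference"):
        raise TeError(f"unknown Te mode {mode!r}")
    if (de_p.cell_line, de_p.treatment) != (de_t.cell_line, de_t.treatment):
        raise TeError("P and T results must come from the same cell line and treatment")
    if de_p.pool != "P" or de_t.pool != "T":
        raise TeError("compute_te expects (P-pool, T-pool) results in that order")
    genes = list(genes)
    p_tab = de_p.table.set_index("gene_id")
    t_tab = de_t.table.set_index("gene_id")
    missing = [g for g in genes if g not in p_tab.index or g not in t_tab.index]
    if missing:
        raise TeError(f"genes absent from one pool's result: {sorted(missing)}")
    fc_p = p_tab.loc[genes, "log2FC"].to_numpy()
    fc_t = t_tab.loc[genes, "log2FC"].to_numpy()

    te = np.full(len(genes), np.nan)
    call = np.array(["unchanged"] * len(genes), dtype=object)
    reason = np.array([""] * len(genes), dtype=object)
    if mode == "ratio":
        bad = np.abs(fc_t) < denom_tolerance
        ok = ~bad
        te[ok] = fc_p[ok] / fc_t[ok]
        te[ok] = np.clip(te[ok], -te_cap, te_cap)
        call[bad] = "excluded"
        reason[bad] = "zero_denominator"
    else:
        te = fc_p - fc_t

    table = pd.DataFrame(
        {
            "gene_id": genes,
            "log2FC_P": fc_p,
            "log2FC_T": fc_t,
            "te": te,
            "zscore": np.nan,
            "call": call,
            "exclusion_reason": reason,
        }
    )
    return TeTable(table, mode, de_p.cell_line, de_p.treatment)


def zscore_te(te: TeTable) -> TeTable:
    """z-score the Te values over non-excluded genes (sample SD, n-1)."""
    tab = te.table.copy()
    ok = tab["call"] != "excluded"
    vals = tab.loc[ok, "te"].to_numpy()
    if vals.size < 2:
        raise TeError("z-scoring needs at least 2 non-excluded genes")
    sd = vals.std(ddof=1)
    if sd == 0:
        raise TeError("degenerate Te distribution: all values identical")
    tab.loc[ok, "zscore"] = (vals - vals.mean()) / sd
    return TeTable(tab, te.mode, te.cell_line, te.treatment, te.z_threshold)


def classify_translational(te: TeTable, z_threshold: float = 1.5) -> TeTable:
    """Call genes translationally activated (z > threshold) or inactivated
    (z < -threshold); both inequalities strict, boundary genes stay
    unchanged. Excluded genes keep their exclusion."""
    if z_threshold <= 0:
        raise TeError(f"z_threshold must be positive, got {z_threshold}")
    tab = te.table.copy()
    if tab.loc[tab["call"] != "excluded", "zscore"].isna().any():
        raise TeError("z-scores missing: run zscore_te first")
    ok = tab["call"] != "excluded"
    z = tab["zscore"]
    tab.loc[ok, "call"] = "unchanged"
    tab.loc[ok & (z > z_threshold), "call"] = "activated"
    tab.loc[ok & (z < -z_threshold), "call"] = "inactivated"
    return TeTable(tab, te.mode, te.cell_line, te.treatment, float(z_threshold))


def classify_four_way(
    de_t: DEResult,
    de_p: DEResult,
    te: TeTable,
    fdr_threshold: float,
    z_threshold: float = 1.5,
) -> GeneClassTable:
    """Four-way classification of every tested gene.

    Precedence: (a) translational — |z| beyond the threshold (the
    translational call wins over any transcriptional evidence);
    (b) transcriptional — significant in both pools with concordant fold-
    change signs; (c) transcriptional_no_translation — significant in the
    total pool only; (d) non_significant otherwise. The classes partition the
    gene universe of the contrast.
    """
    if not 0 < fdr_threshold <= 1:
        raise TeError(f"fdr_threshold must be in (0, 1], got {fdr_threshold}")
    t_tab = de_t.table.set_index("gene_id")
    p_tab = de_p.table.set_index("gene_id")
    if set(t_tab.index) != set(p_tab.index):
        raise TeError("T and P results cover different gene universes")
    universe = list(t_tab.index)
    z = te.table.set_index("gene_id")["zscore"].reindex(universe)

    fdr_t = t_tab.loc[universe, "fdr"].to_numpy()
    fdr_p = p_tab.loc[universe, "fdr"].to_numpy()
    fc_t = t_tab.loc[universe, "log2FC"].to_numpy()
    fc_p = p_tab.loc[universe, "log2FC"].to_numpy()
    zv = z.to_numpy()

    cls = np.array(["non_significant"] * len(universe), dtype=object)
    sig_t = fdr_t < fdr_threshold
    sig_p = fdr_p < fdr_threshold
    cls[sig_t & ~sig_p] = "transcriptional_no_translation"
    cls[sig_t & sig_p & (np.sign(fc_t) == np.sign(fc_p))] = "transcriptional"
    translational = np.abs(np.nan_to_num(zv, nan=0.0)) > z_threshold
    cls[translational] = "translational"

    table = pd.DataFrame(
        {
            "gene_id": universe,
            "gene_class": cls,
            "fdr_T": fdr_t,
            "fdr_P": fdr_p,
            "log2FC_T": fc_t,
            "log2FC_P": fc_p,
            "zscore": zv,
        }
    )
    return GeneClassTable(table, de_t.cell_line, de_t.treatment)


def intersect_sets(named_sets: dict[str, set[str]]) -> VennCounts:
    """Exact Venn-region decomposition of 2-4 named gene sets."""
    names = tuple(named_sets)
    if not 2 <= len(names) <= 4:
        raise TeError(f"intersect_sets needs 2-4 sets, got {len(names)}")
    sets = [set(named_sets[n]) for n in names]
    union = set().union(*sets)
    regions: dict[tuple[bool, ...], set[str]] = {}
    for g in union:
        mask = tuple(g in s for s in sets)
        regions.setdefault(mask, set()).add(g)
    return VennCounts(names, {m: frozenset(v) for m, v in regions.items()})
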