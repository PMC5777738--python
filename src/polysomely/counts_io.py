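"""Reading, validation and writing of count matrices, sample sheets and gene sets.

The pipeline starts from a gene-by-sample table of integer read counts
(e.g. RSEM gene-level quantification collapsed to integers), a sample sheet
describing each library (cell line, treatment, RNA pool, replicate), and
optional gene-set collections in GMT format for over-representation analysis.

All tables are plain tab-separated UTF-8 text with LF line endings on write;
CRLF is tolerated on read. Gene and sample identifiers are opaque strings —
no identifier mapping is attempted.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_POOLS = ("T", "P")

__all__ = [
    "CountMatrix",
    "SampleDesign",
    "GeneSetCollection",
    "CountsError",
    "DesignError",
    "GmtError",
    "read_counts",
    "write_counts",
    "read_counts_mtx",
    "read_design",
    "write_design",
    "read_gmt",
    "write_gmt",
    "write_table",
]


class CountsError(ValueError):
    """Raised for malformed or invalid count matrices."""


class DesignError(ValueError):
    """Raised for malformed or invalid sample sheets."""


class GmtError(ValueError):
    """Raised for malformed GMT gene-set files."""


@dataclass(frozen=True)
class CountMatrix:
    """Non-negative integer gene-by-sample count table.

    Attributes
    ----------
    values : pandas.DataFrame
        Integer counts, index = gene ids, columns = sample ids.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise CountsError(f"duplicate gene identifiers: {dup}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()].unique().tolist()
            raise CountsError(f"duplicate sample identifiers: {dup}")
        arr = df.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            raise CountsError("count matrix must hold integer values")
        if arr.size and (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise CountsError(
                f"negative count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def library_sizes(self) -> np.ndarray:
        """Column sums as float64."""
        return self.values.to_numpy().sum(axis=0).astype(float)

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(self.values.loc[list(gene_ids)])

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(self.values[list(sample_ids)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self.values.equals(other.values)


@dataclass(frozen=True)
class SampleDesign:
    """Per-sample experimental factors.

    One row per library: sample_id, cell_line, treatment, pool (T = total
    RNA, P = polysome-bound RNA), replicate. The first treatment encountered
    is not special here; contrasts name their own control.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "cell_line", "treatment", "pool", "replicate")

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise DesignError(f"sample sheet missing required columns: {missing}")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise DesignError(f"duplicate sample ids: {dup}")
        bad_pool = sorted(set(df["pool"]) - set(VALID_POOLS))
        if bad_pool:
            raise DesignError(
                f"unknown pool label(s) {bad_pool}; allowed values are {set(VALID_POOLS)}"
            )
        key = df[["cell_line", "treatment", "pool", "replicate"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].to_dict("records")
            raise DesignError(f"duplicate (cell_line, treatment, pool, replicate): {dup}")

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.table["sample_id"])

    @property
    def cell_lines(self) -> list[str]:
        return list(dict.fromkeys(self.table["cell_line"]))

    @property
    def treatments(self) -> list[str]:
        return list(dict.fromkeys(self.table["treatment"]))

    def samples_for(self, cell_line=None, treatment=None, pool=None) -> list[str]:
        """Sample ids matching the given factor levels (None = any)."""
        df = self.table
        mask = pd.Series(True, index=df.index)
        if cell_line is not None:
            mask &= df["cell_line"] == cell_line
        if treatment is not None:
            mask &= df["treatment"] == treatment
        if pool is not None:
            mask &= df["pool"] == pool
        return df.loc[mask, "sample_id"].tolist()

    def check_matches(self, counts: CountMatrix) -> None:
        """Require the sheet's sample ids to match the matrix columns exactly."""
        sheet = set(self.sample_ids)
        cols = set(counts.sample_ids)
        if sheet != cols:
            raise DesignError(
                f"sample sheet / count matrix mismatch: only in sheet {sorted(sheet - cols)}, "
                f"only in matrix {sorted(cols - sheet)}"
            )


@dataclass
class GeneSetCollection:
    """Named gene sets with optional free-text descriptions."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise GmtError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


# ---------------------------------------------------------------------------
# count matrix I/O


def read_counts(path, *, allow_fractional: bool = False) -> CountMatrix:
    """Read a tab-separated gene-by-sample count matrix.

    First column holds gene ids, header row holds sample ids. Values must be
    non-negative integers; RSEM-style fractional expected counts are accepted
    only with ``allow_fractional=True``, in which case they are rounded
    half-to-even.
    """
    with open(path, "r", encoding="utf-8", newline=None) as fh:
        return _parse_counts(fh, allow_fractional=allow_fractional, source=str(path))


def _parse_counts(fh, *, allow_fractional: bool, source: str) -> CountMatrix:
    header = fh.readline().rstrip("\n").rstrip("\r")
    if not header:
        raise CountsError(f"{source}: empty file")
    cols = header.split("\t")[1:]
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(fh, start=2):
        line = line.rstrip("\n").rstrip("\r")
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != len(cols) + 1:
            raise CountsError(
                f"{source}:{lineno}: expected {len(cols) + 1} fields, got {len(parts)}"
            )
        gene_ids.append(parts[0])
        try:
            vals = [float(v) for v in parts[1:]]
        except ValueError as exc:
            raise CountsError(f"{source}:{lineno}: non-numeric value ({exc})") from None
        rows.append(vals)
    arr = np.asarray(rows, dtype=float) if rows else np.empty((0, len(cols)))
    if np.isnan(arr).any():
        g, s = np.argwhere(np.isnan(arr))[0]
        raise CountsError(
            f"{source}: missing value at gene {gene_ids[g]!r}, sample {cols[s]!r}"
        )
    if (arr < 0).any():
        g, s = np.argwhere(arr < 0)[0]
        raise CountsError(
            f"{source}: negative value at gene {gene_ids[g]!r}, sample {cols[s]!r}"
        )
    frac = arr != np.floor(arr)
    if frac.any():
        if not allow_fractional:
            g, s = np.argwhere(frac)[0]
            raise CountsError(
                f"{source}: non-integer value {arr[g, s]} at gene {gene_ids[g]!r}, "
                f"sample {cols[s]!r} (pass allow_fractional=True to round half-to-even)"
            )
        # numpy rint rounds half to even
        arr = np.rint(arr)
    df = pd.DataFrame(arr.astype(np.int64), index=pd.Index(gene_ids, name="gene_id"), columns=cols)
    return CountMatrix(df)


def write_counts(counts: CountMatrix, path) -> None:
    """Write a count matrix as tab-separated text (UTF-8, LF)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_id\t" + "\t".join(map(str, counts.sample_ids)) + "\n")
        arr = counts.values.to_numpy()
        for gid, row in zip(counts.gene_ids, arr):
            fh.write(str(gid) + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_counts_mtx(mtx_path, genes_path, samples_path) -> CountMatrix:
    """Read counts from a MatrixMarket triplet (matrix + row-id + column-id files)."""
    from scipy.io import mmread

    mat = mmread(mtx_path)
    arr = np.asarray(mat.todense() if hasattr(mat, "todense") else mat)
    with open(genes_path, encoding="utf-8") as fh:
        genes = [ln.strip() for ln in fh if ln.strip()]
    with open(samples_path, encoding="utf-8") as fh:
        samples = [ln.strip() for ln in fh if ln.strip()]
    if arr.shape != (len(genes), len(samples)):
        raise CountsError(
            f"MTX shape {arr.shape} does not match {len(genes)} gene ids x "
            f"{len(samples)} sample ids"
        )
    if (arr != np.floor(arr)).any() or (arr < 0).any():
        raise CountsError("MTX matrix must contain non-negative integers")
    df = pd.DataFrame(arr.astype(np.int64), index=pd.Index(genes, name="gene_id"), columns=samples)
    return CountMatrix(df)


# ---------------------------------------------------------------------------
# sample sheet I/O


def read_design(path) -> SampleDesign:
    """Read a tab-separated sample sheet with columns
    sample_id, cell_line, treatment, pool, replicate."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SampleDesign.REQUIRED if c not in df.columns]
    if missing:
        raise DesignError(f"{path}: missing required columns {missing}")
    df["replicate"] = df["replicate"].astype(int)
    return SampleDesign(df[list(SampleDesign.REQUIRED)].copy())


def write_design(design: SampleDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name TAB description TAB member...``.

    Members are de-duplicated per set while preserving nothing about order
    (sets are unordered). An empty file yields an empty collection.
    """
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8", newline=None) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise GmtError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields "
                    f"(name, description, members), got {len(parts)}"
                )
            name, desc, *members = parts
            if name in sets:
                raise GmtError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = [m for m in members if m]
            if not members:
                raise GmtError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = frozenset(members)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, members in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def write_table(df: pd.DataFrame, path, *, header_comment: str | None = None) -> None:
    """Write a result table as TSV, optionally preceded by '#' comment lines."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if header_comment:
            for ln in header_comment.splitlines():
                fh.write(f"# {ln}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")
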