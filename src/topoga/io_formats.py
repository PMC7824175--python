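"""Readers and writers for the tabular dialects used throughout the package.

All matrices are kept in a canonical genes x cells (or genes x bins)
orientation regardless of how the file on disk is laid out.  Bin identity is
positional: bin *i* of the reference atlas is row *i* of the geometry file,
and no identifier column is trusted over file order.  Gene-name matching is
exact and case-sensitive (FlyBase symbols are case-meaningful, e.g. *Kr*
versus *kr*).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "BinaryAtlas",
    "Geometry",
    "GeneSet",
    "read_matrix",
    "write_matrix",
    "read_atlas",
    "read_geometry",
    "write_geometry",
    "read_gene_set",
    "write_gene_set",
    "read_annotation_map",
    "read_edge_list",
    "detect_delimiter",
]

Orientation = Literal["genes_in_rows", "genes_in_cols"]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for name in ids:
        if name in seen:
            raise ValueError(f"duplicate {what} identifier: {name!r}")
        seen.add(name)


@dataclass
class ExpressionMatrix:
    """Continuous expression, genes x cells (counts or normalized units)."""

    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.cell_ids)} cells)"
            )
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self, names: Iterable[str]) -> np.ndarray:
        """0-based row indices for *names*; missing genes raise by name."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        idx = []
        for name in names:
            if name not in lookup:
                raise KeyError(f"gene {name!r} not present in matrix")
            idx.append(lookup[name])
        return np.asarray(idx, dtype=int)


@dataclass
class BinaryAtlas:
    """In situ reference: genes x bins strictly 0/1 expression calls."""

    gene_ids: list[str]
    values: np.ndarray
    bin_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        _check_unique(self.gene_ids, "gene")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("atlas values must be strictly binary (0/1)")
        self.values = self.values.astype(np.int8)
        if self.values.shape[0] != len(self.gene_ids):
            raise ValueError("atlas row count does not match gene_ids")
        if not self.bin_ids:
            self.bin_ids = list(range(self.values.shape[1]))
        if len(self.bin_ids) != self.values.shape[1]:
            raise ValueError("bin_ids length does not match atlas columns")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def gene_index(self, names: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        idx = []
        for name in names:
            if name not in lookup:
                raise KeyError(f"gene {name!r} not present in atlas")
            idx.append(lookup[name])
        return np.asarray(idx, dtype=int)


@dataclass
class Geometry:
    """Bin coordinates, one (x, y, z) row per atlas bin, in atlas order."""

    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("geometry must be an n x 3 array of x,y,z")
        if not np.isfinite(self.coords).all():
            raise ValueError("geometry contains non-finite coordinates")

    @property
    def n_bins(self) -> int:
        return self.coords.shape[0]


@dataclass
class GeneSet:
    """Ordered collection of unique gene names."""

    names: list[str]

    def __post_init__(self) -> None:
        if len(self.names) == 0:
            raise ValueError("empty gene set")
        _check_unique(self.names, "gene-set")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def __contains__(self, name: str) -> bool:
        return name in set(self.names)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GeneSet) and self.names == other.names

    @property
    def size(self) -> int:
        return len(self.names)


def detect_delimiter(first_line: str) -> str | None:
    """Pick the delimiter from the first line: tab, then comma, then any
    whitespace (returned as None for the pandas whitespace engine)."""
    if "\t" in first_line:
        return "\t"
    if "," in first_line:
        return ","
    return None


def _read_table(path: str | Path, delimiter: str | None) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if delimiter is None:
        delimiter = detect_delimiter(first)
    kwargs: dict = {"index_col": 0}
    if delimiter is None:
        kwargs["sep"] = r"\s+"
    else:
        kwargs["sep"] = delimiter
    try:
        df = pd.read_csv(path, **kwargs)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ValueError(f"{path}: malformed table ({exc})") from exc
    return df


def _require_numeric(df: pd.DataFrame, path: str | Path) -> np.ndarray:
    values = df.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        coerced = df.apply(pd.to_numeric, errors="coerce")
        bad = coerced.isna() & df.notna()
        if bad.to_numpy().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise ValueError(
                f"{path}: non-numeric value {df.iat[r, c]!r} at "
                f"row {df.index[r]!r}, column {df.columns[c]!r}"
            )
        values = coerced.to_numpy()
    return values.astype(float)


def read_matrix(
    path: str | Path,
    orientation: Orientation = "genes_in_rows",
    delimiter: str | None = None,
) -> ExpressionMatrix:
    """Read a dge-style expression table into genes x cells orientation.

    The file must have a header row and a leading identifier column.  With
    ``orientation="genes_in_cols"`` the parsed table is transposed, so both
    layouts yield the same canonical matrix.
    """
    df = _read_table(path, delimiter)
    if orientation == "genes_in_cols":
        df = df.T
    gene_ids = [str(g) for g in df.index]
    cell_ids = [str(c) for c in df.columns]
    values = _require_numeric(df, path)
    return ExpressionMatrix(gene_ids=gene_ids, cell_ids=cell_ids, values=values)


def write_matrix(
    expr: ExpressionMatrix, path: str | Path, float_format: str = "%.6g"
) -> None:
    df = pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.cell_ids)
    df.to_csv(path, sep="\t", float_format=float_format)


def read_atlas(
    path: str | Path,
    orientation: Orientation = "genes_in_rows",
    delimiter: str | None = None,
) -> BinaryAtlas:
    """Read a binarized reference atlas (genes x bins, entries in {0,1}).

    The on-disk bdtnp dialect stores bins in rows and genes in columns;
    pass ``orientation="genes_in_cols"`` for that layout.  Bin identity is
    positional, matching geometry row order.
    """
    df = _read_table(path, delimiter)
    if orientation == "genes_in_cols":
        df = df.T
    values = _require_numeric(df, path)
    return BinaryAtlas(gene_ids=[str(g) for g in df.index], values=values)


def write_atlas(atlas: BinaryAtlas, path: str | Path) -> None:
    df = pd.DataFrame(
        atlas.values, index=atlas.gene_ids, columns=[str(b) for b in atlas.bin_ids]
    )
    df.to_csv(path, sep="\t")


def read_geometry(path: str | Path, delimiter: str | None = None) -> Geometry:
    """Read bin coordinates; row order is preserved exactly as in the file.

    Accepts an optional single header line; requires at least three numeric
    columns, of which the first three are taken as x, y, z.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty geometry file")
    if delimiter is None:
        delimiter = detect_delimiter(lines[0])

    def split(line: str) -> list[str]:
        return line.split(delimiter) if delimiter else line.split()

    start = 0
    first = split(lines[0])
    try:
        [float(tok) for tok in first[:3]]
    except ValueError:
        start = 1  # header line
    rows = []
    for lineno, line in enumerate(lines[start:], start=start + 1):
        toks = split(line)
        if len(toks) < 3:
            raise ValueError(f"{path}: line {lineno}: fewer than 3 columns")
        try:
            xyz = [float(t) for t in toks[:3]]
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: non-numeric value") from exc
        if not np.all(np.isfinite(xyz)):
            raise ValueError(f"{path}: line {lineno}: non-finite coordinate")
        rows.append(xyz)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return Geometry(coords=np.asarray(rows, dtype=float))


def write_geometry(geom: Geometry, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("x\ty\tz\n")
        for x, y, z in geom.coords:
            fh.write(f"{x:.10g}\t{y:.10g}\t{z:.10g}\n")


def read_gene_set(path: str | Path) -> GeneSet:
    """One gene name per line; order preserved, duplicates rejected."""
    path = Path(path)
    names = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not names:
        raise ValueError(f"{path}: empty gene set")
    return GeneSet(names=names)


def write_gene_set(gs: GeneSet, path: str | Path) -> None:
    Path(path).write_text("\n".join(gs.names) + "\n")


def read_annotation_map(path: str | Path) -> dict[str, set[str]]:
    """Two-column (gene, term) TSV flattened to term -> gene-name sets."""
    terms: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        toks = line.split("\t") if "\t" in line else line.split()
        if len(toks) < 2:
            raise ValueError(f"{path}: line {lineno}: expected gene<TAB>term")
        gene, term = toks[0], toks[1]
        terms.setdefault(term, set()).add(gene)
    if not terms:
        raise ValueError(f"{path}: empty annotation table")
    return terms


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Undirected gene-gene edges from a two/three-column table; self-loops
    are dropped.  A third (weight) column is ignored."""
    edges: list[tuple[str, str]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        toks = line.split("\t") if "\t" in line else line.split()
        if len(toks) < 2:
            raise ValueError(f"{path}: line {lineno}: expected two gene columns")
        a, b = toks[0], toks[1]
        if a == b:
            continue
        edges.append((a, b))
    return edges
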