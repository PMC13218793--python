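"""Expression-matrix and ligand-receptor table I/O.

Expression data are consumed as provided (no internal normalization);
library-size normalized, log-transformed input is the expected convention
for the downstream regression-based network estimation.

Supported on-disk formats:

* dense delimited (CSV/TSV): header row = gene names, first column = cell id;
* MatrixMarket coordinate (``.mtx``) with sidecar one-name-per-line gene and
  cell files;
* ligand-receptor pairs: two-column TSV with header ``ligand<TAB>receptor``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread


class DataFormatError(ValueError):
    """Structured parse/validation error naming the offending file or field."""


@dataclass
class ExpressionMatrix:
    """A cells x genes expression matrix with per-cell group labels.

    Attributes
    ----------
    values
        Dense float array, shape ``(n_cells, n_genes)``; non-negative
        expression levels (raw or normalized — treated as given).
    gene_names
        Ordered unique gene symbols (columns).
    cell_ids
        Ordered unique cell identifiers (rows).
    group_labels
        Per-cell categorical label, aligned to ``cell_ids``.
    """

    values: np.ndarray
    gene_names: list[str]
    cell_ids: list[str]
    group_labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.group_labels = np.asarray(self.group_labels, dtype=object)
        n, p = self.values.shape
        if len(self.cell_ids) != n:
            raise DataFormatError(
                f"{len(self.cell_ids)} cell ids for a matrix with {n} rows"
            )
        if len(self.gene_names) != p:
            raise DataFormatError(
                f"{len(self.gene_names)} gene names for a matrix with {p} columns"
            )
        if len(set(self.gene_names)) != p:
            raise DataFormatError("duplicate gene names")
        if len(set(self.cell_ids)) != n:
            raise DataFormatError("duplicate cell ids")
        if len(self.group_labels) != n:
            raise DataFormatError("group_labels length does not match cell count")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def groups(self) -> list[str]:
        """Distinct group labels, in order of first appearance."""
        return list(dict.fromkeys(self.group_labels))

    def group_view(self, group: str) -> "ExpressionMatrix":
        """Sub-matrix of the cells carrying ``group`` (copy)."""
        mask = self.group_labels == group
        if not mask.any():
            raise KeyError(f"no cells labeled {group!r}")
        return ExpressionMatrix(
            self.values[mask].copy(),
            list(self.gene_names),
            [c for c, m in zip(self.cell_ids, mask) if m],
            self.group_labels[mask].copy(),
        )

    def select_genes(self, genes: list[str]) -> "ExpressionMatrix":
        """Column subset in the given order (copy)."""
        idx = [self.gene_names.index(g) for g in genes]
        return ExpressionMatrix(
            self.values[:, idx].copy(),
            list(genes),
            list(self.cell_ids),
            self.group_labels.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_names)


@dataclass
class LigandReceptorDB:
    """Curated ligand-receptor gene pairs (CellPhoneDB-style export).

    The union of ligand and receptor symbols is the candidate gene universe
    for network estimation; a gene appearing on both sides enters once.
    """

    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for lig, rec in self.pairs:
            if not lig or not rec:
                raise DataFormatError("empty gene symbol in ligand-receptor pair")
            if (lig, rec) in seen:
                raise DataFormatError(f"duplicate ligand-receptor pair ({lig}, {rec})")
            seen.add((lig, rec))

    @property
    def universe(self) -> list[str]:
        """Ligand + receptor symbols, deduplicated, first-appearance order."""
        out: dict[str, None] = {}
        for lig, rec in self.pairs:
            out.setdefault(lig)
            out.setdefault(rec)
        return list(out)


def _read_names(path: Path, what: str) -> list[str]:
    names = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not names:
        raise DataFormatError(f"{path}: empty {what} name file")
    return names


def read_expression(
    matrix_path: str | Path,
    genes_path: str | Path | None,
    cells_path: str | Path | None,
    labels_path: str | Path,
) -> ExpressionMatrix:
    """Read an expression matrix plus cell-group annotations.

    ``matrix_path`` may be a dense delimited file (header = genes, first
    column = cell id; ``genes_path``/``cells_path`` then ignored) or a
    MatrixMarket ``.mtx`` triplet file with sidecar gene/cell name files.
    ``labels_path`` is a two-column delimited file mapping cell id -> group;
    every cell in the matrix must be labeled.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        if genes_path is None or cells_path is None:
            raise DataFormatError(
                f"{matrix_path}: MatrixMarket input requires gene and cell name files"
            )
        raw = mmread(matrix_path)
        values = np.asarray(
            raw.todense() if hasattr(raw, "todense") else raw, dtype=float
        )
        genes = _read_names(Path(genes_path), "gene")
        cells = _read_names(Path(cells_path), "cell")
        if values.shape != (len(cells), len(genes)):
            raise DataFormatError(
                f"{matrix_path}: matrix shape {values.shape} does not match "
                f"{len(cells)} cells x {len(genes)} genes"
            )
    else:
        sep = "\t" if matrix_path.suffix in {".tsv", ".tab"} else ","
        df = pd.read_csv(matrix_path, sep=sep, index_col=0)
        values = df.to_numpy(dtype=float)
        genes = [str(g) for g in df.columns]
        cells = [str(c) for c in df.index]

    labels_path = Path(labels_path)
    lab = pd.read_csv(
        labels_path, sep=None, engine="python", header=None, comment="#"
    )
    if lab.shape[1] < 2:
        raise DataFormatError(f"{labels_path}: expected two columns (cell_id, group)")
    first = str(lab.iloc[0, 0]).lower()
    if first in {"cell_id", "cell", "barcode"}:
        lab = lab.iloc[1:]
    mapping = dict(zip(lab.iloc[:, 0].astype(str), lab.iloc[:, 1].astype(str)))
    missing = [c for c in cells if c not in mapping]
    if missing:
        raise DataFormatError(
            f"{labels_path}: missing group label for cells {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    labels = np.array([mapping[c] for c in cells], dtype=object)
    return ExpressionMatrix(values, genes, cells, labels)


def write_expression(X: ExpressionMatrix, matrix_path: str | Path,
                     labels_path: str | Path) -> None:
    """Write a dense CSV matrix and a cell_id<TAB>group label file."""
    X.to_frame().to_csv(matrix_path)
    with open(labels_path, "w") as fh:
        fh.write("cell_id\tgroup\n")
        for cid, grp in zip(X.cell_ids, X.group_labels):
            fh.write(f"{cid}\t{grp}\n")


def read_lr_pairs(path: str | Path) -> LigandReceptorDB:
    """Read a two-column ligand/receptor TSV (header ``ligand<TAB>receptor``)."""
    df = pd.read_csv(path, sep="\t")
    cols = [c.lower() for c in df.columns]
    if "ligand" in cols and "receptor" in cols:
        lig = df[df.columns[cols.index("ligand")]]
        rec = df[df.columns[cols.index("receptor")]]
    elif df.shape[1] >= 2:
        lig, rec = df.iloc[:, 0], df.iloc[:, 1]
    else:
        raise DataFormatError(f"{path}: expected two columns (ligand, receptor)")
    return LigandReceptorDB([(str(a), str(b)) for a, b in zip(lig, rec)])


def restrict_to_lr_genes(
    X: ExpressionMatrix, db: LigandReceptorDB
) -> tuple[ExpressionMatrix, list[str]]:
    """Restrict columns to genes in the ligand-receptor universe.

    Returns the restricted matrix (original column order preserved) and the
    dropped-genes report: database genes absent from ``X``.
    """
    universe = set(db.universe)
    keep = [g for g in X.gene_names if g in universe]
    if not keep:
        raise DataFormatError("no ligand/receptor genes found in the matrix")
    dropped = [g for g in db.universe if g not in set(X.gene_names)]
    return X.select_genes(keep), dropped


def log1p_transform(X: ExpressionMatrix) -> ExpressionMatrix:
    """Return a log(1 + x)-transformed copy.

    Off by default everywhere: expression is otherwise consumed as given,
    and log-normalized input is the expected convention. The flag exists
    for raw-scale matrices.
    """
    return ExpressionMatrix(
        np.log1p(X.values),
        list(X.gene_names),
        list(X.cell_ids),
        X.group_labels.copy(),
    )


def subsample_group(
    X: ExpressionMatrix, group: str, n_cells: int = 300, seed: int = 0
) -> ExpressionMatrix:
    """Uniform without-replacement subsample of one group's cells.

    Deterministic for a fixed seed. 300 cells is the default because it
    balances network-estimation stability against runtime; groups smaller
    than ``n_cells`` raise, and the caller decides whether to skip them.
    """
    sub = X.group_view(group)
    if sub.n_cells < n_cells:
        raise ValueError(
            f"group {group!r} has {sub.n_cells} cells, fewer than {n_cells}"
        )
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(sub.n_cells, size=n_cells, replace=False))
    return ExpressionMatrix(
        sub.values[idx].copy(),
        list(sub.gene_names),
        [sub.cell_ids[i] for i in idx],
        sub.group_labels[idx].copy(),
    )
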