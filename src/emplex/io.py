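"""Count-matrix containers, file I/O and preprocessing.

Matrices are stored genes x cells, mirroring the raw deposition format of
most scRNA-seq count files. On-disk formats supported:

* MatrixMarket coordinate (``matrix.mtx``) with ``genes.tsv`` /
  ``barcodes.tsv`` sidecars (one name per line, 1-based indices in the
  MTX per the standard);
* dense CSV/TSV with gene rows and a header row of cell names.

Preprocessing follows the standard recipe for this kind of analysis:
keep the top expressed genes (default 3000, by total count), drop cells
expressing fewer than a minimal fraction of the kept panel (default 5%),
then log-transform with a pseudocount.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from emplex.errors import EmptyResultError, FormatError, ValidationError

__all__ = [
    "CountMatrix",
    "PreprocessConfig",
    "ExpressionMatrix",
    "read_counts",
    "write_counts",
    "preprocess",
]


@dataclass
class CountMatrix:
    """Raw integer gene x cell count matrix with names and optional metadata.

    Parameters
    ----------
    values
        Nonnegative integer array of shape ``(n_genes, n_cells)``.
    gene_names, cell_names
        Unique identifiers for rows and columns.
    cell_meta
        Optional per-cell metadata (e.g. ``time_point``, ``condition``,
        ``site``), indexed like ``cell_names``.
    """

    values: np.ndarray
    gene_names: list[str]
    cell_names: list[str]
    cell_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValidationError("count matrix must be 2-dimensional")
        if not np.issubdtype(self.values.dtype, np.integer):
            if not np.allclose(self.values, np.round(self.values)):
                raise ValidationError("count matrix entries must be integers")
            self.values = self.values.astype(np.int64)
        if (self.values < 0).any():
            raise ValidationError("count matrix entries must be nonnegative")
        self.gene_names = [str(g) for g in self.gene_names]
        self.cell_names = [str(c) for c in self.cell_names]
        n_genes, n_cells = self.values.shape
        if len(self.gene_names) != n_genes:
            raise ValidationError(
                f"{len(self.gene_names)} gene names for {n_genes} rows"
            )
        if len(self.cell_names) != n_cells:
            raise ValidationError(
                f"{len(self.cell_names)} cell names for {n_cells} columns"
            )
        if len(set(self.gene_names)) != n_genes:
            raise ValidationError("gene names must be unique")
        if len(set(self.cell_names)) != n_cells:
            raise ValidationError("cell names must be unique")
        if self.cell_meta is not None and len(self.cell_meta) != n_cells:
            raise ValidationError("cell_meta length must match cell count")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, keep: np.ndarray) -> "CountMatrix":
        """Return a new matrix restricted to the given gene index array."""
        keep = np.asarray(keep)
        return CountMatrix(
            values=self.values[keep, :],
            gene_names=[self.gene_names[i] for i in keep],
            cell_names=list(self.cell_names),
            cell_meta=None if self.cell_meta is None else self.cell_meta.copy(),
        )

    def subset_cells(self, keep: np.ndarray) -> "CountMatrix":
        """Return a new matrix restricted to the given cell index array."""
        keep = np.asarray(keep)
        meta = None
        if self.cell_meta is not None:
            meta = self.cell_meta.iloc[keep].copy()
        return CountMatrix(
            values=self.values[:, keep],
            gene_names=list(self.gene_names),
            cell_names=[self.cell_names[i] for i in keep],
            cell_meta=meta,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_names, columns=self.cell_names
        )


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing parameters.

    ``top_n_genes`` genes are kept by total count (default 3000); cells
    expressing fewer than ``ceil(min_gene_fraction * panel size)`` genes
    are dropped (default 5%); survivors are transformed with
    ``log(pseudocount + count)`` (natural log).

    ``min_frac_panel`` selects which panel the 5% filter counts against:
    ``"kept"`` (the top-n panel, the default) or ``"full"`` (the
    pre-selection gene set) — both conventions occur in practice.
    """

    top_n_genes: int = 3000
    min_gene_fraction: float = 0.05
    pseudocount: float = 1.0
    min_frac_panel: str = "kept"

    def __post_init__(self) -> None:
        if self.top_n_genes < 2:
            raise ValidationError("top_n_genes must be >= 2")
        if not (0.0 <= self.min_gene_fraction < 1.0):
            raise ValidationError("min_gene_fraction must be in [0, 1)")
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be positive")
        if self.min_frac_panel not in {"kept", "full"}:
            raise ValidationError("min_frac_panel must be 'kept' or 'full'")


@dataclass
class ExpressionMatrix:
    """Log-transformed gene x cell expression with preprocessing provenance."""

    values: np.ndarray
    gene_names: list[str]
    cell_names: list[str]
    provenance: PreprocessConfig | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValidationError("expression matrix must be finite")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_names, columns=self.cell_names
        )


def _read_names(path: Path, what: str) -> list[str]:
    if not path.exists():
        raise FormatError(f"missing {what} sidecar file: {path}")
    names = [
        line.split("\t")[0].strip()
        for line in path.read_text().splitlines()
        if line.strip()
    ]
    return names


def read_counts(path: str | Path, format: str | None = None) -> CountMatrix:
    """Read a count matrix from disk.

    Parameters
    ----------
    path
        For ``mtx``: the ``.mtx`` file; ``genes.tsv`` and ``barcodes.tsv``
        are expected alongside it. For ``csv``/``tsv``: a dense table with
        gene rows and a header of cell names.
    format
        One of ``{"mtx", "csv", "tsv"}``; inferred from the suffix when
        omitted.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format not in {"mtx", "csv", "tsv"}:
        raise FormatError(f"unsupported format: {format!r}")

    if format == "mtx":
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:  # pragma: no cover - scipy error text varies
            raise FormatError(f"could not parse MatrixMarket file: {exc}") from exc
        dense = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat
        )
        genes = _read_names(path.parent / "genes.tsv", "gene")
        cells = _read_names(path.parent / "barcodes.tsv", "barcode")
        if len(genes) != dense.shape[0] or len(cells) != dense.shape[1]:
            raise FormatError(
                f"sidecar sizes ({len(genes)} genes, {len(cells)} cells) do "
                f"not match matrix shape {dense.shape}"
            )
        meta = None
        meta_path = path.parent / "cell_meta.tsv"
        if meta_path.exists():
            meta = pd.read_csv(meta_path, sep="\t", index_col=0)
            meta = meta.loc[cells]
        return CountMatrix(dense, genes, cells, meta)

    sep = "," if format == "csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    return CountMatrix(
        df.to_numpy(), [str(g) for g in df.index], [str(c) for c in df.columns]
    )


def write_counts(counts: CountMatrix, path: str | Path, format: str = "mtx") -> None:
    """Write a count matrix; inverse of :func:`read_counts`."""
    path = Path(path)
    if format == "mtx":
        path.parent.mkdir(parents=True, exist_ok=True)
        sparse = scipy.sparse.coo_matrix(counts.values)
        scipy.io.mmwrite(str(path), sparse, field="integer")
        (path.parent / "genes.tsv").write_text(
            "\n".join(counts.gene_names) + "\n"
        )
        (path.parent / "barcodes.tsv").write_text(
            "\n".join(counts.cell_names) + "\n"
        )
        if counts.cell_meta is not None:
            counts.cell_meta.to_csv(path.parent / "cell_meta.tsv", sep="\t")
    elif format in {"csv", "tsv"}:
        sep = "," if format == "csv" else "\t"
        counts.to_frame().to_csv(path, sep=sep)
    else:
        raise FormatError(f"unsupported format: {format!r}")


def preprocess(
    raw: CountMatrix, cfg: PreprocessConfig | None = None
) -> tuple[CountMatrix, ExpressionMatrix]:
    """Apply top-gene selection, the minimum-expressed-gene cell filter and
    the pseudocount log transform.

    Order is fixed: genes are selected first (top ``top_n_genes`` by total
    count over all cells, ties broken by ascending gene name); cells are
    then required to express at least ``ceil(min_gene_fraction * kept)``
    of the *kept* panel; finally ``log(pseudocount + count)``.

    Returns
    -------
    (filtered_counts, expression)
        The filtered raw counts and the matching log-transformed matrix.
    """
    cfg = cfg or PreprocessConfig()
    if raw.n_genes == 0 or raw.n_cells == 0:
        raise ValidationError("cannot preprocess an empty matrix")

    totals = raw.values.sum(axis=1)
    n_keep = min(cfg.top_n_genes, raw.n_genes)
    # sort by (-total, name) for a deterministic boundary tie-break
    order = sorted(range(raw.n_genes), key=lambda i: (-totals[i], raw.gene_names[i]))
    kept_genes = np.sort(np.array(order[:n_keep]))
    filtered = raw.subset_genes(kept_genes)

    if cfg.min_frac_panel == "kept":
        min_genes = math.ceil(cfg.min_gene_fraction * filtered.n_genes)
        expressed = (filtered.values > 0).sum(axis=0)
    else:  # count expressed genes over the full pre-selection panel
        min_genes = math.ceil(cfg.min_gene_fraction * raw.n_genes)
        expressed = (raw.values > 0).sum(axis=0)
    kept_cells = np.flatnonzero(expressed >= min_genes)
    if kept_cells.size == 0:
        raise EmptyResultError(
            "the minimum-expressed-gene filter removed every cell"
        )
    filtered = filtered.subset_cells(kept_cells)

    expr = ExpressionMatrix(
        values=np.log(cfg.pseudocount + filtered.values.astype(float)),
        gene_names=list(filtered.gene_names),
        cell_names=list(filtered.cell_names),
        provenance=cfg,
    )
    return filtered, expr
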