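"""Readers, writers and cell-level quality control.

The central in-memory container is :class:`SpatialCellTable`: a cells table
(coordinates in µm plus sample metadata), a sparse cells × genes raw count
matrix, and optional per-cell boundary polygons.  On-disk formats are plain
text: a delimited cells table (CSV/TSV by extension), MatrixMarket counts with
sidecar gene/cell index files, and a JSON polygon map.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .exceptions import (
    AlignmentError,
    ParameterError,
    SchemaError,
    ValidationError,
)

REQUIRED_CELL_COLUMNS = ("cell_id", "x_um", "y_um", "slide_id", "sample_id", "condition")

#: Disease conditions of the cohort; the container accepts any string label,
#: these are the ones the synthetic cohorts generate.
KNOWN_CONDITIONS = ("control", "SLE", "ANCA-GN", "anti-GBM")


@dataclass
class SpatialCellTable:
    """Segmented cells with coordinates, raw counts and metadata.

    Parameters
    ----------
    cells
        One row per cell, indexed by unique ``cell_id``.  Required columns:
        ``x_um``, ``y_um`` (planar coordinates in micrometres, per-slide
        origin arbitrary), ``slide_id``, ``sample_id``, ``condition``.
        Optional columns (``patient_id``, ``cell_type``, ...) are preserved.
    counts
        Sparse non-negative integer matrix, cells × genes, rows aligned with
        ``cells``.
    gene_names
        Ordered gene symbols, one per counts column, unique.
    polygons
        Optional mapping ``cell_id -> (k, 2) array`` of boundary vertices
        in µm.
    """

    cells: pd.DataFrame
    counts: sp.csr_matrix
    gene_names: list[str]
    polygons: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_names = list(self.gene_names)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        missing = [c for c in REQUIRED_CELL_COLUMNS[1:] if c not in self.cells.columns]
        if missing:
            raise SchemaError(f"cells table is missing required column(s): {missing}")
        if not self.cells.index.is_unique:
            dup = self.cells.index[self.cells.index.duplicated()][:5].tolist()
            raise ValidationError(f"cell_id values are not unique (e.g. {dup})")
        if self.counts.shape[0] != len(self.cells):
            raise AlignmentError(
                f"counts has {self.counts.shape[0]} rows but cells table has "
                f"{len(self.cells)} rows"
            )
        if self.counts.shape[1] != len(self.gene_names):
            raise AlignmentError(
                f"counts has {self.counts.shape[1]} columns but "
                f"{len(self.gene_names)} gene names were given"
            )
        if len(set(self.gene_names)) != len(self.gene_names):
            raise ValidationError("gene names are not unique")
        xy = self.cells[["x_um", "y_um"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xy)):
            raise ValidationError("cell coordinates contain non-finite values")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("counts contain negative entries")
        data = self.counts.data
        if data.size and not np.allclose(data, np.round(data)):
            raise ValidationError("counts contain non-integer entries")
        # each sample maps to exactly one condition and one slide
        for col in ("condition", "slide_id"):
            per = self.cells.groupby("sample_id", observed=True)[col].nunique()
            bad = per[per > 1]
            if len(bad):
                raise ValidationError(
                    f"sample(s) {bad.index.tolist()} map to more than one {col}"
                )

    # -- conveniences -------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    @property
    def cell_ids(self) -> np.ndarray:
        return self.cells.index.to_numpy()

    @property
    def xy(self) -> np.ndarray:
        """(n_cells, 2) coordinate array in µm."""
        return self.cells[["x_um", "y_um"]].to_numpy(dtype=float)

    def gene_index(self, genes) -> np.ndarray:
        """Column indices of ``genes`` (all must be present)."""
        lookup = {g: i for i, g in enumerate(self.gene_names)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes not in panel: {missing}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset(self, mask) -> "SpatialCellTable":
        """Row subset (boolean mask or integer positions); order preserved."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        cells = self.cells.iloc[idx].copy()
        polygons = None
        if self.polygons is not None:
            polygons = {cid: self.polygons[cid] for cid in cells.index if cid in self.polygons}
        return SpatialCellTable(cells, self.counts[idx], self.gene_names, polygons)

    def to_anndata(self):
        """View as an :class:`anndata.AnnData` (raw counts in ``.X``)."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts.copy(),
            obs=self.cells.copy(),
            var=pd.DataFrame(index=pd.Index(self.gene_names, name="gene")),
        )
        adata.obsm["spatial"] = self.xy
        return adata


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_delimited(path: Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


def read_cells(
    cells_path,
    counts_path,
    polygons_path=None,
    *,
    genes_path=None,
    cell_index_path=None,
) -> SpatialCellTable:
    """Read a :class:`SpatialCellTable` from disk.

    ``cells_path`` is a delimited table with the required columns;
    ``counts_path`` a MatrixMarket file whose row order follows the sidecar
    cell index (default: ``<counts stem>.cells.txt``) and whose columns follow
    the gene index (default: ``<counts stem>.genes.txt``); ``polygons_path``
    an optional JSON mapping cell_id to a vertex list.
    """
    cells_path = Path(cells_path)
    counts_path = Path(counts_path)
    df = _read_delimited(cells_path)
    missing = [c for c in REQUIRED_CELL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{cells_path.name} is missing required column(s): {missing}")
    df = df.set_index("cell_id")
    df.index = df.index.astype(str)

    stem = counts_path.with_suffix("")
    genes_path = Path(genes_path) if genes_path else stem.with_suffix(".genes.txt")
    cell_index_path = (
        Path(cell_index_path) if cell_index_path else stem.with_suffix(".cells.txt")
    )
    gene_names = genes_path.read_text().split()
    cell_index = cell_index_path.read_text().split()
    counts = sp.csr_matrix(scipy.io.mmread(counts_path))
    if counts.shape[0] != len(cell_index):
        raise AlignmentError(
            f"counts matrix has {counts.shape[0]} rows but cell index lists "
            f"{len(cell_index)} cells"
        )
    if len(cell_index) != len(df):
        raise AlignmentError(
            f"counts cell index has {len(cell_index)} cells but cells table has {len(df)}"
        )
    if list(df.index) != cell_index:
        # allow arbitrary table order; realign counts to the table
        pos = {cid: i for i, cid in enumerate(cell_index)}
        try:
            order = [pos[cid] for cid in df.index]
        except KeyError as e:
            raise AlignmentError(f"cell id {e} in cells table missing from counts index")
        counts = counts[order]

    polygons = None
    if polygons_path is not None:
        with open(polygons_path) as fh:
            raw = json.load(fh)
        polygons = {cid: np.asarray(v, dtype=float) for cid, v in raw.items()}
    return SpatialCellTable(df, counts, gene_names, polygons)


def write_cells(table: SpatialCellTable, cells_path, counts_path, polygons_path=None) -> None:
    """Write a table back to the formats :func:`read_cells` accepts."""
    cells_path = Path(cells_path)
    counts_path = Path(counts_path)
    sep = "\t" if str(cells_path).endswith((".tsv", ".txt")) else ","
    table.cells.rename_axis("cell_id").reset_index().to_csv(cells_path, sep=sep, index=False)
    scipy.io.mmwrite(str(counts_path), sp.coo_matrix(table.counts))
    stem = counts_path.with_suffix("")
    stem.with_suffix(".genes.txt").write_text("\n".join(table.gene_names) + "\n")
    stem.with_suffix(".cells.txt").write_text("\n".join(map(str, table.cell_ids)) + "\n")
    if polygons_path is not None and table.polygons is not None:
        serial = {cid: np.asarray(v).tolist() for cid, v in table.polygons.items()}
        with open(polygons_path, "w") as fh:
            json.dump(serial, fh)


def read_gene_panel(path) -> pd.DataFrame:
    """Read a gene panel: one gene per line, or a 2-column CSV (gene, category).

    Returns a DataFrame with columns ``gene`` and ``category``; gene names
    must be unique.
    """
    path = Path(path)
    text = path.read_text().strip()
    first = text.splitlines()[0]
    if "," in first or "\t" in first:
        sep = "\t" if "\t" in first else ","
        df = pd.read_csv(path, sep=sep)
        if "gene" not in df.columns:
            df.columns = ["gene", "category"][: len(df.columns)]
        if "category" not in df.columns:
            df["category"] = ""
    else:
        df = pd.DataFrame({"gene": text.split(), "category": ""})
    df["gene"] = df["gene"].astype(str)
    if df["gene"].duplicated().any():
        raise ValidationError("gene panel contains duplicate gene names")
    return df[["gene", "category"]]


def read_clinical(path) -> pd.DataFrame:
    """Read the clinical covariate CSV (patient_id, eGFR, albuminuria, age[, anca_risk])."""
    df = pd.read_csv(path)
    if "patient_id" not in df.columns:
        raise SchemaError("clinical table is missing required column 'patient_id'")
    if df["patient_id"].duplicated().any():
        raise ValidationError("clinical table has duplicate patient_id values")
    for col in ("eGFR", "albuminuria", "age"):
        if col in df.columns and (df[col].dropna() < 0).any():
            raise ValidationError(f"clinical covariate {col!r} has negative values")
    return df.set_index("patient_id")


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise SchemaError(f"malformed GMT line (need >=3 tab-separated fields): {line[:60]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def qc_filter_cells(
    table: SpatialCellTable,
    min_unique_genes: int = 5,
    max_mito_fraction: float | None = None,
    *,
    mito_prefix: str = "MT-",
    exclude_cell_ids=None,
) -> tuple[SpatialCellTable, dict[str, int]]:
    """Remove low-quality cells.

    Cells expressing fewer than ``min_unique_genes`` unique genes are removed;
    if ``max_mito_fraction`` is given, cells whose fraction of counts on
    genes starting with ``mito_prefix`` exceeds it are removed as well.
    ``exclude_cell_ids`` supports the manual exclusion of cells from blurred
    or noisy tissue regions, for which no algorithmic rule exists.

    Returns the surviving subset (order preserved) and a report of how many
    cells each criterion removed.  Filtering is idempotent.
    """
    if min_unique_genes < 1:
        raise ParameterError("min_unique_genes must be >= 1")
    n_unique = np.asarray((table.counts > 0).sum(axis=1)).ravel()
    keep = n_unique >= min_unique_genes
    report = {"low_unique_genes": int((~keep).sum())}

    if max_mito_fraction is not None:
        mito_cols = [i for i, g in enumerate(table.gene_names) if g.startswith(mito_prefix)]
        totals = np.asarray(table.counts.sum(axis=1)).ravel()
        mito = (
            np.asarray(table.counts[:, mito_cols].sum(axis=1)).ravel()
            if mito_cols
            else np.zeros(table.n_cells)
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, mito / np.maximum(totals, 1), 0.0)
        mito_fail = frac > max_mito_fraction
        report["high_mito_fraction"] = int((keep & mito_fail).sum())
        keep &= ~mito_fail

    if exclude_cell_ids is not None:
        excl = table.cells.index.isin(set(exclude_cell_ids))
        report["manual_exclusion"] = int((keep & excl).sum())
        keep &= ~excl

    report["retained"] = int(keep.sum())
    return table.subset(keep), report


def subset_to_panel(table: SpatialCellTable, panel_genes) -> SpatialCellTable:
    """Restrict the count matrix to panel genes; genes absent from the panel
    are dropped with a warning (never an error)."""
    panel = [g for g in panel_genes if g in set(table.gene_names)]
    dropped = set(table.gene_names) - set(panel)
    if dropped:
        warnings.warn(f"dropping {len(dropped)} genes absent from the panel")
    idx = table.gene_index(panel)
    return SpatialCellTable(table.cells.copy(), table.counts[:, idx], panel, table.polygons)
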