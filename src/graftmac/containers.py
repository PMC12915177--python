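"""Core in-memory containers shared across the pipeline.

The central object is :class:`CellExperiment`, a genes x cells sparse count
matrix with two aligned metadata tables, mirroring the MTX + sidecar layout
used on disk.  Downstream stages add lineage, truth and survival containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

GENE_FLAG_COLUMNS = ("is_mito", "is_ribo", "is_noncoding")

CELL_COLUMNS = (
    "sample",
    "tissue",
    "outcome",
    "cluster",
    "emb_1",
    "emb_2",
    "donor_sex",
    "recipient_sex",
)


@dataclass
class CellExperiment:
    """Sparse genes x cells counts plus gene and cell metadata tables.

    Parameters
    ----------
    counts
        Non-negative integer sparse matrix, shape ``(n_genes, n_cells)``.
    genes
        DataFrame indexed by unique gene id; expected columns include
        ``symbol`` and the boolean flags ``is_mito``/``is_ribo``/``is_noncoding``.
    cells
        DataFrame indexed by unique cell id; expected columns include
        ``cluster``, ``tissue``, ``outcome``, embedding coordinates
        ``emb_1``/``emb_2`` and ``donor_sex``/``recipient_sex``.
    """

    counts: sp.spmatrix
    genes: pd.DataFrame
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        else:
            self.counts = self.counts.tocsr()
        n_genes, n_cells = self.counts.shape
        if len(self.genes) != n_genes:
            raise ValueError(
                f"gene table has {len(self.genes)} rows but counts has {n_genes} gene rows"
            )
        if len(self.cells) != n_cells:
            raise ValueError(
                f"cell table has {len(self.cells)} rows but counts has {n_cells} cell columns"
            )
        if not self.genes.index.is_unique:
            raise ValueError("gene ids are not unique")
        if not self.cells.index.is_unique:
            raise ValueError("cell ids are not unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def gene_ids(self) -> pd.Index:
        return self.genes.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.cells.index

    def library_sizes(self) -> np.ndarray:
        """Total counts per cell."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def detected_genes(self) -> np.ndarray:
        """Number of genes with count > 0 per cell."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def mito_fraction(self) -> np.ndarray:
        """Per-cell fraction of counts on mitochondrially encoded genes."""
        if "is_mito" not in self.genes.columns:
            raise ValueError("gene table lacks an 'is_mito' flag column")
        mito = self.genes["is_mito"].to_numpy(dtype=bool)
        lib = self.library_sizes().astype(float)
        mito_counts = np.asarray(self.counts[mito].sum(axis=0)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(lib > 0, mito_counts / np.maximum(lib, 1e-300), 0.0)
        return frac

    def subset_cells(self, mask_or_ids) -> "CellExperiment":
        idx = self._resolve(mask_or_ids, self.cells.index, self.n_cells)
        return CellExperiment(
            self.counts[:, idx], self.genes.copy(), self.cells.iloc[idx].copy()
        )

    def subset_genes(self, mask_or_ids) -> "CellExperiment":
        idx = self._resolve(mask_or_ids, self.genes.index, self.n_genes)
        return CellExperiment(
            self.counts[idx, :], self.genes.iloc[idx].copy(), self.cells.copy()
        )

    @staticmethod
    def _resolve(mask_or_ids, index: pd.Index, n: int) -> np.ndarray:
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            if arr.size != n:
                raise ValueError("boolean mask length mismatch")
            return np.flatnonzero(arr)
        if np.issubdtype(arr.dtype, np.integer):
            return arr
        return index.get_indexer(arr)

    def copy(self) -> "CellExperiment":
        return CellExperiment(self.counts.copy(), self.genes.copy(), self.cells.copy())

    def equals(self, other: "CellExperiment") -> bool:
        same_mat = (self.counts != other.counts).nnz == 0
        return (
            same_mat
            and self.genes.equals(other.genes)
            and self.cells.equals(other.cells)
        )


@dataclass
class SimTruth:
    """Ground truth emitted by the synthetic generators.

    Every downstream stage can be scored against this object alone:
    pseudotime/lineage recovery, planted-marker recovery, origin assignment,
    deconvolution accuracy and hazard-ratio recovery.
    """

    pseudotime: Optional[pd.Series] = None          # per cell, true t
    lineage: Optional[pd.Series] = None             # per cell, true lineage label
    planted_marker_ids: list[str] = field(default_factory=list)
    origin: Optional[pd.Series] = None              # per cell, donor|recipient
    proportions: Optional[pd.DataFrame] = None      # samples x cell types
    log_hazard_ratio: Optional[float] = None
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.proportions is not None:
            sums = self.proportions.sum(axis=1).to_numpy()
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("true proportion rows must sum to 1 +/- 1e-9")


@dataclass
class Lineage:
    """One root-to-leaf path: ordered cluster names and its curve control points."""

    name: str
    clusters: list[str]
    control_points: np.ndarray  # (n_points, 2) embedding coordinates


@dataclass
class LineageSet:
    """Inferred lineages plus per-cell pseudotime and lineage weights.

    ``pseudotime`` and ``weights`` are cells x lineages DataFrames; the weight
    rows sum to 1.  ``assignment`` is the hard argmax-weight lineage per cell
    (ties broken lexicographically), used for block design matrices.
    """

    lineages: list[Lineage]
    pseudotime: Optional[pd.DataFrame] = None
    weights: Optional[pd.DataFrame] = None
    assignment: Optional[pd.Series] = None
    converged: bool = True

    @property
    def names(self) -> list[str]:
        return [lin.name for lin in self.lineages]

    def lineage(self, name: str) -> Lineage:
        for lin in self.lineages:
            if lin.name == name:
                return lin
        raise KeyError(name)


@dataclass
class KnotGrid:
    """Shared spline-knot positions on pooled pseudotime (1-based indexing).

    knot 1 sits at the minimum of pooled pseudotime and knot K at its maximum;
    the segment between knots 3 and 4 of the default K=5 grid is the tested
    window for early differential expression.
    """

    positions: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 1 or self.positions.size < 2:
            raise ValueError("need at least two knots")
        if not np.all(np.diff(self.positions) > 0):
            raise ValueError("knot positions must be strictly increasing")

    @property
    def k(self) -> int:
        return self.positions.size

    def knot(self, index: int) -> float:
        """Position of 1-based knot ``index``."""
        if not 1 <= index <= self.k:
            raise IndexError(f"knot index {index} outside 1..{self.k}")
        return float(self.positions[index - 1])


@dataclass
class SignatureMatrix:
    """Cell-type reference profiles on CPM scale (genes x types) plus markers."""

    profiles: pd.DataFrame
    markers: dict[str, list[str]] = field(default_factory=dict)
    condition_number: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.profiles.to_numpy() < 0).any():
            raise ValueError("signature entries must be non-negative")
        if not self.profiles.index.is_unique:
            raise ValueError("signature gene ids must be unique")

    @property
    def cell_types(self) -> list[str]:
        return list(self.profiles.columns)


@dataclass
class MixtureSet:
    """Pseudobulk mixtures (genes x M) with known true proportions (M x types)."""

    mixtures: pd.DataFrame
    proportions: pd.DataFrame

    def __post_init__(self) -> None:
        if self.mixtures.shape[1] != self.proportions.shape[0]:
            raise ValueError("mixture count does not match proportion rows")
        sums = self.proportions.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("true proportion rows must sum to 1 +/- 1e-9")


LESION_COLUMNS = ("g", "ptc", "i", "t")


def validate_survival_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a per-sample survival table (time_days, event, covariates, lesions).

    Returns the table unchanged; raises ``ValueError`` on contract violations.
    """
    if "time_days" not in table.columns or "event" not in table.columns:
        raise ValueError("survival table needs 'time_days' and 'event' columns")
    t = table["time_days"].to_numpy(dtype=float)
    if np.any(t <= 0):
        raise ValueError("survival times must be positive")
    ev = table["event"].to_numpy()
    if not np.isin(ev, [0, 1]).all():
        raise ValueError("event indicator must be 0/1")
    return table
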