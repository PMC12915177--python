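"""Quality control, gene filtering, CPM normalization and MTX round-trip IO.

QC keeps cells whose detected-gene count (genes with count > 0) lies in the
inclusive band [min_genes, max_genes] and whose mitochondrial-transcript
fraction does not exceed the tissue-specific cutoff: circulating (blood)
cells are held to a tighter mitochondrial bound than biopsy-derived cells,
which tolerate more ambient stress transcripts.  Gene filtering for
trajectory differential expression keeps genes expressed in strictly more
than ``min_cells`` cells and drops mitochondrial, ribosomal and non-coding
genes.  Both filters are idempotent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import CellExperiment, GENE_FLAG_COLUMNS

#: fallback symbol patterns when explicit gene flags are missing
DEFAULT_FLAG_PATTERNS = {
    "is_mito": r"^MT-",
    "is_ribo": r"^RP[SL]",
    "is_noncoding": r"(^LINC|-AS\d*$)",
}


@dataclass
class QCConfig:
    """Cell-level QC thresholds (inclusive gene-count band, tissue mito caps)."""

    min_genes: int = 300
    max_genes: int = 10000
    mito_max_blood: float = 0.10
    mito_max_biopsy: float = 0.25

    def __post_init__(self) -> None:
        if not 0 < self.min_genes < self.max_genes:
            raise ValueError("require 0 < min_genes < max_genes")
        for f in (self.mito_max_blood, self.mito_max_biopsy):
            if not 0.0 < f <= 1.0:
                raise ValueError("mito fractions must lie in (0, 1]")


@dataclass
class FilterReport:
    """Per-rule removal counts; rule counts sum to input minus output."""

    n_input: int
    n_kept: int
    removed_by_rule: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_kept


def ensure_gene_flags(experiment: CellExperiment,
                      patterns: dict[str, str] | None = None) -> CellExperiment:
    """Fill missing mito/ribo/noncoding flag columns from symbol patterns."""
    patterns = patterns or DEFAULT_FLAG_PATTERNS
    genes = experiment.genes
    missing = [c for c in GENE_FLAG_COLUMNS if c not in genes.columns]
    if not missing:
        return experiment
    genes = genes.copy()
    symbols = genes.get("symbol", pd.Series(genes.index, index=genes.index))
    for col in missing:
        rx = re.compile(patterns[col])
        genes[col] = [bool(rx.search(str(s))) for s in symbols]
    return CellExperiment(experiment.counts, genes, experiment.cells.copy())


def qc_filter_cells(
    experiment: CellExperiment, qc: QCConfig | None = None
) -> tuple[CellExperiment, FilterReport]:
    """Apply the cell QC filter; raises if no cell survives.

    A cell is removed if its detected-gene count falls strictly below
    ``min_genes`` or strictly above ``max_genes``, or if its mitochondrial
    fraction strictly exceeds the cutoff for its tissue (blood vs biopsy).
    """
    qc = qc or QCConfig()
    experiment = ensure_gene_flags(experiment)
    detected = experiment.detected_genes()
    mito = experiment.mito_fraction()
    tissue = experiment.cells["tissue"].to_numpy()
    mito_cap = np.where(tissue == "blood", qc.mito_max_blood, qc.mito_max_biopsy)

    low = detected < qc.min_genes
    high = detected > qc.max_genes
    mito_fail = (~low) & (~high) & (mito > mito_cap)
    keep = ~(low | high | mito_fail)
    if not keep.any():
        raise ValueError("QC removed every cell; downstream analysis is invalid")
    report = FilterReport(
        n_input=experiment.n_cells,
        n_kept=int(keep.sum()),
        removed_by_rule={
            "too_few_genes": int(low.sum()),
            "too_many_genes": int(high.sum()),
            "mito_fraction": int(mito_fail.sum()),
        },
    )
    return experiment.subset_cells(keep), report


def filter_genes_for_de(
    experiment: CellExperiment,
    min_cells: int = 10,
    drop_classes: tuple[str, ...] = ("is_mito", "is_ribo", "is_noncoding"),
) -> tuple[CellExperiment, FilterReport]:
    """Keep genes expressed in more than ``min_cells`` cells, drop flagged classes."""
    experiment = ensure_gene_flags(experiment)
    n_expressing = np.asarray((experiment.counts > 0).sum(axis=1)).ravel()
    rare = n_expressing <= min_cells
    flagged = np.zeros(experiment.n_genes, dtype=bool)
    for col in drop_classes:
        flagged |= experiment.genes[col].to_numpy(dtype=bool)
    flagged &= ~rare  # attribute each removal to a single rule
    keep = ~(rare | flagged)
    report = FilterReport(
        n_input=experiment.n_genes,
        n_kept=int(keep.sum()),
        removed_by_rule={
            "expressed_in_too_few_cells": int(rare.sum()),
            "dropped_class": int(flagged.sum()),
        },
    )
    if not keep.any():
        report.warnings.append("gene filter removed every gene")
    return experiment.subset_genes(keep), report


def cpm_normalize(counts) -> tuple[np.ndarray, list[int]]:
    """Scale each column (cell/sample) to sum to one million.

    Returns the dense CPM matrix and the indices of all-zero columns, which
    are left at zero and reported instead of producing NaNs.
    """
    if sp.issparse(counts):
        mat = np.asarray(counts.todense(), dtype=float)
    else:
        mat = np.array(counts, dtype=float)
    sums = mat.sum(axis=0)
    zero_cols = [int(i) for i in np.flatnonzero(sums == 0)]
    scale = np.divide(1e6, sums, out=np.zeros_like(sums), where=sums > 0)
    return mat * scale[None, :], zero_cols


# ---------------------------------------------------------------------------
# Matrix Market + TSV sidecar IO
# ---------------------------------------------------------------------------

def write_mtx_experiment(experiment: CellExperiment, directory) -> dict[str, Path]:
    """Write counts.mtx plus genes.tsv / cells.tsv sidecars (UTF-8, header row)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": directory / "counts.mtx",
        "genes": directory / "genes.tsv",
        "cells": directory / "cells.tsv",
    }
    scipy.io.mmwrite(paths["counts"], experiment.counts.tocoo(), field="integer")
    experiment.genes.to_csv(paths["genes"], sep="\t", index_label="gene_id")
    experiment.cells.to_csv(paths["cells"], sep="\t", index_label="cell_id")
    return paths


def read_mtx_experiment(directory) -> CellExperiment:
    """Read an experiment written by :func:`write_mtx_experiment`.

    Raises on dimension mismatch between the MTX header and the sidecars and
    on duplicated ids.  Empty-but-valid files yield an empty experiment.
    """
    directory = Path(directory)
    counts = sp.csr_matrix(scipy.io.mmread(directory / "counts.mtx"), dtype=np.int64)
    genes = pd.read_csv(directory / "genes.tsv", sep="\t", index_col="gene_id")
    cells = pd.read_csv(directory / "cells.tsv", sep="\t", index_col="cell_id")
    for col in GENE_FLAG_COLUMNS:
        if col in genes.columns:
            genes[col] = genes[col].astype(bool)
    if counts.shape[0] != len(genes):
        raise ValueError(
            f"counts.mtx declares {counts.shape[0]} genes but genes.tsv has "
            f"{len(genes)} rows"
        )
    if counts.shape[1] != len(cells):
        raise ValueError(
            f"counts.mtx declares {counts.shape[1]} cells but cells.tsv has "
            f"{len(cells)} rows"
        )
    return CellExperiment(counts, genes, cells)
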