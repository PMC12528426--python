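"""Matrix construction: QC filtering, log transform, gene filter, centering.

The pipeline works on Smart-seq2-style TPM matrices. Cells are kept when
they express at least ``min_genes_per_cell`` genes and their mitochondrial
read fraction is strictly below ``max_mito_fraction``; values are
log2((TPM/10)+1)-transformed; genes with mean log expression <= 4.5
across the cells of the matrix at hand are dropped; finally each gene is
mean-centered. Gene filtering and centering are per constructed analysis
matrix (e.g. one patient's cells plus the pooled reference together), not
global.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .matrix import ExpressionMatrix


class EmptyResultError(ValueError):
    """A filter removed everything it was applied to."""


@dataclass(frozen=True)
class QCThresholds:
    min_genes_per_cell: int = 1000
    max_mito_fraction: float = 0.30
    mito_gene_tag: str = "MT-"

    def __post_init__(self) -> None:
        if self.min_genes_per_cell < 0:
            raise ValueError("min_genes_per_cell must be >= 0")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must be in [0, 1]")


def qc_filter(
    m: ExpressionMatrix,
    thresholds: QCThresholds = QCThresholds(),
    exclude: Iterable[str] | None = None,
) -> tuple[ExpressionMatrix, dict]:
    """Remove low-quality cells from a raw matrix.

    A cell is kept iff it expresses (value > 0) at least
    ``min_genes_per_cell`` genes, its mitochondrial fraction is strictly
    below ``max_mito_fraction``, and it is not on the exclusion list
    (the manually curated doublet/low-quality ids). Returns the filtered
    matrix and a report of removals per criterion.
    """
    if m.space != "raw":
        raise ValueError("qc_filter expects a raw-space matrix")
    exclude_set = set(exclude) if exclude is not None else set()

    n_expressed = (m.values > 0).sum(axis=1)
    mito_mask = np.array(
        [str(g).startswith(thresholds.mito_gene_tag) for g in m.gene_ids]
    )
    totals = m.values.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(
            totals > 0, m.values[:, mito_mask].sum(axis=1) / totals, 0.0
        )

    too_few = n_expressed < thresholds.min_genes_per_cell
    too_mito = mito_frac >= thresholds.max_mito_fraction
    excluded = np.array([c in exclude_set for c in m.cell_ids])
    keep = ~(too_few | too_mito | excluded)

    report = {
        "n_input": int(m.n_cells),
        "removed_low_gene_count": int(too_few.sum()),
        "removed_high_mito": int(too_mito.sum()),
        "removed_excluded": int(excluded.sum()),
        "n_kept": int(keep.sum()),
        "thresholds": {
            "min_genes_per_cell": thresholds.min_genes_per_cell,
            "max_mito_fraction": thresholds.max_mito_fraction,
            "mito_gene_tag": thresholds.mito_gene_tag,
        },
    }
    if not keep.any():
        raise EmptyResultError("no cells pass QC")
    return m.subset_cells(list(m.cell_ids[keep])), report


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Transform raw TPM-like values to log2((TPM/10) + 1)."""
    if m.space != "raw":
        raise ValueError("log_transform expects a raw-space matrix")
    if np.any(m.values < 0):
        raise ValueError("negative values in raw matrix")
    return m.with_values(np.log2(m.values / 10.0 + 1.0), space="log")


def inverse_log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Invert :func:`log_transform` (log space back to TPM-like units)."""
    if m.space != "log":
        raise ValueError("inverse_log_transform expects a log-space matrix")
    return m.with_values((np.exp2(m.values) - 1.0) * 10.0, space="raw")


def filter_genes(m: ExpressionMatrix, cutoff: float = 4.5) -> ExpressionMatrix:
    """Keep genes whose mean log expression across cells is strictly > cutoff.

    The mean is taken over the cells of this matrix, so the surviving
    gene set depends on which cells were assembled into it.
    """
    if m.space != "log":
        raise ValueError("filter_genes expects a log-space matrix")
    keep = m.values.mean(axis=0) > cutoff
    if not keep.any():
        raise EmptyResultError(f"no genes with mean log expression > {cutoff}")
    return m.subset_genes_mask(keep)


def center_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's mean across cells; result is in centered space."""
    if m.space != "log":
        raise ValueError("center_genes expects a log-space matrix")
    return m.with_values(m.values - m.values.mean(axis=0), space="centered")


def fraction_pct(numerator: int, denominator: int, digits: int = 0) -> float:
    """Percentage of a count ratio rounded for reporting (16/199 -> 8.0)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * numerator / denominator, digits)


def cell_accounting(total: int, removals: Sequence[int]) -> int:
    """Cells remaining after stepwise curation removals.

    Used to reconcile reported cohort sizes: a post-QC total minus each
    curated exclusion (doublet clusters, low-quality microenvironment
    cells, ...) gives the number of profiled cells.
    """
    remaining = int(total)
    for r in removals:
        if r < 0:
            raise ValueError("removal counts must be >= 0")
        remaining -= int(r)
    if remaining < 0:
        raise ValueError("removals exceed the total")
    return remaining
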