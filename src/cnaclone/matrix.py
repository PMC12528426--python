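"""Core in-memory containers.

Matrices are cells-as-rows throughout the package. ``ExpressionMatrix``
carries an explicit ``space`` tag (``raw`` TPM-like, ``log`` for
log2((TPM/10)+1), ``centered`` for gene-mean-centered log values) so that
each pipeline stage can assert its precondition instead of silently
double-transforming.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

SPACES = ("raw", "log", "centered")


@dataclass
class ExpressionMatrix:
    """Cells x genes expression values with aligned identifiers.

    Parameters
    ----------
    values : ndarray, shape (n_cells, n_genes)
    cell_ids, gene_ids : sequences of unique string identifiers
    space : one of ``raw``, ``log``, ``centered``
    """

    values: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    space: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-dimensional (cells x genes)")
        n_cells, n_genes = self.values.shape
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix rows"
            )
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix columns"
            )
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("duplicate cell ids")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene ids")
        if self.space not in SPACES:
            raise ValueError(f"unknown space {self.space!r}; expected one of {SPACES}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite expression values")
        if self.space == "raw" and np.any(self.values < 0):
            raise ValueError("raw expression values must be >= 0")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def cell_index(self, cell_ids: Sequence[str]) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in cell_ids if c not in lookup]
        if missing:
            raise KeyError(f"unknown cell ids: {missing[:5]}")
        return np.array([lookup[c] for c in cell_ids], dtype=int)

    def subset_cells(self, cell_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = self.cell_index(cell_ids)
        return replace(
            self,
            values=self.values[idx].copy(),
            cell_ids=self.cell_ids[idx].copy(),
            gene_ids=self.gene_ids.copy(),
        )

    def subset_genes_mask(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask, dtype=bool)
        return replace(
            self,
            values=self.values[:, mask].copy(),
            cell_ids=self.cell_ids.copy(),
            gene_ids=self.gene_ids[mask].copy(),
        )

    def with_values(self, values: np.ndarray, space: str | None = None) -> "ExpressionMatrix":
        return replace(self, values=values, space=space or self.space)


@dataclass
class CNAMatrix:
    """Cells x genome-ordered positions of inferred relative copy number.

    ``gene_ids`` name the ordered positions (one surviving gene each);
    ``provenance`` records the parameters and reference description that
    produced the matrix so a run can be audited.
    """

    values: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError("CNA matrix shape does not match ids")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_positions(self) -> int:
        return self.values.shape[1]

    def cell_index(self, cell_ids: Sequence[str]) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in cell_ids if c not in lookup]
        if missing:
            raise KeyError(f"unknown cell ids: {missing[:5]}")
        return np.array([lookup[c] for c in cell_ids], dtype=int)

    def subset_cells(self, cell_ids: Sequence[str]) -> "CNAMatrix":
        idx = self.cell_index(cell_ids)
        return CNAMatrix(
            values=self.values[idx].copy(),
            cell_ids=self.cell_ids[idx].copy(),
            gene_ids=self.gene_ids.copy(),
            provenance=dict(self.provenance),
        )
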