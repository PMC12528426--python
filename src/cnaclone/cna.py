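"""Per-cell relative copy-number inference from smoothed expression.

The method converts gene-level expression noise into segment-level
copy-number signal: genes are reordered by chromosomal location, centered
log expression is clipped to +/-3, a 100-gene moving average is taken
along the genome within each chromosome, and the smoothed profiles are
calibrated against presumed-diploid reference cells. For each reference
cell type a mean smoothed profile is computed per position; at every
position the highest of those type means is subtracted from positive
cell values and the lowest from negative values (a value whose sign
would flip carries no evidence beyond the normal envelope and is set to
zero). Finally all values strictly inside (-0.15, 0.15) are treated as
noise and zeroed. The result is a relative CNA matrix that is mostly
exactly zero for diploid cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import CNAMatrix, ExpressionMatrix
from . import preprocess


@dataclass(frozen=True)
class CNAParams:
    clip_bound: float = 3.0
    window: int = 100
    noise_floor: float = 0.15
    gene_expr_cutoff: float = 4.5

    def __post_init__(self) -> None:
        if self.clip_bound <= 0 or self.noise_floor <= 0:
            raise ValueError("clip_bound and noise_floor must be > 0")
        if self.window < 1:
            raise ValueError("window must be >= 1")


def order_genes(m: ExpressionMatrix, annotation: pd.DataFrame) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Sort matrix columns by genomic position.

    Genes absent from the annotation are dropped with a warning; if
    fewer than half the matrix genes are annotated the input is
    considered mismatched and an error is raised. Returns the reordered
    matrix together with the matching annotation rows (one per kept
    column, in column order).
    """
    ann = annotation.set_index("gene_id")
    present = np.array([g in ann.index for g in m.gene_ids])
    if present.sum() < 0.5 * m.n_genes:
        raise ValueError(
            f"only {int(present.sum())}/{m.n_genes} genes are annotated; "
            "annotation does not match the matrix"
        )
    if not present.all():
        warnings.warn(f"dropping {int((~present).sum())} unannotated genes")
        m = m.subset_genes_mask(present)
    order = np.argsort([ann.at[g, "order_index"] for g in m.gene_ids], kind="stable")
    reordered = ExpressionMatrix(
        values=m.values[:, order],
        cell_ids=m.cell_ids,
        gene_ids=m.gene_ids[order],
        space=m.space,
    )
    kept_ann = ann.loc[list(reordered.gene_ids)].reset_index()
    return reordered, kept_ann


def clip_values(values: np.ndarray, clip_bound: float = 3.0) -> np.ndarray:
    """Limit centered expression to [-clip_bound, clip_bound]."""
    return np.clip(values, -clip_bound, clip_bound)


def _chromosome_blocks(chromosomes: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous [start, stop) column runs of equal chromosome."""
    blocks = []
    start = 0
    for i in range(1, len(chromosomes) + 1):
        if i == len(chromosomes) or chromosomes[i] != chromosomes[start]:
            blocks.append((start, i))
            start = i
    return blocks


def moving_average(
    values: np.ndarray, chromosomes: np.ndarray, window: int = 100
) -> np.ndarray:
    """Centered moving average along the genome, per cell.

    At genome position ``i`` the window covers up to ``window`` genes
    centered on ``i`` (for even windows, one more gene to the right),
    truncated at chromosome boundaries so windows never span
    chromosomes. ``chromosomes`` labels each column; columns must be
    genome-ordered so chromosome runs are contiguous. ``window=1`` is
    the identity.
    """
    values = np.asarray(values, dtype=np.float64)
    chromosomes = np.asarray(chromosomes)
    if values.shape[1] != len(chromosomes):
        raise ValueError("one chromosome label per column required")
    if window == 1:
        return values.copy()
    left = (window - 1) // 2
    right = window // 2
    out = np.empty_like(values)
    for a, b in _chromosome_blocks(chromosomes):
        block = values[:, a:b]
        n = b - a
        csum = np.zeros((values.shape[0], n + 1))
        np.cumsum(block, axis=1, out=csum[:, 1:])
        idx = np.arange(n)
        lo = np.maximum(idx - left, 0)
        hi = np.minimum(idx + right + 1, n)
        out[:, a:b] = (csum[:, hi] - csum[:, lo]) / (hi - lo)
    return out


def reference_type_profiles(
    smoothed: np.ndarray,
    cell_ids: np.ndarray,
    reference_type_of: dict[str, str],
) -> np.ndarray:
    """Mean smoothed profile per reference cell type (types x positions).

    ``reference_type_of`` maps reference cell id -> cell type; types are
    processed in sorted order.
    """
    by_type: dict[str, list[int]] = {}
    pos = {c: i for i, c in enumerate(cell_ids)}
    for cell, ctype in reference_type_of.items():
        if cell in pos:
            by_type.setdefault(ctype, []).append(pos[cell])
    if not by_type:
        raise ValueError("no reference cells present in the matrix")
    return np.vstack(
        [smoothed[sorted(by_type[t])].mean(axis=0) for t in sorted(by_type)]
    )


def subtract_reference(values: np.ndarray, ref_profiles: np.ndarray) -> np.ndarray:
    """Calibrate smoothed values against the reference envelope.

    At each position, the maximum of the per-type reference means is
    subtracted from positive cell values and the minimum from negative
    values; zeros stay zero. Any result whose sign flipped relative to
    the input carries no evidence beyond the reference envelope and is
    set to zero.
    """
    ref_profiles = np.atleast_2d(np.asarray(ref_profiles, dtype=np.float64))
    if ref_profiles.shape[0] < 1:
        raise ValueError("at least one reference type profile required")
    if ref_profiles.shape[1] != values.shape[1]:
        raise ValueError("reference profiles and matrix positions differ")
    ref_max = ref_profiles.max(axis=0)
    ref_min = ref_profiles.min(axis=0)
    out = np.where(values > 0, values - ref_max, np.where(values < 0, values - ref_min, 0.0))
    flipped = np.sign(out) != np.sign(values)
    out[flipped] = 0.0
    return out


def apply_noise_floor(values: np.ndarray, noise_floor: float = 0.15) -> np.ndarray:
    """Zero all values strictly between -noise_floor and +noise_floor.

    Boundary values of exactly +/-noise_floor are kept (the band is
    open).
    """
    out = values.copy()
    out[np.abs(out) < noise_floor] = 0.0
    return out


def infer_cna(
    expr: ExpressionMatrix,
    annotation: pd.DataFrame,
    reference_type_of: dict[str, str],
    params: CNAParams = CNAParams(),
) -> CNAMatrix:
    """Full CNA-inference pipeline on an assembled analysis matrix.

    ``expr`` holds the cells of interest plus the reference cells (raw
    or log space); ``reference_type_of`` maps each reference cell id to
    its cell type. Pipeline order: log transform (if raw) -> gene filter
    -> gene centering -> genome ordering -> clipping -> moving average
    -> reference-envelope subtraction -> noise floor. The returned
    matrix includes the reference cells, whose values should be mostly
    exactly zero.
    """
    if expr.space == "raw":
        expr = preprocess.log_transform(expr)
    if expr.space != "log":
        raise ValueError("infer_cna expects a raw- or log-space matrix")
    expr = preprocess.filter_genes(expr, cutoff=params.gene_expr_cutoff)
    expr = preprocess.center_genes(expr)
    expr, kept_ann = order_genes(expr, annotation)
    clipped = clip_values(expr.values, params.clip_bound)
    chromosomes = kept_ann["chromosome"].to_numpy()
    smoothed = moving_average(clipped, chromosomes, params.window)
    ref_profiles = reference_type_profiles(smoothed, expr.cell_ids, reference_type_of)
    calibrated = subtract_reference(smoothed, ref_profiles)
    floored = apply_noise_floor(calibrated, params.noise_floor)
    ref_types = sorted(set(reference_type_of.values()))
    return CNAMatrix(
        values=floored,
        cell_ids=expr.cell_ids,
        gene_ids=expr.gene_ids,
        provenance={
            "clip_bound": params.clip_bound,
            "window": params.window,
            "noise_floor": params.noise_floor,
            "gene_expr_cutoff": params.gene_expr_cutoff,
            "reference": {
                "n_cells": len(reference_type_of),
                "types": ref_types,
            },
        },
    )
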