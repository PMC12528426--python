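"""Pooled normal reference construction for CNA calibration.

Not every sample carries enough of its own stromal cells to calibrate
copy-number inference, so a donor-balanced pooled reference is built
once: from every donor holding at least ``min_cells_per_donor`` cells of
an eligible stromal type (fibroblast, endothelial, adrenocortical),
exactly ``sample_per_donor`` cells of that type are drawn at random.
The per-donor cap keeps any one donor from dominating the reference and
thereby creating batch effects in the envelope.

An alternate per-patient mode supports the droplet-data design: the
patient's own stromal cells plus glia from normal tissue serve as the
reference, which absorbs glia-specific transcriptional programs that
would otherwise masquerade as copy-number events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

DEFAULT_ELIGIBLE = ("fibroblast", "endothelial", "adrenocortical")

REQUIRED_META_COLUMNS = ("cell_id", "donor_id", "cell_type")


class EmptyReferenceError(ValueError):
    """No (donor, cell type) pair qualifies for the reference."""


@dataclass(frozen=True)
class ReferencePolicy:
    eligible_types: tuple[str, ...] = DEFAULT_ELIGIBLE
    min_cells_per_donor: int = 15
    sample_per_donor: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_per_donor > self.min_cells_per_donor:
            raise ValueError("sample_per_donor must be <= min_cells_per_donor")
        if self.sample_per_donor < 1:
            raise ValueError("sample_per_donor must be >= 1")


@dataclass
class PooledReference:
    """Reference cell ids grouped by cell type, with a composition report."""

    cells_by_type: dict[str, list[str]]
    report: dict = field(default_factory=dict)

    @property
    def cell_ids(self) -> set[str]:
        return {c for cells in self.cells_by_type.values() for c in cells}

    def type_of(self) -> dict[str, str]:
        return {c: t for t, cells in self.cells_by_type.items() for c in cells}


def _check_metadata(meta: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata is missing required columns: {missing}")
    if meta["cell_id"].duplicated().any():
        raise ValueError("duplicate cell ids in metadata")


def build_pooled_reference(
    meta: pd.DataFrame, policy: ReferencePolicy = ReferencePolicy()
) -> PooledReference:
    """Donor-balanced sampling of eligible stromal cells.

    For each (donor, eligible type) with at least
    ``policy.min_cells_per_donor`` cells, exactly
    ``policy.sample_per_donor`` cells are drawn uniformly without
    replacement. Iteration is in sorted (type, donor) order so a fixed
    seed reproduces the same reference.
    """
    _check_metadata(meta)
    rng = np.random.default_rng(policy.seed)
    cells_by_type: dict[str, list[str]] = {}
    contributing: dict[str, list[str]] = {}
    for ctype in sorted(policy.eligible_types):
        selected: list[str] = []
        donors: list[str] = []
        sub = meta[meta["cell_type"] == ctype]
        for donor in sorted(sub["donor_id"].unique()):
            pool = sub.loc[sub["donor_id"] == donor, "cell_id"].sort_values().to_numpy()
            if len(pool) < policy.min_cells_per_donor:
                continue
            take = rng.choice(pool, size=policy.sample_per_donor, replace=False)
            selected.extend(sorted(take))
            donors.append(donor)
        if selected:
            cells_by_type[ctype] = selected
            contributing[ctype] = donors
    if not cells_by_type:
        raise EmptyReferenceError(
            "no (donor, cell type) pair reaches the minimum cell count"
        )
    per_type = {t: len(c) for t, c in cells_by_type.items()}
    report = {
        "per_type_counts": per_type,
        "contributing_donors": contributing,
        "total": sum(per_type.values()),
        "policy": {
            "eligible_types": list(policy.eligible_types),
            "min_cells_per_donor": policy.min_cells_per_donor,
            "sample_per_donor": policy.sample_per_donor,
            "seed": policy.seed,
        },
    }
    return PooledReference(cells_by_type=cells_by_type, report=report)


def assemble_patient_matrix(
    expr: ExpressionMatrix,
    meta: pd.DataFrame,
    patient: str,
    target_types: list[str],
    reference_ids: set[str] | PooledReference,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Combine one patient's target cells with the reference cells.

    Returns the combined matrix (patient target cells first, then the
    reference cells) and the matching metadata with an ``is_reference``
    flag. Downstream gene filtering and centering are applied to this
    combined matrix, not to the full cohort. Reference cells that are
    themselves among the patient's target cells are removed from the
    target side with a warning.
    """
    if isinstance(reference_ids, PooledReference):
        reference_ids = reference_ids.cell_ids
    _check_metadata(meta)
    if patient not in set(meta["donor_id"]):
        raise ValueError(f"patient {patient!r} absent from metadata")
    targets = meta[
        (meta["donor_id"] == patient) & (meta["cell_type"].isin(target_types))
    ]["cell_id"].tolist()
    if not targets:
        raise ValueError(
            f"patient {patient!r} has no cells of types {target_types}"
        )
    overlap = set(targets) & set(reference_ids)
    if overlap:
        warnings.warn(
            f"{len(overlap)} target cells are also reference cells; "
            "keeping them on the reference side only"
        )
        targets = [c for c in targets if c not in overlap]
        if not targets:
            raise ValueError("all target cells were reference cells")
    known = set(expr.cell_ids)
    ref_cells = sorted(c for c in reference_ids if c in known)
    if not ref_cells:
        raise EmptyReferenceError("no reference cells present in the matrix")
    combined = expr.subset_cells(targets + ref_cells)
    sub_meta = meta.set_index("cell_id").loc[targets + ref_cells].reset_index()
    sub_meta["is_reference"] = sub_meta["cell_id"].isin(set(ref_cells))
    return combined, sub_meta
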