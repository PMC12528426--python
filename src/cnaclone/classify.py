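"""Neoplastic cell classification and glial clonal-status assignment.

Two per-cell metrics quantify aberration: *CNA signal*, the mean of
absolute CNA values over the cell's top 20% positions by |CNA|, and
*CNA correlation*, the Pearson correlation between the cell's CNA
profile and the average profile of the top 20% of candidate cells by CNA
signal (the putative tumor profile). Cutoffs for both metrics are set at
median + 2 SD of the reference cells, and only cells strictly above both
cutoffs are called malignant.

Glial cells are additionally compared to the tumor's arm-event profile:
a glial cell sharing no event is non-neoplastic, one matching the full
tumor event set is a full match, and one sharing a nonempty proper
subset — canonically a lone 3p deletion, the VHL second hit — is
pre-neoplastic.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .matrix import CNAMatrix
from .subclones import NONE, call_arm_events

NOT_APPLICABLE = "not_applicable"
NON_NEOPLASTIC = "non_neoplastic"
PRE_NEOPLASTIC = "pre_neoplastic"
FULL_MATCH = "full_match"


def cna_signal(cell_profile: np.ndarray, top_fraction: float = 0.2) -> float:
    """Mean |CNA| over the cell's top positions by absolute value.

    ``ceil(top_fraction * n)`` positions are used; ties are broken by
    genome order.
    """
    v = np.abs(np.asarray(cell_profile, dtype=np.float64))
    if v.ndim != 1 or v.size == 0:
        raise ValueError("cell profile must be a nonempty vector")
    k = math.ceil(top_fraction * v.size)
    top = np.argsort(-v, kind="stable")[:k]
    return float(v[top].mean())


def tumor_profile(
    cna: CNAMatrix,
    cells: list[str] | np.ndarray,
    top_cell_fraction: float = 0.2,
    top_gene_fraction: float = 0.2,
) -> np.ndarray:
    """Average CNA profile of the top candidate cells by CNA signal.

    Cells are ranked by :func:`cna_signal`; ties are broken by cell-id
    order. The top ``ceil(top_cell_fraction * n_cells)`` profiles are
    averaged.
    """
    cells = sorted(cells)
    if len(cells) < 5:
        raise ValueError("need at least 5 candidate tumor cells")
    idx = cna.cell_index(cells)
    signals = np.array([cna_signal(cna.values[i], top_gene_fraction) for i in idx])
    k = math.ceil(top_cell_fraction * len(cells))
    top = np.argsort(-signals, kind="stable")[:k]
    return cna.values[idx[top]].mean(axis=0)


def cna_correlation(cell_profile: np.ndarray, profile: np.ndarray) -> float:
    """Pearson correlation between a cell's CNA profile and the tumor profile.

    Returns 0 (with a warning) when either vector is constant, where the
    correlation is undefined.
    """
    a = np.asarray(cell_profile, dtype=np.float64)
    b = np.asarray(profile, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("profiles have different lengths")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant profile; CNA correlation undefined, returning 0")
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def compute_cutoffs(
    reference_values: np.ndarray, sd_multiplier: float = 2.0
) -> float:
    """Median + sd_multiplier x sample SD (n-1) of the reference metric."""
    v = np.asarray(reference_values, dtype=np.float64)
    if v.size < 3:
        raise ValueError("need at least 3 reference cells to set a cutoff")
    return float(np.median(v) + sd_multiplier * np.std(v, ddof=1))


def classify_cells(
    cna: CNAMatrix,
    reference_ids: set[str],
    candidate_ids: list[str] | None = None,
    top_gene_fraction: float = 0.2,
    top_cell_fraction: float = 0.2,
    sd_multiplier: float = 2.0,
) -> pd.DataFrame:
    """Compute metrics, reference cutoffs and the malignant flag per cell.

    ``candidate_ids`` are the cells from which the tumor profile is
    built (default: all non-reference cells). Cutoffs come from the
    reference cells only; the malignant call is metric-based, so a
    reference cell that happens to exceed both cutoffs is flagged too.
    Returns one row per cell with cna_signal, cna_correlation, the
    applied cutoffs and the malignant flag.
    """
    all_ids = list(cna.cell_ids)
    ref_present = [c for c in all_ids if c in reference_ids]
    if not ref_present:
        raise ValueError("no reference cells present in the CNA matrix")
    if candidate_ids is None:
        candidate_ids = [c for c in all_ids if c not in reference_ids]
    if not candidate_ids:
        raise ValueError("no candidate tumor cells")

    profile = tumor_profile(
        cna, candidate_ids, top_cell_fraction, top_gene_fraction
    )
    signals = np.array(
        [cna_signal(cna.values[i], top_gene_fraction) for i in range(cna.n_cells)]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        correlations = np.array(
            [cna_correlation(cna.values[i], profile) for i in range(cna.n_cells)]
        )

    ref_idx = cna.cell_index(ref_present)
    signal_cutoff = compute_cutoffs(signals[ref_idx], sd_multiplier)
    correlation_cutoff = compute_cutoffs(correlations[ref_idx], sd_multiplier)
    malignant = (signals > signal_cutoff) & (correlations > correlation_cutoff)

    return pd.DataFrame(
        {
            "cell_id": cna.cell_ids,
            "cna_signal": signals,
            "cna_correlation": correlations,
            "signal_cutoff": signal_cutoff,
            "correlation_cutoff": correlation_cutoff,
            "is_reference": [c in reference_ids for c in all_ids],
            "malignant": malignant,
        }
    )


def _event_set(profile: dict[str, str]) -> set[tuple[str, str]]:
    return {(arm, call) for arm, call in profile.items() if call != NONE}


def classify_glial(
    glial_profiles: dict[str, dict[str, str]],
    tumor_events: dict[str, str],
) -> pd.DataFrame:
    """Assign clonal status to glial cells by event sharing with the tumor.

    ``glial_profiles`` maps glial cell id -> per-cell arm-event profile
    (from :func:`~cnaclone.subclones.call_arm_events` on single cells);
    ``tumor_events`` is the tumor clone's profile. A shared event must
    match in arm and direction. Status: non_neoplastic (no shared
    events), full_match (shared set equals the tumor set),
    pre_neoplastic (nonempty proper subset).
    """
    tumor_set = _event_set(tumor_events)
    if not tumor_set:
        warnings.warn("tumor event set is empty; all glial cells non-neoplastic")
    rows = []
    for cell in sorted(glial_profiles):
        cell_set = _event_set(glial_profiles[cell])
        shared = cell_set & tumor_set
        if not shared:
            status = NON_NEOPLASTIC
        elif shared == tumor_set:
            status = FULL_MATCH
        else:
            status = PRE_NEOPLASTIC
        rows.append(
            {
                "cell_id": cell,
                "n_cell_events": len(cell_set),
                "n_shared_events": len(shared),
                "shared_events": "|".join(sorted(f"{a}:{d}" for a, d in shared)),
                "glial_status": status,
            }
        )
    return pd.DataFrame(rows)


def per_cell_arm_profiles(
    cna: CNAMatrix,
    cells: list[str],
    annotation: pd.DataFrame,
    threshold: float = 0.15,
) -> dict[str, dict[str, str]]:
    """Arm-event profile of each individual cell (singleton cell sets)."""
    return {
        c: call_arm_events(cna, [c], annotation, threshold) for c in cells
    }
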