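"""Synthetic multi-donor cohort simulator with planted arm-level CNA events.

The generator emulates deep Smart-seq2-like single-nucleus data from
paraganglioma/pheochromocytoma-style cohorts: a neuroendocrine tumor
compartment, Schwann/sustentacular glia, and stromal cell types
(fibroblast, endothelial, adrenocortical) across one or more donors.
Gene baselines are lognormal in linear units (log2 means ~ Normal(5, 2)),
cell types carry their own log2-space expression programs, and clonal
copy-number events are planted as additive shifts in log2 space — a
chromosome-arm deletion of effect ``e`` lowers every gene on that arm by
``e`` log2 units in its carrier cells before back-transformation to
TPM-like units. Carrier sets per cell type are sampled at the configured
fractions, so the truth labels make every event recoverable downstream.

Not emulated: transcriptome-wide co-expression programs, cell-cycle
structure, allele-specific expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

KNOWN_CELL_TYPES = (
    "neuroendocrine",
    "schwann",
    "fibroblast",
    "endothelial",
    "adrenocortical",
)

COMPARTMENTS = {
    "neuroendocrine": "neuroendocrine",
    "schwann": "glial",
    "fibroblast": "stromal",
    "endothelial": "stromal",
    "adrenocortical": "stromal",
}

#: Gene spacing (bp) used for synthetic coordinates; value is arbitrary,
#: only the order matters downstream.
GENE_SPACING = 100_000


class ConfigurationError(ValueError):
    """Raised when a cohort or genome specification is inconsistent."""


@dataclass(frozen=True)
class PlantedEvent:
    """A clonal arm-level copy-number event planted in the simulation.

    ``effect`` is the per-gene shift in log2 units (always positive; the
    sign is applied from ``direction``). ``carriers`` maps cell type to
    the fraction of that type carrying the event.
    """

    arm: str
    direction: str  # "deletion" | "amplification"
    effect: float
    carriers: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.direction not in ("deletion", "amplification"):
            raise ConfigurationError(f"unknown direction {self.direction!r}")
        if not self.effect > 0:
            raise ConfigurationError("event effect must be > 0")
        for ctype, frac in self.carriers.items():
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(
                    f"carrier fraction for {ctype} must be in [0, 1], got {frac}"
                )

    @property
    def key(self) -> str:
        return f"{self.arm}:{self.direction}"

    @property
    def signed_effect(self) -> float:
        return -self.effect if self.direction == "deletion" else self.effect


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort.

    ``cells_per_type_per_donor`` maps ``(donor, cell_type) -> count``.
    ``genome`` is an arm table: list of ``(arm, gene_count)`` pairs in
    genome order (e.g. ``[("1p", 120), ("1q", 140), ...]``).
    """

    donors: list[str]
    cells_per_type_per_donor: dict[tuple[str, str], int]
    genome: list[tuple[str, int]]
    events: list[PlantedEvent] = field(default_factory=list)
    noise_sd: float = 0.6
    depth_sd: float = 0.0
    dropout_rate: float = 0.0
    type_effect_sd: float = 0.2
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        arms = {arm for arm, _ in self.genome}
        if len(arms) != len(self.genome):
            raise ConfigurationError("duplicate arms in genome table")
        for arm, n in self.genome:
            if n <= 0:
                raise ConfigurationError(f"arm {arm!r} declared with {n} genes")
        for ev in self.events:
            if ev.arm not in arms:
                raise ConfigurationError(f"event on unknown arm {ev.arm!r}")
            for ctype in ev.carriers:
                if ctype not in KNOWN_CELL_TYPES:
                    raise ConfigurationError(f"unknown carrier cell type {ctype!r}")
        for (donor, ctype), n in self.cells_per_type_per_donor.items():
            if donor not in self.donors:
                raise ConfigurationError(f"cell counts reference unknown donor {donor!r}")
            if ctype not in KNOWN_CELL_TYPES:
                raise ConfigurationError(f"unknown cell type {ctype!r}")
            if n < 0:
                raise ConfigurationError("cell counts must be >= 0")
        if self.noise_sd < 0 or self.depth_sd < 0 or self.type_effect_sd < 0:
            raise ConfigurationError("standard deviations must be >= 0")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ConfigurationError("dropout_rate must be in [0, 1]")

    @property
    def n_genes(self) -> int:
        return sum(n for _, n in self.genome)

    @property
    def cell_types(self) -> list[str]:
        return sorted({ct for _, ct in self.cells_per_type_per_donor})


def build_genome_model(
    n_genes: int, arm_table: Sequence[tuple[str, int]]
) -> pd.DataFrame:
    """Build a gene annotation table for a synthetic genome.

    Each arm contributes ``gene_count`` genes with strictly increasing
    start coordinates within its chromosome; ``order_index`` is the
    genome-wide rank. The chromosome name is the arm id minus its final
    p/q letter. Returns a DataFrame with columns ``gene_id``,
    ``chromosome``, ``start``, ``end``, ``arm``, ``order_index``.
    """
    total = sum(c for _, c in arm_table)
    if total != n_genes:
        raise ConfigurationError(
            f"arm table holds {total} genes but n_genes={n_genes}"
        )
    for arm, count in arm_table:
        if count <= 0:
            raise ConfigurationError(f"arm {arm!r} has {count} genes (must be >= 1)")
        if len(arm) < 2 or arm[-1] not in "pq":
            raise ConfigurationError(f"arm id {arm!r} must end in 'p' or 'q'")

    rows = []
    order = 0
    next_start: dict[str, int] = {}
    for arm, count in arm_table:
        chrom = arm[:-1]
        start = next_start.get(chrom, 0)
        for i in range(count):
            rows.append(
                {
                    "gene_id": f"g_{arm}_{i:04d}",
                    "chromosome": chrom,
                    "start": start,
                    "end": start + GENE_SPACING // 2,
                    "arm": arm,
                    "order_index": order,
                }
            )
            start += GENE_SPACING
            order += 1
        next_start[chrom] = start
    return pd.DataFrame(rows)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def simulate_expression(
    spec: CohortSpec,
) -> tuple["ExpressionMatrix", pd.DataFrame, pd.DataFrame]:
    """Simulate a raw TPM-like cells x genes matrix with planted events.

    Returns ``(expr, metadata, truth)`` where ``expr`` is an
    :class:`~cnaclone.matrix.ExpressionMatrix` in ``raw`` space,
    ``metadata`` has columns cell_id/donor_id/cell_type/compartment and
    ``truth`` additionally lists the carried events per cell
    (pipe-separated ``arm:direction`` keys, empty string for none).

    The per-cell log2 profile is
    ``gene_mean + type_program + sum(signed event effects) + N(0, noise_sd)``
    back-transformed through the inverse of the log2((TPM/10)+1) map and
    clipped at zero, then optionally depth-scaled and dropped out. The
    same spec (including seed) reproduces bit-identical output.
    """
    from .matrix import ExpressionMatrix

    rng = np.random.default_rng(spec.seed)
    annotation = build_genome_model(spec.n_genes, spec.genome)
    arm_index = {
        arm: annotation.index[annotation["arm"] == arm].to_numpy()
        for arm, _ in spec.genome
    }

    gene_means = rng.normal(spec.baseline_log2_mean, spec.baseline_log2_sd, spec.n_genes)
    type_programs = {
        ctype: rng.normal(0.0, spec.type_effect_sd, spec.n_genes)
        for ctype in sorted(KNOWN_CELL_TYPES)
    }

    cell_rows: list[dict] = []
    for donor in sorted(spec.donors):
        for ctype in sorted(KNOWN_CELL_TYPES):
            n = spec.cells_per_type_per_donor.get((donor, ctype), 0)
            for i in range(n):
                cell_rows.append(
                    {
                        "cell_id": f"{donor}_{ctype}_{i:04d}",
                        "donor_id": donor,
                        "cell_type": ctype,
                        "compartment": COMPARTMENTS[ctype],
                    }
                )
    if not cell_rows:
        raise ConfigurationError("cohort spec declares zero cells")
    meta = pd.DataFrame(cell_rows)
    n_cells = len(meta)

    # carrier assignment: per (event, donor, type), round(fraction * count)
    # cells sampled without replacement
    carried: list[set[str]] = [set() for _ in range(n_cells)]
    group_positions = {
        key: grp.index.to_numpy() for key, grp in meta.groupby(["donor_id", "cell_type"])
    }
    for ev in spec.events:
        for donor in sorted(spec.donors):
            for ctype in sorted(ev.carriers):
                frac = ev.carriers[ctype]
                pos = group_positions.get((donor, ctype))
                if pos is None or len(pos) == 0:
                    continue
                k = _round_half_up(frac * len(pos))
                chosen = rng.choice(pos, size=k, replace=False) if k else []
                for c in chosen:
                    carried[c].add(ev.key)

    log2_expr = np.tile(gene_means, (n_cells, 1))
    for ctype, program in type_programs.items():
        mask = (meta["cell_type"] == ctype).to_numpy()
        if mask.any():
            log2_expr[mask] += program
    for ev in spec.events:
        cols = arm_index[ev.arm]
        rows = np.array([ev.key in s for s in carried])
        if rows.any():
            log2_expr[np.ix_(rows, cols)] += ev.signed_effect
    if spec.noise_sd > 0:
        log2_expr += rng.normal(0.0, spec.noise_sd, log2_expr.shape)

    # inverse of log2((TPM/10)+1); negative log2 values floor at TPM=0
    tpm = np.maximum(10.0 * (np.exp2(log2_expr) - 1.0), 0.0)
    if spec.depth_sd > 0:
        depth = np.exp2(rng.normal(0.0, spec.depth_sd, (n_cells, 1)))
        tpm = tpm * depth
    if spec.dropout_rate > 0:
        keep = rng.random(tpm.shape) >= spec.dropout_rate
        tpm = tpm * keep

    expr = ExpressionMatrix(
        values=tpm,
        cell_ids=meta["cell_id"].to_numpy(),
        gene_ids=annotation["gene_id"].to_numpy(),
        space="raw",
    )
    truth = meta.copy()
    truth["events"] = ["|".join(sorted(s)) for s in carried]
    return expr, meta, truth


def default_arm_table() -> list[tuple[str, int]]:
    """Miniature ten-arm genome used by the default scenarios.

    Five chromosomes with p and q arms, 2240 genes total. Arms carry
    150-260 genes each so that, after the >4.5 expression filter removes
    roughly 40% of genes, every arm still spans well over one 100-gene
    smoothing window: arm-level events stay resolvable and the window's
    bleed across a centromere stays a small fraction of the neighbouring
    arm. 3p carries 150 genes, the canonical event arm of the VHL-like
    scenario.
    """
    return [
        ("1p", 220),
        ("1q", 260),
        ("2p", 220),
        ("2q", 260),
        ("3p", 150),
        ("3q", 260),
        ("4p", 200),
        ("4q", 240),
        ("5p", 180),
        ("5q", 250),
    ]


def vhl_like_cohort(
    seed: int = 0,
    n_tumor: int = 300,
    n_glia: int = 200,
    glia_carrier_fraction: float = 0.1,
    effect: float = 0.6,
    noise_sd: float = 1.0,
    n_stromal_each: int = 40,
) -> CohortSpec:
    """Canonical single-donor scenario mirroring a VHL-mutant tumor.

    All tumor (neuroendocrine) cells carry a 3p deletion — the second hit
    — plus a 1q amplification as a later progression event; a minority of
    Schwann/sustentacular glia carry the 3p deletion only, making them
    pre-neoplastic by definition. Stromal cell types are present in
    reference-eligible numbers.
    """
    donor = "D1"
    counts = {
        (donor, "neuroendocrine"): n_tumor,
        (donor, "schwann"): n_glia,
        (donor, "fibroblast"): n_stromal_each,
        (donor, "endothelial"): n_stromal_each,
        (donor, "adrenocortical"): n_stromal_each,
    }
    events = [
        PlantedEvent(
            arm="3p",
            direction="deletion",
            effect=effect,
            carriers={"neuroendocrine": 1.0, "schwann": glia_carrier_fraction},
        ),
        PlantedEvent(
            arm="1q",
            direction="amplification",
            effect=effect,
            carriers={"neuroendocrine": 1.0},
        ),
    ]
    return CohortSpec(
        donors=[donor],
        cells_per_type_per_donor=counts,
        genome=default_arm_table(),
        events=events,
        noise_sd=noise_sd,
        seed=seed,
    )


def null_cohort(seed: int = 0, n_each: int = 40, donors: int = 3) -> CohortSpec:
    """Stromal-only cohort with no planted events, for null calibration."""
    donor_ids = [f"D{i + 1}" for i in range(donors)]
    counts = {
        (d, ct): n_each
        for d in donor_ids
        for ct in ("fibroblast", "endothelial", "adrenocortical")
    }
    return CohortSpec(
        donors=donor_ids,
        cells_per_type_per_donor=counts,
        genome=default_arm_table(),
        events=[],
        seed=seed,
    )
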