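"""End-to-end orchestration of the analysis stages.

``run_pipeline`` chains simulate (optional) -> QC -> pooled reference ->
per-patient CNA inference -> subclones -> neoplastic and glial
classification -> differential expression, writing every stage's output
plus a manifest (config, config hash, per-stage seeds) that allows an
exact re-run. Any stage failure is re-raised with the stage name
attached.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

from . import __version__, classify, cna, de, io, preprocess, reference, subclones
from .config import PipelineConfig
from .synthetic import CohortSpec, build_genome_model, simulate_expression, vhl_like_cohort

TARGET_TYPES = ["neuroendocrine", "schwann"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
        return inner
    return wrap


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    cohort_spec: CohortSpec | None = None,
    expr=None,
    meta: pd.DataFrame | None = None,
    annotation: pd.DataFrame | None = None,
    exclude: list[str] | None = None,
    dry_run: bool = False,
) -> dict:
    """Run every stage and write an output bundle under ``out_dir``.

    With no explicit inputs, a synthetic cohort is simulated from
    ``cohort_spec`` (default: the canonical VHL-like single-donor
    scenario seeded from the config). Returns a dict of in-memory
    results keyed by stage.
    """
    out = Path(out_dir)
    if expr is None and cohort_spec is None:
        cohort_spec = vhl_like_cohort(seed=config.stage_seed("simulate"))
    if dry_run:
        if expr is not None and meta is None:
            raise StageError("validate", ValueError("expression given without metadata"))
        return {"dry_run": True, "config_hash": config.config_hash()}

    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    if expr is None:
        expr, meta, truth = _stage("simulate")(simulate_expression)(cohort_spec)
        annotation = build_genome_model(
            cohort_spec.n_genes, cohort_spec.genome
        )
        io.write_table(truth, out / "truth_labels.tsv")
        results["truth"] = truth
    if meta is None or annotation is None:
        raise StageError("validate", ValueError("metadata and annotation are required"))

    qc_expr, qc_report = _stage("preprocess")(preprocess.qc_filter)(
        expr,
        preprocess.QCThresholds(
            min_genes_per_cell=config.qc_min_genes,
            max_mito_fraction=config.qc_max_mito,
        ),
        exclude,
    )
    meta = meta[meta["cell_id"].isin(set(qc_expr.cell_ids))].reset_index(drop=True)
    io.write_json(qc_report, out / "qc_report.json")
    results["qc_report"] = qc_report

    policy = reference.ReferencePolicy(
        min_cells_per_donor=config.ref_min_cells,
        sample_per_donor=config.ref_sample_n,
        seed=config.stage_seed("reference"),
    )
    pooled = _stage("reference")(reference.build_pooled_reference)(meta, policy)
    io.write_json(pooled.report, out / "reference_report.json")
    io.write_table(
        pd.DataFrame(
            [(c, t) for t, cells in pooled.cells_by_type.items() for c in cells],
            columns=["cell_id", "cell_type"],
        ),
        out / "reference_cells.tsv",
    )
    results["reference"] = pooled

    params = cna.CNAParams(
        clip_bound=config.clip_bound,
        window=config.window,
        noise_floor=config.noise_floor,
        gene_expr_cutoff=config.gene_expr_cutoff,
    )
    ref_type_of = pooled.type_of()
    per_patient: dict[str, dict] = {}
    patients = sorted(
        meta.loc[meta["cell_type"].isin(TARGET_TYPES), "donor_id"].unique()
    )
    for patient in patients:
        pres: dict = {}
        combined, sub_meta = _stage("assemble")(reference.assemble_patient_matrix)(
            qc_expr, meta, patient, TARGET_TYPES, pooled.cell_ids
        )
        cna_matrix = _stage("infer-cna")(cna.infer_cna)(
            combined, annotation, ref_type_of, params
        )
        io.write_cna(cna_matrix, out / f"cna_{patient}.tsv")
        pres["cna"] = cna_matrix

        non_ref = sub_meta.loc[~sub_meta["is_reference"], "cell_id"].tolist()
        sub = _stage("subclones")(subclones.detect_subclones)(
            cna_matrix.subset_cells(non_ref),
            annotation,
            fraction=config.subclone_fraction,
            k_neighbors=config.k_neighbors,
            threshold=config.arm_threshold,
            seed=config.stage_seed("subclones"),
        )
        io.write_json(
            {
                "profiles": {str(k): v for k, v in sub.profiles.items()},
                "merge_history": sub.merge_history,
            },
            out / f"subclones_{patient}.json",
        )
        io.write_table(sub.assignments(), out / f"subclones_{patient}.tsv")
        pres["subclones"] = sub

        ne_cells = sub_meta.loc[
            (~sub_meta["is_reference"]) & (sub_meta["cell_type"] == "neuroendocrine"),
            "cell_id",
        ].tolist()
        records = _stage("classify")(classify.classify_cells)(
            cna_matrix,
            pooled.cell_ids,
            candidate_ids=ne_cells or None,
            top_gene_fraction=config.top_gene_frac,
            top_cell_fraction=config.top_cell_frac,
            sd_multiplier=config.sd_multiplier,
        )
        pres["classification"] = records

        glial_cells = sub_meta.loc[
            (~sub_meta["is_reference"]) & (sub_meta["cell_type"] == "schwann"),
            "cell_id",
        ].tolist()
        if ne_cells and glial_cells:
            malignant_ne = records.loc[
                records["malignant"] & records["cell_id"].isin(ne_cells), "cell_id"
            ].tolist()
            tumor_cells = malignant_ne if malignant_ne else ne_cells
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tumor_events = subclones.call_arm_events(
                    cna_matrix, tumor_cells, annotation, config.arm_threshold
                )
                glial_profiles = classify.per_cell_arm_profiles(
                    cna_matrix, glial_cells, annotation, config.arm_threshold
                )
            glial_status = _stage("classify")(classify.classify_glial)(
                glial_profiles, tumor_events
            )
            records = records.merge(
                glial_status[["cell_id", "glial_status"]], on="cell_id", how="left"
            )
            records["glial_status"] = records["glial_status"].fillna("not_applicable")
            pres["tumor_events"] = tumor_events
            pres["classification"] = records
        io.write_table(pres["classification"], out / f"classification_{patient}.tsv")
        per_patient[patient] = pres
    results["per_patient"] = per_patient

    log_expr = _stage("de")(preprocess.log_transform)(qc_expr)
    labels = meta.set_index("cell_id")["cell_type"]
    type_counts = labels.value_counts()
    if (type_counts >= 3).sum() >= 2 and "neuroendocrine" in type_counts:
        usable = labels[labels.isin(type_counts[type_counts >= 3].index)]
        sub_expr = log_expr.subset_cells(list(usable.index))
        degs = _stage("de")(de.specific_degs)(
            sub_expr, usable, "neuroendocrine",
            lfc_min=config.de_lfc_min, alpha=config.de_alpha,
        )
        io.write_table(pd.DataFrame({"gene_id": degs}), out / "specific_degs_neuroendocrine.tsv")
        results["specific_degs"] = degs

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seeds": {
            s: config.stage_seed(s) for s in ("simulate", "reference", "subclones")
        },
        "patients": patients,
    }
    io.write_json(manifest, out / "manifest.json")
    results["manifest"] = manifest
    return results
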