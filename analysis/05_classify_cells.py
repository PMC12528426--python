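#!/usr/bin/env python
"""Neoplastic classification and glial clonal status versus truth.

Computes CNA signal and CNA correlation per cell, sets cutoffs at
median + 2 SD of the reference cells, flags malignant cells, then
assigns each glial cell a clonal status by comparing its arm events
with the tumor profile. Reports sensitivity/specificity for the planted
pre-neoplastic glia.
"""

import warnings
from pathlib import Path

import pandas as pd

from cnaclone import classify, io
from cnaclone.subclones import call_arm_events

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def main() -> None:
    if not (SCRATCH / "cna_D1.tsv").exists():
        raise SystemExit("run analysis/03_infer_cna.py first")
    result_cna = io.read_cna(SCRATCH / "cna_D1.tsv")
    annotation = io.read_annotation(SCRATCH / "genes.bed", SCRATCH / "arms.tsv")
    sub_meta = pd.read_csv(SCRATCH / "cna_cells.tsv", sep="\t")
    truth = pd.read_csv(SCRATCH / "truth_labels.tsv", sep="\t").fillna({"events": ""})

    ref_ids = set(sub_meta.loc[sub_meta["is_reference"], "cell_id"])
    ne_cells = sub_meta.loc[
        (~sub_meta["is_reference"]) & (sub_meta["cell_type"] == "neuroendocrine"),
        "cell_id",
    ].tolist()
    glial_cells = sub_meta.loc[
        (~sub_meta["is_reference"]) & (sub_meta["cell_type"] == "schwann"),
        "cell_id",
    ].tolist()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        records = classify.classify_cells(
            result_cna, ref_ids, candidate_ids=ne_cells
        ).set_index("cell_id")
        malignant_ne = [c for c in ne_cells if records.at[c, "malignant"]]
        tumor_events = call_arm_events(result_cna, malignant_ne, annotation)
        glial_profiles = classify.per_cell_arm_profiles(
            result_cna, glial_cells, annotation
        )
    status = classify.classify_glial(glial_profiles, tumor_events).set_index("cell_id")

    tset = truth.set_index("cell_id")
    carriers = [c for c in glial_cells if tset.at[c, "events"] != ""]
    noncarriers = [c for c in glial_cells if tset.at[c, "events"] == ""]
    is_pre = status["glial_status"] == "pre_neoplastic"
    sensitivity = float(is_pre[carriers].mean())
    specificity = float((~is_pre[noncarriers]).mean())

    out = records.reset_index().merge(
        status.reset_index()[["cell_id", "glial_status"]], on="cell_id", how="left"
    )
    out["glial_status"] = out["glial_status"].fillna("not_applicable")
    RESULTS.mkdir(parents=True, exist_ok=True)
    io.write_table(out, RESULTS / "classification.tsv")
    io.write_json(
        {
            "signal_cutoff": float(records["signal_cutoff"].iloc[0]),
            "correlation_cutoff": float(records["correlation_cutoff"].iloc[0]),
            "neuroendocrine_malignant": f"{len(malignant_ne)}/{len(ne_cells)}",
            "tumor_events": {a: v for a, v in tumor_events.items() if v != "none"},
            "glial_status_counts": status["glial_status"].value_counts().to_dict(),
            "preneoplastic_sensitivity": round(sensitivity, 3),
            "preneoplastic_specificity": round(specificity, 3),
        },
        RESULTS / "classification_summary.json",
    )

    print(f"cutoffs: signal {records['signal_cutoff'].iloc[0]:.3f}, "
          f"correlation {records['correlation_cutoff'].iloc[0]:.3f}")
    print(f"neuroendocrine malignant: {len(malignant_ne)}/{len(ne_cells)}")
    events = {a: v for a, v in tumor_events.items() if v != "none"}
    print(f"tumor arm events: {events}")
    print(f"glial status counts: {status['glial_status'].value_counts().to_dict()}")
    print(f"pre-neoplastic glia: sensitivity {sensitivity:.2f}, "
          f"specificity {specificity:.2f}")


if __name__ == "__main__":
    main()
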