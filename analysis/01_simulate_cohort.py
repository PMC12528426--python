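#!/usr/bin/env python
"""Simulate the canonical VHL-like cohort.

One donor: 300 neuroendocrine tumor cells all carrying a 3p deletion
(the VHL second hit) plus a 1q amplification; 200 Schwann/sustentacular
glia of which 10% carry the 3p deletion only (planted pre-neoplastic
cells); 40 cells each of fibroblast, endothelial and adrenocortical
stroma. Writes the expression matrix under scratch/ (large) and the
small tables under results/.
"""

from pathlib import Path

import pandas as pd

from cnaclone import io
from cnaclone.synthetic import build_genome_model, simulate_expression, vhl_like_cohort

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"
SEED = 1


def main() -> None:
    spec = vhl_like_cohort(seed=SEED)
    expr, meta, truth = simulate_expression(spec)
    annotation = build_genome_model(spec.n_genes, spec.genome)

    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    io.write_expression_mtx(expr, SCRATCH / "expression")
    io.write_table(meta, SCRATCH / "metadata.tsv")
    io.write_table(truth, SCRATCH / "truth_labels.tsv")
    io.write_annotation(annotation, SCRATCH / "genes.bed", SCRATCH / "arms.tsv")

    summary = (
        truth.assign(carries_event=truth["events"] != "")
        .groupby(["cell_type", "events"], sort=True)
        .size()
        .rename("n_cells")
        .reset_index()
    )
    io.write_table(summary, RESULTS / "cohort_composition.tsv")

    print(f"simulated {expr.n_cells} cells x {expr.n_genes} genes (seed {SEED})")
    print(summary.to_string(index=False))
    print(f"expression + truth written to {SCRATCH}")


if __name__ == "__main__":
    main()
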