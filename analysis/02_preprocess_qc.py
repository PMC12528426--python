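#!/usr/bin/env python
"""Quality control and matrix construction on the simulated cohort.

Applies the cell filters (>=1000 expressed genes, mitochondrial fraction
< 30%), then log2((TPM/10)+1) transform, the >4.5 mean-expression gene
filter and per-gene centering, and reports what survives each step.
Synthetic nuclei are deep, so the interesting number here is the gene
filter, which sets how many genome positions the moving average sees.
"""

from pathlib import Path

from cnaclone import io, preprocess

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def main() -> None:
    if not (SCRATCH / "expression").exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    expr = io.read_expression(SCRATCH / "expression")

    filtered, report = preprocess.qc_filter(expr, preprocess.QCThresholds())
    logged = preprocess.log_transform(filtered)
    kept = preprocess.filter_genes(logged)
    centered = preprocess.center_genes(kept)

    report["genes_input"] = expr.n_genes
    report["genes_passing_4_5_filter"] = kept.n_genes
    RESULTS.mkdir(parents=True, exist_ok=True)
    io.write_json(report, RESULTS / "qc_report.json")

    print(f"cells: {report['n_input']} in, {report['n_kept']} kept "
          f"({report['removed_low_gene_count']} low-complexity, "
          f"{report['removed_high_mito']} high-mito)")
    print(f"genes: {expr.n_genes} in, {kept.n_genes} with mean log expression > 4.5")
    print(f"centered matrix: {centered.n_cells} x {centered.n_genes} "
          f"(column means |m| < 1e-9: {bool((abs(centered.values.mean(0)) < 1e-9).all())})")


if __name__ == "__main__":
    main()
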