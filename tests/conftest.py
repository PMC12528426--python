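import warnings

import numpy as np
import pytest

from cnaclone import classify, cna, reference, subclones, synthetic
from cnaclone.matrix import ExpressionMatrix


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def tiny_annotation():
    """Two chromosomes, 20 genes (1p/1q/2p/2q with 5 each)."""
    return synthetic.build_genome_model(
        20, [("1p", 5), ("1q", 5), ("2p", 5), ("2q", 5)]
    )


def small_matrix(values, space="log"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return ExpressionMatrix(
        values=values,
        cell_ids=[f"c{i}" for i in range(values.shape[0])],
        gene_ids=[f"g{j}" for j in range(values.shape[1])],
        space=space,
    )


@pytest.fixture(scope="session")
def vhl_bundle():
    """One full run of the canonical VHL-like scenario (seed fixed).

    All tumor cells carry 3p deletion + 1q amplification; 10% of glia
    carry the 3p deletion only. Bundles every intermediate the
    downstream tests interrogate.
    """
    spec = synthetic.vhl_like_cohort(seed=11)
    expr, meta, truth = synthetic.simulate_expression(spec)
    ann = synthetic.build_genome_model(spec.n_genes, spec.genome)
    pooled = reference.build_pooled_reference(meta, reference.ReferencePolicy(seed=11))
    combined, sub_meta = reference.assemble_patient_matrix(
        expr, meta, "D1", ["neuroendocrine", "schwann"], pooled.cell_ids
    )
    cm = cna.infer_cna(combined, ann, pooled.type_of())
    non_ref = sub_meta.loc[~sub_meta["is_reference"], "cell_id"].tolist()
    tumor_cna = cm.subset_cells(non_ref)
    initial_labels = subclones.overcluster_cells(
        subclones.select_top_positions(tumor_cna), seed=11
    )
    result = subclones.merge_identical_clusters(initial_labels, tumor_cna, ann)
    tset = truth.set_index("cell_id")
    ne_cells = sub_meta.loc[
        (~sub_meta["is_reference"]) & (sub_meta["cell_type"] == "neuroendocrine"),
        "cell_id",
    ].tolist()
    glial_cells = sub_meta.loc[
        (~sub_meta["is_reference"]) & (sub_meta["cell_type"] == "schwann"),
        "cell_id",
    ].tolist()
    carrier_glia = {c for c in glial_cells if tset.at[c, "events"] != ""}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        records = classify.classify_cells(cm, pooled.cell_ids, candidate_ids=ne_cells)
    return {
        "spec": spec,
        "expr": expr,
        "meta": meta,
        "truth": truth,
        "annotation": ann,
        "pooled": pooled,
        "cna": cm,
        "sub_meta": sub_meta,
        "tumor_cna": tumor_cna,
        "initial_labels": initial_labels,
        "subclones": result,
        "ne_cells": ne_cells,
        "glial_cells": glial_cells,
        "carrier_glia": carrier_glia,
        "classification": records,
    }
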