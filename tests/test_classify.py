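import math
import warnings

import numpy as np
import pytest

from cnaclone import classify
from cnaclone.classify import (
    classify_cells,
    classify_glial,
    cna_correlation,
    cna_signal,
    compute_cutoffs,
    per_cell_arm_profiles,
    tumor_profile,
)
from cnaclone.matrix import CNAMatrix


def cna_from(values, cell_ids=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if cell_ids is None:
        cell_ids = [f"c{i:03d}" for i in range(values.shape[0])]
    return CNAMatrix(
        values=values,
        cell_ids=cell_ids,
        gene_ids=[f"g{j}" for j in range(values.shape[1])],
    )


class TestCNASignal:
    def test_all_zeros(self):
        assert cna_signal(np.zeros(10)) == 0.0

    def test_sort_and_mean_oracle(self):
        profile = np.array([0.9, 0.7] + [0.1] * 8)
        assert cna_signal(profile) == pytest.approx(0.8)

    def test_constant_absolute_value(self):
        assert cna_signal(np.full(15, -0.3)) == pytest.approx(0.3)

    def test_ceil_of_fraction_used(self):
        # 7 positions, top_fraction 0.2 -> ceil(1.4) = 2 positions
        profile = np.array([1.0, 0.5, 0.1, 0.1, 0.1, 0.1, 0.1])
        assert cna_signal(profile) == pytest.approx(0.75)

    def test_scale_equivariance(self, rng):
        profile = rng.normal(size=50)
        assert cna_signal(3.0 * profile) == pytest.approx(3.0 * cna_signal(profile))


class TestTumorProfile:
    def test_identical_cells_return_that_profile(self):
        row = np.array([0.5, -0.3, 0.0, 0.2])
        m = cna_from(np.tile(row, (6, 1)))
        np.testing.assert_allclose(tumor_profile(m, list(m.cell_ids)), row)

    def test_top_clone_ranked_by_hand(self):
        quiet = np.zeros(10)
        loud = np.array([1.0] * 5 + [-1.0] * 5)
        values = np.vstack([quiet] * 8 + [loud, loud * 0.9])
        m = cna_from(values)
        # top 20% of 10 cells = 2 cells: the two loud ones
        expected = (loud + 0.9 * loud) / 2
        np.testing.assert_allclose(tumor_profile(m, list(m.cell_ids)), expected)

    def test_tie_break_by_cell_id_deterministic(self):
        row = np.array([0.4, -0.4, 0.4, -0.4, 0.4])
        m = cna_from(np.tile(row, (5, 1)))
        a = tumor_profile(m, list(m.cell_ids))
        b = tumor_profile(m, list(m.cell_ids)[::-1])
        np.testing.assert_allclose(a, b)

    def test_too_few_candidates_rejected(self):
        m = cna_from(np.zeros((4, 5)))
        with pytest.raises(ValueError):
            tumor_profile(m, list(m.cell_ids))


class TestCNACorrelation:
    def test_identical_nonconstant_is_one(self):
        v = np.array([0.5, -0.2, 0.1, 0.0])
        assert cna_correlation(v, v) == pytest.approx(1.0)

    def test_negated_is_minus_one(self):
        v = np.array([0.5, -0.2, 0.1, 0.0])
        assert cna_correlation(v, -v) == pytest.approx(-1.0)

    def test_orthogonal_toy_vectors(self):
        assert cna_correlation(
            np.array([1.0, -1.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.0, -1.0])
        ) == pytest.approx(0.0)

    def test_constant_vector_returns_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            assert cna_correlation(np.zeros(4), np.array([1.0, 2, 3, 4])) == 0.0


class TestCutoffs:
    def test_all_equal_gives_that_value(self):
        assert compute_cutoffs(np.full(5, 2.5)) == pytest.approx(2.5)

    def test_hand_computed_example(self):
        values = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        expected = 2.0 + 2.0 * math.sqrt(2.5)
        assert compute_cutoffs(values) == pytest.approx(expected)

    def test_zero_multiplier_gives_median(self):
        assert compute_cutoffs(np.array([1.0, 5.0, 9.0]), 0.0) == pytest.approx(5.0)

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError):
            compute_cutoffs(np.array([1.0, 2.0]))


class TestClassifyCells:
    def test_planted_clone_recovered(self, vhl_bundle):
        records = vhl_bundle["classification"].set_index("cell_id")
        truth = vhl_bundle["truth"].set_index("cell_id")
        ne = vhl_bundle["ne_cells"]
        glia = vhl_bundle["glial_cells"]
        noncarrier_glia = [c for c in glia if truth.at[c, "events"] == ""]
        assert records.loc[ne, "malignant"].mean() >= 0.9
        assert records.loc[noncarrier_glia, "malignant"].mean() <= 0.05

    def test_invariant_malignant_iff_both_cutoffs(self, vhl_bundle):
        rec = vhl_bundle["classification"]
        expected = (rec["cna_signal"] > rec["signal_cutoff"]) & (
            rec["cna_correlation"] > rec["correlation_cutoff"]
        )
        assert (rec["malignant"] == expected).all()

    def test_scale_invariance_of_the_decision(self, vhl_bundle):
        """Scaling all CNA values by lambda>0 scales signals, keeps
        correlations, and leaves the malignant partition unchanged."""
        cm = vhl_bundle["cna"]
        scaled = CNAMatrix(cm.values * 2.0, cm.cell_ids, cm.gene_ids)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = vhl_bundle["classification"]
            b = classify_cells(
                scaled, vhl_bundle["pooled"].cell_ids,
                candidate_ids=vhl_bundle["ne_cells"],
            )
        np.testing.assert_allclose(
            b["cna_signal"].to_numpy(), 2.0 * a["cna_signal"].to_numpy()
        )
        np.testing.assert_allclose(
            b["cna_correlation"].to_numpy(), a["cna_correlation"].to_numpy(),
            atol=1e-12,
        )
        assert (a["malignant"] == b["malignant"]).all()

    def test_metrics_not_labels_decide(self):
        """A reference cell identical to the tumor profile is flagged."""
        tumor_row = np.array([0.8] * 10 + [0.0] * 10)
        quiet = np.zeros(20)
        values = np.vstack([tumor_row] * 10 + [quiet] * 9 + [tumor_row])
        ref_ids = [f"r{i}" for i in range(10)]
        m = cna_from(values, cell_ids=[f"t{i}" for i in range(10)] + ref_ids)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec = classify_cells(m, set(ref_ids)).set_index("cell_id")
        assert rec.at["r9", "malignant"]


class TestClassifyGlial:
    def test_proper_subset_is_pre_neoplastic(self):
        tumor = {"3p": "deletion", "1p": "deletion", "2q": "none"}
        glia = {"a": {"3p": "deletion", "1p": "none", "2q": "none"}}
        status = classify_glial(glia, tumor).set_index("cell_id")
        assert status.at["a", "glial_status"] == "pre_neoplastic"

    def test_no_events_is_non_neoplastic(self):
        tumor = {"3p": "deletion"}
        glia = {"a": {"3p": "none"}}
        status = classify_glial(glia, tumor).set_index("cell_id")
        assert status.at["a", "glial_status"] == "non_neoplastic"

    def test_equal_sets_full_match(self):
        tumor = {"3p": "deletion", "1q": "amplification"}
        glia = {"a": dict(tumor)}
        status = classify_glial(glia, tumor).set_index("cell_id")
        assert status.at["a", "glial_status"] == "full_match"

    def test_direction_must_match(self):
        tumor = {"3p": "deletion"}
        glia = {"a": {"3p": "amplification"}}
        status = classify_glial(glia, tumor).set_index("cell_id")
        assert status.at["a", "glial_status"] == "non_neoplastic"

    def test_empty_tumor_set_warns_all_non_neoplastic(self):
        glia = {"a": {"3p": "deletion"}}
        with pytest.warns(UserWarning, match="empty"):
            status = classify_glial(glia, {"3p": "none"}).set_index("cell_id")
        assert status.at["a", "glial_status"] == "non_neoplastic"

    def test_permutation_invariant_over_cells(self):
        tumor = {"3p": "deletion", "1q": "amplification"}
        glia = {
            "a": {"3p": "deletion"},
            "b": {"1q": "amplification"},
            "c": {},
        }
        fwd = classify_glial(glia, tumor)
        rev = classify_glial(dict(reversed(list(glia.items()))), tumor)
        assert fwd.equals(rev)

    def test_planted_pre_neoplastic_glia_recovered(self, vhl_bundle):
        cm = vhl_bundle["cna"]
        ann = vhl_bundle["annotation"]
        glia = vhl_bundle["glial_cells"]
        carriers = vhl_bundle["carrier_glia"]
        records = vhl_bundle["classification"].set_index("cell_id")
        malignant_ne = [
            c for c in vhl_bundle["ne_cells"] if records.at[c, "malignant"]
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from cnaclone.subclones import call_arm_events

            tumor_events = call_arm_events(cm, malignant_ne, ann)
            profiles = per_cell_arm_profiles(cm, glia, ann)
        status = classify_glial(profiles, tumor_events).set_index("cell_id")
        is_pre = status["glial_status"] == "pre_neoplastic"
        sens = is_pre[sorted(carriers)].mean()
        spec = (~is_pre[[c for c in glia if c not in carriers]]).mean()
        assert sens >= 0.9
        assert spec >= 0.9
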