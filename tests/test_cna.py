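import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnaclone import cna, preprocess, reference, synthetic
from cnaclone.cna import (
    CNAParams,
    apply_noise_floor,
    clip_values,
    infer_cna,
    moving_average,
    order_genes,
    subtract_reference,
)
from cnaclone.matrix import ExpressionMatrix

from conftest import small_matrix


def oracle_moving_average(values, chromosomes, window):
    """Brute-force per-window enumeration, truncated per chromosome."""
    values = np.asarray(values, dtype=float)
    left = (window - 1) // 2
    right = window // 2
    out = np.empty_like(values)
    n = values.shape[1]
    for i in range(n):
        cols = [
            j
            for j in range(max(0, i - left), min(n - 1, i + right) + 1)
            if chromosomes[j] == chromosomes[i]
        ]
        out[:, i] = values[:, cols].mean(axis=1)
    return out


class TestOrderGenes:
    def test_already_ordered_is_identity(self, tiny_annotation):
        m = small_matrix(
            np.arange(20.0).reshape(1, 20), space="centered"
        ).with_values(np.arange(20.0).reshape(1, 20))
        m = ExpressionMatrix(
            m.values, m.cell_ids, tiny_annotation["gene_id"].tolist(), "centered"
        )
        ordered, _ = order_genes(m, tiny_annotation)
        assert list(ordered.gene_ids) == tiny_annotation["gene_id"].tolist()
        np.testing.assert_array_equal(ordered.values, m.values)

    def test_reversed_input_restored(self, tiny_annotation):
        genes = tiny_annotation["gene_id"].tolist()
        m = ExpressionMatrix(
            np.arange(20.0)[::-1].reshape(1, 20), ["c0"], genes[::-1], "centered"
        )
        ordered, _ = order_genes(m, tiny_annotation)
        assert list(ordered.gene_ids) == genes
        np.testing.assert_array_equal(ordered.values.ravel(), np.arange(20.0))

    def test_chromosome_one_before_chromosome_two(self):
        ann = synthetic.build_genome_model(5, [("1p", 2), ("2p", 3)])
        # matrix lists the chr2 genes first
        genes = ann["gene_id"].tolist()
        shuffled = genes[2:] + genes[:2]
        m = ExpressionMatrix(
            np.arange(5.0).reshape(1, 5), ["c0"], shuffled, "centered"
        )
        ordered, kept = order_genes(m, ann)
        assert list(ordered.gene_ids) == genes
        assert list(kept["chromosome"][:2]) == ["1", "1"]

    def test_unannotated_genes_dropped_with_warning(self, tiny_annotation):
        genes = tiny_annotation["gene_id"].tolist() + ["mystery"]
        m = ExpressionMatrix(np.zeros((1, 21)), ["c0"], genes, "centered")
        with pytest.warns(UserWarning, match="unannotated"):
            ordered, _ = order_genes(m, tiny_annotation)
        assert ordered.n_genes == 20

    def test_mostly_unannotated_is_error(self, tiny_annotation):
        genes = ["x1", "x2", "x3", tiny_annotation["gene_id"].iloc[0]]
        m = ExpressionMatrix(np.zeros((1, 4)), ["c0"], genes, "centered")
        with pytest.raises(ValueError, match="annotated"):
            order_genes(m, tiny_annotation)


class TestClip:
    @pytest.mark.parametrize("v,expected", [(3.7, 3.0), (-5.0, -3.0), (2.0, 2.0)])
    def test_bounds(self, v, expected):
        assert clip_values(np.array([[v]]))[0, 0] == expected


class TestMovingAverage:
    def test_constant_row_unchanged(self):
        values = np.full((2, 7), 1.3)
        out = moving_average(values, np.array(["1"] * 7), window=3)
        np.testing.assert_allclose(out, 1.3)

    def test_window_three_hand_example(self):
        values = np.array([[0.0, 3.0, 0.0, 3.0, 0.0]])
        out = moving_average(values, np.array(["1"] * 5), window=3)
        np.testing.assert_allclose(out.ravel(), [1.5, 1.0, 2.0, 1.0, 1.5])

    def test_windows_never_span_chromosomes(self):
        values = np.array([[1.0] * 5 + [9.0] * 5])
        chroms = np.array(["1"] * 5 + ["2"] * 5)
        out = moving_average(values, chroms, window=3)
        np.testing.assert_allclose(out[0, :5], 1.0)
        np.testing.assert_allclose(out[0, 5:], 9.0)

    def test_window_one_is_identity(self, rng):
        values = rng.normal(size=(4, 12))
        chroms = np.array(["1"] * 6 + ["2"] * 6)
        np.testing.assert_array_equal(moving_average(values, chroms, 1), values)

    @settings(max_examples=40, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        window=st.integers(1, 7),
        n_genes=st.integers(2, 60),
        n_cells=st.integers(1, 20),
    )
    def test_matches_bruteforce_oracle(self, seed, window, n_genes, n_cells):
        r = np.random.default_rng(seed)
        values = r.normal(size=(n_cells, n_genes))
        split = r.integers(0, n_genes + 1)
        chroms = np.array(["1"] * split + ["2"] * (n_genes - split))
        expected = oracle_moving_average(values, chroms, window)
        np.testing.assert_allclose(
            moving_average(values, chroms, window), expected, atol=1e-12
        )

    def test_shift_equivariance_within_chromosome(self, rng):
        """Adding c to one cell's chromosome shifts its smoothed values by c."""
        values = rng.normal(size=(3, 10))
        chroms = np.array(["1"] * 4 + ["2"] * 6)
        base = moving_average(values, chroms, window=5)
        shifted = values.copy()
        shifted[1, :4] += 2.5
        out = moving_average(shifted, chroms, window=5)
        np.testing.assert_allclose(out[1, :4], base[1, :4] + 2.5)
        np.testing.assert_allclose(out[1, 4:], base[1, 4:])
        np.testing.assert_allclose(out[[0, 2]], base[[0, 2]])


class TestSubtractReference:
    def test_positive_value_minus_reference_max(self):
        refs = np.array([[0.1], [0.2], [0.3]])
        out = subtract_reference(np.array([[0.5]]), refs)
        assert out[0, 0] == pytest.approx(0.2)

    def test_negative_value_minus_reference_min(self):
        refs = np.array([[-0.2], [0.0], [0.1]])
        out = subtract_reference(np.array([[-0.5]]), refs)
        assert out[0, 0] == pytest.approx(-0.3)

    def test_sign_flip_clamped_to_zero(self):
        refs = np.array([[0.3]])
        out = subtract_reference(np.array([[0.25]]), refs)
        assert out[0, 0] == 0.0

    def test_zero_stays_zero(self):
        refs = np.array([[-0.4], [0.4]])
        assert subtract_reference(np.array([[0.0]]), refs)[0, 0] == 0.0

    def test_mismatched_positions_rejected(self):
        with pytest.raises(ValueError):
            subtract_reference(np.zeros((1, 3)), np.zeros((2, 4)))


class TestNoiseFloor:
    @pytest.mark.parametrize(
        "v,expected",
        [(0.149, 0.0), (-0.151, -0.151), (0.0, 0.0), (0.15, 0.15), (-0.15, -0.15)],
    )
    def test_open_band(self, v, expected):
        assert apply_noise_floor(np.array([[v]]))[0, 0] == expected


class TestInferCNA:
    def build_cohort(self, events, noise_sd=0.0, seed=2):
        spec = synthetic.CohortSpec(
            donors=["D1"],
            cells_per_type_per_donor={
                ("D1", "neuroendocrine"): 40,
                ("D1", "fibroblast"): 16,
                ("D1", "endothelial"): 16,
                ("D1", "adrenocortical"): 16,
            },
            genome=[("1p", 150), ("1q", 150), ("3p", 150), ("3q", 150)],
            events=events,
            noise_sd=noise_sd,
            type_effect_sd=0.0,
            seed=seed,
        )
        expr, meta, truth = synthetic.simulate_expression(spec)
        ann = synthetic.build_genome_model(spec.n_genes, spec.genome)
        pooled = reference.build_pooled_reference(
            meta, reference.ReferencePolicy(seed=seed)
        )
        return expr, meta, truth, ann, pooled

    def test_zero_noise_no_events_gives_all_zero(self):
        expr, meta, truth, ann, pooled = self.build_cohort([])
        result = infer_cna(expr, ann, pooled.type_of())
        assert np.all(result.values == 0)

    def test_planted_deletion_recovered_in_carriers_only(self):
        event = synthetic.PlantedEvent(
            arm="3p", direction="deletion", effect=1.0,
            carriers={"neuroendocrine": 1.0},
        )
        expr, meta, truth, ann, pooled = self.build_cohort([event], noise_sd=0.5)
        result = infer_cna(expr, ann, pooled.type_of())
        arm_of = ann.set_index("gene_id")["arm"]
        p3 = [i for i, g in enumerate(result.gene_ids) if arm_of[g] == "3p"]
        carriers = truth.loc[truth["events"] != "", "cell_id"].tolist()
        others = [
            c for c in truth.loc[truth["events"] == "", "cell_id"] if c in set(result.cell_ids)
        ]
        carrier_mean = result.values[np.ix_(result.cell_index(carriers), p3)].mean()
        other_mean = result.values[np.ix_(result.cell_index(others), p3)].mean()
        assert carrier_mean < -0.15
        assert abs(other_mean) < 0.05

    def test_reference_cells_mostly_exactly_zero(self):
        expr, meta, truth, ann, pooled = self.build_cohort([], noise_sd=0.6)
        result = infer_cna(expr, ann, pooled.type_of())
        ref_idx = result.cell_index(sorted(pooled.cell_ids))
        assert (result.values[ref_idx] == 0).mean() >= 0.95

    def test_provenance_recorded(self):
        expr, meta, truth, ann, pooled = self.build_cohort([])
        params = CNAParams(window=50, noise_floor=0.2)
        result = infer_cna(expr, ann, pooled.type_of(), params)
        assert result.provenance["window"] == 50
        assert result.provenance["noise_floor"] == 0.2
        assert result.provenance["reference"]["types"] == [
            "adrenocortical", "endothelial", "fibroblast",
        ]

    def test_values_respect_floor_invariant(self):
        expr, meta, truth, ann, pooled = self.build_cohort([], noise_sd=1.0)
        result = infer_cna(expr, ann, pooled.type_of())
        nonzero = result.values[result.values != 0]
        assert np.all(np.abs(nonzero) >= 0.15)
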