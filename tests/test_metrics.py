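"""Entropy, diversity/specificity and CV: oracles, extremes, invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossgex import (ExpressionTable, ProbabilityProfile, SelectionSpec,
                      compute_cv, cv_analysis, ds_from_expression,
                      gene_diversity_specificity, median_by_group,
                      shannon_entropy, tissue_diversity_specificity,
                      ds_analysis)
from crossgex.errors import ValidationError


def _profile(weights):
    return ProbabilityProfile.from_values(
        weights, [f"c{i}" for i in range(len(weights))])


def _brute_entropy(p):
    return -sum(pi * np.log2(pi) for pi in p if pi > 0)


class TestEntropy:
    @pytest.mark.parametrize("weights,expected", [
        ([1.0] * 5, np.log2(5)),          # uniform: maximal
        ([1.0, 0.0, 0.0], 0.0),           # one-hot
        ([0.5, 0.5, 0.0, 0.0, 0.0], 1.0),  # two equal atoms
    ])
    def test_known_values(self, weights, expected):
        assert shannon_entropy(_profile(weights)) == pytest.approx(
            expected, abs=1e-12)

    def test_matches_brute_force_on_fuzzed_profiles(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            k = rng.integers(2, 20)
            w = rng.random(k) * (rng.random(k) > 0.2)
            if w.sum() == 0:
                w[0] = 1.0
            prof = _profile(w)
            assert abs(shannon_entropy(prof)
                       - _brute_entropy(prof.p)) < 1e-12

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        w = rng.random(8)
        h1 = shannon_entropy(_profile(w))
        h2 = shannon_entropy(_profile(w[rng.permutation(8)]))
        assert h1 == pytest.approx(h2, abs=1e-12)

    def test_unnormalized_profile_rejected(self):
        prof = ProbabilityProfile(("a", "b"), np.array([0.5, 0.6]))
        with pytest.raises(ValidationError, match="not normalized"):
            shannon_entropy(prof)


class TestGeneDS:
    def test_uniform_is_fully_diverse(self):
        d, s = gene_diversity_specificity(_profile([1.0] * 7))
        assert (d, s) == (pytest.approx(1.0), pytest.approx(0.0))

    def test_one_hot_is_fully_specific(self):
        d, s = gene_diversity_specificity(_profile([0, 0, 1.0, 0]))
        assert (d, s) == (0.0, 1.0)

    def test_two_atom_profile_against_entropy_oracle(self):
        d, s = gene_diversity_specificity(
            _profile([0.5, 0.5, 0.0, 0.0, 0.0]))
        assert d == pytest.approx(1.0 / np.log2(5), abs=1e-12)
        assert s == pytest.approx(1.0 - 1.0 / np.log2(5), abs=1e-12)

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=15))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_range_and_exact_complement(self, weights):
        if sum(weights) == 0:
            weights[0] = 1.0
        d, s = gene_diversity_specificity(_profile(weights))
        assert 0.0 <= d <= 1.0 and 0.0 <= s <= 1.0
        assert d + s == pytest.approx(1.0, abs=1e-12)

    def test_specificity_schur_convex_under_mass_transfer(self):
        """Moving mass from a smaller to a larger atom never decreases
        specificity."""
        rng = np.random.default_rng(9)
        for _ in range(50):
            w = rng.random(6)
            w /= w.sum()
            i, j = np.argsort(w)[[0, -1]]
            eps = w[i] * rng.uniform(0, 1)
            w2 = w.copy()
            w2[i] -= eps
            w2[j] += eps
            _, s1 = gene_diversity_specificity(_profile(w))
            _, s2 = gene_diversity_specificity(_profile(w2))
            assert s2 >= s1 - 1e-12


class TestTissueDS:
    def test_all_one_hot_on_same_tissue_gives_specificity_one(self):
        mat = pd.DataFrame(0.0, index=["g1", "g2", "g3"],
                           columns=["t1", "t2", "t3", "t4"])
        mat["t2"] = 1.0
        d, s = tissue_diversity_specificity(mat, "t2")
        assert s == pytest.approx(1.0, abs=1e-12)
        assert d == pytest.approx(1.0, abs=1e-12)  # genes equally weighted

    def test_uniform_genes_give_zero_specificity(self):
        mat = pd.DataFrame(1.0, index=["g1", "g2"], columns=["t1", "t2", "t3"])
        for t in mat.columns:
            _, s = tissue_diversity_specificity(mat, t)
            assert s == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_matrix_against_brute_force(self):
        """3x3 instance with rotated rows: specificity equal across
        tissues and matching an explicit double loop over the formulas."""
        mat = pd.DataFrame([[8.0, 1.0, 1.0],
                            [1.0, 8.0, 1.0],
                            [1.0, 1.0, 8.0]],
                           index=["g1", "g2", "g3"],
                           columns=["t1", "t2", "t3"])
        arr = mat.to_numpy()
        G, T = arr.shape
        results = {}
        for ti, t in enumerate(mat.columns):
            q = arr[:, ti] / arr[:, ti].sum()
            div = -sum(qi * np.log2(qi) for qi in q if qi > 0) / np.log2(G)
            spec = 0.0
            for gi in range(G):
                p = arr[gi] / arr[gi].sum()
                h = -sum(pi * np.log2(pi) for pi in p if pi > 0)
                spec += q[gi] * (np.log2(T) - h)
            results[t] = (div, spec / np.log2(T))
        specs = []
        for t in mat.columns:
            d, s = tissue_diversity_specificity(mat, t)
            assert d == pytest.approx(results[t][0], abs=1e-12)
            assert s == pytest.approx(results[t][1], abs=1e-12)
            specs.append(s)
        assert max(specs) - min(specs) < 1e-12

    def test_all_zero_column_rejected(self):
        mat = pd.DataFrame([[1.0, 0.0], [2.0, 0.0]],
                           index=["g1", "g2"], columns=["t1", "t2"])
        with pytest.raises(ValidationError, match="all-zero"):
            tissue_diversity_specificity(mat, "t2")


class TestComputeCV:
    def test_constant_vector_is_zero(self):
        cv, reason = compute_cv([4.0, 4.0, 4.0])
        assert cv == 0.0 and reason == "ok"

    def test_hand_calculation_with_n_minus_one_sd(self):
        cv, _ = compute_cv([2.0, 4.0, 6.0])
        assert cv == pytest.approx(0.5, abs=1e-12)

    @given(st.lists(st.floats(0.5, 100.0), min_size=2, max_size=20),
           st.floats(0.01, 100.0))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_positive_scale_invariance(self, xs, c):
        cv1, r1 = compute_cv(np.asarray(xs))
        cv2, r2 = compute_cv(c * np.asarray(xs))
        assert r1 == r2
        if cv1 is not None:
            assert cv2 == pytest.approx(cv1, rel=1e-9)

    def test_zero_iff_constant(self):
        cv, _ = compute_cv([3.0, 3.0, 3.000001])
        assert cv > 0

    def test_missing_reasons(self):
        assert compute_cv([1.0]) == (None, "insufficient_values")
        assert compute_cv([-1.0, 0.0, 1.0]) == (None, "zero_median")


def _vst_table(cells):
    rows = []
    for (gene, sp, tissue), samples in cells.items():
        for i, v in enumerate(samples):
            rows.append((gene, sp, tissue, f"s{i}", v))
    return ExpressionTable(
        pd.DataFrame(rows, columns=["gene_id", "species", "tissue",
                                    "sample_id", "value"]), scale="vst")


class TestCVAnalysis:
    def test_identical_medians_give_zero(self):
        cells = {("g", "human", f"t{i}"): [5.0, 5.0] for i in range(5)}
        res = cv_analysis(_vst_table(cells), SelectionSpec(), "cv_tissue")
        assert res.frame["cv"].tolist() == [0.0]

    def test_cv_species_equal_medians(self):
        cells = {("g", sp, "liver"): [4.0, 6.0] for sp in ("human", "mouse")}
        res = cv_analysis(_vst_table(cells), SelectionSpec(), "cv_species")
        assert res.frame["cv"].tolist() == [0.0]
        assert res.frame["group_label"].tolist() == ["liver"]

    def test_medians_vs_samples_switch(self):
        cells = {("g", "human", "t1"): [1.0, 9.0],
                 ("g", "human", "t2"): [5.0, 5.0]}
        on_medians = cv_analysis(_vst_table(cells), SelectionSpec(),
                                 "cv_tissue", on="medians").frame
        on_samples = cv_analysis(_vst_table(cells), SelectionSpec(),
                                 "cv_tissue", on="samples").frame
        assert on_medians["cv"].iloc[0] == pytest.approx(0.0)
        assert on_samples["cv"].iloc[0] > 0


class TestDSAnalysis:
    def test_flat_gene_is_fully_diverse_with_flag(self):
        cells = {("g1", "human", f"t{i}"): [5.0] for i in range(4)}
        cells.update({("g2", "human", f"t{i}"): [float(i)] for i in range(4)})
        res = ds_from_expression(_vst_table(cells), SelectionSpec(),
                                 "ds_gene").frame
        g1 = res[res.unit_id == "g1"].iloc[0]
        assert g1["diversity"] == pytest.approx(1.0)
        assert "degenerate" in g1["flags"]

    def test_single_tissue_gene_is_fully_specific(self):
        cells = {("g1", "human", f"t{i}"): [10.0 if i == 0 else 0.0]
                 for i in range(4)}
        cells.update({("g2", "human", f"t{i}"): [float(i)] for i in range(4)})
        res = ds_from_expression(_vst_table(cells), SelectionSpec(),
                                 "ds_gene").frame
        g1 = res[res.unit_id == "g1"].iloc[0]
        assert g1["specificity"] == pytest.approx(1.0)

    def test_mode_consistency_full_tissue_set(self):
        rng = np.random.default_rng(17)
        cells = {(f"g{i}", "human", f"t{j}"): [float(rng.uniform(1, 10))]
                 for i in range(4) for j in range(5)}
        table = _vst_table(cells)
        a = ds_from_expression(table, SelectionSpec(), "ds_gene").frame
        b = ds_from_expression(table, SelectionSpec(), "ds_gene_all").frame
        pd.testing.assert_frame_equal(
            a.drop(columns="mode"), b.drop(columns="mode"))

    def test_all_outputs_in_unit_interval_on_fuzzed_matrices(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            g, t = rng.integers(2, 7), rng.integers(2, 7)
            cells = {(f"g{i}", "human", f"t{j}"):
                     [float(rng.uniform(0, 20))]
                     for i in range(g) for j in range(t)}
            table = _vst_table(cells)
            for mode in ("ds_gene", "ds_tissue"):
                res = ds_from_expression(table, SelectionSpec(), mode).frame
                vals = res[["diversity", "specificity"]].dropna().to_numpy()
                assert np.all((vals >= -1e-12) & (vals <= 1 + 1e-12))

    def test_tissue_rows_per_species(self):
        cells = {(f"g{i}", sp, f"t{j}"): [float(i + j + 1)]
                 for i in range(3) for j in range(3)
                 for sp in ("human", "mouse")}
        res = ds_from_expression(_vst_table(cells), SelectionSpec(),
                                 "ds_tissue").frame
        assert len(res) == 6  # 3 tissues x 2 species
        assert set(res["unit"]) == {"tissue"}
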