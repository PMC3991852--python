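"""Per-feature statistics: oracle equivalence, invariances, edge cases."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellscale import (
    FeatureMatrix,
    ValidationError,
    abundance_stratified_summary,
    adjust_pvalues,
    build_correlation_table,
    correlate_features,
    correlation_density,
    generate_design,
    generate_matrix,
    normalize_radius,
    size_fold_change,
)
from cellscale.datatypes import SampleTable

from tests.oracles import bh_adjust_oracle, bh_reject_oracle, pearson_oracle


def _table(radii, genotypes=None, timepoints=None):
    n = len(radii)
    return SampleTable(
        pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "genotype": genotypes
                or ["control"] * (n // 2) + ["knockout"] * (n - n // 2),
                "timepoint": timepoints or (["pre", "post"] * n)[:n],
                "replicate": list(range(1, n + 1)),
                "relative_radius": radii,
            }
        )
    )


def _matrix(values, table, kind="gene"):
    values = np.atleast_2d(np.asarray(values, float))
    return FeatureMatrix(
        [f"f{i}" for i in range(values.shape[0])], table.sample_ids, values, kind
    )


class TestNormalizeRadius:
    def test_reference_mean_becomes_one(self):
        t = _table(
            [2.0, 2.0, 3.0, 5.0],
            genotypes=["control", "control", "knockout", "knockout"],
            timepoints=["pre", "pre", "post", "post"],
        )
        out = normalize_radius(t, reference=("control", "pre"))
        np.testing.assert_allclose(out.radii, [1.0, 1.0, 1.5, 2.5])

    def test_idempotent(self, design_exact):
        once = normalize_radius(design_exact)
        twice = normalize_radius(once)
        np.testing.assert_allclose(once.radii, twice.radii)

    def test_missing_reference_group_errors(self):
        t = _table(
            [1.0, 2.0],
            genotypes=["knockout", "knockout"],
            timepoints=["pre", "post"],
        )
        with pytest.raises(ValidationError, match="reference"):
            normalize_radius(t, reference=("control", "pre"))


class TestCorrelateFeatures:
    def test_matches_direct_formula_oracle_on_random_instances(self):
        """Vectorized r/p/CI equals the scalar direct-formula oracle to
        1e-10 on 100 random small instances."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(4, 15))
            radii = rng.uniform(0.5, 3.0, n)
            t = _table(radii)
            y = rng.uniform(0.1, 50.0, size=(3, n))
            tab = correlate_features(_matrix(y, t), t)
            for i in range(3):
                r, p, lo, hi = pearson_oracle(radii, y[i])
                assert tab["r"].iloc[i] == pytest.approx(r, abs=1e-10)
                assert tab["p"].iloc[i] == pytest.approx(p, rel=1e-9, abs=1e-300)
                assert tab["ci_low"].iloc[i] == pytest.approx(lo, abs=1e-10)
                assert tab["ci_high"].iloc[i] == pytest.approx(hi, abs=1e-10)

    def test_fixed_design_against_oracle(self):
        """Radii from the 2x2 design duplicated over replicates, abundance
        from a fixed printed list: r/p/CI agree with the oracle to 1e-10."""
        radii = [1.00, 1.00, 1.05, 1.05, 1.30, 1.30, 2.50, 2.50]
        y = [12.1, 11.4, 13.0, 12.2, 15.8, 14.9, 25.3, 26.1]
        t = _table(radii)
        tab = correlate_features(_matrix(y, t), t)
        r, p, lo, hi = pearson_oracle(radii, y)
        assert tab["r"].iloc[0] == pytest.approx(r, abs=1e-10)
        assert tab["p"].iloc[0] == pytest.approx(p, rel=1e-10)
        assert (tab["ci_low"].iloc[0], tab["ci_high"].iloc[0]) == pytest.approx(
            (lo, hi), abs=1e-10
        )

    def test_perfect_linearity_gives_r_one_and_tiny_p(self):
        t = _table([1.0, 1.5, 2.0, 2.5])
        tab = correlate_features(_matrix(np.array([2.0, 3.0, 4.0, 5.0]), t), t)
        assert tab["r"].iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert 0 < tab["p"].iloc[0] < 1e-12  # smallest positive float if r hits 1 exactly

    def test_constant_feature_flagged_missing(self):
        t = _table([1.0, 1.5, 2.0, 2.5])
        tab = correlate_features(_matrix([[3.0] * 4, [1, 2, 3, 4]], t), t)
        assert np.isnan(tab["r"].iloc[0]) and np.isnan(tab["p"].iloc[0])
        assert np.isfinite(tab["r"].iloc[1])

    def test_too_few_samples(self):
        t = _table([1.0, 2.0])
        with pytest.raises(ValidationError, match="3 samples"):
            correlate_features(_matrix([[1.0, 2.0]], t), t)

    def test_all_constant_features_error(self):
        t = _table([1.0, 1.5, 2.0, 2.5])
        with pytest.raises(ValidationError, match="zero variance"):
            correlate_features(_matrix([[1.0] * 4], t), t)

    @given(
        scale=st.floats(0.1, 100.0),
        offset=st.floats(0.0, 50.0),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_affine_invariance_and_sign_flip(self, scale, offset, seed):
        """r is invariant under positive affine rescaling of abundance and
        flips sign when the radius gradient is negated."""
        rng = np.random.default_rng(seed)
        radii = rng.uniform(0.5, 3.0, 8)
        y = rng.uniform(1.0, 10.0, size=(1, 8))
        t = _table(radii)
        r0 = correlate_features(_matrix(y, t), t)["r"].iloc[0]
        r1 = correlate_features(_matrix(y * scale + offset, t), t)["r"].iloc[0]
        assert r1 == pytest.approx(r0, abs=1e-9)
        t_neg = t.with_radii(-radii + 5.0)
        r2 = correlate_features(_matrix(y, t), t_neg)["r"].iloc[0]
        assert r2 == pytest.approx(-r0, abs=1e-9)


class TestAdjustPvalues:
    def test_single_p_is_identity(self):
        assert adjust_pvalues([0.03])[0] == pytest.approx(0.03)

    def test_all_equal_stay_equal(self):
        np.testing.assert_allclose(adjust_pvalues([0.2] * 5), [0.2] * 5)

    def test_hand_worked_step_up(self):
        np.testing.assert_allclose(adjust_pvalues([0.01, 0.02, 0.03]), [0.03] * 3)

    def test_matches_brute_force_oracle_on_random_vectors(self):
        """Adjusted values and the rejection set match the step-up oracle on
        100 random p-vectors."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            m = int(rng.integers(1, 40))
            p = rng.uniform(1e-6, 1.0, m)
            adj = adjust_pvalues(p)
            np.testing.assert_allclose(adj, bh_adjust_oracle(list(p)), atol=1e-12)
            alpha = float(rng.uniform(0.01, 0.2))
            np.testing.assert_array_equal(
                adj <= alpha + 1e-12, bh_reject_oracle(list(p), alpha)
            )
            assert np.all(adj >= p - 1e-12)

    def test_rejects_out_of_range(self):
        for bad in ([0.0], [1.2], [-0.1], [float("nan")]):
            with pytest.raises(ValidationError):
                adjust_pvalues(bad)


class TestSizeFoldChange:
    def test_hand_arithmetic(self, design_exact):
        values = np.array([[2.0, 2.0, 3.0, 3.0, 4.0, 4.0, 8.0, 8.0]])
        mat = _matrix(values, design_exact)
        fc = size_fold_change(mat, design_exact, pseudocount=0.0)
        assert fc.iloc[0] == pytest.approx(2.0)

    def test_pseudocount_with_zero_mean(self, design_exact):
        values = np.array([[4.0, 4.0, 1.0, 1.0, 1.0, 1.0, 0.0, 0.0]])
        fc = size_fold_change(_matrix(values, design_exact), design_exact, pseudocount=1.0)
        assert fc.iloc[0] == pytest.approx(math.log2(1.0 / 5.0))

    def test_identical_group_means_give_zero(self, design_exact):
        fc = size_fold_change(_matrix([[5.0] * 8], design_exact), design_exact)
        assert fc.iloc[0] == 0.0

    def test_antisymmetric_under_group_swap(self, design_exact):
        rng = np.random.default_rng(3)
        values = rng.uniform(1, 20, size=(5, 8))
        mat = _matrix(values, design_exact)
        fc = size_fold_change(mat, design_exact, pseudocount=0.5)
        flipped = design_exact.with_radii(1.0 / design_exact.radii)
        fc_flip = size_fold_change(mat, flipped, pseudocount=0.5)
        np.testing.assert_allclose(fc_flip, -fc, atol=1e-12)

    def test_tied_extreme_groups_error(self):
        t = _table(
            [1.0, 1.0, 2.0, 2.0],
            genotypes=["control", "control", "knockout", "knockout"],
            timepoints=["pre", "post", "pre", "post"],
        )
        with pytest.raises(ValidationError, match="tie"):
            size_fold_change(_matrix([[1, 2, 3, 4]], t), t)


class TestCorrelationDensity:
    def test_boundary_convention(self):
        edges, counts, median = correlation_density([-1.0, 0.0, 1.0], bin_width=0.1)
        assert median == 0.0
        assert counts.sum() == 3
        assert counts[0] == 1 and counts[-1] == 1  # -1 in first, +1 in closed last bin
        assert counts[10] == 1  # 0.0 falls in [0.0, 0.1)

    def test_single_value_bin(self):
        _, counts, median = correlation_density([0.5] * 7)
        assert median == 0.5 and counts.max() == 7 and (counts > 0).sum() == 1

    def test_null_simulation_median_near_zero(self):
        """1000 features with no size coupling: median r within Monte-Carlo
        error of 0 (null oracle)."""
        d = generate_design(seed=9)
        mat, _ = generate_matrix(
            d, n_positive=0, n_negative=0, n_null=1000, n_genotype_shifted=0, seed=9
        )
        tab = correlate_features(mat, d)
        _, _, median = correlation_density(tab["r"])
        # se of the median of n=1000 r-values, r sd ~= 1/sqrt(11)
        assert abs(median) < 4 * 1.25 * (1 / math.sqrt(11)) / math.sqrt(1000)

    def test_no_defined_values_error(self):
        with pytest.raises(ValidationError):
            correlation_density([float("nan")])


class TestAbundanceStrata:
    def test_even_split(self):
        t = pd.DataFrame(
            {
                "feature_id": [f"f{i}" for i in range(10)],
                "mean_abundance": np.arange(10, dtype=float),
                "r": np.linspace(-1, 1, 10),
                "log2_fc_size": np.zeros(10),
            }
        )
        out = abundance_stratified_summary(t, n_strata=5)
        assert out["n"].tolist() == [2] * 5

    def test_ties_broken_stably(self):
        t = pd.DataFrame(
            {
                "feature_id": [f"f{i}" for i in range(4)],
                "mean_abundance": [1.0] * 4,
                "r": [0.1, 0.2, 0.3, 0.4],
                "log2_fc_size": [0.0] * 4,
            }
        )
        out = abundance_stratified_summary(t, n_strata=2)
        assert out.loc[0, "mean_r"] == pytest.approx(0.15)
        assert out.loc[1, "mean_r"] == pytest.approx(0.35)

    def test_planted_high_abundance_negative_slope(self):
        """When negative-slope features are planted at high baselines, the
        top abundance stratum has lower mean r than the bottom stratum."""
        d = generate_design(seed=4)
        mat, _ = generate_matrix(
            d,
            n_positive=100,
            n_negative=100,
            n_null=0,
            baseline_log2={"positive": 2.0, "negative": 10.0, "null": 6.0},
            baseline_log2_sd=0.5,
            n_genotype_shifted=0,
            seed=4,
        )
        tab = build_correlation_table(mat, d)
        out = abundance_stratified_summary(tab, n_strata=5)
        assert out.loc[4, "mean_r"] < out.loc[0, "mean_r"]

    def test_too_few_features(self):
        t = pd.DataFrame(
            {
                "feature_id": ["a"],
                "mean_abundance": [1.0],
                "r": [0.5],
                "log2_fc_size": [0.0],
            }
        )
        with pytest.raises(ValidationError):
            abundance_stratified_summary(t, n_strata=2)


class TestBuildCorrelationTable:
    def test_invariants_hold_on_default_run(self, default_bundle):
        from cellscale.datatypes import validate_correlation_table

        tab = validate_correlation_table(default_bundle["gene_table"])
        defined = tab["r"].notna()
        assert (tab.loc[defined, "p_adj"] >= tab.loc[defined, "p"] - 1e-15).all()
        assert tab.loc[defined, "r"].between(-1, 1).all()
        # undefined r iff zero variance: none in the noisy default run
        assert defined.all()
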