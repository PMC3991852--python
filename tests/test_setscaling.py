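"""Gene-set scaling profiles, KS comparison, lipid classes, geometry curve."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellscale import (
    GeneSetCollection,
    ValidationError,
    ks_compare,
    lipid_class_summary,
    set_scaling_profile,
    surface_volume_expectation,
)
from cellscale.setscaling import profiles_long_frame, profiles_summary_frame

from tests.oracles import ks_d_oracle


def _stat_table(r_by_feature, fc=None):
    ids = list(r_by_feature)
    return pd.DataFrame(
        {
            "feature_id": ids,
            "r": [r_by_feature[i] for i in ids],
            "log2_fc_size": [0.0 if fc is None else fc[i] for i in ids],
        }
    )


class TestKsCompare:
    def test_identical_samples(self):
        d, p = ks_compare([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert d == 0.0 and p == 1.0

    def test_fully_separated_samples(self):
        d, _ = ks_compare([0.0, 0.1, 0.2], [0.5, 0.6, 0.7])
        assert d == 1.0

    def test_hand_enumerated_example(self):
        d, _ = ks_compare([0.1, 0.4, 0.6], [0.2, 0.3, 0.9])
        assert d == pytest.approx(1 / 3)

    def test_matches_ecdf_enumeration_oracle(self):
        """D equals the exhaustive ECDF-difference oracle on 100 random
        instances, exactly."""
        rng = np.random.default_rng(13)
        for _ in range(100):
            a = rng.normal(size=int(rng.integers(2, 30)))
            b = rng.normal(size=int(rng.integers(2, 30)))
            d, _ = ks_compare(a, b)
            assert d == pytest.approx(ks_d_oracle(a, b), abs=1e-12)

    @given(
        shift=st.floats(-2.0, 2.0),
        scale=st.floats(0.1, 5.0),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_symmetry_and_monotone_invariance(self, shift, scale, seed):
        """ks(A,B) = ks(B,A); D is invariant under a common increasing
        affine transform of both samples."""
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=10), rng.normal(0.3, 1.0, size=12)
        d_ab, p_ab = ks_compare(a, b)
        d_ba, p_ba = ks_compare(b, a)
        assert d_ab == d_ba and p_ab == p_ba
        d_t, _ = ks_compare(a * scale + shift, b * scale + shift)
        assert d_t == pytest.approx(d_ab, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            ks_compare([], [1.0])


class TestScalingProfile:
    def test_self_comparison_background_equals_set(self):
        """A set identical to the whole background: normalized background
        counts equal the set counts bin for bin."""
        ids = [f"g{i}" for i in range(40)]
        rng = np.random.default_rng(0)
        table = _stat_table(dict(zip(ids, rng.uniform(-1, 1, 40))))
        sets = GeneSetCollection({"everything": frozenset(ids)})
        (profile,) = set_scaling_profile(table, sets)
        np.testing.assert_allclose(
            profile.background_counts_normalized, profile.set_counts
        )
        assert profile.ks_D == 0.0 and profile.ks_p == 1.0

    def test_median_of_two_member_set(self):
        table = _stat_table({"a": -0.9, "b": -0.8, "c": 0.5, "d": 0.6})
        sets = GeneSetCollection(
            {"neg": frozenset({"a", "b"}), "bg": frozenset({"c", "d"})}
        )
        profiles = set_scaling_profile(table, sets)
        by_name = {p.set_name: p for p in profiles}
        assert by_name["neg"].median_stat == pytest.approx(-0.85)

    def test_background_conservation_and_counts(self, default_bundle):
        """Normalized background counts sum to the set's measured size for
        every profile; set counts sum to n_members_measured."""
        profiles = set_scaling_profile(
            default_bundle["gene_table"], default_bundle["gene_sets"]
        )
        assert profiles
        for pr in profiles:
            assert pr.set_counts.sum() == pr.n_members_measured
            assert pr.background_counts_normalized.sum() == pytest.approx(
                pr.n_members_measured
            )

    def test_planted_mito_set_shifts_negative(self, default_bundle):
        profiles = set_scaling_profile(
            default_bundle["gene_table"], default_bundle["gene_sets"]
        )
        by_name = {p.set_name: p for p in profiles}
        mito = by_name["mito_like"]
        cyto = by_name["cytoskeleton_like"]
        bg_median = np.median(
            default_bundle["gene_table"].set_index("feature_id").loc[
                sorted(default_bundle["gene_sets"].all_members()), "r"
            ]
        )
        assert mito.median_stat < bg_median < cyto.median_stat
        assert mito.ks_p < 0.05 and cyto.ks_p < 0.05
        # profile mass shifted into negative bins relative to its background
        neg_bins = mito.bin_edges[:-1] < 0
        assert mito.set_counts[neg_bins].sum() > (
            mito.background_counts_normalized[neg_bins].sum()
        )

    def test_small_sets_skipped(self):
        table = _stat_table({"a": 0.1, "b": 0.2, "c": 0.3})
        sets = GeneSetCollection(
            {"tiny": frozenset({"a"}), "ok": frozenset({"a", "b", "c"})}
        )
        profiles = set_scaling_profile(table, sets)
        assert [p.set_name for p in profiles] == ["ok"]

    def test_log2fc_mode_reproduces_correlation_ranking(self, default_bundle):
        """log2fc-mode profiles rank the planted sets like correlation mode:
        the mito-like set is the most negative, cytoskeleton-like the most
        positive."""
        for mode in ("correlation", "log2fc"):
            profiles = set_scaling_profile(
                default_bundle["gene_table"],
                default_bundle["gene_sets"],
                statistic_mode=mode,
                set_names=["mito_like", "cytoskeleton_like", "decoy_component_1"],
            )
            medians = {p.set_name: p.median_stat for p in profiles}
            assert min(medians, key=medians.get) == "mito_like"
            assert max(medians, key=medians.get) == "cytoskeleton_like"
            for pr in profiles:
                assert pr.set_counts.sum() == pr.n_members_measured

    def test_long_and_summary_frames(self, default_bundle):
        profiles = set_scaling_profile(
            default_bundle["gene_table"], default_bundle["gene_sets"]
        )
        long = profiles_long_frame(profiles)
        assert set(long.columns) == {
            "set", "bin_left", "bin_right", "set_count", "background_normalized"
        }
        summary = profiles_summary_frame(profiles)
        assert len(summary) == len(profiles)
        assert (summary["ks_p_adj"] >= summary["ks_p"] - 1e-15).all()

    def test_empty_background_errors(self):
        table = _stat_table({"a": 0.1, "b": 0.2})
        sets = GeneSetCollection({"missing": frozenset({"x", "y"})})
        with pytest.raises(ValidationError, match="background"):
            set_scaling_profile(table, sets)


class TestLipidClassSummary:
    def test_boundary_more_than_four(self):
        table = _stat_table({f"m{i}": 0.5 for i in range(9)})
        class_map = {f"m{i}": "small" for i in range(4)}
        class_map.update({f"m{i}": "big" for i in range(4, 9)})
        out = lipid_class_summary(table, class_map, min_class_size=5)
        assert out["lipid_class"].tolist() == ["big"]

    def test_median_of_uniform_class(self):
        table = _stat_table({f"m{i}": 0.7 for i in range(6)})
        out = lipid_class_summary(table, {f"m{i}": "c" for i in range(6)})
        assert out.loc[0, "median_r"] == pytest.approx(0.7)

    def test_planted_storage_lipid_class_ranks_first(self, default_bundle):
        out = lipid_class_summary(
            default_bundle["met_table"], default_bundle["lipid_map"]
        )
        assert out.loc[0, "lipid_class"] == "triacylglycerol_like"
        assert out.loc[0, "median_r"] > 0.5
        # the 4-member prenol class is below the "more than four" cutoff
        assert "prenol_like" not in set(out["lipid_class"])

    def test_no_class_passes_filter(self):
        table = _stat_table({"m0": 0.1})
        out = lipid_class_summary(table, {"m0": "c"}, min_class_size=5)
        assert out.empty


class TestSurfaceVolume:
    @pytest.mark.parametrize("radius,expected", [(1.0, 1.0), (2.0, 0.5), (2.5, 0.4)])
    def test_inverse_radius(self, radius, expected):
        assert surface_volume_expectation([radius])[0] == pytest.approx(expected)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValidationError):
            surface_volume_expectation([1.0, 0.0])
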