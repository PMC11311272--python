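"""Shannon index, CLR/PCA ordination and PERMANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gmci.diversity import (
    CLRTransformer,
    aitchison_distance,
    clr_transform,
    compare_alpha,
    compare_alpha_all,
    pca_beta,
    permanova,
    shannon_index,
    shannon_per_sample,
)
from gmci.io import ValidationError

from .conftest import make_count_table, make_metadata


class TestShannon:
    @pytest.mark.parametrize("counts, expected", [
        ([10, 10, 10, 10], np.log(4)),
        ([42, 0, 0], 0.0),
        # -(1/6)ln(1/6) - (1/3)ln(1/3) - (1/2)ln(1/2), worked by hand
        ([1, 2, 3], 1.0114042647073518),
    ])
    def test_closed_forms(self, counts, expected):
        assert shannon_index(counts) == pytest.approx(expected, abs=1e-9)

    def test_all_zero_sample_errors(self):
        with pytest.raises(ValidationError):
            shannon_index([0, 0, 0])

    @given(st.lists(st.integers(1, 1000), min_size=2, max_size=20),
           st.integers(2, 100))
    @settings(max_examples=50, derandomize=True)
    def test_invariant_to_count_rescaling(self, counts, factor):
        scaled = [c * factor for c in counts]
        assert shannon_index(scaled) == pytest.approx(shannon_index(counts), abs=1e-9)


class TestAlphaComparison:
    def _four_sample_cohort(self):
        # evenness strictly increasing from cases to controls
        table = make_count_table([[100, 1], [100, 2], [100, 50], [100, 100]],
                                 sample_ids=["c1", "c2", "h1", "h2"])
        meta = make_metadata([("c1", "CRC", "CRC", "M", 60),
                              ("c2", "CRC", "CRC", "F", 62),
                              ("h1", "HC", "CRC", "M", 61),
                              ("h2", "HC", "CRC", "F", 63)])
        return table, meta

    def test_exact_small_sample_p(self):
        table, meta = self._four_sample_cohort()
        res = compare_alpha(table, meta, "CRC")
        # U=0 among C(4,2)=6 equally likely splits, two-sided
        assert res["p"] == pytest.approx(1 / 3)
        assert res["direction"] == "lower_in_cases"

    def test_identical_groups_give_p_one(self):
        table = make_count_table([[10, 20], [5, 15], [10, 20], [5, 15]],
                                 sample_ids=["c1", "c2", "h1", "h2"])
        meta = make_metadata([("c1", "CRC", "CRC", "M", 60),
                              ("c2", "CRC", "CRC", "F", 62),
                              ("h1", "HC", "CRC", "M", 61),
                              ("h2", "HC", "CRC", "F", 63)])
        res = compare_alpha(table, meta, "CRC")
        assert res["p"] == 1.0

    def test_bh_applied_across_cohorts(self, strong_cohort):
        table, meta, _, _ = strong_cohort
        df = compare_alpha_all(table, meta)
        assert "q" in df.columns and (df["q"] >= df["p"] - 1e-12).all()


class TestCLR:
    def test_equal_counts_row_is_zero(self):
        clr = clr_transform(pd.DataFrame([[7, 7, 7, 7]]), pseudocount=0.5)
        assert np.allclose(clr.to_numpy(), 0.0)

    def test_two_part_composition_closed_form(self):
        # ln(p / sqrt(p1 p2)) in the vanishing-pseudocount limit
        clr = clr_transform(pd.DataFrame([[0.25, 0.75]]), pseudocount=1e-12)
        assert clr.iloc[0, 0] == pytest.approx(-0.5493061443, abs=1e-6)
        assert clr.iloc[0, 1] == pytest.approx(+0.5493061443, abs=1e-6)

    @given(st.lists(st.integers(0, 10_000), min_size=2, max_size=30))
    @settings(max_examples=50, derandomize=True)
    def test_rows_sum_to_zero(self, counts):
        clr = clr_transform(pd.DataFrame([counts]), pseudocount=0.5)
        assert abs(clr.to_numpy().sum()) < 1e-9

    def test_transformer_matches_function(self, strong_cohort):
        table = strong_cohort[0]
        est = CLRTransformer(pseudocount=0.5).fit(table.counts.to_numpy())
        np.testing.assert_allclose(est.transform(table.counts.to_numpy()),
                                   clr_transform(table).to_numpy())

    def test_pseudocount_must_be_positive(self):
        with pytest.raises(ValidationError):
            clr_transform(pd.DataFrame([[1, 2]]), pseudocount=0)


class TestPCA:
    def test_duplicated_samples_get_identical_scores(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 5))
        doubled = np.vstack([X, X])
        scores, _ = pca_beta(doubled - doubled.mean(axis=1, keepdims=True), k=2)
        np.testing.assert_allclose(scores.iloc[:6].to_numpy(),
                                   scores.iloc[6:].to_numpy(), atol=1e-9)

    def test_variance_explained_non_increasing(self, strong_cohort):
        clr = clr_transform(strong_cohort[0])
        _, varexp = pca_beta(clr, k=5)
        assert np.all(np.diff(varexp) <= 1e-12) and varexp.sum() <= 1 + 1e-9

    def test_rank_one_case(self):
        scores, varexp = pca_beta(np.array([[0.0, 1.0], [2.0, 3.0]]), k=1)
        assert varexp[0] == pytest.approx(1.0)

    def test_k_beyond_rank_errors(self):
        with pytest.raises(ValidationError, match="rank"):
            pca_beta(np.array([[0.0, 1.0], [2.0, 3.0]]), k=2)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 4))
        s1, _ = pca_beta(X, k=2)
        s2, _ = pca_beta(X.copy(), k=2)
        pd.testing.assert_frame_equal(s1, s2)


class TestPermanova:
    def test_p_bounded_below(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 3))
        from scipy.spatial.distance import pdist, squareform
        d = squareform(pdist(X))
        res = permanova(d, ["a"] * 6 + ["b"] * 6, n_perm=999, seed=0)
        assert res["p"] >= 1 / 1000

    def test_separated_clouds_hit_floor(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (8, 3)), rng.normal(50, 0.1, (8, 3))])
        from scipy.spatial.distance import pdist, squareform
        d = squareform(pdist(X))
        res = permanova(d, ["a"] * 8 + ["b"] * 8, n_perm=999, seed=1)
        assert res["p"] == pytest.approx(1 / 1000)

    def test_single_group_errors(self):
        d = np.zeros((4, 4))
        with pytest.raises(ValidationError, match="two groups"):
            permanova(d, ["a"] * 4)

    def test_pseudo_f_matches_reference_implementation(self, strong_cohort):
        """Cross-check the pseudo-F statistic against scikit-bio."""
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        table, meta, _, _ = strong_cohort
        d = aitchison_distance(table)
        labels = ["case" if g != "HC" else "hc" for g in meta.table["group"]]
        ours = permanova(d, labels, n_perm=9, seed=0)
        theirs = skbio_stats.permanova(
            skbio_stats.DistanceMatrix(d.to_numpy(), ids=d.index),
            labels, permutations=9)
        assert ours["pseudo_F"] == pytest.approx(theirs["test statistic"], rel=1e-9)


def test_aitchison_depth_invariance_on_proportions():
    """Scaling a sample's counts leaves proportion-based distances unchanged."""
    rng = np.random.default_rng(2)
    counts = rng.integers(1, 1000, size=(5, 8)).astype(float)
    depth_factor = rng.integers(2, 50, size=(5, 1)).astype(float)
    rescaled = counts * depth_factor  # same compositions, different depths
    props1 = counts / counts.sum(axis=1, keepdims=True)
    props2 = rescaled / rescaled.sum(axis=1, keepdims=True)
    d1 = aitchison_distance(pd.DataFrame(props1), pseudocount=1e-9)
    d2 = aitchison_distance(pd.DataFrame(props2), pseudocount=1e-9)
    np.testing.assert_allclose(d1.to_numpy(), d2.to_numpy(), atol=1e-9)
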