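"""Cancer index: closed forms, algebraic invariants, evaluation modes."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold, cross_val_score

from gmci.index import (
    CancerIndexClassifier,
    IndexParams,
    IndexResult,
    auc_rank,
    compute_index,
    evaluate_index,
)
from gmci.io import ValidationError
from gmci.markers import MarkerSets
from gmci.simulate import generate_cohort, scenario_presets


def _markers(h, c):
    return MarkerSets(tuple(h), tuple(c), pd.DataFrame(), alpha=0.05)


class TestComputeIndex:
    def test_all_h_detected_none_c(self):
        markers = _markers(["h1", "h2"], ["c1"])
        abund = {"h1": 0.1, "h2": 0.2, "c1": 0.0}
        expected = np.log2(1.01 / 0.01)  # ~6.658
        assert compute_index(abund, markers) == pytest.approx(expected, abs=1e-9)

    def test_balanced_fractions_give_zero(self):
        markers = _markers(["h1", "h2"], ["c1", "c2"])
        abund = {"h1": 0.1, "h2": 0.0, "c1": 0.1, "c2": 0.0}
        assert compute_index(abund, markers) == pytest.approx(0.0, abs=1e-12)

    def test_hand_worked_ratio(self):
        # f_H = 0.5, f_C = 0.25 -> log2(0.51/0.26)
        markers = _markers(["h1", "h2"], ["c1", "c2", "c3", "c4"])
        abund = {"h1": 0.1, "h2": 0.0, "c1": 0.1, "c2": 0.0, "c3": 0.0, "c4": 0.0}
        assert compute_index(abund, markers) == pytest.approx(
            np.log2(0.51 / 0.26), abs=1e-9)

    def test_both_sets_empty_errors(self):
        with pytest.raises(ValidationError):
            compute_index({"x": 0.1}, _markers([], []))

    def test_antisymmetry_under_swap(self):
        rng = np.random.default_rng(0)
        species = [f"sp{i}" for i in range(20)]
        for _ in range(50):
            abund = dict(zip(species, rng.dirichlet(np.ones(20))))
            h = list(rng.choice(species, 5, replace=False))
            c = [s for s in rng.choice(species, 8, replace=False) if s not in h][:3]
            fwd = compute_index(abund, _markers(h, c))
            rev = compute_index(abund, _markers(c, h))
            assert fwd == pytest.approx(-rev, abs=1e-12)

    def test_monotone_in_marker_detection(self):
        rng = np.random.default_rng(1)
        species = [f"sp{i}" for i in range(30)]
        params = IndexParams()
        for _ in range(200):
            abund = dict(zip(species, rng.dirichlet(np.ones(30))))
            pool = list(rng.permutation(species))
            h, c, extra = pool[:5], pool[5:8], pool[8]
            # make the added marker detected, then adding it to H can only
            # raise the index and adding it to C can only lower it
            abund_extra = dict(abund, **{extra: max(abund[extra], 1e-3)})
            base = compute_index(abund_extra, _markers(h, c), params)
            more_h = compute_index(abund_extra, _markers(h + [extra], c), params)
            more_c = compute_index(abund_extra, _markers(h, c + [extra]), params)
            assert more_h >= base - 1e-12
            assert more_c <= base + 1e-12

    def test_depth_invariance_on_proportions(self):
        markers = _markers(["h1", "h2"], ["c1"])
        abund = {"h1": 0.2, "h2": 1e-6, "c1": 0.05}
        assert compute_index(abund, markers) == compute_index(dict(abund), markers)

    def test_abundance_weighted_variant(self):
        params = IndexParams(weighting="abundance", epsilon=0.01)
        markers = _markers(["h1"], ["c1"])
        abund = {"h1": 0.3, "c1": 0.1}
        expected = np.log2((0.3 + 0.01) / (0.1 + 0.01))
        assert compute_index(abund, markers, params) == pytest.approx(expected)


class TestAucRank:
    def test_perfect_separation(self):
        assert auc_rank([0.9, 0.8], [0.7, 0.1]) == 1.0

    def test_three_of_four_concordant(self):
        assert auc_rank([3, 1], [2, 0]) == pytest.approx(0.75)

    def test_identical_scores_give_half(self):
        assert auc_rank([1, 2, 3], [1, 2, 3]) == pytest.approx(0.5)

    def test_matches_pairwise_concordance_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            pos = rng.normal(size=rng.integers(2, 10))
            neg = rng.normal(size=rng.integers(2, 10))
            brute = np.mean([(p > n) + 0.5 * (p == n)
                             for p in pos for n in neg])
            assert auc_rank(pos, neg) == pytest.approx(brute, abs=1e-12)


class TestEvaluateIndex:
    def test_strong_signal_held_out_separation(self, strong_cohort):
        table, meta, _, _ = strong_cohort
        res = evaluate_index(table, meta, "CRC", seed=1)
        assert res.auc >= 0.9 and res.p < 0.05
        assert res.median_case < res.median_control

    def test_label_inversion_flips_auc(self, strong_cohort):
        """Swapping which group counts as positive mirrors the AUC."""
        table, meta, _, _ = strong_cohort
        res = evaluate_index(table, meta, "CRC", mode="in_sample")
        cases, controls = meta.cohort_samples("CRC")
        idx_case = res.per_sample_index.loc[cases]
        idx_ctrl = res.per_sample_index.loc[controls]
        assert auc_rank(idx_case, idx_ctrl) == pytest.approx(1 - res.auc, abs=1e-12)

    def test_null_cohort_auc_near_half(self, null_cohort):
        table, meta, _, _ = null_cohort
        res = evaluate_index(table, meta, "CRC", seed=0)
        assert abs(res.auc - 0.5) < 0.3  # single cohort; sweep in acceptance

    def test_in_sample_circularity_inflates_auc_under_null(self):
        """With a permissive alpha so markers always exist, markers chosen
        and scored on the same null samples look better than chance, while
        held-out scoring stays honest at 0.5."""
        in_sample, cv = [], []
        for seed in range(25):
            cfg = scenario_presets("null", seed=1000 + seed)
            table, meta, _, _ = generate_cohort(cfg)
            kw = dict(alpha=0.5, seed=seed)
            in_sample.append(evaluate_index(table, meta, cfg.cohort_id,
                                            mode="in_sample", **kw).auc)
            cv.append(evaluate_index(table, meta, cfg.cohort_id,
                                     mode="cv", **kw).auc)
        assert np.mean(in_sample) > np.mean(cv)
        assert np.mean(in_sample) > 0.55
        assert abs(np.mean(cv) - 0.5) < 1.96 * 0.5 / np.sqrt(25)

    def test_too_many_folds_rejected(self, null_cohort):
        table, meta, _, _ = null_cohort
        with pytest.raises(ValidationError, match="folds"):
            evaluate_index(table, meta, "CRC", k_folds=25)

    def test_markers_per_fold_recorded(self, strong_cohort):
        table, meta, _, _ = strong_cohort
        res = evaluate_index(table, meta, "CRC", k_folds=5, seed=0)
        assert len(res.markers_per_fold) == 5


class TestClassifierAPI:
    def test_fits_into_sklearn_model_selection(self, strong_cohort):
        table, meta, _, _ = strong_cohort
        X = table.counts.to_numpy()
        y = (meta.table["group"] != "HC").astype(int).to_numpy()
        clf = clone(CancerIndexClassifier(alpha=0.05))
        cv = StratifiedKFold(n_splits=3, shuffle=True, random_state=0)
        scores = cross_val_score(clf, X, y, cv=cv, scoring="roc_auc")
        assert scores.mean() > 0.9

    def test_predict_thresholds_index_at_zero(self, strong_cohort):
        table, meta, _, _ = strong_cohort
        X = table.counts.to_numpy()
        y = (meta.table["group"] != "HC").astype(int).to_numpy()
        clf = CancerIndexClassifier().fit(X, y)
        index = clf.cancer_index(X)
        np.testing.assert_allclose(clf.decision_function(X), -index)
        np.testing.assert_array_equal(clf.predict(X), (index < 0).astype(int))
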