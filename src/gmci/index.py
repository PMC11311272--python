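"""Per-sample gut microbiome cancer index and its case/control evaluation.

The index belongs to the GMHI family of richness-ratio dysbiosis scores.
Given the two directed marker sets for a cohort — H (control-associated
species, under-represented in cases) and C (case-associated species) — a
sample's index is

    f_H = |{h in H : abundance_h >= theta}| / |H|        (0 if H is empty)
    f_C = |{c in C : abundance_c >= theta}| / |C|        (0 if C is empty)
    index = log2((f_H + eps) / (f_C + eps))

i.e. the epsilon-regularized log-ratio of the detected fraction of
healthy-associated markers to the detected fraction of cancer-associated
markers.  Positive values mean a healthier-looking profile; 0 is balanced.
An abundance-weighted variant (mean relative abundance of detected markers
instead of detected fraction) and a raw (un-logged) ratio are exposed as
options.

Evaluation is cross-validated by default: markers are re-derived on each
training fold and samples are scored only by folds they did not help
select, so the reported separation (Mann–Whitney p, AUC) is free of the
selection circularity that inflates in-sample estimates.  The in-sample
design (markers from all samples, scored on the same samples) is retained
as a labelled mode for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from gmci.io import CountTable, SampleMetadata, ValidationError
from gmci.markers import MarkerSets, MarkerSelector, mann_whitney

__all__ = [
    "IndexParams",
    "compute_index",
    "auc_rank",
    "CancerIndexClassifier",
    "IndexResult",
    "evaluate_index",
]


@dataclass(frozen=True)
class IndexParams:
    """Regularization and variant knobs of the cancer index.

    Attributes
    ----------
    detection_threshold
        Relative abundance above which a marker counts as detected
        (default 1e-5, about one read at a depth of 100 000).
    epsilon
        Pseudo-fraction stabilizing the ratio when a marker set is
        undetected or empty.
    log_base
        Base of the final logarithm (0/None disables the log and returns
        the raw regularized ratio).
    weighting
        ``"richness"`` — detected fraction of each marker set (default);
        ``"abundance"`` — mean relative abundance of detected markers.
    """

    detection_threshold: float = 1e-5
    epsilon: float = 0.01
    log_base: float = 2.0
    weighting: str = "richness"

    def __post_init__(self) -> None:
        if self.detection_threshold < 0:
            raise ValidationError("detection_threshold must be >= 0")
        if self.epsilon <= 0:
            raise ValidationError("epsilon must be > 0")
        if self.weighting not in ("richness", "abundance"):
            raise ValidationError(f"unknown weighting {self.weighting!r}")


def _marker_fraction(abund: pd.Series, members: tuple[str, ...],
                     params: IndexParams) -> float:
    if not members:
        return 0.0
    values = abund.reindex(list(members)).fillna(0.0).to_numpy(dtype=float)
    detected = values >= params.detection_threshold
    if params.weighting == "richness":
        return float(detected.mean())
    return float(np.where(detected, values, 0.0).mean())


def compute_index(sample_abundances, markers: MarkerSets,
                  params: IndexParams = IndexParams()) -> float:
    """Cancer index of one sample from its relative-abundance profile."""
    if not markers.control_associated and not markers.case_associated:
        raise ValidationError("both marker sets are empty; index undefined")
    abund = pd.Series(sample_abundances, dtype=float)
    f_h = _marker_fraction(abund, markers.control_associated, params)
    f_c = _marker_fraction(abund, markers.case_associated, params)
    ratio = (f_h + params.epsilon) / (f_c + params.epsilon)
    if not params.log_base:
        return float(ratio)
    return float(np.log(ratio) / np.log(params.log_base))


def auc_rank(scores_pos, scores_neg) -> float:
    """Rank-based AUC: P(pos > neg) with ties counted 1/2.

    Equals Mann–Whitney U of the positive sample divided by n_pos * n_neg.
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("auc_rank requires non-empty score sets")
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided",
                           method="asymptotic").statistic
    return float(u) / (pos.size * neg.size)


class CancerIndexClassifier(ClassifierMixin, BaseEstimator):
    """Marker-derivation + cancer-index scoring as a sklearn classifier.

    ``fit(X, y)`` derives the directed marker sets from a counts matrix
    (samples x species) and labels (1 = case, 0 = control);
    ``cancer_index`` returns the per-sample index (higher = more
    control-like) while ``decision_function`` follows the sklearn
    convention and scores the positive (case) class with the negated
    index; ``predict`` thresholds the index at 0 (index >= 0 -> control).  This makes the index compatible with sklearn model
    selection, which is how the cross-validated evaluation is run.
    """

    def __init__(self, alpha: float = 0.05, min_mean_reads: float = 50.0,
                 universe_fraction: float = 1e-4,
                 detection_threshold: float = 1e-5, epsilon: float = 0.01,
                 log_base: float = 2.0, weighting: str = "richness"):
        self.alpha = alpha
        self.min_mean_reads = min_mean_reads
        self.universe_fraction = universe_fraction
        self.detection_threshold = detection_threshold
        self.epsilon = epsilon
        self.log_base = log_base
        self.weighting = weighting

    def _params(self) -> IndexParams:
        return IndexParams(self.detection_threshold, self.epsilon,
                           self.log_base, self.weighting)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.array([0, 1])
        self.selector_ = MarkerSelector(
            alpha=self.alpha, min_mean_reads=self.min_mean_reads,
            universe_fraction=self.universe_fraction).fit(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def cancer_index(self, X):
        """Per-sample cancer index (higher = healthier-looking profile).

        A fold whose training data yields no markers scores every sample
        0 (uninformative), keeping downstream rank statistics defined.
        """
        check_is_fitted(self, "selector_")
        X = np.asarray(X, dtype=float)
        params = self._params()
        h = self.selector_.support_h_
        c = self.selector_.support_c_
        n_h, n_c = int(h.sum()), int(c.sum())
        if n_h + n_c == 0:
            return np.zeros(X.shape[0])
        ra = X / X.sum(axis=1, keepdims=True)
        detected = ra >= params.detection_threshold
        if params.weighting == "richness":
            f_h = detected[:, h].mean(axis=1) if n_h else np.zeros(X.shape[0])
            f_c = detected[:, c].mean(axis=1) if n_c else np.zeros(X.shape[0])
        else:
            masked = np.where(detected, ra, 0.0)
            f_h = masked[:, h].mean(axis=1) if n_h else np.zeros(X.shape[0])
            f_c = masked[:, c].mean(axis=1) if n_c else np.zeros(X.shape[0])
        ratio = (f_h + params.epsilon) / (f_c + params.epsilon)
        if not params.log_base:
            return ratio
        return np.log(ratio) / np.log(params.log_base)

    def decision_function(self, X):
        """Case-likeness score (sklearn convention: higher = positive
        class, i.e. case) — the negated cancer index."""
        return -self.cancer_index(X)

    def predict(self, X):
        # index >= 0 looks control-like (class 0); below 0, case-like
        return (self.decision_function(X) > 0).astype(int)


@dataclass
class IndexResult:
    """Per-sample index values and group-separation summary for a cohort."""

    per_sample_index: pd.Series
    median_case: float
    median_control: float
    U: float
    p: float
    auc: float
    cv_scheme: str
    markers_per_fold: list = field(default_factory=list)
    cohort: str | None = None


def evaluate_index(table: CountTable, meta: SampleMetadata, cohort: str,
                   params: IndexParams = IndexParams(), alpha: float = 0.05,
                   min_mean_reads: float = 50.0, universe_fraction: float = 1e-4,
                   k_folds: int = 5, seed: int = 0,
                   mode: str = "cv") -> IndexResult:
    """Evaluate case/control separation of the index for one cohort.

    ``mode="cv"`` (default) derives markers on training folds only and
    scores held-out samples; ``mode="in_sample"`` reproduces the
    markers-from-all-samples design.  AUC ranks controls above cases
    (AUC of the control > case ordering); under no signal it sits at 0.5.
    """
    if mode not in ("cv", "in_sample"):
        raise ValidationError(f"unknown mode {mode!r}")
    cases, controls = meta.cohort_samples(cohort)
    samples = cases + controls
    X = table.counts.loc[samples].to_numpy(dtype=float)
    y = np.array([1] * len(cases) + [0] * len(controls))
    clf = CancerIndexClassifier(
        alpha=alpha, min_mean_reads=min_mean_reads,
        universe_fraction=universe_fraction,
        detection_threshold=params.detection_threshold, epsilon=params.epsilon,
        log_base=params.log_base, weighting=params.weighting)

    index = np.empty(len(samples))
    markers_per_fold: list[int] = []
    if mode == "in_sample":
        clf.fit(X, y)
        index[:] = clf.cancer_index(X)
        markers_per_fold.append(int(clf.selector_._support_union().sum()))
        scheme = "in_sample"
    else:
        if min(np.bincount(y)) < k_folds:
            raise ValidationError(
                f"smallest class has fewer samples than k_folds={k_folds}; "
                "use fewer folds")
        skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
        for train, test in skf.split(X, y):
            if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
                raise ValidationError("fold with an empty class; use fewer folds")
            clf.fit(X[train], y[train])
            index[test] = clf.cancer_index(X[test])
            markers_per_fold.append(int(clf.selector_._support_union().sum()))
        scheme = f"stratified {k_folds}-fold CV, seed={seed}"

    per_sample = pd.Series(index, index=samples, name="cancer_index")
    idx_case = per_sample.loc[cases].to_numpy()
    idx_ctrl = per_sample.loc[controls].to_numpy()
    u, p = mann_whitney(idx_case, idx_ctrl)
    auc = auc_rank(idx_ctrl, idx_case)
    return IndexResult(
        per_sample_index=per_sample,
        median_case=float(np.median(idx_case)),
        median_control=float(np.median(idx_ctrl)),
        U=u, p=p, auc=auc, cv_scheme=scheme,
        markers_per_fold=markers_per_fold, cohort=cohort)
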