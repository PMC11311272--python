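"""Marker-species selection: per-cohort differential abundance testing.

For one case group versus its matched healthy controls:

1. restrict to the detectable species universe (species carrying more than
   a fixed fraction — default 0.01% — of all reads),
2. keep species whose mean read count exceeds 50 in the case group OR in
   the control group (strict inequality),
3. two-sided Mann–Whitney U-test on per-sample relative abundances,
4. Benjamini–Hochberg adjustment across the filtered species,
5. direction by the sign of the difference in group mean relative
   abundance.

Species with adjusted p < alpha split into two directed sets: H
(control-associated, under-represented in cases) and C (case-associated,
over-represented in cases).  These feed the cancer index.

The selection is exposed both as a scikit-learn style estimator
(:class:`MarkerSelector`, operating on an array/labels pair) and as the
metadata-aware function :func:`derive_marker_sets`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from gmci.io import CountTable, SampleMetadata, ValidationError

__all__ = [
    "mann_whitney",
    "bh_adjust",
    "filter_species",
    "MarkerSets",
    "MarkerSelector",
    "derive_marker_sets",
]

logger = logging.getLogger("gmci")

#: Largest combined sample size for which the exact Mann–Whitney null
#: distribution is enumerated (tie-free inputs only).
_EXACT_LIMIT = 12


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann–Whitney U-test.

    Returns ``(U, p)`` where U is the statistic of ``x``.  The exact
    permutation null is used for tie-free inputs with ``len(x)+len(y) <=
    12``; otherwise the normal approximation with midrank tie correction
    and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("mann_whitney requires non-empty samples")
    combined = np.concatenate([x, y])
    tie_free = np.unique(combined).size == combined.size
    method = "exact" if (tie_free and combined.size <= _EXACT_LIMIT) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u, p = float(res.statistic), float(res.pvalue)
    if u == x.size * y.size / 2:
        # perfectly balanced rank sums: no evidence in either direction
        p = 1.0
    return u, min(p, 1.0)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values), input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def universe_species(table: CountTable, min_fraction: float = 1e-4) -> list[str]:
    """Species carrying more than ``min_fraction`` of all reads (strict)."""
    totals = table.counts.sum(axis=0)
    frac = totals / totals.sum()
    return list(frac.index[frac > min_fraction])


def filter_species(table: CountTable, meta: SampleMetadata, cohort: str,
                   min_mean_reads: float = 50.0,
                   universe_fraction: float = 1e-4) -> list[str]:
    """Species eligible for differential testing in one cohort.

    The global detectable-universe filter is applied first; a species is
    then retained iff its mean read count strictly exceeds
    ``min_mean_reads`` in the case group or in the control group.
    """
    cases, controls = meta.cohort_samples(cohort)
    universe = universe_species(table, universe_fraction)
    sub = table.counts[universe]
    mean_case = sub.loc[cases].mean(axis=0)
    mean_ctrl = sub.loc[controls].mean(axis=0)
    keep = (mean_case > min_mean_reads) | (mean_ctrl > min_mean_reads)
    return list(keep.index[keep])


@dataclass
class MarkerSets:
    """Directed marker-species sets for one cohort comparison.

    ``control_associated`` (H) are under-represented in cases;
    ``case_associated`` (C) are over-represented in cases.  ``stats`` holds
    U, p, q, direction and group mean relative abundances for every tested
    species.
    """

    control_associated: tuple[str, ...]
    case_associated: tuple[str, ...]
    stats: pd.DataFrame
    alpha: float
    cohort: str | None = None

    def __post_init__(self) -> None:
        if set(self.control_associated) & set(self.case_associated):
            raise ValidationError("H and C must be disjoint")

    @property
    def n_markers(self) -> int:
        return len(self.control_associated) + len(self.case_associated)


def _marker_stats(case_ra: np.ndarray, ctrl_ra: np.ndarray) -> pd.DataFrame:
    """Vectorized per-species Mann–Whitney + means on relative abundances."""
    n1, n2 = case_ra.shape[0], ctrl_ra.shape[0]
    if n1 + n2 > _EXACT_LIMIT:
        res = stats.mannwhitneyu(case_ra, ctrl_ra, alternative="two-sided",
                                 method="asymptotic", axis=0)
        u = np.asarray(res.statistic, dtype=float)
        p = np.asarray(res.pvalue, dtype=float)
        p[u == n1 * n2 / 2] = 1.0
    else:
        u = np.empty(case_ra.shape[1])
        p = np.empty(case_ra.shape[1])
        for j in range(case_ra.shape[1]):
            u[j], p[j] = mann_whitney(case_ra[:, j], ctrl_ra[:, j])
    return pd.DataFrame({
        "U": u,
        "p": np.minimum(p, 1.0),
        "mean_relabund_case": case_ra.mean(axis=0),
        "mean_relabund_control": ctrl_ra.mean(axis=0),
    })


class MarkerSelector(TransformerMixin, BaseEstimator):
    """Directed differential-abundance feature selector (scikit-learn API).

    Fit on a counts matrix ``X`` (samples x species) and binary labels
    ``y`` (1 = case, 0 = control).  After fitting, ``support_h_`` and
    ``support_c_`` mark the control-associated and case-associated marker
    columns; ``transform`` keeps the union of both marker sets.

    Parameters
    ----------
    alpha : float, default 0.05
        FDR threshold on BH-adjusted p-values.
    min_mean_reads : float, default 50
        Group-mean read-count filter (strict, case OR control group).
    universe_fraction : float, default 1e-4
        Global detectable-universe filter: species must carry more than
        this fraction of all reads.
    """

    def __init__(self, alpha: float = 0.05, min_mean_reads: float = 50.0,
                 universe_fraction: float = 1e-4):
        self.alpha = alpha
        self.min_mean_reads = min_mean_reads
        self.universe_fraction = universe_fraction

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValidationError("X must be 2-dimensional (samples x species)")
        if X.shape[0] != y.shape[0]:
            raise ValidationError("X and y have different numbers of samples")
        case = X[y == 1]
        ctrl = X[y == 0]
        if case.shape[0] == 0 or ctrl.shape[0] == 0:
            raise ValidationError("both classes must be non-empty")
        n_species = X.shape[1]

        totals = X.sum(axis=0)
        universe = totals > self.universe_fraction * totals.sum()
        tested = universe & (
            (case.mean(axis=0) > self.min_mean_reads)
            | (ctrl.mean(axis=0) > self.min_mean_reads)
        )
        self.tested_mask_ = tested

        ra = X / X.sum(axis=1, keepdims=True)
        case_ra, ctrl_ra = ra[y == 1][:, tested], ra[y == 0][:, tested]

        self.pvalues_ = np.full(n_species, np.nan)
        self.qvalues_ = np.full(n_species, np.nan)
        self.statistic_ = np.full(n_species, np.nan)
        self.mean_case_ = np.full(n_species, np.nan)
        self.mean_control_ = np.full(n_species, np.nan)
        self.support_h_ = np.zeros(n_species, dtype=bool)
        self.support_c_ = np.zeros(n_species, dtype=bool)
        if tested.any():
            st = _marker_stats(case_ra, ctrl_ra)
            idx = np.flatnonzero(tested)
            self.statistic_[idx] = st["U"].to_numpy()
            self.pvalues_[idx] = st["p"].to_numpy()
            self.qvalues_[idx] = bh_adjust(st["p"].to_numpy())
            self.mean_case_[idx] = st["mean_relabund_case"].to_numpy()
            self.mean_control_[idx] = st["mean_relabund_control"].to_numpy()
            sig = self.qvalues_ < self.alpha
            delta = self.mean_control_ - self.mean_case_
            undirected = sig & (delta == 0)
            if undirected.any():
                logger.info("dropped %d significant species with exactly equal "
                            "group means (no direction)", int(undirected.sum()))
            self.support_h_ = sig & (delta > 0)
            self.support_c_ = sig & (delta < 0)
        self.n_features_in_ = n_species
        return self

    def _support_union(self) -> np.ndarray:
        check_is_fitted(self, "support_h_")
        return self.support_h_ | self.support_c_

    def transform(self, X):
        X = np.asarray(X)
        return X[:, self._support_union()]

    def get_support(self, indices: bool = False):
        mask = self._support_union()
        return np.flatnonzero(mask) if indices else mask


def derive_marker_sets(table: CountTable, meta: SampleMetadata, cohort: str,
                       alpha: float = 0.05, min_mean_reads: float = 50.0,
                       universe_fraction: float = 1e-4) -> MarkerSets:
    """Derive the directed marker sets H and C for one cohort.

    Mann–Whitney is run on relative abundances of the filtered species;
    BH adjustment is applied within this cohort's filtered family only.
    """
    cases, controls = meta.cohort_samples(cohort)
    samples = cases + controls
    # detectable-universe filter over ALL samples, then per-cohort testing
    universe = universe_species(table, universe_fraction)
    sub = table.counts.loc[samples, universe]
    y = np.array([1] * len(cases) + [0] * len(controls))
    sel = MarkerSelector(alpha=alpha, min_mean_reads=min_mean_reads,
                         universe_fraction=0.0).fit(sub.to_numpy(), y)
    species = np.array(universe)
    tested = sel.tested_mask_
    directions = np.where(sel.support_h_, "control_associated",
                          np.where(sel.support_c_, "case_associated", "none"))
    stats_df = pd.DataFrame({
        "U": sel.statistic_[tested],
        "p": sel.pvalues_[tested],
        "q": sel.qvalues_[tested],
        "direction": directions[tested],
        "mean_relabund_case": sel.mean_case_[tested],
        "mean_relabund_control": sel.mean_control_[tested],
    }, index=pd.Index(species[tested], name="species"))
    return MarkerSets(
        control_associated=tuple(species[sel.support_h_]),
        case_associated=tuple(species[sel.support_c_]),
        stats=stats_df,
        alpha=alpha,
        cohort=cohort,
    )
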