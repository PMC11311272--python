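"""Alpha- and beta-diversity of species-level count tables.

Alpha diversity is the Shannon index (natural log) on per-sample relative
abundances, compared between cases and matched controls with a two-sided
Mann–Whitney test (BH-adjusted across cohorts when all comparisons are run
together).

Beta diversity works in Aitchison geometry: counts are shifted by a
pseudocount, centered-log-ratio (CLR) transformed, and ordinated with
plain PCA; group separation is tested with a seeded two-group PERMANOVA on
Euclidean distances between CLR rows (= Aitchison distances).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from gmci.io import CountTable, SampleMetadata, ValidationError
from gmci.markers import bh_adjust, mann_whitney

__all__ = [
    "shannon_index",
    "shannon_per_sample",
    "compare_alpha",
    "compare_alpha_all",
    "clr_transform",
    "CLRTransformer",
    "pca_beta",
    "aitchison_distance",
    "permanova",
    "DiversityResult",
    "analyze_cohort",
]


def shannon_index(counts) -> float:
    """Shannon diversity H = -sum p_i ln p_i (nats) for one sample.

    Zero-count species contribute nothing; an all-zero sample is an error.
    """
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValidationError("negative counts")
    total = c.sum()
    if total == 0:
        raise ValidationError("all-zero sample has undefined diversity")
    # scipy normalizes and uses natural log; zero entries are skipped
    return float(stats.entropy(c[c > 0]))


def shannon_per_sample(table: CountTable) -> pd.Series:
    values = [shannon_index(row) for row in table.counts.to_numpy()]
    return pd.Series(values, index=table.sample_ids, name="shannon")


def compare_alpha(table: CountTable, meta: SampleMetadata, cohort: str) -> dict:
    """Two-sided Mann–Whitney on per-sample Shannon values, case vs control."""
    cases, controls = meta.cohort_samples(cohort)
    if len(cases) < 2 or len(controls) < 2:
        raise ValidationError("need >= 2 samples per group for the alpha test")
    shannon = shannon_per_sample(table)
    x, y = shannon.loc[cases], shannon.loc[controls]
    u, p = mann_whitney(x, y)
    med_case, med_ctrl = float(x.median()), float(y.median())
    if med_case < med_ctrl:
        direction = "lower_in_cases"
    elif med_case > med_ctrl:
        direction = "higher_in_cases"
    else:
        direction = "none"
    return {"cohort": cohort, "U": u, "p": p,
            "median_case": med_case, "median_control": med_ctrl,
            "direction": direction,
            "n_case": len(cases), "n_control": len(controls)}


def compare_alpha_all(table: CountTable, meta: SampleMetadata,
                      cohorts: list[str] | None = None) -> pd.DataFrame:
    """Alpha comparison for every cohort, BH-adjusted across cohorts."""
    cohorts = cohorts or meta.cohorts
    rows = [compare_alpha(table, meta, c) for c in cohorts]
    df = pd.DataFrame(rows).set_index("cohort")
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df


def clr_transform(table, pseudocount: float = 0.5) -> pd.DataFrame:
    """Centered log-ratio transform of counts (rows sum to zero).

    ``x_ij = ln((c_ij + pseudocount) / g_i)`` with ``g_i`` the geometric
    mean of the shifted row.  Accepts a CountTable or a samples x species
    DataFrame/array of counts or proportions.
    """
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    if isinstance(table, CountTable):
        df = table.counts.astype(float)
    else:
        df = pd.DataFrame(table).astype(float)
    shifted = np.log(df.to_numpy() + pseudocount)
    clr = shifted - shifted.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=df.index, columns=df.columns)


class CLRTransformer(TransformerMixin, BaseEstimator):
    """Centered log-ratio transform as a scikit-learn transformer.

    Stateless (fit learns nothing); exists so compositional embedding can
    sit inside sklearn pipelines.
    """

    def __init__(self, pseudocount: float = 0.5):
        self.pseudocount = pseudocount

    def fit(self, X, y=None):
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be > 0")
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        shifted = np.log(X + self.pseudocount)
        return shifted - shifted.mean(axis=1, keepdims=True)


def pca_beta(matrix, k: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered PCA of a CLR matrix, deterministic up to fixed sign.

    Each component's sign is fixed by making its largest-magnitude loading
    positive.  Raises if ``k`` exceeds the matrix rank.
    """
    df = pd.DataFrame(matrix)
    X = df.to_numpy(dtype=float)
    centered = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(centered)
    if k > rank:
        raise ValidationError(f"k={k} exceeds matrix rank {rank}")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    for j in range(k):
        i = int(np.argmax(np.abs(pca.components_[j])))
        if pca.components_[j, i] < 0:
            pca.components_[j] *= -1
            scores[:, j] *= -1
    cols = [f"PC{j + 1}" for j in range(k)]
    return pd.DataFrame(scores, index=df.index, columns=cols), pca.explained_variance_ratio_


def aitchison_distance(table, pseudocount: float = 0.5) -> pd.DataFrame:
    """Pairwise Euclidean distance between CLR-transformed samples."""
    clr = clr_transform(table, pseudocount)
    d = squareform(pdist(clr.to_numpy(), metric="euclidean"))
    return pd.DataFrame(d, index=clr.index, columns=clr.index)


def _permanova_f(d2: np.ndarray, mask1: np.ndarray) -> float:
    """Two-group PERMANOVA pseudo-F from a squared distance matrix."""
    mask1 = np.asarray(mask1, dtype=float)
    n = d2.shape[0]
    n1 = int(mask1.sum())
    n2 = n - n1
    ss_total = d2.sum() / (2 * n)
    w1 = float(mask1 @ d2 @ mask1) / 2
    mask2 = 1.0 - mask1
    w2 = float(mask2 @ d2 @ mask2) / 2
    ss_within = w1 / n1 + w2 / n2
    ss_between = ss_total - ss_within
    return (ss_between / 1.0) / (ss_within / (n - 2))


def permanova(distance, labels, n_perm: int = 999, seed: int = 0) -> dict:
    """Seeded two-group PERMANOVA on a distance matrix.

    ``p = (1 + #{permuted F >= observed F}) / (1 + n_perm)``.
    """
    d = pd.DataFrame(distance).to_numpy(dtype=float)
    if d.shape[0] != d.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValidationError("distance matrix must be symmetric with zero diagonal")
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValidationError(f"permanova needs exactly two groups, got {uniq.size}")
    mask1 = labels == uniq[0]
    if mask1.sum() < 2 or (~mask1).sum() < 2:
        raise ValidationError("each group needs >= 2 samples")
    d2 = d ** 2
    observed = _permanova_f(d2, mask1)
    rng = np.random.default_rng(seed)
    n = d.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _permanova_f(d2, mask1[perm]) >= observed:
            count += 1
    return {"pseudo_F": float(observed), "p": (1 + count) / (1 + n_perm),
            "n_permutations": n_perm, "seed": seed}


@dataclass
class DiversityResult:
    """Bundle of alpha/beta diversity outputs for one cohort."""

    per_sample_shannon: pd.Series
    group_test: dict
    pca_scores: pd.DataFrame
    variance_explained: np.ndarray
    permanova: dict


def analyze_cohort(table: CountTable, meta: SampleMetadata, cohort: str,
                   k: int = 2, pseudocount: float = 0.5,
                   n_perm: int = 999, seed: int = 0) -> DiversityResult:
    """Full diversity analysis of one case/control cohort."""
    cases, controls = meta.cohort_samples(cohort)
    sub = table.subset(cases + controls)
    shannon = shannon_per_sample(sub)
    group_test = compare_alpha(table, meta, cohort)
    clr = clr_transform(sub, pseudocount)
    scores, varexp = pca_beta(clr, k)
    dist = squareform(pdist(clr.to_numpy(), metric="euclidean"))
    labels = np.array(["case"] * len(cases) + ["control"] * len(controls))
    perm = permanova(dist, labels, n_perm=n_perm, seed=seed)
    return DiversityResult(shannon, group_test, scores, varexp, perm)
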