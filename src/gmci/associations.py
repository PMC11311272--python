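"""Taxa-metabolite Spearman correlations and correlation-pattern modules.

Over the pooled case + healthy-control samples, every pairwise Spearman
correlation between the relative abundance of a (sufficiently abundant and
prevalent) species and each metabolite concentration is computed.  Taxa
are then grouped into correlation modules by Ward agglomeration on the
correlation distance (1 - Pearson r) between their correlation-profile
rows; metabolites are clustered the same way on the columns.  The default
cuts are five taxa modules and two metabolite clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from gmci.io import CountTable, MetaboliteTable, ValidationError

__all__ = [
    "filter_taxa_for_association",
    "spearman_rho",
    "correlation_matrix",
    "cluster_correlations",
    "AssociationResult",
    "associate",
]

logger = logging.getLogger("gmci")


def filter_taxa_for_association(table: CountTable,
                                min_mean_reads: float = 1000.0,
                                min_prevalence: float = 0.10) -> list[str]:
    """Taxa with mean reads > min_mean_reads (strict) and prevalence >= 10%."""
    counts = table.counts
    mean_reads = counts.mean(axis=0)
    prevalence = (counts > 0).mean(axis=0)
    keep = (mean_reads > min_mean_reads) & (prevalence >= min_prevalence)
    return list(keep.index[keep])


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (midranks for ties); errors on constants."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("spearman_rho needs two equal-length vectors, n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValidationError("zero-variance input; correlation undefined")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def correlation_matrix(table: CountTable, metabolites: MetaboliteTable,
                       taxa: list[str] | None = None) -> pd.DataFrame:
    """Taxa x metabolites Spearman matrix over the shared samples.

    Taxa or metabolites that are constant across the shared samples are
    excluded with a log message (their correlation is undefined).
    """
    shared = [s for s in table.sample_ids if s in set(metabolites.sample_ids)]
    if len(shared) < 3:
        raise ValidationError("need >= 3 shared samples for correlations")
    taxa = taxa if taxa is not None else filter_taxa_for_association(table)
    if not taxa:
        raise ValidationError("no taxa pass the association filters")
    conc = metabolites.concentrations.loc[shared]
    incomplete = conc.isna().any(axis=1)
    if incomplete.any():
        logger.warning("excluded %d samples with missing metabolite values "
                       "from correlations", int(incomplete.sum()))
        shared = list(conc.index[~incomplete])
        if len(shared) < 3:
            raise ValidationError("need >= 3 complete shared samples")
        conc = conc.loc[shared]
    ra = table.relative_abundance().loc[shared, taxa]

    const_taxa = [t for t in ra.columns if ra[t].nunique() == 1]
    if const_taxa:
        logger.warning("excluded %d constant taxa from correlations", len(const_taxa))
        ra = ra.drop(columns=const_taxa)
    const_met = [m for m in conc.columns if conc[m].nunique() == 1]
    if const_met:
        logger.warning("excluded %d constant metabolites from correlations", len(const_met))
        conc = conc.drop(columns=const_met)
    if ra.shape[1] == 0:
        raise ValidationError("no non-constant taxa left")

    # Spearman = Pearson on midranks; one pass over the rank matrices
    rank_taxa = ra.rank().to_numpy()
    rank_met = conc.rank().to_numpy()
    rt = (rank_taxa - rank_taxa.mean(axis=0)) / rank_taxa.std(axis=0)
    rm = (rank_met - rank_met.mean(axis=0)) / rank_met.std(axis=0)
    corr = rt.T @ rm / rank_taxa.shape[0]
    return pd.DataFrame(np.clip(corr, -1.0, 1.0), index=ra.columns, columns=conc.columns)


def _ward_cut(profiles: np.ndarray, labels, k: int) -> dict:
    if k > profiles.shape[0]:
        raise ValidationError(f"k={k} exceeds number of leaves {profiles.shape[0]}")
    if profiles.shape[0] == 1:
        return {labels[0]: 1}
    d = pdist(profiles, metric="correlation")
    d = np.clip(d, 0.0, None)  # guard tiny negative rounding
    assignments = fcluster(linkage(d, method="ward"), t=k, criterion="maxclust")
    return dict(zip(labels, (int(a) for a in assignments)))


def cluster_correlations(corr: pd.DataFrame, k_taxa: int = 5,
                         k_metab: int = 2) -> tuple[dict, dict]:
    """Ward modules of taxa (rows) and metabolites (columns).

    Distance between two taxa is 1 - Pearson r of their correlation-profile
    rows; metabolites likewise on columns.  Deterministic given the input.
    """
    values = corr.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValidationError("correlation matrix contains non-finite values")
    taxa_modules = _ward_cut(values, list(corr.index), k_taxa)
    metabolite_clusters = _ward_cut(values.T, list(corr.columns), k_metab)
    return taxa_modules, metabolite_clusters


@dataclass
class AssociationResult:
    """Correlation matrix plus module assignments."""

    taxa_kept: list[str]
    corr: pd.DataFrame
    taxa_modules: dict
    metabolite_clusters: dict


def associate(table: CountTable, metabolites: MetaboliteTable,
              min_mean_reads: float = 1000.0, min_prevalence: float = 0.10,
              k_taxa: int = 5, k_metab: int = 2) -> AssociationResult:
    """Full association analysis over the pooled samples."""
    taxa = filter_taxa_for_association(table, min_mean_reads, min_prevalence)
    corr = correlation_matrix(table, metabolites, taxa)
    taxa_modules, metab_clusters = cluster_correlations(corr, k_taxa, k_metab)
    return AssociationResult(taxa_kept=list(corr.index), corr=corr,
                             taxa_modules=taxa_modules,
                             metabolite_clusters=metab_clusters)
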