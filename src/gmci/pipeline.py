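"""End-to-end orchestration: simulate or load, then run every stage.

One :class:`PipelineConfig` drives the whole analysis; every output file
carries the package version, the seed and a hash of the configuration, so
a bundle can be reproduced bit-exactly from its own headers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from gmci import __version__
from gmci.associations import associate
from gmci.diversity import analyze_cohort, compare_alpha_all
from gmci.index import IndexParams, evaluate_index
from gmci.io import (
    CASE_GROUPS,
    CountTable,
    MetaboliteTable,
    SampleMetadata,
    ValidationError,
    read_count_matrix,
    read_metabolites,
    read_metadata,
    reconcile_samples,
    write_count_matrix,
    write_metabolites,
    write_metadata,
)
from gmci.markers import derive_marker_sets
from gmci.metabolomics import compare_metabolites
from gmci.simulate import GROUP_DEMOGRAPHICS, generate_cohort, scenario_presets

__all__ = ["PipelineConfig", "config_hash", "simulate_study", "run_all"]

logger = logging.getLogger("gmci")


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of a full pipeline run.

    Either ``preset`` (synthetic study) or the three input paths must be
    set.  Thresholds default to the pipeline's canonical values: 0.01%
    detectable-universe fraction, 50-read marker filter, 1000-read / 10%
    prevalence association filter, FDR alpha 0.05.
    """

    preset: str | None = "paper_like"
    counts_path: str | None = None
    metadata_path: str | None = None
    metabolites_path: str | None = None
    cohorts: tuple[str, ...] = CASE_GROUPS
    alpha: float = 0.05
    universe_fraction: float = 1e-4
    marker_min_mean_reads: float = 50.0
    assoc_min_mean_reads: float = 1000.0
    assoc_min_prevalence: float = 0.10
    detection_threshold: float = 1e-5
    epsilon: float = 0.01
    k_folds: int = 5
    n_permutations: int = 999
    pseudocount: float = 0.5
    seed: int = 0
    out_dir: str = "gmci_out"

    def __post_init__(self) -> None:
        if not self.cohorts:
            raise ValidationError("config must name at least one cohort")
        for name, value in (("alpha", self.alpha),
                            ("universe_fraction", self.universe_fraction),
                            ("marker_min_mean_reads", self.marker_min_mean_reads),
                            ("assoc_min_mean_reads", self.assoc_min_mean_reads),
                            ("pseudocount", self.pseudocount)):
            if value <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.preset is None and not (
                self.counts_path and self.metadata_path):
            raise ValidationError("either a preset or input paths are required")


def config_hash(config: PipelineConfig) -> str:
    """Short stable hash of the analysis configuration.

    ``out_dir`` is excluded: where a bundle is written does not change its
    contents, so bundles from identical analyses hash identically.
    """
    payload = dataclasses.asdict(config)
    payload.pop("out_dir")
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _concat_counts(tables: list[CountTable]) -> CountTable:
    merged = pd.concat([t.counts for t in tables], axis=0).fillna(0)
    return CountTable(merged)


def simulate_study(config: PipelineConfig,
                   ) -> tuple[CountTable, SampleMetadata, MetaboliteTable, dict]:
    """Generate one synthetic cohort per configured case group.

    Each cohort gets an independent child seed derived from the master
    seed, so the whole study is reproducible from one integer.
    """
    children = np.random.SeedSequence(config.seed).spawn(len(config.cohorts))
    tables, metas, metabs, truths = [], [], [], {}
    for group, child in zip(config.cohorts, children):
        n = GROUP_DEMOGRAPHICS[group]["n_cases"]
        cohort_cfg = scenario_presets(
            config.preset, group=group, n_cases=n, n_controls=n,
            seed=int(child.generate_state(1)[0] % (2 ** 31)))
        table, meta, metab, truth = generate_cohort(cohort_cfg)
        tables.append(table)
        metas.append(meta.table)
        metabs.append(metab.concentrations)
        truths[group] = truth
    counts = _concat_counts(tables)
    meta = SampleMetadata(pd.concat(metas))
    metab = MetaboliteTable(pd.concat(metabs))
    return counts, meta, metab, truths


def _load_study(config: PipelineConfig,
                ) -> tuple[CountTable, SampleMetadata, MetaboliteTable | None]:
    counts = read_count_matrix(config.counts_path)
    meta = read_metadata(config.metadata_path)
    reconcile_samples(counts, meta)
    metab = read_metabolites(config.metabolites_path) if config.metabolites_path else None
    return counts, meta, metab


def _write_tsv(df: pd.DataFrame, path: Path, header: dict) -> None:
    with open(path, "w") as fh:
        fh.write(f"# gmci={__version__}\n")
        for k, v in header.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t")


def run_all(config: PipelineConfig) -> dict:
    """Run every stage for every cohort; write the bundle; return summary.

    The bundle contains per-cohort diversity, marker, index and metabolite
    tables, a pooled association analysis, and ``summary.json``.  Identical
    config + seed reproduce the bundle bit-identically.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    header = {"seed": config.seed, "config_hash": chash}
    params = IndexParams(detection_threshold=config.detection_threshold,
                         epsilon=config.epsilon)

    if config.preset is not None:
        counts, meta, metab, _ = simulate_study(config)
        write_count_matrix(counts, out / "counts.tsv", header)
        write_metadata(meta, out / "metadata.tsv", header)
        write_metabolites(metab, out / "metabolites.tsv", header)
    else:
        counts, meta, metab = _load_study(config)

    summary: dict = {"gmci": __version__, "seed": config.seed,
                     "config_hash": chash, "cohorts": {}}
    seed_rng = np.random.SeedSequence(config.seed).spawn(len(config.cohorts) + 1)

    alpha_table = compare_alpha_all(counts, meta, list(config.cohorts))
    _write_tsv(alpha_table, out / "alpha_diversity_tests.tsv", header)

    for i, cohort in enumerate(config.cohorts):
        logger.info("cohort %s: diversity", cohort)
        stage_seed = int(seed_rng[i].generate_state(1)[0] % (2 ** 31))
        div = analyze_cohort(counts, meta, cohort,
                             pseudocount=config.pseudocount,
                             n_perm=config.n_permutations, seed=stage_seed)
        _write_tsv(div.per_sample_shannon.to_frame(), out / f"{cohort}_shannon.tsv", header)
        _write_tsv(div.pca_scores, out / f"{cohort}_pca_scores.tsv", header)

        logger.info("cohort %s: markers", cohort)
        markers = derive_marker_sets(
            counts, meta, cohort, alpha=config.alpha,
            min_mean_reads=config.marker_min_mean_reads,
            universe_fraction=config.universe_fraction)
        _write_tsv(markers.stats, out / f"{cohort}_markers.tsv", header)
        logger.info("cohort %s: %d tested, |H|=%d |C|=%d", cohort,
                    len(markers.stats), len(markers.control_associated),
                    len(markers.case_associated))

        logger.info("cohort %s: cancer index", cohort)
        idx = evaluate_index(counts, meta, cohort, params=params,
                             alpha=config.alpha,
                             min_mean_reads=config.marker_min_mean_reads,
                             universe_fraction=config.universe_fraction,
                             k_folds=config.k_folds, seed=stage_seed)
        _write_tsv(idx.per_sample_index.to_frame(), out / f"{cohort}_index.tsv", header)

        cohort_summary = {
            "n_case": div.group_test["n_case"],
            "n_control": div.group_test["n_control"],
            "shannon_p": alpha_table.loc[cohort, "p"],
            "shannon_q": alpha_table.loc[cohort, "q"],
            "shannon_direction": alpha_table.loc[cohort, "direction"],
            "permanova_F": div.permanova["pseudo_F"],
            "permanova_p": div.permanova["p"],
            "n_control_associated": len(markers.control_associated),
            "n_case_associated": len(markers.case_associated),
            "index_median_case": idx.median_case,
            "index_median_control": idx.median_control,
            "index_p": idx.p,
            "index_auc": idx.auc,
            "index_cv_scheme": idx.cv_scheme,
        }

        if metab is not None:
            rows = []
            for mode in ("concentration", "proportion"):
                cmp_res = compare_metabolites(metab, meta, cohort, mode=mode)
                tab = cmp_res.per_metabolite.reset_index()
                tab.insert(0, "mode", mode)
                tab.insert(0, "cohort", cohort)
                rows.append(tab)
            long = pd.concat(rows, ignore_index=True)
            _write_tsv(long.set_index("cohort"), out / f"{cohort}_metabolites.tsv", header)
            formic = long[(long["mode"] == "concentration")
                          & (long["metabolite"] == "formic")].iloc[0]
            cohort_summary["formic_code"] = int(formic["code"])
            cohort_summary["formic_direction"] = formic["direction"]
        summary["cohorts"][cohort] = cohort_summary

    if metab is not None:
        logger.info("pooled associations")
        assoc = associate(counts, metab,
                          min_mean_reads=config.assoc_min_mean_reads,
                          min_prevalence=config.assoc_min_prevalence)
        _write_tsv(assoc.corr, out / "associations_corr.tsv", header)
        modules = pd.DataFrame({
            "label": list(assoc.taxa_modules) + list(assoc.metabolite_clusters),
            "kind": ["taxon"] * len(assoc.taxa_modules)
                    + ["metabolite"] * len(assoc.metabolite_clusters),
            "module": list(assoc.taxa_modules.values())
                      + list(assoc.metabolite_clusters.values()),
        }).set_index("label")
        _write_tsv(modules, out / "associations_modules.tsv", header)
        summary["associations"] = {
            "n_taxa": len(assoc.taxa_kept),
            "n_taxa_modules": len(set(assoc.taxa_modules.values())),
            "n_metabolite_clusters": len(set(assoc.metabolite_clusters.values())),
        }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    return summary
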