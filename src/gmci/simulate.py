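"""Seeded synthetic case/control cohorts with planted effect structure.

The generator emulates the statistical skeleton of a seven-malignancy gut
metagenome + fecal metabolome study:

* a species universe of ~260 detectable species whose baseline profile is
  heavy-tailed (a handful of species carry roughly half the reads);
* per-sample compositions drawn from a Dirichlet around the group profile
  (a Dirichlet-multinomial count model, so the compositional sum constraint
  is respected: depleting many species implicitly enriches the rest);
* case groups with a planted, strongly asymmetric marker structure — many
  control-associated (depleted-in-cases) species and few case-associated
  (enriched-in-cases) species;
* sex- and age-matched metadata following the enrolment table of each
  malignancy group;
* log-normal fecal metabolite panels with an optional planted case-side
  shift of formic acid (the one metabolite elevated across all case groups
  in the study design this emulates).

Everything is driven by a single integer seed: identical configuration and
seed give bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from gmci.io import (
    AMINO_ACIDS,
    CASE_GROUPS,
    METABOLITES,
    SCFAS,
    CountTable,
    MetaboliteTable,
    SampleMetadata,
    ValidationError,
)

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "GROUP_DEMOGRAPHICS",
    "generate_cohort",
    "scenario_presets",
    "PRESETS",
]


#: Enrolment-table demographics per malignancy group: number of cases,
#: number of women among them, and the case age range (years).
GROUP_DEMOGRAPHICS: dict[str, dict] = {
    "CRC": {"n_cases": 40, "n_women": 20, "age_range": (35, 82)},
    "stomach": {"n_cases": 45, "n_women": 15, "age_range": (37, 87)},
    "breast": {"n_cases": 71, "n_women": 71, "age_range": (30, 79)},
    "lung": {"n_cases": 34, "n_women": 17, "age_range": (35, 85)},
    "melanoma": {"n_cases": 50, "n_women": 23, "age_range": (34, 88)},
    "lymphoid": {"n_cases": 60, "n_women": 35, "age_range": (22, 78)},
    "AML": {"n_cases": 40, "n_women": 26, "age_range": (20, 74)},
}

#: Baseline median concentrations (µg per g stool, arbitrary but plausible
#: scale) for the 16-metabolite panel.
METABOLITE_BASELINES: dict[str, float] = {
    "acetic": 3500.0, "propanoic": 1300.0, "butanoic": 1200.0, "formic": 60.0,
    "hexanoic": 100.0, "isobutyric": 180.0, "pentanoic": 250.0,
    "Ala": 120.0, "Gly": 110.0, "Glu": 250.0, "Ile": 60.0, "Leu": 90.0,
    "Met": 25.0, "Phe": 60.0, "Pro": 90.0, "Val": 80.0,
}

#: Reference universe size against which planted marker counts are scaled
#: (the 179:24 depleted:enriched asymmetry is preserved at any n_species).
_MARKER_SCALE_UNIVERSE = 1030
_N_DEPLETED_REF = 179
_N_ENRICHED_REF = 24


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of one synthetic case/control cohort.

    Attributes
    ----------
    group
        Malignancy group label; fixes the sex ratio and age range used for
        matching.
    n_cases, n_controls
        Group sizes.  ``None`` means "use the enrolment table for group"
        (controls matched 1:1).
    n_species
        Size of the detectable species universe.
    depth_mean
        Mean sequencing depth (reads/sample); depths are Poisson around it.
        Default 100 000 — a desk-scale stand-in for production depths.
    n_depleted, n_enriched
        Numbers of planted control-associated / case-associated species.
    effect_fold
        Multiplicative shift applied to planted species in the case profile
        (> 1): depleted species are divided by it, enriched multiplied.
    base_concentration
        Dirichlet concentration: larger = less sample-to-sample
        overdispersion around the group profile.
    profile_sigma
        Log-normal sigma of the baseline species profile; 2.0 concentrates
        roughly half the reads in the top ten species of a 260-species
        universe.
    formic_shift
        Multiplicative case-side shift of formic acid concentration.
    metabolite_sigma
        Log-scale standard deviation of metabolite concentrations
        (~50% coefficient of variation at the default 0.5).
    marker_min_proportion, marker_max_proportion
        Planted markers are drawn only from species whose baseline
        proportion lies in this band: abundant enough to be detectable at
        the configured depth, but not among the dominant community
        backbone (a several-fold shift on a dominant species would rescale
        the whole composition and scramble every other species'
        direction, which is not the marker structure being emulated).
    seed
        RNG seed; same config + seed reproduces every table bit-exactly.
    """

    group: str = "CRC"
    cohort: str | None = None
    n_cases: int = 20
    n_controls: int = 20
    n_species: int = 260
    depth_mean: float = 100_000.0
    n_depleted: int = 0
    n_enriched: int = 0
    effect_fold: float = 2.0
    base_concentration: float = 500.0
    profile_sigma: float = 2.0
    formic_shift: float = 1.0
    metabolite_sigma: float = 0.5
    marker_min_proportion: float = 1e-3
    marker_max_proportion: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group not in GROUP_DEMOGRAPHICS:
            raise ValidationError(f"unknown group {self.group!r}")
        if self.n_depleted + self.n_enriched > self.n_species:
            raise ValidationError("n_depleted + n_enriched exceeds n_species")
        if self.effect_fold <= 1:
            raise ValidationError("effect_fold must be > 1")
        if self.depth_mean <= 0:
            raise ValidationError("depth_mean must be positive")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValidationError("n_cases and n_controls must be >= 1")
        if self.base_concentration <= 0 or self.formic_shift <= 0:
            raise ValidationError("concentration parameters must be positive")

    @property
    def cohort_id(self) -> str:
        return self.cohort or self.group


@dataclass(frozen=True)
class GroundTruth:
    """Ledger of planted effects, for recovery tests."""

    depleted_species: frozenset[str]
    enriched_species: frozenset[str]
    metabolite_shifts: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.depleted_species & self.enriched_species:
            raise ValidationError("planted species sets must be disjoint")


def _species_names(n: int) -> list[str]:
    return [f"Species{i:04d}" for i in range(n)]


def _assign_demographics(rng: np.random.Generator, cfg: CohortConfig, n: int,
                         prefix: str) -> pd.DataFrame:
    demo = GROUP_DEMOGRAPHICS[cfg.group]
    frac_women = demo["n_women"] / demo["n_cases"]
    n_women = int(round(n * frac_women))
    sexes = np.array(["F"] * n_women + ["M"] * (n - n_women))
    rng.shuffle(sexes)
    lo, hi = demo["age_range"]
    ages = rng.integers(lo, hi + 1, size=n)
    ids = [f"{cfg.cohort_id}_{prefix}{i:03d}" for i in range(n)]
    return pd.DataFrame({"sex": sexes, "age": ages}, index=ids)


def generate_cohort(config: CohortConfig,
                    ) -> tuple[CountTable, SampleMetadata, MetaboliteTable, GroundTruth]:
    """Generate one matched case/control cohort.

    Returns the count table, metadata, metabolite panel and the ground-truth
    ledger of planted species and metabolite shifts.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    species = _species_names(cfg.n_species)

    # heavy-tailed baseline profile, drawn once per cohort
    log_abund = rng.normal(0.0, cfg.profile_sigma, size=cfg.n_species)
    baseline = np.exp(log_abund)
    baseline /= baseline.sum()

    # plant directed effects on detectable, non-dominant species
    eligible = np.flatnonzero((baseline >= cfg.marker_min_proportion)
                              & (baseline <= cfg.marker_max_proportion))
    n_plant = cfg.n_depleted + cfg.n_enriched
    if n_plant > len(eligible):
        # widen to the next most abundant non-dominant species if needed
        below_cap = np.flatnonzero(baseline <= cfg.marker_max_proportion)
        eligible = below_cap[np.argsort(baseline[below_cap])[::-1][:n_plant]]
    if n_plant > len(eligible):
        raise ValidationError("species universe too small for the requested "
                              "number of planted markers")
    planted = rng.choice(eligible, size=n_plant, replace=False) if n_plant else np.array([], int)
    depleted_idx = planted[: cfg.n_depleted]
    enriched_idx = planted[cfg.n_depleted:]

    case_profile = baseline.copy()
    case_profile[depleted_idx] /= cfg.effect_fold
    case_profile[enriched_idx] *= cfg.effect_fold
    case_profile /= case_profile.sum()

    # metadata: cases then matched controls, same sex ratio and age range
    meta_case = _assign_demographics(rng, cfg, cfg.n_cases, "case")
    meta_case["group"] = cfg.group
    meta_ctrl = _assign_demographics(rng, cfg, cfg.n_controls, "hc")
    meta_ctrl["group"] = "HC"
    meta = pd.concat([meta_case, meta_ctrl])
    meta["cohort"] = cfg.cohort_id
    meta["timepoint"] = "pre"
    metadata = SampleMetadata(meta[["group", "cohort", "sex", "age", "timepoint"]])

    # Dirichlet-multinomial counts
    n_total = cfg.n_cases + cfg.n_controls
    profiles = np.vstack([case_profile] * cfg.n_cases + [baseline] * cfg.n_controls)
    counts = np.empty((n_total, cfg.n_species), dtype=np.int64)
    for i in range(n_total):
        composition = rng.dirichlet(cfg.base_concentration * profiles[i])
        depth = max(int(rng.poisson(cfg.depth_mean)), 1)
        counts[i] = rng.multinomial(depth, composition)
    # guarantee the CountTable invariant total_reads > 0 even at tiny depths
    empty = counts.sum(axis=1) == 0
    if empty.any():
        counts[empty, 0] = 1
    table = CountTable(pd.DataFrame(counts, index=metadata.sample_ids, columns=species))

    # log-normal metabolite panel with planted case-side shifts
    shifts = {"formic": cfg.formic_shift} if cfg.formic_shift != 1.0 else {}
    base = np.array([METABOLITE_BASELINES[m] for m in METABOLITES])
    noise = rng.normal(0.0, cfg.metabolite_sigma, size=(n_total, len(METABOLITES)))
    conc = base * np.exp(noise)
    shift_vec = np.array([shifts.get(m, 1.0) for m in METABOLITES])
    conc[: cfg.n_cases] *= shift_vec
    metabolites = MetaboliteTable(
        pd.DataFrame(conc, index=metadata.sample_ids, columns=list(METABOLITES))
    )

    truth = GroundTruth(
        depleted_species=frozenset(species[i] for i in depleted_idx),
        enriched_species=frozenset(species[i] for i in enriched_idx),
        metabolite_shifts=shifts,
    )
    return table, metadata, metabolites, truth


def _paper_like_marker_counts(n_species: int) -> tuple[int, int]:
    """Scale the 179:24 depleted:enriched asymmetry to a species universe."""
    scale = n_species / _MARKER_SCALE_UNIVERSE
    return int(round(_N_DEPLETED_REF * scale)), int(round(_N_ENRICHED_REF * scale))


def scenario_presets(name: str, **overrides) -> CohortConfig:
    """Named study scenarios.

    ``null``
        No planted effects anywhere: groups are exchangeable.  Used for
        false-discovery-rate and type-I-error calibration.
    ``paper_like``
        The study-like regime: many depleted and few enriched species
        (179:24 scaled to the species universe — 45:6 at 260 species),
        a modest 2x effect, and a 2x case-side formic acid shift.
    ``strong_dysbiosis``
        Large (4x) effects on a compact marker set, for signal-recovery and
        AUC-ceiling tests.
    """
    if name == "null":
        cfg = CohortConfig(n_cases=20, n_controls=20,
                           n_depleted=0, n_enriched=0,
                           effect_fold=1.5, formic_shift=1.0)
    elif name == "paper_like":
        n_species = int(overrides.get("n_species", 260))
        n_dep, n_enr = _paper_like_marker_counts(n_species)
        cfg = CohortConfig(n_cases=40, n_controls=40,
                           n_depleted=n_dep, n_enriched=n_enr,
                           effect_fold=2.0, formic_shift=2.0)
    elif name == "strong_dysbiosis":
        cfg = CohortConfig(n_cases=40, n_controls=40,
                           n_depleted=20, n_enriched=5,
                           effect_fold=4.0, formic_shift=2.0)
    else:
        raise ValueError(f"unknown preset {name!r}")
    return replace(cfg, **overrides) if overrides else cfg


PRESETS = ("null", "paper_like", "strong_dysbiosis")
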