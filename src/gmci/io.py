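"""Typed tables and readers/writers for the pipeline's external formats.

Three in-memory containers back every stage:

* :class:`CountTable` — samples x species integer read counts (the output of
  a k-mer classifier plus species-level re-estimation, e.g. a merged set of
  Bracken reports).
* :class:`SampleMetadata` — per-sample group / matched-control cohort / sex /
  age / timepoint.
* :class:`MetaboliteTable` — samples x 16 fecal metabolites (7 short-chain
  fatty acids + 9 amino acids), concentration per gram of stool.

All on-disk formats are plain TSV.  Written tables carry ``#``-prefixed
header comment lines recording the package version and, where relevant, the
seed and configuration hash, so that any result file can be traced back to
the exact run that produced it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "CASE_GROUPS",
    "SEXES",
    "TIMEPOINTS",
    "SCFAS",
    "AMINO_ACIDS",
    "METABOLITES",
    "FormatError",
    "ValidationError",
    "ReconciliationError",
    "CountTable",
    "SampleMetadata",
    "MetaboliteTable",
    "read_bracken_reports",
    "read_count_matrix",
    "write_count_matrix",
    "read_metadata",
    "write_metadata",
    "read_metabolites",
    "write_metabolites",
    "reconcile_samples",
]

logger = logging.getLogger("gmci")

#: Study groups: seven malignancies plus healthy controls.
GROUPS = ("CRC", "stomach", "breast", "lung", "melanoma", "lymphoid", "AML", "HC")
CASE_GROUPS = tuple(g for g in GROUPS if g != "HC")
SEXES = ("F", "M")
TIMEPOINTS = ("pre", "post")

#: Seven short-chain fatty acids assayed per gram of stool.
SCFAS = ("acetic", "butanoic", "formic", "hexanoic", "isobutyric", "pentanoic", "propanoic")
#: Nine amino acids assayed per gram of stool.
AMINO_ACIDS = ("Ala", "Gly", "Glu", "Ile", "Leu", "Met", "Phe", "Pro", "Val")
#: The fixed 16-metabolite panel.
METABOLITES = SCFAS + AMINO_ACIDS

#: Required header of a Bracken species report.
BRACKEN_COLUMNS = (
    "name",
    "taxonomy_id",
    "taxonomy_lvl",
    "kraken_assigned_reads",
    "added_reads",
    "new_est_reads",
    "fraction_total_reads",
)


class FormatError(ValueError):
    """A file does not conform to its declared external format."""


class ValidationError(ValueError):
    """A table violates a domain invariant."""


class ReconciliationError(ValidationError):
    """Samples present in one table are missing from another."""


def _check_unique(labels: Iterable, what: str) -> None:
    labels = list(labels)
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if list(labels).count(x) > 1})
        raise ValidationError(f"duplicate {what}: {dupes[:10]}")


@dataclass
class CountTable:
    """Samples x species matrix of non-negative integer read counts.

    Parameters
    ----------
    counts
        DataFrame indexed by sample id with species names as columns.
        Values must be non-negative and integer-valued; every sample must
        have at least one read.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        _check_unique(df.index, "sample ids")
        _check_unique(df.columns, "species names")
        values = df.to_numpy()
        if values.size == 0:
            raise ValidationError("empty count table")
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("non-numeric counts")
        if np.isnan(values.astype(float)).any():
            raise ValidationError("missing values in counts")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at sample {df.index[i]!r}, species {df.columns[j]!r}"
            )
        if not np.allclose(values, np.round(values)):
            raise ValidationError("counts must be integer-valued")
        self.counts = df.astype(np.int64)
        self.counts.index.name = None
        self.counts.columns.name = None
        zero = self.counts.sum(axis=1) == 0
        if zero.any():
            raise ValidationError(
                f"samples with zero total reads: {list(self.counts.index[zero])[:10]}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def species_names(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_species(self) -> int:
        return self.counts.shape[1]

    @property
    def total_reads(self) -> pd.Series:
        """Per-sample sequencing depth (row sums)."""
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        """Counts divided by per-sample total reads; rows sum to 1."""
        return self.counts.div(self.total_reads, axis=0)

    def subset(self, sample_ids: Sequence[str]) -> "CountTable":
        missing = [s for s in sample_ids if s not in self.counts.index]
        if missing:
            raise ReconciliationError(f"unknown sample ids: {missing[:10]}")
        return CountTable(self.counts.loc[list(sample_ids)].copy())


@dataclass
class SampleMetadata:
    """Per-sample group / cohort / sex / age / timepoint records.

    ``cohort`` links each case group to its matched healthy-control subset:
    case samples and their matched HC samples share a cohort identifier.
    """

    table: pd.DataFrame

    REQUIRED = ("group", "cohort", "sex", "age", "timepoint")

    def __post_init__(self) -> None:
        df = self.table
        _check_unique(df.index, "sample ids")
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        bad_group = sorted(set(df["group"]) - set(GROUPS))
        if bad_group:
            raise ValidationError(f"unknown group values: {bad_group}")
        bad_sex = sorted(set(df["sex"]) - set(SEXES))
        if bad_sex:
            raise ValidationError(f"unknown sex values: {bad_sex}")
        bad_tp = sorted(set(df["timepoint"]) - set(TIMEPOINTS))
        if bad_tp:
            raise ValidationError(f"unknown timepoint values: {bad_tp}")
        if (pd.to_numeric(df["age"], errors="coerce") <= 0).any() or df["age"].isna().any():
            raise ValidationError("ages must be positive numbers")
        # every case cohort must have at least one matched HC sample
        case_cohorts = set(df.loc[df["group"] != "HC", "cohort"])
        hc_cohorts = set(df.loc[df["group"] == "HC", "cohort"])
        orphan = sorted(case_cohorts - hc_cohorts)
        if orphan:
            raise ValidationError(f"case cohorts with no matched HC samples: {orphan}")
        self.table = df.copy()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def cohorts(self) -> list[str]:
        """Cohort identifiers that contain at least one case sample."""
        return sorted(set(self.table.loc[self.table["group"] != "HC", "cohort"]))

    def cohort_samples(self, cohort: str) -> tuple[list[str], list[str]]:
        """Case and matched-HC sample ids for one cohort (pre-treatment)."""
        df = self.table[(self.table["cohort"] == cohort) & (self.table["timepoint"] == "pre")]
        cases = list(df.index[df["group"] != "HC"])
        controls = list(df.index[df["group"] == "HC"])
        if not cases:
            raise ValidationError(f"cohort {cohort!r} has no case samples")
        if not controls:
            raise ValidationError(f"cohort {cohort!r} has no control samples")
        return cases, controls

    def hc_samples(self) -> list[str]:
        """All healthy-control sample ids (pre-treatment), across cohorts."""
        df = self.table[(self.table["group"] == "HC") & (self.table["timepoint"] == "pre")]
        return list(df.index)


@dataclass
class MetaboliteTable:
    """Samples x 16 metabolite concentrations (µg per g stool).

    The metabolite panel is fixed (7 SCFAs + 9 amino acids).  Missing
    measurements are carried as NaN — never silently as zero — and each
    downstream mode decides how to handle them.
    """

    concentrations: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.concentrations
        _check_unique(df.index, "sample ids")
        missing = [m for m in METABOLITES if m not in df.columns]
        if missing:
            raise ValidationError(f"missing metabolite columns: {missing}")
        extra = [c for c in df.columns if c not in METABOLITES]
        if extra:
            raise ValidationError(f"unknown metabolite columns: {extra}")
        df = df[list(METABOLITES)].astype(float)
        if (df.to_numpy() < 0).any():
            raise ValidationError("negative metabolite concentrations")
        n_missing = int(df.isna().to_numpy().sum())
        if n_missing:
            logger.warning("metabolite table has %d missing values (kept as NaN)", n_missing)
        self.concentrations = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.concentrations.index)

    def subset(self, sample_ids: Sequence[str]) -> "MetaboliteTable":
        missing = [s for s in sample_ids if s not in self.concentrations.index]
        if missing:
            raise ReconciliationError(f"unknown sample ids: {missing[:10]}")
        return MetaboliteTable(self.concentrations.loc[list(sample_ids)].copy())


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_bracken_reports(paths: Sequence[str | Path], sample_ids: Sequence[str]) -> CountTable:
    """Merge per-sample Bracken species reports into one CountTable.

    Counts are taken from ``new_est_reads`` (Bracken's re-estimated
    species-level counts).  The species set is the union across files;
    species absent from a file get a count of zero.  Rows whose
    ``taxonomy_lvl`` is not ``'S'`` are skipped with a warning.
    """
    if len(paths) != len(sample_ids):
        raise ValueError("paths and sample_ids must have equal length")
    per_sample: list[pd.Series] = []
    for path, sid in zip(paths, sample_ids):
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in BRACKEN_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing Bracken column(s) {missing}")
        non_species = df["taxonomy_lvl"] != "S"
        if non_species.any():
            logger.warning(
                "%s: skipped %d non-species rows (taxonomy_lvl != 'S')",
                path, int(non_species.sum()),
            )
            df = df[~non_species]
        if df["name"].duplicated().any():
            raise FormatError(f"{path}: duplicate species names")
        counts = pd.Series(
            df["new_est_reads"].to_numpy(), index=df["name"].astype(str), name=sid
        )
        per_sample.append(counts)
    merged = pd.concat(per_sample, axis=1).T.fillna(0)
    merged.index = list(sample_ids)
    return CountTable(merged)


def read_count_matrix(path: str | Path, orientation: str = "samples_in_rows") -> CountTable:
    """Read a plain TSV count matrix, normalized to samples x species."""
    if orientation not in ("samples_in_rows", "species_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if orientation == "species_in_rows":
        df = df.T
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"{path}: non-numeric cell at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    neg = numeric.to_numpy() < 0
    if neg.any():
        i, j = np.argwhere(neg)[0]
        raise ValidationError(
            f"{path}: negative count at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    return CountTable(numeric)


def _header_lines(extra: dict | None) -> str:
    from gmci import __version__

    fields = {"gmci": __version__, **(extra or {})}
    return "".join(f"# {k}={v}\n" for k, v in fields.items())


def write_count_matrix(table: CountTable, path: str | Path, extra_header: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(extra_header))
        table.counts.rename_axis("sample_id").to_csv(fh, sep="\t")


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing sample_id column")
    df = df.set_index("sample_id")
    if "timepoint" not in df.columns:
        df["timepoint"] = "pre"
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str | Path, extra_header: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(extra_header))
        meta.table.rename_axis("sample_id").to_csv(fh, sep="\t")


def read_metabolites(path: str | Path) -> MetaboliteTable:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing sample_id column")
    return MetaboliteTable(df.set_index("sample_id"))


def write_metabolites(tbl: MetaboliteTable, path: str | Path, extra_header: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(extra_header))
        tbl.concentrations.rename_axis("sample_id").to_csv(fh, sep="\t")


def reconcile_samples(table: CountTable, meta: SampleMetadata) -> None:
    """Raise if any count-table sample lacks a metadata record."""
    missing = [s for s in table.sample_ids if s not in set(meta.sample_ids)]
    if missing:
        raise ReconciliationError(
            f"samples in counts absent from metadata: {missing[:20]}"
        )
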