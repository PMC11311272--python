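"""Fecal SCFA / amino-acid profile comparisons between cases and controls.

Two modes, computed independently and never coerced to agree:

* ``concentration`` — per-metabolite concentrations (µg per g stool),
* ``proportion`` — each metabolite as a percentage of the sample's total
  SCFA + amino-acid concentration (rows sum to 100 before testing).

Each metabolite gets a two-sided Mann–Whitney test (case group versus the
whole healthy-control pool), BH adjustment across the 16-metabolite panel
within one cohort x mode, a direction from the median difference, and a
significance code: 1 (q < 0.05), 2 (q < 0.01), 3 (q < 0.001),
4 (q < 0.0001), 0 otherwise.

Samples with a missing value are excluded per-metabolite in concentration
mode, and entirely in proportion mode (the denominator is undefined).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from gmci.io import METABOLITES, MetaboliteTable, SampleMetadata, ValidationError
from gmci.markers import bh_adjust, mann_whitney

__all__ = [
    "to_proportions",
    "significance_code",
    "MetaboliteComparison",
    "compare_metabolites",
]

logger = logging.getLogger("gmci")

MODES = ("concentration", "proportion")


def to_proportions(row) -> np.ndarray:
    """One sample's concentrations as percentages of its panel total.

    Output sums to 100.  All-zero rows and rows with missing values are
    errors (proportions are undefined for them).
    """
    x = np.asarray(row, dtype=float)
    if np.isnan(x).any():
        raise ValidationError("missing value; proportions undefined")
    if (x < 0).any():
        raise ValidationError("negative concentration")
    total = x.sum()
    if total == 0:
        raise ValidationError("all-zero metabolite row")
    return x * 100.0 / total


def significance_code(q: float) -> int:
    """Map an adjusted p-value to the 0-4 significance code."""
    if not 0 <= q <= 1:
        raise ValidationError(f"adjusted p-value out of range: {q}")
    for code, cut in ((4, 1e-4), (3, 1e-3), (2, 1e-2), (1, 0.05)):
        if q < cut:
            return code
    return 0


@dataclass
class MetaboliteComparison:
    """Per-metabolite case/control comparison for one cohort and mode."""

    mode: str
    cohort: str
    per_metabolite: pd.DataFrame  # index metabolite: medians, direction, p, q, code

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValidationError(f"unknown mode {self.mode!r}")


def _group_values(tbl: MetaboliteTable, meta: SampleMetadata, cohort: str,
                  mode: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    cases, _ = meta.cohort_samples(cohort)
    # whole-HC pool as the reference group for every cohort
    controls = meta.hc_samples()
    have = set(tbl.sample_ids)
    cases = [s for s in cases if s in have]
    controls = [s for s in controls if s in have]
    if not cases or not controls:
        raise ValidationError(f"cohort {cohort!r}: empty case or control group "
                              "in the metabolite table")
    case_df = tbl.concentrations.loc[cases]
    ctrl_df = tbl.concentrations.loc[controls]
    if mode == "proportion":
        for name, df in (("case", case_df), ("control", ctrl_df)):
            incomplete = df.isna().any(axis=1)
            if incomplete.any():
                logger.warning("proportion mode: excluded %d %s samples with "
                               "missing values", int(incomplete.sum()), name)
        case_df = case_df.dropna()
        ctrl_df = ctrl_df.dropna()
        if case_df.empty or ctrl_df.empty:
            raise ValidationError("proportion mode: no complete samples left")
        case_df = pd.DataFrame(np.vstack([to_proportions(r) for r in case_df.to_numpy()]),
                               index=case_df.index, columns=case_df.columns)
        ctrl_df = pd.DataFrame(np.vstack([to_proportions(r) for r in ctrl_df.to_numpy()]),
                               index=ctrl_df.index, columns=ctrl_df.columns)
    return case_df, ctrl_df


def compare_metabolites(tbl: MetaboliteTable, meta: SampleMetadata, cohort: str,
                        mode: str = "concentration") -> MetaboliteComparison:
    """Compare all 16 metabolites between one case group and the HC pool."""
    if mode not in MODES:
        raise ValidationError(f"unknown mode {mode!r}")
    case_df, ctrl_df = _group_values(tbl, meta, cohort, mode)
    rows = []
    for m in METABOLITES:
        x = case_df[m].dropna().to_numpy()
        y = ctrl_df[m].dropna().to_numpy()
        if x.size == 0 or y.size == 0:
            raise ValidationError(f"metabolite {m}: empty group after "
                                  "missing-value removal")
        u, p = mann_whitney(x, y)
        med_case, med_ctrl = float(np.median(x)), float(np.median(y))
        if med_case > med_ctrl:
            direction = "higher_in_cases"
        elif med_case < med_ctrl:
            direction = "higher_in_controls"
        else:
            direction = "none"
        rows.append({"metabolite": m, "median_case": med_case,
                     "median_control": med_ctrl, "direction": direction,
                     "U": u, "p": p, "n_case": x.size, "n_control": y.size})
    df = pd.DataFrame(rows).set_index("metabolite")
    df["q"] = bh_adjust(df["p"].to_numpy())
    df["code"] = [significance_code(q) for q in df["q"]]
    return MetaboliteComparison(mode=mode, cohort=cohort, per_metabolite=df)
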