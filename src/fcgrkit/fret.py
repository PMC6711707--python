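"""De-quenching (acceptor-photobleaching) FRET efficiency.

Donor intensity is read per cell before (``Q``, quenched) and after
(``DQ``, de-quenched) photobleaching the acceptor; efficiency is
E = (DQ − Q)/DQ.  Higher E means the donor sits closer to the acceptor —
here, a membrane-proximal receptor ectodomain conformation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FretCellMeasurement",
    "FretGroupSummary",
    "GroupComparison",
    "fret_efficiency",
    "summarize_group",
    "compare_groups",
    "cells_from_csv",
    "efficiency_table",
]


@dataclass(frozen=True)
class FretCellMeasurement:
    """Donor intensities (arbitrary units) for one cell.

    ``background`` is an optional per-image background level subtracted
    from both intensities before the ratio (autofluorescence correction
    is otherwise assumed done upstream).
    """

    cell_id: str
    q: float
    dq: float
    group: str = ""
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.dq - self.background <= 0:
            raise ValueError("de-quenched intensity must exceed background")
        if self.q < 0:
            raise ValueError("quenched intensity must be non-negative")


@dataclass(frozen=True)
class FretGroupSummary:
    group: str
    n_cells: int
    mean_e: float
    sem_e: float
    median_e: float
    n_flagged: int  # cells with E <= 0 (photobleach failure)


@dataclass(frozen=True)
class GroupComparison:
    fold_change: float  # mean(a) / mean(b)
    statistic: float
    p_value: float
    test: str


def fret_efficiency(m: FretCellMeasurement) -> float:
    """Per-cell FRET efficiency E = (DQ − Q)/DQ after background subtraction.

    Scale-invariant: multiplying both intensities (and background) by any
    c > 0 leaves E unchanged.  Cells with Q > DQ yield E < 0 and are kept;
    exclusion is an explicit choice made downstream.
    """
    dq = m.dq - m.background
    q = m.q - m.background
    return (dq - q) / dq


def _efficiencies(
    cells: Sequence[FretCellMeasurement], drop_nonpositive: bool = False
) -> np.ndarray:
    e = np.array([fret_efficiency(c) for c in cells])
    if drop_nonpositive:
        e = e[e > 0]
    return e


def summarize_group(
    cells: Sequence[FretCellMeasurement], drop_nonpositive: bool = False
) -> FretGroupSummary:
    """Mean, SEM and median efficiency over the cells of one group.

    Whether a published group efficiency is a mean or a median is often
    ambiguous, so both are reported.  Requires at least 2 cells (SEM).
    """
    if len(cells) < 2:
        raise ValueError("need at least 2 cells for a group summary")
    e_all = _efficiencies(cells)
    n_flagged = int(np.sum(e_all <= 0))
    e = _efficiencies(cells, drop_nonpositive)
    if len(e) < 2:
        raise ValueError("fewer than 2 cells remain after exclusion")
    group = cells[0].group
    return FretGroupSummary(
        group=group,
        n_cells=len(e),
        mean_e=float(np.mean(e)),
        sem_e=float(np.std(e, ddof=1) / math.sqrt(len(e))),
        median_e=float(np.median(e)),
        n_flagged=n_flagged,
    )


def compare_groups(
    a: Sequence[FretCellMeasurement],
    b: Sequence[FretCellMeasurement],
    test: str = "welch",
    drop_nonpositive: bool = False,
) -> GroupComparison:
    """Two-group efficiency comparison: fold change of means plus a test.

    Default is Welch's t on per-cell efficiencies (unequal variances —
    appropriate at ~20 cells per group); ``test="mannwhitney"`` switches
    to the rank test.  With n < 3 in a group and zero variance the t test
    is undefined, so the rank test is used with a warning.
    """
    if test not in ("welch", "mannwhitney"):
        raise ValueError(f"unknown test: {test!r}")
    ea = _efficiencies(a, drop_nonpositive)
    eb = _efficiencies(b, drop_nonpositive)
    if len(ea) < 2 or len(eb) < 2:
        raise ValueError("both groups need at least 2 cells")
    fold = float(np.mean(ea) / np.mean(eb))
    degenerate = (len(ea) < 3 and np.var(ea) == 0) or (
        len(eb) < 3 and np.var(eb) == 0
    )
    if test == "welch" and degenerate:
        warnings.warn(
            "degenerate variance with n<3; falling back to Mann-Whitney",
            RuntimeWarning,
        )
        test = "mannwhitney"
    if test == "welch":
        res = stats.ttest_ind(ea, eb, equal_var=False)
        return GroupComparison(fold, float(res.statistic), float(res.pvalue), "welch")
    res = stats.mannwhitneyu(ea, eb, alternative="two-sided")
    return GroupComparison(fold, float(res.statistic), float(res.pvalue), "mannwhitney")


def cells_from_csv(path) -> list[FretCellMeasurement]:
    """Read cells from CSV with columns cell_id, group, Q, DQ [, background]."""
    df = pd.read_csv(path)
    required = {"cell_id", "group", "Q", "DQ"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"FRET CSV missing columns: {sorted(missing)}")
    has_bg = "background" in df.columns
    return [
        FretCellMeasurement(
            cell_id=str(r.cell_id), group=str(r.group), q=float(r.Q),
            dq=float(r.DQ),
            background=float(r.background) if has_bg else 0.0,
        )
        for r in df.itertuples()
    ]


def efficiency_table(cells: Sequence[FretCellMeasurement]) -> pd.DataFrame:
    """Per-cell efficiency table (cell_id, group, E, flagged)."""
    e = [fret_efficiency(c) for c in cells]
    return pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "group": [c.group for c in cells],
            "E": e,
            "flagged": [v <= 0 for v in e],
        }
    )
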