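"""Recessive-model case–control statistics on genotype count tables.

For a biallelic SNP the recessive contrast collapses genotypes to
homozygous-minor (CC) versus all others (TT+TC), giving a 2×2 table of
cases/controls × CC/other.  The module parses the compact published row
dialect ``"TT+TC (pct)/CC (pct)"``, computes CC genotype frequencies,
crude odds ratios with Woolf (log-scale) 95% confidence intervals, and
Pearson chi-square tests without continuity correction by default.

Covariate-adjusted (logistic regression) odds ratios require
individual-level data and are deliberately not computed here; crude ORs
from the same counts typically sit somewhat below published adjusted
values.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import NamedTuple, Sequence

import pandas as pd
from scipy import special, stats

__all__ = [
    "RecessiveTable",
    "AssociationResult",
    "GenotypeRow",
    "parse_genotype_row",
    "cc_frequency",
    "cc_fraction",
    "crude_odds_ratio",
    "pearson_chi2",
    "batch_table1",
    "table_from_row",
]

_ROW_RE = re.compile(
    r"^\s*(\d+)\s*\+\s*(\d+)\s*\(\s*([\d.]+)\s*\)\s*/\s*(\d+)\s*\(\s*([\d.]+)\s*\)\s*$"
)


class GenotypeRow(NamedTuple):
    """Parsed genotype row: counts plus the printed percentages."""

    tt: int
    tc: int
    cc: int
    pct_other: float
    pct_cc: float


@dataclass(frozen=True)
class RecessiveTable:
    """2×2 recessive-model table (CC vs TT+TC, cases vs controls)."""

    cases_cc: int
    cases_other: int
    controls_cc: int
    controls_other: int
    label: str = ""

    def __post_init__(self) -> None:
        for v in (self.cases_cc, self.cases_other, self.controls_cc, self.controls_other):
            if v < 0:
                raise ValueError("counts must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.cases_cc + self.cases_other

    @property
    def n_controls(self) -> int:
        return self.controls_cc + self.controls_other

    def swapped(self) -> "RecessiveTable":
        """Cases and controls interchanged (OR inverts)."""
        return RecessiveTable(
            self.controls_cc, self.controls_other,
            self.cases_cc, self.cases_other, self.label,
        )


@dataclass(frozen=True)
class AssociationResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    chi2: float
    p: float
    correction: str = "none"  # "none" | "haldane"
    label: str = ""


def _round_half_up_1(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def parse_genotype_row(text: str) -> GenotypeRow:
    """Parse a row of the form ``"376+286 (96.2)/26 (3.8)"``.

    The first two counts are TT and TC carriers, the third CC; the
    percentages in parentheses are the printed genotype frequencies.
    Recomputed percentages must round (half-up, 1 decimal) to the printed
    ones within 0.05, otherwise a ValueError names the offending row.
    """
    m = _ROW_RE.match(text)
    if m is None:
        raise ValueError(f"malformed genotype row: {text!r}")
    tt, tc, cc = int(m.group(1)), int(m.group(2)), int(m.group(4))
    pct_other, pct_cc = float(m.group(3)), float(m.group(5))
    total = tt + tc + cc
    if total > 0:
        calc_other = _round_half_up_1(100.0 * (tt + tc) / total)
        calc_cc = _round_half_up_1(100.0 * cc / total)
        if abs(calc_other - pct_other) > 0.05 or abs(calc_cc - pct_cc) > 0.05:
            raise ValueError(
                f"percentage mismatch in row {text!r}: recomputed "
                f"({calc_other}, {calc_cc}) vs printed ({pct_other}, {pct_cc})"
            )
    return GenotypeRow(tt, tc, cc, pct_other, pct_cc)


def cc_fraction(tt: int, tc: int, cc: int) -> float:
    """Full-precision CC genotype frequency as a percentage."""
    total = tt + tc + cc
    if total <= 0:
        raise ValueError("zero total genotype count")
    return 100.0 * cc / total


def cc_frequency(tt: int, tc: int, cc: int) -> float:
    """CC genotype frequency in percent, rounded half-up to 1 decimal.

    Display convention matching published genotype tables; use
    :func:`cc_fraction` for the unrounded value.
    """
    return _round_half_up_1(cc_fraction(tt, tc, cc))


def _cells(t: RecessiveTable) -> tuple[float, float, float, float, str]:
    a, b = float(t.cases_cc), float(t.cases_other)
    c, d = float(t.controls_cc), float(t.controls_other)
    correction = "none"
    if min(a, b, c, d) == 0.0:
        # Haldane–Anscombe: +0.5 to every cell when any cell is empty.
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        correction = "haldane"
    return a, b, c, d, correction


def crude_odds_ratio(t: RecessiveTable) -> AssociationResult:
    """Crude recessive OR with Woolf 95% CI, plus the Pearson chi-square.

    OR = (cases_CC · controls_other) / (cases_other · controls_CC);
    CI = exp(ln OR ± 1.96·sqrt(Σ 1/cell)).  When any cell is zero all
    cells get the Haldane–Anscombe +0.5 and the result is flagged.
    """
    if t.n_cases == 0 or t.n_controls == 0:
        raise ValueError("both margins must be positive for an odds ratio")
    if (t.cases_cc + t.controls_cc) == 0 or (t.cases_other + t.controls_other) == 0:
        raise ValueError("both genotype margins must be positive for an odds ratio")
    a, b, c, d, correction = _cells(t)
    or_ = (a * d) / (b * c)
    se_log = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci_low = math.exp(math.log(or_) - 1.96 * se_log)
    ci_high = math.exp(math.log(or_) + 1.96 * se_log)
    chi2, p = pearson_chi2(t)
    return AssociationResult(
        odds_ratio=or_, ci_low=ci_low, ci_high=ci_high,
        chi2=chi2, p=p, correction=correction, label=t.label,
    )


def pearson_chi2(
    t: RecessiveTable, continuity: bool = False
) -> tuple[float, float]:
    """Pearson chi-square on the 2×2 table, df=1.

    No continuity correction by default (``continuity=True`` applies
    Yates).  The p-value is the chi-square(1) survival function, i.e. the
    regularized upper incomplete gamma Q(1/2, x/2).
    """
    a, b = float(t.cases_cc), float(t.cases_other)
    c, d = float(t.controls_cc), float(t.controls_other)
    n = a + b + c + d
    observed = (a, b, c, d)
    row1, row2 = a + b, c + d
    col1, col2 = a + c, b + d
    expected = (
        row1 * col1 / n, row1 * col2 / n, row2 * col1 / n, row2 * col2 / n
    )
    if min(expected) == 0.0:
        raise ValueError("zero expected cell; chi-square undefined")
    chi2 = 0.0
    for o, e in zip(observed, expected):
        diff = abs(o - e)
        if continuity:
            diff = max(diff - 0.5, 0.0)
        chi2 += diff * diff / e
    p = float(special.gammaincc(0.5, chi2 / 2.0))
    return chi2, p


def table_from_row(
    case_row: GenotypeRow | str, control_row: GenotypeRow | str, label: str = ""
) -> RecessiveTable:
    """Assemble a recessive 2×2 table from parsed (or raw) genotype rows."""
    if isinstance(case_row, str):
        case_row = parse_genotype_row(case_row)
    if isinstance(control_row, str):
        control_row = parse_genotype_row(control_row)
    return RecessiveTable(
        cases_cc=case_row.cc, cases_other=case_row.tt + case_row.tc,
        controls_cc=control_row.cc, controls_other=control_row.tt + control_row.tc,
        label=label,
    )


def batch_table1(
    rows: Sequence[tuple[str, str]], control_row: str
) -> pd.DataFrame:
    """Crude association statistics for labelled subphenotype rows.

    Each ``(label, row_text)`` is contrasted against the shared control
    row; output preserves input order with one record per subphenotype
    (counts, CC percentage, OR, CI, chi2, p, correction flag).
    """
    control = parse_genotype_row(control_row)
    records = []
    for label, text in rows:
        row = parse_genotype_row(text)
        table = table_from_row(row, control, label=label)
        res = crude_odds_ratio(table)
        records.append(
            {
                "label": label,
                "tt": row.tt, "tc": row.tc, "cc": row.cc,
                "cc_pct": cc_frequency(row.tt, row.tc, row.cc),
                "odds_ratio": res.odds_ratio,
                "ci_low": res.ci_low, "ci_high": res.ci_high,
                "chi2": res.chi2, "p": res.p,
                "correction": res.correction,
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=["label", "tt", "tc", "cc", "cc_pct", "odds_ratio",
                 "ci_low", "ci_high", "chi2", "p", "correction"],
    )
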