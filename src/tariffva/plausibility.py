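"""Plausibility assessment of VA-derived mortality statistics.

Verbal-autopsy CSMFs feeding a national statistics system need a sanity
review before anyone acts on them.  This module operationalises that review
with a small set of quantitative checks against an external reference
distribution (typically GBD-style model estimates for the country):

* the age distribution of VA deaths versus the reference age distribution,
  summarised by the index of dissimilarity (half the sum of absolute
  percentage-point differences);
* broad cause-group fractions with bootstrap CIs versus the reference, with
  a flag whenever the reference value falls outside a group's CI;
* the undetermined fraction and the sex ratio of the sample.

The reference is a comparator, not a gold standard: the report surfaces
discrepancies and leaves interpretation to the analyst, because a flagged
difference can reflect a genuinely different epidemiological environment
rather than an implausible VA result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .schema import DEFAULT_AGE_SCHEME, UNDETERMINED, AgeGroupScheme, VARecord, bin_age


@dataclass(frozen=True)
class AgeDistributionTable:
    """Counts and percentages of deaths per age group, VA side and optional
    reference side with absolute differences."""

    table: pd.DataFrame  # columns: age_group, count, percent [, ref_percent, abs_difference]
    n: int
    dissimilarity: float | None = None

    def row(self, age_group: str) -> pd.Series:
        return self.table.set_index("age_group").loc[age_group]


def age_distribution(
    records: Sequence[VARecord], scheme: AgeGroupScheme = DEFAULT_AGE_SCHEME
) -> AgeDistributionTable:
    """Tabulate deaths per age bin (including Unknown).

    Percentages are 100 x count / n rounded to 1 decimal, the precision at
    which such tables are conventionally printed.
    """
    if not len(records):
        raise ValueError("no records to tabulate")
    counts = dict.fromkeys(scheme.labels, 0)
    for r in records:
        counts[bin_age(r.age_years, scheme)] += 1
    n = len(records)
    table = pd.DataFrame(
        {
            "age_group": list(counts),
            "count": list(counts.values()),
        }
    )
    table["percent"] = (100.0 * table["count"] / n).round(1)
    return AgeDistributionTable(table, n)


def compare_age(
    va_table: AgeDistributionTable, ref_percent_by_bin: Mapping[str, float]
) -> AgeDistributionTable:
    """Attach reference percentages and the index of dissimilarity.

    The reference must cover the same bins (bins it omits are taken as 0,
    the usual convention for an Unknown row; a reference bin absent from
    the VA scheme is an error).  The dissimilarity index
    ``sum |va% - ref%| / 2`` ranges from 0 (identical) to 100 (disjoint).
    """
    known = set(va_table.table["age_group"])
    extra = set(ref_percent_by_bin) - known
    if extra:
        raise ValueError(f"reference age bins not in the VA scheme: {sorted(extra)}")
    table = va_table.table.copy()
    table["ref_percent"] = [float(ref_percent_by_bin.get(g, 0.0)) for g in table["age_group"]]
    table["abs_difference"] = (table["percent"] - table["ref_percent"]).abs()
    dissimilarity = float(table["abs_difference"].sum() / 2)
    return AgeDistributionTable(table, va_table.n, dissimilarity)


@dataclass(frozen=True)
class GroupComparison:
    group: str
    va_fraction: float
    ci_low: float
    ci_high: float
    ref_fraction: float
    flagged: bool


def compare_broad_groups(
    va_groups: Mapping[str, tuple[float, float, float]],
    ref_groups: Mapping[str, float],
) -> list[GroupComparison]:
    """Compare broad-group fractions (with CIs) against reference fractions.

    ``va_groups`` maps group -> (fraction, ci_low, ci_high).  A group is
    flagged when the reference fraction lies outside the VA CI — a prompt
    for scrutiny, not a verdict.
    """
    if set(va_groups) != set(ref_groups):
        raise ValueError(
            f"group sets differ: VA {sorted(va_groups)} vs reference {sorted(ref_groups)}"
        )
    rows = []
    for g in va_groups:
        frac, lo, hi = va_groups[g]
        ref = float(ref_groups[g])
        rows.append(
            GroupComparison(
                group=g,
                va_fraction=float(frac),
                ci_low=float(lo),
                ci_high=float(hi),
                ref_fraction=ref,
                flagged=not (lo <= ref <= hi),
            )
        )
    return rows


def undetermined_fraction(predictions: Sequence) -> float:
    """Share of predictions assigned the undetermined category."""
    if not len(predictions):
        raise ValueError("no predictions")
    n_undet = sum(1 for p in predictions if p.assigned_cause == UNDETERMINED)
    return n_undet / len(predictions)


def sex_ratio(records: Sequence[VARecord]) -> dict[str, float]:
    """Percent male / female / unknown among the records."""
    n = len(records)
    out = {}
    for s in ("male", "female", "unknown"):
        out[s] = 100.0 * sum(1 for r in records if r.sex == s) / n if n else 0.0
    return out


@dataclass(frozen=True)
class PlausibilityReport:
    """Structured plausibility review: tables, flags, and a rendered body."""

    age_table: AgeDistributionTable
    group_rows: list[GroupComparison]
    undetermined: float
    sex_percent: Mapping[str, float]
    flags: tuple[str, ...] = field(default_factory=tuple)

    def render(self) -> str:
        """Plain-markdown report body; byte-identical for identical inputs."""
        lines: list[str] = ["# VA plausibility review", ""]
        lines.append("## Age distribution")
        lines.append("")
        lines.append("| Age group | Deaths | VA % | Ref % | |diff| |")
        lines.append("|---|---|---|---|---|")
        t = self.age_table.table
        has_ref = "ref_percent" in t.columns
        for _, row in t.iterrows():
            ref = f"{row['ref_percent']:.1f}" if has_ref else "-"
            diff = f"{row['abs_difference']:.1f}" if has_ref else "-"
            lines.append(
                f"| {row['age_group']} | {int(row['count'])} | {row['percent']:.1f} | {ref} | {diff} |"
            )
        lines.append(f"| Total | {self.age_table.n} | 100.0 | | |")
        lines.append("")
        if self.age_table.dissimilarity is not None:
            lines.append(
                f"Index of dissimilarity (age): {self.age_table.dissimilarity:.2f} "
                "percentage points."
            )
            lines.append("")
        lines.append("## Broad cause groups vs reference")
        lines.append("")
        lines.append("| Group | VA fraction | 95% CI | Ref fraction | Flag |")
        lines.append("|---|---|---|---|---|")
        for row in self.group_rows:
            flag = "OUTSIDE CI" if row.flagged else ""
            lines.append(
                f"| {row.group} | {row.va_fraction:.3f} | "
                f"({row.ci_low:.3f}, {row.ci_high:.3f}) | {row.ref_fraction:.3f} | {flag} |"
            )
        lines.append("")
        lines.append("## Sample diagnostics")
        lines.append("")
        lines.append(f"- Undetermined fraction: {self.undetermined:.3f}")
        lines.append(
            "- Sex composition (%): male {male:.1f}, female {female:.1f}, "
            "unknown {unknown:.1f}".format(**self.sex_percent)
        )
        lines.append(
            "- Registration completeness: not assessed (requires population "
            "denominators external to this pipeline)."
        )
        lines.append("")
        if self.flags:
            lines.append("## Flags")
            lines.append("")
            for f in self.flags:
                lines.append(f"- {f}")
            lines.append("")
        lines.append(
            "The reference distribution is a modelled comparator, not a gold "
            "standard; flagged differences warrant scrutiny of both sources."
        )
        return "\n".join(lines) + "\n"


def build_report(
    records: Sequence[VARecord],
    predictions: Sequence,
    va_groups: Mapping[str, tuple[float, float, float]],
    ref_groups: Mapping[str, float],
    ref_age_percent: Mapping[str, float] | None = None,
    scheme: AgeGroupScheme = DEFAULT_AGE_SCHEME,
) -> PlausibilityReport:
    """Assemble the full plausibility report from pipeline outputs."""
    age_table = age_distribution(records, scheme)
    if ref_age_percent is not None:
        age_table = compare_age(age_table, ref_age_percent)
    group_rows = compare_broad_groups(va_groups, ref_groups)
    flags = tuple(
        f"broad group {row.group}: reference fraction {row.ref_fraction:.3f} "
        f"outside VA 95% CI ({row.ci_low:.3f}, {row.ci_high:.3f})"
        for row in group_rows
        if row.flagged
    )
    return PlausibilityReport(
        age_table=age_table,
        group_rows=group_rows,
        undetermined=undetermined_fraction(predictions),
        sex_percent=sex_ratio(records),
        flags=flags,
    )
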