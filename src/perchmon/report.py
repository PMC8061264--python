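"""Monitoring tallies and headline percentages.

Counts are cross-tabulated per monitoring year, origin and ancestry
category; percentages are always recomputed from the integer counts,
rounded half-up at the printed precision.  Note that 4/296 rounds to 1.4%
half-up at one decimal, while truncation would print 1.3% — both
conventions occur in published summaries of such tables, so the rounding
policy here is explicit.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

ANCESTRY_ORDER = ("DxD", "DxY", "YxY")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal rounding with .5 always going up (unlike banker's rounding)."""
    factor = 10.0**ndigits
    return math.floor(x * factor + 0.5) / factor


def percent(numerator: int, denominator: int, ndigits: int = 1) -> float:
    if denominator == 0:
        raise ZeroDivisionError("empty denominator in percentage")
    return round_half_up(100.0 * numerator / denominator, ndigits)


@dataclass
class MonitoringSummary:
    """Long-form counts by (capture year, origin, ancestry category).

    ``per_year`` counts samples (a recaptured fish appears in each year it
    was caught); ``unique_counts`` counts unique individuals once.
    """

    per_year: pd.DataFrame  # capture_year, origin, ancestry, count
    unique_counts: pd.DataFrame  # origin, ancestry, count

    def total_unique(self) -> int:
        return int(self.unique_counts["count"].sum())

    def origin_totals(self) -> pd.Series:
        return self.unique_counts.groupby("origin")["count"].sum()

    def origin_percentages(self, ndigits: int = 1) -> pd.Series:
        totals = self.origin_totals()
        denom = self.total_unique()
        return totals.map(lambda c: percent(int(c), denom, ndigits))

    def ancestry_breakdown(self, origin: str, ndigits: int = 1) -> pd.DataFrame:
        sub = self.unique_counts[self.unique_counts.origin == origin]
        denom = int(sub["count"].sum())
        rows = []
        for anc in ANCESTRY_ORDER:
            c = int(sub.loc[sub.ancestry == anc, "count"].sum())
            rows.append(dict(ancestry=anc, count=c,
                             pct=percent(c, denom, ndigits) if denom else float("nan")))
        return pd.DataFrame(rows)


_CATEGORY_TO_ANCESTRY = {
    "sourceD": "DxD",
    "sourceY": "YxY",
    "two_population": "DxY",
    "DxD": "DxD",
    "DxY": "DxY",
    "YxY": "YxY",
}


def tally_origins(origin_calls: pd.DataFrame) -> MonitoringSummary:
    """Cross-tabulate OriginCalls into a :class:`MonitoringSummary`.

    Recaptures must already be collapsed (one row per unique fish with its
    ``capture_years``).  Category order is fixed DxD, DxY, YxY; stocked fish
    take their cross-type from the assigned pair when ``cross_type`` is
    present, otherwise their ancestry category.
    """
    cols = ["capture_year", "origin", "ancestry", "count"]
    if origin_calls.empty:
        return MonitoringSummary(
            per_year=pd.DataFrame(columns=cols),
            unique_counts=pd.DataFrame(columns=cols[1:]),
        )
    df = origin_calls.copy()
    if "cross_type" in df.columns:
        anc = df["cross_type"].where(df["cross_type"].notna(),
                                     df["ancestry_category"])
    else:
        anc = df["ancestry_category"]
    df["ancestry"] = anc.map(lambda c: _CATEGORY_TO_ANCESTRY.get(c, c))

    per_year_rows = []
    for row in df.itertuples():
        for y in str(row.capture_years).split(";"):
            per_year_rows.append(
                dict(capture_year=int(y), origin=row.origin, ancestry=row.ancestry)
            )
    per_year = (
        pd.DataFrame(per_year_rows)
        .groupby(["capture_year", "origin", "ancestry"], dropna=False)
        .size()
        .rename("count")
        .reset_index()
    )
    unique_counts = (
        df.groupby(["origin", "ancestry"], dropna=False)
        .size()
        .rename("count")
        .reset_index()
    )
    return MonitoringSummary(per_year=per_year, unique_counts=unique_counts)


def summary_from_counts(counts: pd.DataFrame) -> MonitoringSummary:
    """Build a summary straight from a published-style count table.

    ``counts`` columns: ``capture_year``, ``origin``, ``ancestry``,
    ``count``.  Unique totals are the per-year sums (callers subtract known
    recaptures themselves if they have them).
    """
    per_year = counts.copy()
    unique_counts = (
        counts.groupby(["origin", "ancestry"])["count"].sum().reset_index()
    )
    return MonitoringSummary(per_year=per_year, unique_counts=unique_counts)


def yearly_proportions(
    summary: MonitoringSummary,
    numerator: list,
    ndigits: int = 2,
) -> pd.Series:
    """Per-year fraction of samples in the numerator categories.

    ``numerator`` lists ``(origin, ancestry)`` tuples; they must all occur
    in the summary's category space.  Fractions are of each year's total
    sample count, rounded half-up to ``ndigits``.
    """
    per_year = summary.per_year
    seen = set(zip(per_year.origin, per_year.ancestry))
    unknown = [pair for pair in numerator if pair not in seen]
    if unknown:
        raise ValueError(f"numerator categories absent from summary: {unknown}")
    out = {}
    for year, sub in per_year.groupby("capture_year"):
        total = int(sub["count"].sum())
        num = int(
            sub[[(o, a) in numerator for o, a in zip(sub.origin, sub.ancestry)]][
                "count"
            ].sum()
        )
        out[int(year)] = round_half_up(num / total, ndigits)
    return pd.Series(out).sort_index()
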