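"""Calibration windows from clade-age credibility intervals and group rate summaries.

The age of a clade can be constrained by intersecting the per-gene 95%
credibility intervals obtained from independent relaxed-clock analyses:
genes agree on an age window exactly where all their intervals overlap
(the "concordant overlap").  That window is then exported as a normal
calibration prior for downstream dating runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import Interval, TraitTable

__all__ = [
    "EmptyIntersectionError",
    "concordant_overlap",
    "select_calibration_set",
    "NormalCalibration",
    "normal_calibration",
    "group_rate_summary",
]


class EmptyIntersectionError(ValueError):
    """Raised when a set of intervals has no common point."""


def concordant_overlap(intervals: Sequence[Interval]) -> Interval:
    """Intersection of closed intervals: ``[max(lows), min(highs)]``.

    Boundary-touching intervals intersect in a point, which is returned.
    An empty intersection raises, naming a conflicting pair.
    """
    intervals = list(intervals)
    if not intervals:
        raise ValueError("need at least one interval")
    argmax_low = max(range(len(intervals)), key=lambda i: intervals[i].low)
    argmin_high = min(range(len(intervals)), key=lambda i: intervals[i].high)
    low = intervals[argmax_low].low
    high = intervals[argmin_high].high
    if low > high:
        raise EmptyIntersectionError(
            f"intervals {intervals[argmax_low]} and {intervals[argmin_high]} are disjoint"
        )
    return Interval(low, high)


def select_calibration_set(
    table: TraitTable, exclude: Iterable[str] = ()
) -> list[tuple[str, Interval]]:
    """Collect per-gene age CIs eligible for clade calibration.

    A row contributes its interval when it has a numeric CI, the clade was
    recovered monophyletic (no paraphyly flag), and the gene is not in
    ``exclude`` (used for genes whose age conflicts with the fossil
    record).  Returns ``(gene, Interval)`` pairs; an empty selection is an
    error.
    """
    exclude = set(exclude)
    if not table.has_column("age_low"):
        raise ValueError("table has no age interval columns")
    df = table.df
    selected: list[tuple[str, Interval]] = []
    for _, row in df.iterrows():
        if row["gene"] in exclude:
            continue
        if pd.isna(row.get("age_low")) or pd.isna(row.get("age_high")):
            continue
        para = row.get("coleoptera_paraphyletic")
        if pd.notna(para) and bool(para):
            continue
        selected.append((row["gene"], Interval(float(row["age_low"]), float(row["age_high"]))))
    if not selected:
        raise ValueError("no rows eligible for calibration (empty selection)")
    return selected


@dataclass(frozen=True)
class NormalCalibration:
    """Serializable normal calibration prior on a clade age (Ma)."""

    mean: float
    sd: float

    def quantile(self, q: float) -> float:
        return float(norm.ppf(q, loc=self.mean, scale=self.sd))

    def central_interval(self, coverage: float = 0.95) -> Interval:
        alpha = (1.0 - coverage) / 2.0
        return Interval(self.quantile(alpha), self.quantile(1.0 - alpha))

    def to_dict(self) -> dict:
        return {"distribution": "normal", "mean": self.mean, "sd": self.sd}


def normal_calibration(mean: float, sd: float) -> NormalCalibration:
    """Construct a normal age prior; ``sd`` must be positive."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    return NormalCalibration(mean=float(mean), sd=float(sd))


def group_rate_summary(
    table: TraitTable, by: str, rate_column: str = "rate"
) -> pd.DataFrame:
    """Mean +/- sample SD (n - 1 denominator) of rates per trait level.

    Returns a DataFrame indexed by level with columns ``n``, ``mean``,
    ``sd``; levels without data are skipped.
    """
    df = table.df
    if by not in df.columns:
        raise KeyError(f"no grouping column {by!r}")
    if rate_column not in df.columns:
        raise KeyError(f"no rate column {rate_column!r}")
    sub = df[[by, rate_column]].dropna()
    records = {}
    for level, grp in sub.groupby(by, sort=True):
        vals = grp[rate_column].to_numpy(dtype=float)
        records[level] = {
            "n": len(vals),
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        }
    return pd.DataFrame.from_dict(records, orient="index")
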