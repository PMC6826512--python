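"""Sex-bias classification of expression profiles by a fold-change rule.

A gene counts as sex biased when its summary expression score in one sex
is at least ``fold`` times the score in the other sex (default twofold,
applied symmetrically); anything between the two thresholds is unbiased.
Multi-stage profiles are reduced to one score per sex by a configurable
aggregator (mean by default) before the rule is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .core import BiasLabel

__all__ = ["ExpressionProfile", "classify_bias", "aggregate_stages", "log2_heatmap_matrix"]


@dataclass(frozen=True)
class ExpressionProfile:
    """Per-gene male/female expression summary scores (non-negative)."""

    gene_name: str
    male_expr: float
    female_expr: float
    stage_label: str | None = None

    def __post_init__(self) -> None:
        if self.male_expr < 0 or self.female_expr < 0:
            raise ValueError(f"{self.gene_name}: negative expression score")


def classify_bias(
    profile: ExpressionProfile, fold: float = 2.0, pseudocount: float = 0.0
) -> BiasLabel:
    """Label a profile male-/female-biased or unbiased by the fold rule.

    Biased iff the ratio reaches ``fold`` on either side (a score exactly
    ``fold`` times the other counts as biased).  With pseudocount 0 a
    both-zero profile is unbiased.
    """
    if fold <= 1:
        raise ValueError("fold must exceed 1")
    m = profile.male_expr + pseudocount
    f = profile.female_expr + pseudocount
    if m == 0.0 and f == 0.0:
        return BiasLabel.UNBIASED
    if m >= fold * f:
        return BiasLabel.MALE_BIASED
    if f >= fold * m:
        return BiasLabel.FEMALE_BIASED
    return BiasLabel.UNBIASED


def aggregate_stages(
    profiles: Sequence[ExpressionProfile],
    aggregator: Callable[[np.ndarray], float] = np.mean,
) -> ExpressionProfile:
    """Reduce multiple per-stage profiles of one gene to a single summary."""
    if not profiles:
        raise ValueError("no profiles to aggregate")
    names = {p.gene_name for p in profiles}
    if len(names) != 1:
        raise ValueError(f"profiles span several genes: {sorted(names)}")
    m = float(aggregator(np.array([p.male_expr for p in profiles])))
    f = float(aggregator(np.array([p.female_expr for p in profiles])))
    return ExpressionProfile(profiles[0].gene_name, m, f, stage_label="aggregated")


def log2_heatmap_matrix(
    profiles: Sequence[ExpressionProfile], pseudocount: float = 0.0
) -> np.ndarray:
    """Element-wise log2 score matrix (genes x [male, female])."""
    scores = np.array(
        [[p.male_expr + pseudocount, p.female_expr + pseudocount] for p in profiles]
    )
    if (scores <= 0).any():
        raise ValueError("zero or negative score without pseudocount")
    return np.log2(scores)
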