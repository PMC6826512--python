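"""Domain types, trait-table I/O, and molecular-clock categorization.

The central container is :class:`TraitTable`, a validated, pandas-backed
table with one row per gene carrying the categorical traits used in the
rate contrasts (sex bias, duplication status, network membership), the
posterior mean substitution rate with its standard deviation, the relaxed
clock rate-heterogeneity parameter (``ucld.stdev``), and, where available,
the estimated crown age of Coleoptera with its 95% credibility interval.

Rates are stored in natural units (substitutions per lineage per million
years).  Fixture files print them scaled by 10^3, which the reader undoes
at load time.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "BiasLabel",
    "Interval",
    "TableDialect",
    "TraitTable",
    "TestResult",
    "TraitTableError",
    "read_trait_table",
    "write_trait_table",
    "categorize_clock",
    "packaged_fixture",
    "DEFAULT_CLOCK_THRESHOLD",
]

#: ucld.stdev below which a gene is considered to evolve in a clocklike
#: fashion; at or above it the gene is rate heterogeneous.
DEFAULT_CLOCK_THRESHOLD = 0.6


class TraitTableError(ValueError):
    """Raised for malformed or inconsistent trait tables."""


class BiasLabel(str, enum.Enum):
    """Sex-bias classification of a gene's expression profile."""

    UNBIASED = "unbiased"
    MALE_BIASED = "male_biased"
    FEMALE_BIASED = "female_biased"

    @property
    def is_biased(self) -> bool:
        return self is not BiasLabel.UNBIASED


@dataclass(frozen=True, order=True)
class Interval:
    """Closed interval ``[low, high]`` in Ma (million years)."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if math.isnan(self.low) or math.isnan(self.high):
            raise ValueError("interval bounds must be finite")
        if self.low > self.high:
            raise ValueError(f"interval low {self.low} exceeds high {self.high}")

    @property
    def width(self) -> float:
        return self.high - self.low

    def contains(self, x: float) -> bool:
        return self.low <= x <= self.high

    def intersect(self, other: "Interval") -> "Interval | None":
        low = max(self.low, other.low)
        high = min(self.high, other.high)
        if low > high:
            return None
        return Interval(low, high)


@dataclass(frozen=True)
class TestResult:
    """Outcome of a statistical contrast.

    ``statistics`` is a named map, e.g. ``{"U_x": ..., "U_y": ..., "U_min": ...}``
    for a Mann-Whitney test or ``{"S": ..., "rho": ...}`` for a Spearman
    correlation, so every convention in which a statistic is reported stays
    available to the caller.
    """

    method: str
    statistics: Mapping[str, float]
    n_per_group: tuple[int, ...]
    p_value: float
    p_method: str
    seed: int | None = None
    detail: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    def __getitem__(self, key: str) -> float:
        return self.statistics[key]

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistics": dict(self.statistics),
            "n_per_group": list(self.n_per_group),
            "p_value": self.p_value,
            "p_method": self.p_method,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class TableDialect:
    """How a tab-separated trait table encodes its values."""

    missing: str = "-"
    rate_scale: float = 1e-3  # printed rate columns are x10^3
    sep: str = "\t"


#: Columns a TraitTable may carry, in canonical order.  Only ``gene`` is
#: mandatory; everything else is per-fixture optional.
_CANONICAL_COLUMNS = (
    "gene",
    "flybase_id",
    "function",
    "bias_label",
    "sex_biased",
    "duplicated",
    "in_network",
    "rate",
    "rate_sd",
    "ucld_stdev",
    "ucld_censored",
    "clock_like",
    "age_mean",
    "age_low",
    "age_high",
    "coleoptera_paraphyletic",
    "n_species",
    "aligned_len",
    "model_name",
)

_BOOL_COLUMNS = ("sex_biased", "duplicated", "in_network", "coleoptera_paraphyletic")


class TraitTable:
    """Immutable-row-count collection of per-gene trait records."""

    def __init__(self, df: pd.DataFrame, provenance: str = "unspecified"):
        self._df = df.reset_index(drop=True)
        self.provenance = provenance
        self._n_rows = len(self._df)
        self._validate()

    def _validate(self) -> None:
        if "gene" not in self._df.columns:
            raise TraitTableError("trait table lacks a 'gene' column")
        dup = self._df["gene"][self._df["gene"].duplicated()]
        if len(dup):
            raise TraitTableError(f"duplicate gene name: {dup.iloc[0]!r}")
        if "bias_label" in self._df.columns:
            allowed = {b.value for b in BiasLabel}
            bad = set(self._df["bias_label"].dropna()) - allowed
            if bad:
                raise TraitTableError(f"unknown bias label(s): {sorted(bad)}")
        for col in ("rate", "rate_sd"):
            if col in self._df.columns:
                vals = self._df[col].dropna()
                if col == "rate" and (vals <= 0).any():
                    raise TraitTableError("substitution rates must be positive")
                if col == "rate_sd" and (vals < 0).any():
                    raise TraitTableError("rate standard deviations must be non-negative")

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return self._n_rows

    def __repr__(self) -> str:
        return f"TraitTable(n={len(self)}, provenance={self.provenance!r})"

    @property
    def df(self) -> pd.DataFrame:
        """The underlying data as a defensive copy."""
        return self._df.copy()

    @property
    def genes(self) -> list[str]:
        return list(self._df["gene"])

    def column(self, name: str) -> pd.Series:
        if name not in self._df.columns:
            raise KeyError(f"trait table has no column {name!r}")
        return self._df[name].copy()

    def has_column(self, name: str) -> bool:
        return name in self._df.columns

    def subset(self, mask: Sequence[bool], provenance: str | None = None) -> "TraitTable":
        return TraitTable(
            self._df[list(mask)], provenance or f"{self.provenance}[subset]"
        )

    def with_columns(self, **cols) -> "TraitTable":
        df = self._df.copy()
        for name, values in cols.items():
            df[name] = values
        return TraitTable(df, self.provenance)

    def age_interval(self, gene: str) -> Interval | None:
        row = self._df[self._df["gene"] == gene]
        if row.empty:
            raise KeyError(f"no gene {gene!r} in table")
        low, high = row["age_low"].iloc[0], row["age_high"].iloc[0]
        if pd.isna(low) or pd.isna(high):
            return None
        return Interval(float(low), float(high))


def _parse_ucld(raw: str, missing: str) -> tuple[float | None, bool]:
    """Parse a ucld.stdev cell; censored entries ``>x`` keep x and a flag."""
    raw = raw.strip()
    if raw == missing or raw == "":
        return None, False
    if raw.startswith(">"):
        return float(raw[1:]), True
    return float(raw), False


def read_trait_table(
    path: str | Path,
    dialect: TableDialect = TableDialect(),
    provenance: str | None = None,
) -> TraitTable:
    """Read a tab-separated trait table with a header row.

    Missing values are encoded with ``dialect.missing`` (default ``-``).
    Printed rate columns named ``rate_x1e3``/``rate_sd_x1e3`` are rescaled
    to natural units at load.  A censored ``ucld.stdev`` entry ``">3"`` is
    parsed as value 3.0 with ``ucld_censored`` set; such genes can never be
    classified clocklike.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=dialect.sep, dtype=str, keep_default_na=False)
    if raw.empty:
        raise TraitTableError(f"{path}: no data rows")
    if "gene" not in raw.columns:
        raise TraitTableError(f"{path}: missing 'gene' header column")

    out = pd.DataFrame({"gene": raw["gene"].str.strip()})
    for col in ("flybase_id", "function", "bias_label", "model_name"):
        if col in raw.columns:
            out[col] = raw[col].replace(dialect.missing, pd.NA)

    for col in _BOOL_COLUMNS:
        if col in raw.columns:
            out[col] = (
                raw[col]
                .replace(dialect.missing, pd.NA)
                .map({"0": False, "1": True, pd.NA: pd.NA})
                .astype("boolean")
            )

    def numeric(col: str, scale: float = 1.0) -> pd.Series:
        vals = []
        for i, cell in enumerate(raw[col]):
            cell = cell.strip()
            if cell == dialect.missing or cell == "":
                vals.append(None)
                continue
            try:
                vals.append(float(cell) * scale)
            except ValueError:
                raise TraitTableError(
                    f"{path}: non-numeric value {cell!r} in column {col!r}, row {i + 2}"
                ) from None
        return pd.Series(vals, dtype="float64")

    if "rate_x1e3" in raw.columns:
        out["rate"] = numeric("rate_x1e3", dialect.rate_scale)
    if "rate_sd_x1e3" in raw.columns:
        out["rate_sd"] = numeric("rate_sd_x1e3", dialect.rate_scale)
    for col, scale in (("rate", 1.0), ("rate_sd", 1.0)):
        if col in raw.columns:
            out[col] = numeric(col, scale)

    if "ucld_stdev" in raw.columns:
        parsed = [
            _parse_ucld(cell, dialect.missing) for cell in raw["ucld_stdev"]
        ]
        out["ucld_stdev"] = pd.Series(
            [v for v, _ in parsed], dtype="float64"
        )
        out["ucld_censored"] = [c for _, c in parsed]

    for col in ("age_mean", "age_low", "age_high"):
        if col in raw.columns:
            out[col] = numeric(col)
    for col in ("n_species", "aligned_len", "n_seqs", "n_single_copy_species",
                "median_len", "rel_rate", "aligned_n"):
        if col in raw.columns:
            out[col] = numeric(col)

    # sanity: CI brackets its mean when both present
    if {"age_mean", "age_low", "age_high"} <= set(out.columns):
        have = out[["age_mean", "age_low", "age_high"]].dropna()
        bad = have[(have["age_mean"] < have["age_low"]) | (have["age_mean"] > have["age_high"])]
        if len(bad):
            gene = out.loc[bad.index[0], "gene"]
            raise TraitTableError(f"{path}: age CI does not bracket mean for gene {gene!r}")

    return TraitTable(out, provenance or path.name)


def write_trait_table(
    table: TraitTable, path: str | Path, dialect: TableDialect = TableDialect()
) -> None:
    """Write a TraitTable back to TSV in the fixture encoding.

    Numeric text round-trips: rates are re-scaled to the printed x10^3
    representation and censored ucld.stdev entries are re-encoded as ``>x``.
    """
    df = table.df
    out = pd.DataFrame({"gene": df["gene"]})

    def fmt(x, nd=None) -> str:
        if pd.isna(x):
            return dialect.missing
        s = f"{x:.12g}"
        return s

    for col in ("flybase_id", "function", "bias_label", "model_name"):
        if col in df.columns:
            out[col] = df[col].fillna(dialect.missing)
    for col in _BOOL_COLUMNS:
        if col in df.columns:
            out[col] = df[col].map({True: "1", False: "0"}).fillna(dialect.missing)
    if "rate" in df.columns:
        out["rate_x1e3"] = (df["rate"] / dialect.rate_scale).map(fmt)
    if "rate_sd" in df.columns:
        out["rate_sd_x1e3"] = (df["rate_sd"] / dialect.rate_scale).map(fmt)
    if "ucld_stdev" in df.columns:
        cens = df.get("ucld_censored", pd.Series([False] * len(df)))
        out["ucld_stdev"] = [
            dialect.missing if pd.isna(v) else (f">{fmt(v)}" if c else fmt(v))
            for v, c in zip(df["ucld_stdev"], cens)
        ]
    for col in ("age_mean", "age_low", "age_high", "n_species", "aligned_len"):
        if col in df.columns:
            out[col] = df[col].map(fmt)
    out.to_csv(path, sep=dialect.sep, index=False)


def categorize_clock(
    table: TraitTable, threshold: float = DEFAULT_CLOCK_THRESHOLD
) -> TraitTable:
    """Partition genes into clocklike vs rate-heterogeneous.

    A gene is heterogeneous iff ``ucld.stdev >= threshold`` (the partition
    is exhaustive at the boundary).  Censored entries recorded as ``>x``
    are never clocklike provided ``x >= threshold`` does not contradict the
    censoring; since censoring marks inconclusive relaxed-clock runs they
    are always classified heterogeneous.  Rows without a ucld.stdev value
    get a missing classification.
    """
    if not table.has_column("ucld_stdev"):
        raise TraitTableError("table has no ucld_stdev column to categorize")
    ucld = table.column("ucld_stdev")
    censored = (
        table.column("ucld_censored")
        if table.has_column("ucld_censored")
        else pd.Series([False] * len(table))
    )
    clock_like = pd.array(
        [
            pd.NA
            if pd.isna(v)
            else bool((not c) and v < threshold)
            for v, c in zip(ucld, censored)
        ],
        dtype="boolean",
    )
    return table.with_columns(clock_like=clock_like)


def packaged_fixture(name: str) -> Path:
    """Path to a fixture table shipped with the package (e.g. ``table4``)."""
    p = Path(__file__).parent / "data" / f"{name}.tsv"
    if not p.exists():
        raise FileNotFoundError(f"no packaged fixture {name!r}")
    return p
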