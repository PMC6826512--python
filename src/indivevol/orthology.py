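"""Multicopy flagging from ortholog-database counts and recovery summaries.

An orthologous group that yields more sequences than there are species in
the database usually hides paralogs; the flag raised here is advisory
metadata for curation, never an automatic exclusion.  Recovery summaries
condense a genes x species presence/absence matrix into the per-gene and
per-species retrieval statistics used to judge search performance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OrthoGroupSummary",
    "RecoveryMatrix",
    "flag_multicopy",
    "recovery_summaries",
]

#: Number of insect species curated in the ortholog database at study time.
DEFAULT_N_SPECIES = 119


@dataclass(frozen=True)
class OrthoGroupSummary:
    """Sequence statistics of one orthologous group."""

    gene_name: str
    n_seqs: int
    n_species: int
    n_single_copy_species: int | None = None
    median_len: int | None = None
    rel_rate: float | None = None
    aligned_n: int | None = None
    aligned_len: int | None = None
    model_name: str | None = None

    def __post_init__(self) -> None:
        if self.n_species > self.n_seqs:
            raise ValueError(
                f"{self.gene_name}: species count {self.n_species} exceeds sequence count {self.n_seqs}"
            )
        if (
            self.n_single_copy_species is not None
            and self.n_single_copy_species > self.n_species
        ):
            raise ValueError(
                f"{self.gene_name}: single-copy species exceed species count"
            )


def flag_multicopy(
    summary: OrthoGroupSummary, n_species_total: int = DEFAULT_N_SPECIES
) -> bool:
    """True iff the group holds more sequences than species in the database.

    Strictly more: a gene retrieved once per species is not flagged.
    """
    if n_species_total <= 0:
        raise ValueError("n_species_total must be positive")
    return summary.n_seqs > n_species_total


class RecoveryMatrix:
    """Boolean genes x species matrix of ortholog presence."""

    def __init__(self, df: pd.DataFrame):
        if df.empty:
            raise ValueError("recovery matrix is empty")
        self.df = df.astype(bool)

    @classmethod
    def from_arrays(
        cls, genes: Sequence[str], species: Sequence[str], found: np.ndarray
    ) -> "RecoveryMatrix":
        found = np.asarray(found, dtype=bool)
        if found.shape != (len(genes), len(species)):
            raise ValueError(
                f"matrix shape {found.shape} does not match {len(genes)} genes x {len(species)} species"
            )
        return cls(pd.DataFrame(found, index=list(genes), columns=list(species)))

    @property
    def genes(self) -> list[str]:
        return list(self.df.index)

    @property
    def species(self) -> list[str]:
        return list(self.df.columns)


def recovery_summaries(
    m: RecoveryMatrix,
    gene_thresholds: Sequence[int] = (),
    species_thresholds: Sequence[float] = (),
) -> dict:
    """Per-gene/per-species recovery counts and threshold exceedance fractions.

    ``gene_thresholds`` are absolute species counts: the summary reports,
    for each threshold t, the fraction of genes found in at least t
    species.  ``species_thresholds`` are fractions of the gene set: the
    fraction of species yielding at least that proportion of the genes.
    """
    found = m.df.to_numpy()
    n_genes, n_species = found.shape
    per_gene = pd.Series(found.sum(axis=1), index=m.genes, name="n_species_found")
    per_species = pd.Series(found.sum(axis=0), index=m.species, name="n_genes_found")

    gene_frac = {
        int(t): float((per_gene >= t).mean()) for t in gene_thresholds
    }
    species_frac = {
        float(t): float((per_species >= t * n_genes).mean())
        for t in species_thresholds
    }
    return {
        "per_gene": per_gene,
        "per_species": per_species,
        "gene_threshold_fractions": gene_frac,
        "species_threshold_fractions": species_frac,
        "n_genes": n_genes,
        "n_species": n_species,
    }
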