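"""Curation filters for multiple sequence alignments.

Sequence data mined from public databases and raw transcriptomes carries
recurrent artifacts: short fragments covering a fraction of the gene,
long private (autapomorphic) insertion runs that usually correspond to
unrecognized introns, redundant near-identical conspecific sequences, and
occasional wholly divergent sequences whose homology is doubtful.  The
filters here remove each artifact class reproducibly, with numeric
thresholds replacing what is otherwise manual curation, and report every
action taken.  Coordinates in reports are 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Alignment",
    "AlignmentError",
    "TrimmedSpan",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "remove_short_fragments",
    "trim_autapomorphic_runs",
    "merge_disjoint_fragments",
    "flag_divergent_sequences",
    "dedupe_conspecific",
    "run_qc",
]

GAP = "-"
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
NT_ALPHABET = set("ACGTU")


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class TrimmedSpan:
    """A column span removed because of a private insertion run."""

    seq_id: str
    start: int  # 0-based, inclusive
    end: int    # exclusive


@dataclass(frozen=True)
class Alignment:
    """Rectangular MSA over amino acids or nucleotides.

    Rows keep their input order.  ``taxa`` maps each sequence to its taxon
    label (by default the part of the id before the first ``|``, or the
    whole id); conspecific filters key on it.
    """

    ids: tuple[str, ...]
    seqs: tuple[str, ...]
    alphabet: str = "amino_acid"  # or "nucleotide"
    taxa: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and seqs differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("duplicate sequence ids")
        if self.alphabet not in ("amino_acid", "nucleotide"):
            raise AlignmentError(f"unknown alphabet {self.alphabet!r}")
        widths = {len(s) for s in self.seqs}
        if len(widths) > 1:
            raise AlignmentError(f"unequal row lengths: {sorted(widths)}")
        allowed = (AA_ALPHABET if self.alphabet == "amino_acid" else NT_ALPHABET) | {
            GAP,
            self.missing_char,
        }
        for sid, s in zip(self.ids, self.seqs):
            bad = set(s.upper()) - allowed
            if bad:
                raise AlignmentError(f"{sid}: illegal characters {sorted(bad)}")
        if not self.taxa:
            object.__setattr__(
                self, "taxa", tuple(i.split("|")[0] for i in self.ids)
            )
        elif len(self.taxa) != len(self.ids):
            raise AlignmentError("taxa and ids differ in length")

    @property
    def missing_char(self) -> str:
        return "X" if self.alphabet == "amino_acid" else "N"

    @property
    def n_seqs(self) -> int:
        return len(self.ids)

    @property
    def width(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def residue_counts(self) -> np.ndarray:
        """Non-gap, non-missing residue count per sequence."""
        miss = self.missing_char
        return np.array(
            [sum(c != GAP and c.upper() != miss for c in s) for s in self.seqs]
        )

    def matrix(self) -> np.ndarray:
        return np.array([list(s.upper()) for s in self.seqs])

    def select_rows(self, keep: Sequence[int]) -> "Alignment":
        return replace(
            self,
            ids=tuple(self.ids[i] for i in keep),
            seqs=tuple(self.seqs[i] for i in keep),
            taxa=tuple(self.taxa[i] for i in keep),
        )

    def select_columns(self, keep: Sequence[int]) -> "Alignment":
        keep = list(keep)
        return replace(
            self, seqs=tuple("".join(s[j] for j in keep) for s in self.seqs)
        )

    def drop_all_gap_columns(self) -> "Alignment":
        if self.n_seqs == 0:
            return self
        m = self.matrix()
        keep = [j for j in range(self.width) if not (m[:, j] == GAP).all()]
        return self.select_columns(keep)


def read_fasta_alignment(path: str | Path, alphabet: str = "amino_acid") -> Alignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"{path}: no sequences")
    return Alignment(
        ids=tuple(r.id for r in records),
        seqs=tuple(str(r.seq) for r in records),
        alphabet=alphabet,
    )


def write_fasta_alignment(aln: Alignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description="") for i, s in zip(aln.ids, aln.seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


def remove_short_fragments(
    aln: Alignment, min_span: float = 0.5
) -> tuple[Alignment, list[str]]:
    """Drop sequences spanning less than ``min_span`` of the gene.

    Span is measured as the residue count relative to the *median* residue
    count over all sequences (alignment width inflates with indels, the
    median does not).  All-gap columns left by removals are pruned.
    """
    if aln.n_seqs == 0:
        raise AlignmentError("empty alignment")
    counts = aln.residue_counts()
    cutoff = min_span * float(np.median(counts))
    keep = [i for i in range(aln.n_seqs) if counts[i] >= cutoff]
    removed = [aln.ids[i] for i in range(aln.n_seqs) if counts[i] < cutoff]
    if not keep:
        raise AlignmentError("no sequences survive span filter")
    return aln.select_rows(keep).drop_all_gap_columns(), removed


def trim_autapomorphic_runs(
    aln: Alignment, min_run: int = 10
) -> tuple[Alignment, list[TrimmedSpan]]:
    """Delete long single-sequence insertion runs.

    A column belongs to a private insertion when exactly one sequence has
    a residue there and every other row is a gap.  Maximal runs of at
    least ``min_run`` consecutive such columns attributable to the same
    sequence are deleted; shorter runs are untouched.  Other sequences
    lose only gap columns, so their residues are never altered.
    """
    if aln.n_seqs < 3:
        raise AlignmentError("need at least 3 sequences")
    m = aln.matrix()
    miss = aln.missing_char
    is_res = (m != GAP) & (m != miss)
    res_per_col = is_res.sum(axis=0)
    # owner[j] = row index of the single residue, or -1
    owner = np.where(res_per_col == 1, is_res.argmax(axis=0), -1)

    spans: list[TrimmedSpan] = []
    drop = np.zeros(aln.width, dtype=bool)
    j = 0
    while j < aln.width:
        if owner[j] >= 0:
            k = j
            while k + 1 < aln.width and owner[k + 1] == owner[j]:
                k += 1
            if k - j + 1 >= min_run:
                spans.append(TrimmedSpan(aln.ids[int(owner[j])], j, k + 1))
                drop[j : k + 1] = True
            j = k + 1
        else:
            j += 1
    keep = [j for j in range(aln.width) if not drop[j]]
    return aln.select_columns(keep), spans


def merge_disjoint_fragments(
    fragments: Sequence[tuple[str, int]], total_length: int, missing_char: str = "X"
) -> str:
    """Reconstitute a full-length sequence from disjoint fragments.

    Positions covered by a fragment copy its residues; gaps between
    fragments are filled with the missing-data character.  Overlaps are
    allowed only when the overlapping residues agree.
    """
    out: list[str | None] = [None] * total_length
    for seq, start in fragments:
        if start < 0 or start + len(seq) > total_length:
            raise AlignmentError(
                f"fragment at offset {start} (length {len(seq)}) exceeds total length {total_length}"
            )
        for k, c in enumerate(seq):
            p = start + k
            if out[p] is not None and out[p] != c:
                raise AlignmentError(f"fragment conflict at position {p}")
            out[p] = c
    return "".join(c if c is not None else missing_char for c in out)


def _pairwise_p_distance(a: str, b: str, miss: str) -> float | None:
    """Proportion of differing sites over columns where both have residues."""
    used = diff = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in (GAP, miss) or y in (GAP, miss):
            continue
        used += 1
        if x != y:
            diff += 1
    if used == 0:
        return None
    return diff / used


def flag_divergent_sequences(aln: Alignment, k_sd: float = 3.0) -> list[str]:
    """Flag sequences unusually divergent for the alignment's variability.

    Each sequence's mean pairwise p-distance to all others is z-scored
    leave-one-out: sequence i is flagged when its mean exceeds
    ``mean + k_sd * SD`` of the *other* sequences' means.  Excluding the
    candidate keeps a single extreme outlier from inflating the spread it
    is judged against.  A zero-variance alignment (e.g. identical
    sequences) flags nothing.
    """
    if aln.n_seqs < 4:
        raise AlignmentError("need at least 4 sequences")
    miss = aln.missing_char
    n = aln.n_seqs
    dists = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            d = _pairwise_p_distance(aln.seqs[i], aln.seqs[j], miss)
            if d is not None:
                dists[i, j] = dists[j, i] = d
    with np.errstate(invalid="ignore"):
        means = np.nanmean(dists, axis=1)
    flagged = []
    for i in range(n):
        others = np.delete(means, i)
        mu = float(np.nanmean(others))
        sd = float(np.nanstd(others))
        if sd == 0.0 or np.isnan(sd) or np.isnan(means[i]):
            continue
        if means[i] > mu + k_sd * sd:
            flagged.append(aln.ids[i])
    return flagged


def _identity(a: str, b: str, miss: str) -> float:
    d = _pairwise_p_distance(a, b, miss)
    return 1.0 if d is None else 1.0 - d


def dedupe_conspecific(
    aln: Alignment, min_identity: float = 0.99
) -> tuple[Alignment, list[str]]:
    """Collapse near-identical sequences of the same taxon, keeping the longest.

    Same-taxon sequences with pairwise identity >= ``min_identity`` are
    grouped (transitively); the longest member of each group survives,
    ties broken by input order.
    """
    miss = aln.missing_char
    counts = aln.residue_counts()
    removed: set[int] = set()
    by_taxon: dict[str, list[int]] = {}
    for i, t in enumerate(aln.taxa):
        by_taxon.setdefault(t, []).append(i)
    for members in by_taxon.values():
        if len(members) < 2:
            continue
        # union-find over near-identical pairs
        parent = {i: i for i in members}

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                i, j = members[a], members[b]
                if _identity(aln.seqs[i], aln.seqs[j], miss) >= min_identity:
                    parent[find(i)] = find(j)
        groups: dict[int, list[int]] = {}
        for i in members:
            groups.setdefault(find(i), []).append(i)
        for grp in groups.values():
            if len(grp) > 1:
                keep = max(grp, key=lambda i: (counts[i], -i))
                removed.update(i for i in grp if i != keep)
    keep_rows = [i for i in range(aln.n_seqs) if i not in removed]
    return (
        aln.select_rows(keep_rows).drop_all_gap_columns(),
        [aln.ids[i] for i in sorted(removed)],
    )


def run_qc(
    aln: Alignment,
    min_span: float = 0.5,
    min_run: int = 10,
    k_sd: float = 3.0,
    min_identity: float = 0.99,
) -> tuple[Alignment, list[dict]]:
    """Apply the full curation cascade and return a per-action report.

    Order: private-insertion trimming, short-fragment removal, conspecific
    deduplication, then divergence flagging (flagged sequences are
    removed).  The report lists (sequence id, action, span) rows plus the
    thresholds in effect, since they stand in for manual curation.
    """
    report: list[dict] = []
    aln2, spans = trim_autapomorphic_runs(aln, min_run=min_run)
    for s in spans:
        report.append(
            {"seq_id": s.seq_id, "action": "trim_insertion", "span": f"{s.start}:{s.end}"}
        )
    aln3, removed = remove_short_fragments(aln2, min_span=min_span)
    for sid in removed:
        report.append({"seq_id": sid, "action": "remove_short_fragment", "span": ""})
    aln4, dropped = dedupe_conspecific(aln3, min_identity=min_identity)
    for sid in dropped:
        report.append({"seq_id": sid, "action": "remove_conspecific_duplicate", "span": ""})
    if aln4.n_seqs >= 4:
        flagged = flag_divergent_sequences(aln4, k_sd=k_sd)
        if flagged and aln4.n_seqs - len(flagged) >= 1:
            keep = [i for i in range(aln4.n_seqs) if aln4.ids[i] not in flagged]
            aln4 = aln4.select_rows(keep).drop_all_gap_columns()
            for sid in flagged:
                report.append({"seq_id": sid, "action": "remove_divergent", "span": ""})
    report.append(
        {
            "seq_id": "",
            "action": "thresholds",
            "span": f"min_span={min_span},min_run={min_run},k_sd={k_sd},min_identity={min_identity}",
        }
    )
    return aln4, report
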