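"""Conserved-residue census and per-column statistics on external MSAs.

The headline cross-species statistic — how many homologs retain all five
conserved residues of the active peptide domain (D, Y, N, H, P at fixed
spacing) — is computed per ungapped sequence with the relaxed 13-position
pattern, so it does not depend on reproducing any particular multiple
aligner's output.  MSA ingestion and per-column statistics are provided
separately for alignment-figure style reporting.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from Bio import AlignIO

from .motifs import relaxed_five_residue_pattern, scan
from .seqio import PrecursorRecord

# (0-based offset within the 13-residue window, residue, label)
FIVE_CONSTRAINTS: tuple[tuple[int, str], ...] = (
    (0, "D"),
    (1, "Y"),
    (7, "N"),
    (10, "H"),
    (12, "P"),
)


@dataclass(frozen=True)
class ConservationCensus:
    """Which records carry all five conserved domain residues."""

    per_record: tuple[tuple[str, bool], ...]
    failures: tuple[tuple[str, tuple[str, ...]], ...]  # (id, missing residues)

    @property
    def n_total(self) -> int:
        return len(self.per_record)

    @property
    def n_pass(self) -> int:
        return sum(ok for _, ok in self.per_record)


def _best_partial_window(sequence: str) -> tuple[str, ...]:
    """Missing residues of the window satisfying the most of the 5 constraints.

    Ties are broken leftmost, so failure attribution is deterministic and
    auditable.  A sequence shorter than 13 residues misses all five.
    """
    if len(sequence) < 13:
        return tuple(aa for _, aa in FIVE_CONSTRAINTS)
    best_missing: tuple[str, ...] | None = None
    best_count = -1
    for start in range(len(sequence) - 12):
        missing = tuple(
            aa for off, aa in FIVE_CONSTRAINTS if sequence[start + off] != aa
        )
        satisfied = 5 - len(missing)
        if satisfied > best_count:
            best_count = satisfied
            best_missing = missing
    assert best_missing is not None
    return best_missing


def five_residue_census(records: list[PrecursorRecord]) -> ConservationCensus:
    """Count records whose sequence matches the relaxed five-residue pattern.

    Record ids must be unique; the census is independent of record order.
    """
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate record ids: {dupes}")
    pattern = relaxed_five_residue_pattern()
    per_record = []
    failures = []
    for record in records:
        ok = bool(scan(record, pattern))
        per_record.append((record.id, ok))
        if not ok:
            failures.append((record.id, _best_partial_window(record.sequence)))
    return ConservationCensus(per_record=tuple(per_record), failures=tuple(failures))


@dataclass(frozen=True)
class Msa:
    """An externally built multiple sequence alignment."""

    records: tuple[tuple[str, str], ...]  # (id, gapped sequence)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("MSA must contain >= 1 sequence")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise ValueError("all gapped sequences must have equal length")

    @property
    def n_cols(self) -> int:
        return len(self.records[0][1])

    @property
    def n_records(self) -> int:
        return len(self.records)


def read_msa(path: str | Path, fmt: str = "fasta") -> Msa:
    """Read an aligned FASTA ("fasta") or Clustal ("clustal") file.

    ``.`` gap characters are normalized to ``-``; sequences are uppercased.
    """
    alignment = AlignIO.read(str(path), fmt)
    return Msa(
        records=tuple(
            (rec.id, str(rec.seq).upper().replace(".", "-")) for rec in alignment
        )
    )


@dataclass(frozen=True)
class ColumnStat:
    column: int  # 0-based
    fraction_identical: float  # majority residue count / n_records
    majority_residue: str | None  # None for an all-gap column
    gap_fraction: float


def column_stats(msa: Msa) -> list[ColumnStat]:
    """Per-column conservation: majority-residue fraction and gap fraction.

    Counts satisfy identical + non-identical + gaps = n_records per column.
    Majority ties break to the alphabetically smallest residue.
    """
    n = msa.n_records
    stats = []
    for col in range(msa.n_cols):
        residues = [seq[col] for _, seq in msa.records]
        gaps = residues.count("-")
        counts = Counter(r for r in residues if r != "-")
        if counts:
            # deterministic tie-break: highest count, then alphabetical
            best = max(counts.values())
            top = min(r for r, c in counts.items() if c == best)
            identical = counts[top]
        else:
            top, identical = None, 0
        stats.append(
            ColumnStat(
                column=col,
                fraction_identical=identical / n,
                majority_residue=top,
                gap_fraction=gaps / n,
            )
        )
    return stats
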