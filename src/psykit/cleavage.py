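"""Subtilase (SBT) recognition-motif annotation for peptide precursors.

Three subtilisin-like serine proteases implicated in the maturation of
tyrosine-sulfated plant peptides are screened for:

* **SBT1.1** — cleaves the phytosulfokine PSK4 precursor three residues
  upstream of the mature peptide, at RRSLVL/HTDY (the slash marks the
  scissile bond).
* **SBT6.1** — cleaves the RGF6 precursor at RRLR and RRAL, generalized
  here to the patterns RXLX and RXXL with X = any residue.
* **SBT3.8** — an aspartate-specific phytaspase that releases mature
  peptides N-terminally at their DY motif.  Reported DY hits are candidate
  sites, not asserted cleavages, and the cut is placed immediately before
  the D (provisional, since mature peptides retain the DY).

All hits, overlapping or not, are reported, ordered by (start, enzyme).
"""

from __future__ import annotations

from dataclasses import dataclass

from .motifs import MotifPattern, parse_pattern, scan
from .seqio import PrecursorRecord


@dataclass(frozen=True)
class EnzymeMotif:
    """A protease recognition pattern.

    ``cut_offset`` is the 0-based position within the match immediately
    after which the scissile bond lies; ``-1`` places the bond immediately
    before the match (SBT3.8 convention here); ``None`` means unknown.
    """

    enzyme: str
    pattern: MotifPattern
    cut_offset: int | None = None

    def __post_init__(self) -> None:
        if len(self.pattern) < 2:
            raise ValueError(f"{self.enzyme}: pattern must have length >= 2")


@dataclass(frozen=True)
class CleavageHit:
    enzyme: str
    start: int
    end: int
    matched: str
    cut_after: int | None  # 0-based residue index the bond follows, or None


@dataclass(frozen=True)
class CleavageReport:
    record_id: str
    hits: tuple[CleavageHit, ...]

    def enzymes_present(self) -> set[str]:
        return {h.enzyme for h in self.hits}


def builtin_enzyme_motifs() -> list[EnzymeMotif]:
    """The built-in SBT recognition motifs."""
    return [
        EnzymeMotif("SBT1.1", parse_pattern("RRSLVLHTDY", name="SBT1.1"), cut_offset=5),
        EnzymeMotif("SBT6.1", parse_pattern("RXLX", name="SBT6.1/RXLX"), cut_offset=None),
        EnzymeMotif("SBT6.1", parse_pattern("RXXL", name="SBT6.1/RXXL"), cut_offset=None),
        EnzymeMotif("SBT3.8", parse_pattern("DY", name="SBT3.8"), cut_offset=-1),
    ]


def _signal_span(record: PrecursorRecord) -> tuple[int, int] | None:
    """Parse an annotated signal-peptide span ("start-end", 1-based) if present."""
    raw = record.annotations.get("signal_peptide")
    if not raw:
        return None
    lo, hi = raw.split("-")
    return int(lo) - 1, int(hi)  # to 0-based half-open


def annotate(
    record: PrecursorRecord,
    enzymes: list[EnzymeMotif] | None = None,
    *,
    mask_signal: bool = False,
) -> CleavageReport:
    """Scan one precursor for all enzyme recognition motifs.

    With ``mask_signal`` and a ``signal_peptide`` annotation on the record,
    hits overlapping the signal peptide are dropped (sites inside the
    secretion leader are biologically implausible).
    """
    if enzymes is None:
        enzymes = builtin_enzyme_motifs()
    signal = _signal_span(record) if mask_signal else None
    hits: list[CleavageHit] = []
    for enzyme in enzymes:
        for match in scan(record, enzyme.pattern):
            if signal is not None and match.start < signal[1] and match.end > signal[0]:
                continue
            cut_after: int | None = None
            if enzyme.cut_offset is not None:
                cut_after = match.start + enzyme.cut_offset
            hits.append(
                CleavageHit(
                    enzyme=enzyme.enzyme,
                    start=match.start,
                    end=match.end,
                    matched=match.matched,
                    cut_after=cut_after,
                )
            )
    hits.sort(key=lambda h: (h.start, h.enzyme, h.end))
    return CleavageReport(record_id=record.id, hits=tuple(hits))


def table3_report(
    records: list[PrecursorRecord],
    enzymes: list[EnzymeMotif] | None = None,
    *,
    mask_signal: bool = False,
) -> dict[str, list[str]]:
    """Per-enzyme membership report: which records carry >= 1 recognition motif.

    Returns a mapping enzyme -> ordered list of record ids with at least one
    hit; every built-in enzyme appears as a key even when its list is empty.
    """
    if enzymes is None:
        enzymes = builtin_enzyme_motifs()
    report: dict[str, list[str]] = {e.enzyme: [] for e in enzymes}
    for record in records:
        present = annotate(record, enzymes, mask_signal=mask_signal).enzymes_present()
        for enzyme in report:
            if enzyme in present:
                report[enzyme].append(record.id)
    return report
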