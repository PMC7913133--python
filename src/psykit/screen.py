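"""Homolog screening criteria for putative PSY precursors.

A candidate passes when (i) its BLAST expect value, if a hit is supplied,
is at most ``evalue_max`` (default 20), (ii) its full length lies in the
inclusive 60-200 aa window, (iii) a DY-anchored motif match exists, and
(iv) at least one such match starts in the second half of the precursor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .motifs import MotifMatch, MotifPattern, scan
from .seqio import BlastHit, PrecursorRecord

logger = logging.getLogger(__name__)

# Failure codes, in report order.
EVALUE = "EVALUE"
LENGTH = "LENGTH"
NO_MOTIF = "NO_MOTIF"
MOTIF_FIRST_HALF = "MOTIF_FIRST_HALF"


@dataclass(frozen=True)
class ScreenCriteria:
    """Acceptance thresholds for the homolog screen (defaults as published)."""

    evalue_max: float = 20.0
    min_len: int = 60
    max_len: int = 200
    require_dy_start: bool = True
    require_second_half: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.min_len <= self.max_len):
            raise ValueError("need 0 < min_len <= max_len")
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be > 0")


@dataclass(frozen=True)
class ScreenVerdict:
    """Outcome of applying the criteria to one record."""

    record_id: str
    passed: bool
    reasons: tuple[str, ...]
    motif_used: MotifMatch | None = None

    def __post_init__(self) -> None:
        if self.passed != (len(self.reasons) == 0):
            raise ValueError("passed must be equivalent to empty reasons")
        if NO_MOTIF in self.reasons and MOTIF_FIRST_HALF in self.reasons:
            raise ValueError("NO_MOTIF and MOTIF_FIRST_HALF are mutually exclusive")


def second_half_start(length: int) -> int:
    """Smallest 0-based start counting as "second half" of a ``length``-aa protein.

    ceil(length/2), so for an odd-length precursor the motif must start
    strictly within the latter half.
    """
    return math.ceil(length / 2)


def apply_criteria(
    record: PrecursorRecord,
    hit: BlastHit | None,
    matches: list[MotifMatch],
    criteria: ScreenCriteria = ScreenCriteria(),
) -> ScreenVerdict:
    """Judge one record; returns a verdict, never raises on failing records.

    ``matches`` should come from scanning ``record`` with a DY-anchored
    pattern (strict or relaxed).  When ``require_dy_start`` is set, matches
    whose first two residues are not DY are discarded before judging, so the
    Asp-Tyr requirement holds even for user-supplied patterns.  With no
    BLAST hit the expect-value criterion is vacuously satisfied, letting the
    screen run on plain FASTA input.
    """
    reasons: list[str] = []
    if hit is not None and hit.evalue > criteria.evalue_max:
        reasons.append(EVALUE)
    if not (criteria.min_len <= len(record) <= criteria.max_len):
        reasons.append(LENGTH)
    usable = [m for m in matches if m.record_id == record.id]
    if criteria.require_dy_start:
        usable = [m for m in usable if m.matched[:2] == "DY"]
    motif_used: MotifMatch | None = None
    if not usable:
        reasons.append(NO_MOTIF)
    elif criteria.require_second_half:
        boundary = second_half_start(len(record))
        in_second = [m for m in usable if m.start >= boundary]
        if not in_second:
            reasons.append(MOTIF_FIRST_HALF)
        else:
            motif_used = in_second[0]
    else:
        motif_used = usable[0]
    passed = not reasons
    return ScreenVerdict(
        record_id=record.id,
        passed=passed,
        reasons=tuple(reasons),
        motif_used=motif_used if passed else None,
    )


def screen_collection(
    records: list[PrecursorRecord],
    hits: dict[str, BlastHit] | None,
    criteria: ScreenCriteria = ScreenCriteria(),
    pattern: MotifPattern | None = None,
) -> tuple[list[PrecursorRecord], list[ScreenVerdict]]:
    """Screen a record collection; returns (passing records, all verdicts).

    ``hits`` maps record id to its BLAST hit; ids without a hit are judged
    without the expect-value criterion.  ``pattern`` defaults to the strict
    PSY motif.
    """
    from .motifs import psy_strict_pattern

    if pattern is None:
        pattern = psy_strict_pattern()
    verdicts = []
    passing = []
    for record in records:
        hit = hits.get(record.id) if hits else None
        verdict = apply_criteria(record, hit, scan(record, pattern), criteria)
        verdicts.append(verdict)
        if verdict.passed:
            passing.append(record)
    logger.info(
        "screened %d records: %d passed, %d failed",
        len(records),
        len(passing),
        len(records) - len(passing),
    )
    return passing, verdicts
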