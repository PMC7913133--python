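"""PROSITE-style protein motif patterns and scanning.

Implements the pattern subset needed for PSY screening: literal residues,
``X`` (any residue) and bracketed residue classes like ``[AP]``.  Richer
ScanProsite grammar (repeat ranges ``x(2,4)``, exclusions ``{..}``, anchors
``<``/``>``) is deliberately rejected with an explicit error rather than
silently mis-matched.

Scanning is overlap-inclusive: every start position that matches is
reported.  An ``X`` in the *sequence* (unknown residue) matches only "any"
pattern positions, never a literal or a class, so unknown residues cannot
fabricate motif hits.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqio import STANDARD_AA, PrecursorRecord

#: Strict PSY motif: DY, four spacers, A or P, N, two spacers, H, spacer, P.
PSY_PATTERN_TEXT = "DYXXXX[AP]NXXHXP"

_UNSUPPORTED = set("{}()<>-.0123456789,")


class PatternError(ValueError):
    """Raised for malformed or unsupported pattern text."""


@dataclass(frozen=True)
class MotifPattern:
    """A parsed fixed-length motif.

    ``elements`` holds one entry per position: a frozenset of allowed
    residues, or ``None`` for an "any residue" position.
    """

    name: str
    elements: tuple[frozenset[str] | None, ...]

    def __post_init__(self) -> None:
        if len(self.elements) < 1:
            raise PatternError(f"pattern {self.name!r}: must have >= 1 position")
        for i, el in enumerate(self.elements):
            if el is not None and len(el) == 0:
                raise PatternError(f"pattern {self.name!r}: empty class at position {i}")

    def __len__(self) -> int:
        return len(self.elements)

    def matches_at(self, sequence: str, start: int) -> bool:
        """True iff the pattern matches ``sequence`` at offset ``start``."""
        if start < 0 or start + len(self) > len(sequence):
            return False
        for el, residue in zip(self.elements, sequence[start : start + len(self)]):
            if el is not None and residue not in el:
                return False
        return True

    def render(self) -> str:
        """Render back to pattern text; ``parse_pattern(render())`` is identity."""
        parts = []
        for el in self.elements:
            if el is None:
                parts.append("X")
            elif len(el) == 1:
                parts.append(next(iter(el)))
            else:
                parts.append("[" + "".join(sorted(el)) + "]")
        return "".join(parts)


@dataclass(frozen=True)
class MotifMatch:
    """One occurrence of a pattern in a record (0-based half-open span)."""

    record_id: str
    start: int
    end: int
    matched: str
    pattern_name: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.matched):
            raise ValueError("span length disagrees with matched substring")


def parse_pattern(text: str, *, name: str | None = None) -> MotifPattern:
    """Parse pattern text into a :class:`MotifPattern`.

    Supported constructs: uppercase/lowercase literal residues, ``X`` for
    any residue, and ``[..]`` residue classes.  Anything else raises
    :class:`PatternError` with the offending 0-based offset.
    """
    if not text:
        raise PatternError("empty pattern")
    elements: list[frozenset[str] | None] = []
    i = 0
    while i < len(text):
        ch = text[i].upper()
        if ch == "X":
            elements.append(None)
            i += 1
        elif ch in STANDARD_AA:
            elements.append(frozenset(ch))
            i += 1
        elif ch == "[":
            close = text.find("]", i + 1)
            if close == -1:
                raise PatternError(f"unbalanced '[' at offset {i}")
            body = text[i + 1 : close].upper()
            if not body:
                raise PatternError(f"empty class '[]' at offset {i}")
            bad = set(body) - STANDARD_AA
            if bad:
                raise PatternError(
                    f"illegal residue(s) {sorted(bad)} in class at offset {i}"
                )
            elements.append(frozenset(body))
            i = close + 1
        elif ch == "]":
            raise PatternError(f"unbalanced ']' at offset {i}")
        elif ch in _UNSUPPORTED:
            raise PatternError(
                f"unsupported construct {text[i]!r} at offset {i}: only literals, "
                "X and [..] classes are implemented"
            )
        else:
            raise PatternError(f"illegal character {text[i]!r} at offset {i}")
    return MotifPattern(name=name if name is not None else text, elements=tuple(elements))


def psy_strict_pattern() -> MotifPattern:
    """The 13-position PSY motif ``DYXXXX[AP]NXXHXP``."""
    return parse_pattern(PSY_PATTERN_TEXT, name="PSY")


def relaxed_five_residue_pattern() -> MotifPattern:
    """13-position pattern constraining only the five conserved residues.

    Positions (1-based) 1=D, 2=Y, 8=N, 11=H, 13=P; every other position is
    free.  This is the variant used for the cross-species conserved-residue
    census, where e.g. a non-[AP] residue at position 7 must not disqualify
    a homolog.
    """
    elements: list[frozenset[str] | None] = [None] * 13
    for pos, aa in ((0, "D"), (1, "Y"), (7, "N"), (10, "H"), (12, "P")):
        elements[pos] = frozenset(aa)
    return MotifPattern(name="PSY-relaxed", elements=tuple(elements))


def scan(record: PrecursorRecord, pattern: MotifPattern) -> list[MotifMatch]:
    """All (possibly overlapping) matches, in ascending start order.

    A pattern longer than the sequence yields an empty list.
    """
    seq = record.sequence
    L = len(pattern)
    out = []
    for start in range(0, len(seq) - L + 1):
        if pattern.matches_at(seq, start):
            out.append(
                MotifMatch(
                    record_id=record.id,
                    start=start,
                    end=start + L,
                    matched=seq[start : start + L],
                    pattern_name=pattern.name,
                )
            )
    return out


def sulfation_context(record: PrecursorRecord, tyr_index: int) -> bool:
    """Is the tyrosine at ``tyr_index`` in a favorable sulfation context?

    Tyrosylprotein sulfotransferase activity depends on an acidic residue
    (D or E) immediately N- or C-terminal of the target tyrosine; this
    checks positions −1 and +1.  Sequence boundaries count as absent
    neighbors, not as acidic.
    """
    seq = record.sequence
    if tyr_index < 0 or tyr_index >= len(seq) or seq[tyr_index] != "Y":
        raise ValueError(
            f"record {record.id!r}: position {tyr_index} is not a tyrosine"
        )
    acidic = {"D", "E"}
    if tyr_index > 0 and seq[tyr_index - 1] in acidic:
        return True
    if tyr_index + 1 < len(seq) and seq[tyr_index + 1] in acidic:
        return True
    return False
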