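"""Independent oracles used by the test suite.

These deliberately avoid the code paths they validate: alignment scores are
maximized by exhaustive enumeration of every gapped pairing, and motif
matching is re-done with a hand-built lookahead regex.
"""

from __future__ import annotations

import re
from collections.abc import Iterator

from psykit.align import AlignParams, load_matrix


def enumerate_alignments(a: str, b: str) -> Iterator[tuple[str, str]]:
    """Every global alignment of ``a`` and ``b`` (no gap-vs-gap columns)."""

    def rec(i: int, j: int, ca: list[str], cb: list[str]) -> Iterator[tuple[str, str]]:
        if i == len(a) and j == len(b):
            yield "".join(ca), "".join(cb)
            return
        if i < len(a) and j < len(b):
            ca.append(a[i])
            cb.append(b[j])
            yield from rec(i + 1, j + 1, ca, cb)
            ca.pop()
            cb.pop()
        if i < len(a):
            ca.append(a[i])
            cb.append("-")
            yield from rec(i + 1, j, ca, cb)
            ca.pop()
            cb.pop()
        if j < len(b):
            ca.append("-")
            cb.append(b[j])
            yield from rec(i, j + 1, ca, cb)
            ca.pop()
            cb.pop()

    yield from rec(0, 0, [], [])


def score_gapped_pair(aligned_a: str, aligned_b: str, params: AlignParams) -> float:
    """Affine-gap score of one complete alignment, written independently.

    Each gap run costs ``gap_open + gap_extend * run_length``; with free end
    gaps a run touching either end of the alignment costs nothing.
    """
    matrix = load_matrix(params.matrix_name)
    L = len(aligned_a)
    score = 0.0
    runs = []  # (start, end, length) of gap runs, per sequence side
    side = None
    for i in range(L):
        ca, cb = aligned_a[i], aligned_b[i]
        if ca == "-":
            if side == "a":
                runs[-1][1] = i
                runs[-1][2] += 1
            else:
                runs.append([i, i, 1])
            side = "a"
        elif cb == "-":
            if side == "b":
                runs[-1][1] = i
                runs[-1][2] += 1
            else:
                runs.append([i, i, 1])
            side = "b"
        else:
            side = None
            score += matrix[(ca, cb)]
    for start, end, length in runs:
        if not params.penalize_end_gaps and (start == 0 or end == L - 1):
            continue
        score -= params.gap_open + params.gap_extend * length
    return score


def brute_force_best_score(a: str, b: str, params: AlignParams) -> float:
    return max(
        score_gapped_pair(x, y, params) for x, y in enumerate_alignments(a, b)
    )


def regex_scan_starts(pattern_text_regex: str, sequence: str) -> list[int]:
    """Overlap-inclusive match starts using a lookahead regex."""
    return [m.start() for m in re.finditer(r"(?=" + pattern_text_regex + r")", sequence)]
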