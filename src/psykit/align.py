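"""Needleman-Wunsch global alignment with affine gaps, EMBOSS-needle style.

The published precursor/domain similarity table was produced with the EMBOSS
needle web service (BLOSUM62, gap open 10, gap extend 0.5), so this module
follows needle's conventions precisely:

* opening a gap costs ``gap_open + gap_extend`` for its first column and
  ``gap_extend`` for each further column;
* end gaps are unpenalized by default;
* percent identity counts identical residue pairs over *all* alignment
  columns (gap columns included in the denominator);
* percent similarity counts columns whose substitution score is positive,
  over the same denominator.

Traceback is deterministic: among co-optimal moves, diagonal is preferred
over up (gap in the second sequence) over left (gap in the first).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

from Bio.Align import substitution_matrices

from .motifs import MotifPattern, scan
from .screen import second_half_start
from .seqio import PrecursorRecord

NEG_INF = float("-inf")

_MATRIX_FILES = {"BLOSUM62": "BLOSUM62"}
_MATRIX_CACHE: dict[str, dict[tuple[str, str], float]] = {}


def available_matrices() -> list[str]:
    return sorted(_MATRIX_FILES)


def load_matrix(name: str) -> dict[tuple[str, str], float]:
    """Load a vendored substitution matrix as a residue-pair -> score dict."""
    if name not in _MATRIX_FILES:
        raise ValueError(
            f"unknown matrix {name!r}; available: {', '.join(available_matrices())}"
        )
    if name not in _MATRIX_CACHE:
        ref = resources.files("psykit.data") / _MATRIX_FILES[name]
        with resources.as_file(ref) as path:
            arr = substitution_matrices.read(str(path))
        table: dict[tuple[str, str], float] = {}
        for a in arr.alphabet:
            for b in arr.alphabet:
                table[(a, b)] = float(arr[a, b])
        _MATRIX_CACHE[name] = table
    return _MATRIX_CACHE[name]


@dataclass(frozen=True)
class AlignParams:
    """Alignment parameters (defaults are the published EMBOSS settings)."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    penalize_end_gaps: bool = False

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValueError("need gap_open >= gap_extend >= 0")


@dataclass(frozen=True)
class AlignmentResult:
    """A pairwise global alignment and its EMBOSS-style summary statistics."""

    aligned_a: str
    aligned_b: str
    score: float
    length: int
    identity_pct: float
    similarity_pct: float
    gaps_pct: float


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention used for reports)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def score_alignment(
    aligned_a: str, aligned_b: str, params: AlignParams = AlignParams()
) -> float:
    """Score a complete gapped alignment under the affine-gap model.

    Independent of the DP: walks the columns, charging ``gap_open +
    gap_extend`` for the first column of each gap run and ``gap_extend``
    thereafter, with the leading and trailing run free unless
    ``penalize_end_gaps``.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned strings must have equal length")
    matrix = load_matrix(params.matrix_name)
    L = len(aligned_a)
    score = 0.0
    # gap runs as (start_col, end_col_inclusive, total_cost); a run is a
    # maximal stretch of gap columns in the same sequence
    runs: list[list[float]] = []
    gap_state = 0  # 0 none, 1 gap in a, 2 gap in b
    for i in range(L):
        ca, cb = aligned_a[i], aligned_b[i]
        if ca == "-" and cb == "-":
            raise ValueError("gap-vs-gap column")
        if ca == "-" or cb == "-":
            state = 1 if ca == "-" else 2
            if state == gap_state:
                runs[-1][1] = i
                runs[-1][2] += params.gap_extend
            else:
                runs.append([i, i, params.gap_open + params.gap_extend])
            gap_state = state
        else:
            gap_state = 0
            score += matrix[(ca, cb)]
    for start, end, cost in runs:
        if not params.penalize_end_gaps and (start == 0 or end == L - 1):
            continue  # leading/trailing run is free
        score -= cost
    return score


def _summarize(aligned_a: str, aligned_b: str, score: float, params: AlignParams) -> AlignmentResult:
    matrix = load_matrix(params.matrix_name)
    L = len(aligned_a)
    ident = simil = gaps = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if ca == "-" or cb == "-":
            gaps += 1
            continue
        if ca == cb:
            ident += 1
        if matrix[(ca, cb)] > 0:
            simil += 1
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=score,
        length=L,
        identity_pct=100.0 * ident / L,
        similarity_pct=100.0 * simil / L,
        gaps_pct=100.0 * gaps / L,
    )


def nw_align(a: str, b: str, params: AlignParams = AlignParams()) -> AlignmentResult:
    """Optimal global alignment of two sequences (three-state affine DP).

    The DP always runs on the lexicographically ordered pair and swaps the
    result back, so co-optimal tie-breaking cannot make the reported
    percentages depend on argument order: every statistic is exactly
    symmetric in (a, b).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if a > b:
        res = nw_align(b, a, params)
        return AlignmentResult(
            aligned_a=res.aligned_b,
            aligned_b=res.aligned_a,
            score=res.score,
            length=res.length,
            identity_pct=res.identity_pct,
            similarity_pct=res.similarity_pct,
            gaps_pct=res.gaps_pct,
        )
    matrix = load_matrix(params.matrix_name)
    n, m = len(a), len(b)
    go = params.gap_open + params.gap_extend  # first gap column
    ge = params.gap_extend
    penalize = params.penalize_end_gaps

    # M: a[i-1] aligned to b[j-1]; X: a[i-1] vs gap (up); Y: gap vs b[j-1] (left)
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Mp = [[""] * (m + 1) for _ in range(n + 1)]
    Xp = [[""] * (m + 1) for _ in range(n + 1)]
    Yp = [[""] * (m + 1) for _ in range(n + 1)]

    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = 0.0 if not penalize else -(go + (i - 1) * ge)
        Xp[i][0] = "M" if i == 1 else "X"
    for j in range(1, m + 1):
        Y[0][j] = 0.0 if not penalize else -(go + (j - 1) * ge)
        Yp[0][j] = "M" if j == 1 else "Y"

    for i in range(1, n + 1):
        ai = a[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mu, Xu, Yu = M[i - 1], X[i - 1], Y[i - 1]
        Mpi, Xpi, Ypi = Mp[i], Xp[i], Yp[i]
        for j in range(1, m + 1):
            s = matrix[(ai, b[j - 1])]
            # diagonal: predecessor preference M > X > Y
            dm, dx, dy = Mu[j - 1], Xu[j - 1], Yu[j - 1]
            if dm >= dx and dm >= dy:
                Mi[j], Mpi[j] = dm + s, "M"
            elif dx >= dy:
                Mi[j], Mpi[j] = dx + s, "X"
            else:
                Mi[j], Mpi[j] = dy + s, "Y"
            # up (gap in b, consume a)
            um, ux, uy = Mu[j] - go, Xu[j] - ge, Yu[j] - go
            if um >= ux and um >= uy:
                Xi[j], Xpi[j] = um, "M"
            elif ux >= uy:
                Xi[j], Xpi[j] = ux, "X"
            else:
                Xi[j], Xpi[j] = uy, "Y"
            # left (gap in a, consume b)
            lm, lx, ly = Mi[j - 1] - go, Xi[j - 1] - go, Yi[j - 1] - ge
            if lm >= lx and lm >= ly:
                Yi[j], Ypi[j] = lm, "M"
            elif lx >= ly:
                Yi[j], Ypi[j] = lx, "X"
            else:
                Yi[j], Ypi[j] = ly, "Y"

    def best_state(i: int, j: int) -> tuple[float, str]:
        vm, vx, vy = M[i][j], X[i][j], Y[i][j]
        if vm >= vx and vm >= vy:
            return vm, "M"
        if vx >= vy:
            return vx, "X"
        return vy, "Y"

    if penalize:
        score, state = best_state(n, m)
        end_i, end_j = n, m
        tail_a, tail_b = "", ""
    else:
        # free trailing gaps: end anywhere on the last row/column and pad.
        # Preference: no trailing gap, then shortest trailing gap in b
        # ("up" before "left", matching the move preference).
        candidates: list[tuple[float, int, int, str, str, str]] = []
        s0, st0 = best_state(n, m)
        candidates.append((s0, n, m, st0, "", ""))
        for i in range(n - 1, -1, -1):
            s, st = best_state(i, m)
            candidates.append((s, i, m, st, a[i:], "-" * (n - i)))
        for j in range(m - 1, -1, -1):
            s, st = best_state(n, j)
            candidates.append((s, n, j, st, "-" * (m - j), b[j:]))
        best = max(c[0] for c in candidates)
        score = best
        for c in candidates:
            if c[0] == best:
                _, end_i, end_j, state, ta, tb = c
                tail_a, tail_b = ta, tb
                break

    # traceback
    cols_a: list[str] = []
    cols_b: list[str] = []
    i, j = end_i, end_j
    while i > 0 or j > 0:
        if state == "M":
            prev = Mp[i][j]
            cols_a.append(a[i - 1])
            cols_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif state == "X":
            prev = Xp[i][j]
            cols_a.append(a[i - 1])
            cols_b.append("-")
            i -= 1
        else:
            prev = Yp[i][j]
            cols_a.append("-")
            cols_b.append(b[j - 1])
            j -= 1
        state = prev
    aligned_a = "".join(reversed(cols_a)) + (tail_a if not penalize else "")
    aligned_b = "".join(reversed(cols_b)) + (tail_b if not penalize else "")
    return _summarize(aligned_a, aligned_b, score, params)


def extract_domain(
    record: PrecursorRecord,
    strict_pattern: MotifPattern,
    relaxed_pattern: MotifPattern | None = None,
) -> str | None:
    """Extract the 13-residue conserved peptide domain from a precursor.

    Preference order: leftmost second-half strict match, leftmost strict
    match anywhere, then the same two steps with the relaxed pattern.
    Returns ``None`` when nothing matches.
    """
    boundary = second_half_start(len(record))
    for pattern in (strict_pattern, relaxed_pattern):
        if pattern is None:
            continue
        matches = scan(record, pattern)
        if matches:
            second = [m for m in matches if m.start >= boundary]
            chosen = second[0] if second else matches[0]
            return chosen.matched
    return None


@dataclass(frozen=True)
class SimilarityTable:
    """Per-homolog percent similarity to a reference precursor and its domain."""

    reference_id: str
    rows: tuple[tuple[str, float, float | None], ...]


def similarity_table(
    reference: PrecursorRecord,
    others: list[PrecursorRecord],
    params: AlignParams = AlignParams(),
    *,
    strict_pattern: MotifPattern | None = None,
    relaxed_pattern: MotifPattern | None = None,
) -> SimilarityTable:
    """Similarity of each record (full precursor and extracted domain) to a reference.

    Percentages are rounded half-up to one decimal for reporting; a record
    with no extractable domain gets ``None`` in the domain column.
    """
    from .motifs import psy_strict_pattern, relaxed_five_residue_pattern

    if strict_pattern is None:
        strict_pattern = psy_strict_pattern()
    if relaxed_pattern is None:
        relaxed_pattern = relaxed_five_residue_pattern()
    ref_domain = extract_domain(reference, strict_pattern, relaxed_pattern)
    if ref_domain is None:
        raise ValueError(f"reference {reference.id!r} has no extractable domain")
    rows = []
    for other in others:
        prec = nw_align(reference.sequence, other.sequence, params)
        domain = extract_domain(other, strict_pattern, relaxed_pattern)
        dom_pct: float | None = None
        if domain is not None:
            dom_pct = round_half_up(nw_align(ref_domain, domain, params).similarity_pct)
        rows.append((other.id, round_half_up(prec.similarity_pct), dom_pct))
    return SimilarityTable(reference_id=reference.id, rows=tuple(rows))
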