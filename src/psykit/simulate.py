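"""Synthetic prepropeptides and Ct tables with known ground truth.

Every downstream stage (motif scan, homolog screen, domain similarity,
cleavage annotation, ddCt analysis) can be exercised offline against these
generators, whose truth tables are produced independently of the code under
test: motif placement is verified with a compiled regular expression, and
cleavage fixtures restrict the background alphabet so planted protease
motifs are the only ones present.

Generated precursors mimic the published screening conditions: 60-200 aa
total, a 25-residue hydrophobicity-biased N-terminal leader standing in for
the secretion signal (signal-peptide prediction proper is external), and a
PSY-style motif instantiated in the configured half of the sequence.  Ct
tables default to the published design of 3 biological x 2 technical
replicates normalized to actin-2.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ddct import CtTable
from .motifs import MotifPattern, psy_strict_pattern
from .screen import LENGTH, MOTIF_FIRST_HALF, NO_MOTIF, second_half_start
from .seqio import PrecursorRecord

AMINO_ACIDS = tuple(sorted("ACDEFGHIKLMNPQRSTVWY"))
HYDROPHOBIC = tuple(sorted("AFILMVW"))

#: Background alphabet for cleavage fixtures: no R, D or L, so the planted
#: protease motifs are provably the only ones present.
_CLEAVAGE_BACKGROUND = tuple(sorted(set("ACEFGHIKMNPQSTVWY") - set("RDL")))


def pattern_to_regex(pattern: MotifPattern) -> re.Pattern[str]:
    """Compile a motif pattern to an overlap-reporting lookahead regex."""
    parts = []
    for el in pattern.elements:
        if el is None:
            parts.append("[A-Z]")
        elif len(el) == 1:
            parts.append(next(iter(el)))
        else:
            parts.append("[" + "".join(sorted(el)) + "]")
    return re.compile(r"(?=(" + "".join(parts) + r"))")


def regex_match_starts(pattern: MotifPattern, sequence: str) -> list[int]:
    """All (overlapping) match start offsets, via the regex oracle."""
    return [m.start() for m in pattern_to_regex(pattern).finditer(sequence)]


@dataclass(frozen=True)
class PrecursorSimConfig:
    """Conditions for the precursor generator.

    ``motif_half`` places the instantiated motif in the second half
    (screen-passing), the first half (failing the positional criterion), or
    nowhere.  ``substitutions`` > 0 knocks out that many constrained motif
    positions after embedding, producing near-miss candidates that carry no
    motif match at all.
    """

    seed: int
    n: int
    length_range: tuple[int, int] = (60, 200)
    leader_length: int = 25
    motif: MotifPattern = field(default_factory=psy_strict_pattern)
    motif_half: str = "second"  # "first" | "second" | "none"
    substitutions: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (30 <= lo <= hi <= 500):
            raise ValueError("length_range must lie within [30, 500]")
        if self.leader_length >= lo:
            raise ValueError("leader_length must be shorter than the minimum length")
        if self.motif_half not in ("first", "second", "none"):
            raise ValueError("motif_half must be 'first', 'second' or 'none'")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def _instantiate_motif(pattern: MotifPattern, rng: np.random.Generator) -> str:
    out = []
    for el in pattern.elements:
        if el is None:
            out.append(AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))])
        else:
            choices = sorted(el)
            out.append(choices[rng.integers(len(choices))])
    return "".join(out)


def _constrained_offsets(pattern: MotifPattern) -> list[int]:
    return [i for i, el in enumerate(pattern.elements) if el is not None]


def _knockout(instance: str, pattern: MotifPattern, k: int, rng: np.random.Generator) -> str:
    """Violate ``k`` constrained positions of an embedded motif instance."""
    offsets = _constrained_offsets(pattern)
    chosen = list(rng.permutation(len(offsets))[:k])
    chars = list(instance)
    for idx in chosen:
        off = offsets[idx]
        allowed = pattern.elements[off]
        assert allowed is not None
        forbidden = sorted(set(AMINO_ACIDS) - set(allowed))
        chars[off] = forbidden[rng.integers(len(forbidden))]
    return "".join(chars)


def _random_background(length: int, leader: int, rng: np.random.Generator) -> str:
    chars = []
    for i in range(length):
        if i < leader and rng.random() < 0.85:
            chars.append(HYDROPHOBIC[rng.integers(len(HYDROPHOBIC))])
        else:
            chars.append(AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))])
    return "".join(chars)


def gen_precursors(
    config: PrecursorSimConfig,
) -> tuple[list[PrecursorRecord], pd.DataFrame]:
    """Generate precursor records plus an independent ground-truth table.

    The truth table columns are ``id``, ``length``, ``motif_start`` (0-based,
    -1 when no intact motif was planted), ``motif_half``, ``expected_pass``
    and ``expected_reasons`` (screen outcome assuming no BLAST hit is
    supplied).  Each candidate is re-checked with a regex oracle and
    resampled until its match structure is exactly as intended, so the truth
    table does not depend on the package's own scanner.
    """
    rng = np.random.default_rng(config.seed)
    pattern = config.motif
    records = []
    rows = []
    for i in range(config.n):
        rec_id = f"SIM{i:04d}"
        for _ in range(1000):
            lo, hi = config.length_range
            L = int(rng.integers(lo, hi + 1))
            boundary = second_half_start(L)
            seq = _random_background(L, config.leader_length, rng)
            motif_start = -1
            if config.motif_half != "none":
                if config.motif_half == "second":
                    start_lo, start_hi = boundary, L - len(pattern)
                else:
                    start_lo = config.leader_length
                    start_hi = min(boundary - 1, L - len(pattern))
                if start_hi < start_lo:
                    continue  # geometry impossible for this length; redraw
                motif_start = int(rng.integers(start_lo, start_hi + 1))
                instance = _instantiate_motif(pattern, rng)
                if config.substitutions > 0:
                    instance = _knockout(instance, pattern, config.substitutions, rng)
                seq = (
                    seq[:motif_start]
                    + instance
                    + seq[motif_start + len(pattern) :]
                )
            # independent verification of the intended match structure
            starts = regex_match_starts(pattern, seq)
            if config.motif_half == "none" or config.substitutions > 0:
                if starts:
                    continue
                motif_start = -1
                expected_reasons: tuple[str, ...] = (NO_MOTIF,)
            elif config.motif_half == "second":
                if not starts or any(s < boundary for s in starts):
                    continue
                expected_reasons = ()
            else:  # first
                if not starts or any(s >= boundary for s in starts):
                    continue
                expected_reasons = (MOTIF_FIRST_HALF,)
            break
        else:
            raise RuntimeError("could not generate a conforming precursor")
        records.append(PrecursorRecord(id=rec_id, sequence=seq))
        rows.append(
            {
                "id": rec_id,
                "length": L,
                "motif_start": motif_start,
                "motif_half": config.motif_half,
                "expected_pass": not expected_reasons,
                "expected_reasons": ";".join(expected_reasons),
            }
        )
    return records, pd.DataFrame(rows)


_PLANTABLE = {
    "RRLR": {"SBT6.1"},
    "RRAL": {"SBT6.1"},
    "DY": {"SBT3.8"},
    "RRSLVLHTDY": {"SBT1.1", "SBT6.1", "SBT3.8"},
}


def gen_cleavage_fixture(
    seed: int, n: int, length: int = 120
) -> tuple[list[PrecursorRecord], pd.DataFrame]:
    """Sequences with planted protease motifs and exact membership truth.

    The background alphabet contains no R, D or L, so the only subtilase
    recognition motifs in each sequence are the planted ones (RRSLVLHTDY
    internally also carries SBT6.1- and SBT3.8-matching submotifs, which the
    truth accounts for).  Columns: id, plus one boolean per enzyme.
    """
    rng = np.random.default_rng(seed)
    motif_names = list(_PLANTABLE)
    records = []
    rows = []
    for i in range(n):
        rec_id = f"CLV{i:04d}"
        seq = "".join(
            _CLEAVAGE_BACKGROUND[rng.integers(len(_CLEAVAGE_BACKGROUND))]
            for _ in range(length)
        )
        k = int(rng.integers(0, 3))  # plant 0-2 motifs
        planted = [motif_names[j] for j in rng.permutation(len(motif_names))[:k]]
        present: set[str] = set()
        cursor = 10
        for motif in planted:
            gap = int(rng.integers(4, 15))
            start = cursor + gap
            if start + len(motif) > length - 5:
                break
            seq = seq[:start] + motif + seq[start + len(motif) :]
            cursor = start + len(motif)
            present |= _PLANTABLE[motif]
        records.append(PrecursorRecord(id=rec_id, sequence=seq))
        rows.append(
            {
                "id": rec_id,
                "SBT1.1": "SBT1.1" in present,
                "SBT6.1": "SBT6.1" in present,
                "SBT3.8": "SBT3.8" in present,
            }
        )
    return records, pd.DataFrame(rows)


def mutate_motif(
    record: PrecursorRecord,
    k: int,
    rng: np.random.Generator,
    span: tuple[int, int] | None = None,
) -> tuple[PrecursorRecord, list[int]]:
    """Substitute ``k`` residues inside the motif span of ``record``.

    Positions are the first ``k`` entries of a random permutation of the
    span, so for a generator seeded identically, increasing ``k`` yields
    nested mutation sets (useful for monotonicity properties).  Each chosen
    residue is replaced by its worst-scoring BLOSUM62 partner (ties broken
    alphabetically), which is always non-positive.
    """
    from .align import load_matrix
    from .motifs import relaxed_five_residue_pattern, scan

    if span is None:
        pattern = psy_strict_pattern()
        matches = scan(record, pattern) or scan(record, relaxed_five_residue_pattern())
        if not matches:
            raise ValueError(f"record {record.id!r} contains no motif instance")
        span = (matches[0].start, matches[0].end)
    start, end = span
    if not (0 <= start < end <= len(record.sequence)):
        raise ValueError("span out of bounds")
    if k > end - start:
        raise ValueError("k exceeds span length")
    matrix = load_matrix("BLOSUM62")
    order = [start + int(p) for p in rng.permutation(end - start)]
    positions = order[:k]
    chars = list(record.sequence)
    for pos in positions:
        orig = chars[pos]
        worst = min(
            (aa for aa in AMINO_ACIDS if aa != orig),
            key=lambda aa: (matrix[(orig, aa)], aa),
        )
        chars[pos] = worst
    mutated = PrecursorRecord(
        id=record.id,
        sequence="".join(chars),
        accession=record.accession,
        species=record.species,
        annotations=dict(record.annotations),
    )
    return mutated, positions


@dataclass(frozen=True)
class CtSimConfig:
    """Conditions for the Ct-table generator.

    ``genes`` maps each target gene to its true expression ratio
    (treatment relative to control); the reference gene is fixed at 1.0.
    Defaults mirror the published design: 3 biological x 2 technical
    replicates, actin-2 reference.
    """

    seed: int
    genes: dict[str, float] = field(default_factory=lambda: {"PSY4": 4.0})
    n_bio: int = 3
    n_tech: int = 2
    ct_base: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.2
    efficiency: float = 2.0
    reference_gene: str = "actin-2"
    control_group: str = "control"
    treatment_group: str = "treatment"

    def __post_init__(self) -> None:
        if self.n_bio < 2:
            raise ValueError("n_bio must be >= 2")
        if self.n_tech < 1:
            raise ValueError("n_tech must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.efficiency <= 1:
            raise ValueError("efficiency must exceed 1")


def gen_ct_table(config: CtSimConfig) -> tuple[CtTable, dict[str, float]]:
    """Generate a replicate-structured Ct table with known true ratios.

    Ct = ct_base - log_efficiency(true relative expression) + N(0, noise_sd)
    per technical replicate; the expression ratio applies to every
    biological replicate of the treatment group.  Returns the table and the
    gene -> true ratio map (reference gene included at 1.0).
    """
    rng = np.random.default_rng(config.seed)
    log_eff = np.log(config.efficiency)
    all_genes = dict(config.genes)
    all_genes[config.reference_gene] = 1.0
    rows = []
    for gene, ratio in all_genes.items():
        base = config.ct_base.get(
            gene, 20.0 if gene == config.reference_gene else 26.0
        )
        for group in (config.control_group, config.treatment_group):
            rel = ratio if group == config.treatment_group else 1.0
            shift = np.log(rel) / log_eff
            for bio in range(1, config.n_bio + 1):
                for tech in range(1, config.n_tech + 1):
                    ct = base - shift + rng.normal(0.0, config.noise_sd)
                    rows.append(
                        {
                            "gene": gene,
                            "group": group,
                            "bio_rep": bio,
                            "tech_rep": tech,
                            "ct": float(ct),
                        }
                    )
    table = CtTable(
        data=pd.DataFrame(rows),
        reference_gene=config.reference_gene,
        control_group=config.control_group,
    )
    return table, all_genes
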