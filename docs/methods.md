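# Methods

## Motif model

The conserved PSY peptide domain is modeled as a fixed-length, 13-position
pattern `DYXXXX[AP]NXXHXP` over the 20 standard residues.  The pattern
grammar implemented is the subset actually needed — literal residues, `X`
(any residue) and `[..]` residue classes; repeat ranges, exclusion classes
and anchors from the richer PROSITE grammar are rejected with an explicit
error rather than silently approximated.  Scanning is overlap-inclusive
(every matching start position is reported), because candidate screening
must see every possible motif placement.  An `X` in a *sequence* (unknown
residue) matches only any-residue pattern positions: an unknown residue is
never allowed to satisfy a literal or class constraint, so unknown content
cannot fabricate hits.

The relaxed five-residue variant keeps only the universally conserved
positions (D1, Y2, N8, H11, P13) and is used for the cross-species census,
where homologs may deviate at the `[AP]` position.  Every strict match is by
construction a relaxed match.

## Homolog screen

A candidate passes when all of the following hold:

| criterion | default | note |
|---|---|---|
| BLAST expect value | ≤ 20 | vacuously satisfied when no hit is supplied |
| precursor length | 60–200 aa inclusive | both bounds inclusive ("between … and") |
| motif present | DY-anchored match | non-DY matches of user patterns are discarded |
| motif position | start ≥ ⌈L/2⌉ (0-based) | "second half" for odd lengths via ceiling |

The ceiling convention means a motif straddling the midpoint of an
odd-length precursor must start strictly in the latter half.  Verdicts carry
machine-readable failure codes (EVALUE, LENGTH, NO_MOTIF, MOTIF_FIRST_HALF);
NO_MOTIF and MOTIF_FIRST_HALF are mutually exclusive by construction.

## Alignment

Global alignment uses a three-state affine-gap dynamic program
(match / gap-in-first / gap-in-second) under the EMBOSS needle conventions,
since the published similarity figures came from that tool:

- gap of length k costs `gap_open + k·gap_extend` (first gap column pays
  `gap_open + gap_extend`); defaults 10 and 0.5 with BLOSUM62;
- end gaps are free by default (`penalize_end_gaps` exposes the
  alternative);
- identity % and similarity % both use total alignment columns as the
  denominator; a column is "similar" when its substitution score is > 0.

Determinism: co-optimal traceback ties resolve diagonal > up > left, and the
DP always runs on the lexicographically ordered sequence pair (the output is
swapped back), which makes the score *and* all reported percentages exactly
symmetric in the two arguments — otherwise co-optimal alignments chosen for
(a,b) and (b,a) can differ in their column statistics even at equal score.
Reported percentages are rounded half-up to one decimal.

The BLOSUM62 table is vendored as a static file and verified
entry-for-entry against Biopython's copy in the test suite, because matrix
dialects differ subtly across toolkits.  The DP is validated two ways:
exhaustive enumeration of every global alignment for short sequences, and
score agreement with an independently configured Biopython
`PairwiseAligner` on longer ones.

The domain column of the similarity table is computed on the 13-residue
motif span (leftmost second-half strict match, falling back to a strict
match anywhere, then relaxed).  On a 13-column gapless alignment,
similarity percentages are multiples of 1/13 (84.6% = 11/13, 92.3% = 12/13),
which is why the domain-level regression checks use those values; published
domain figures that are not multiples of 1/13 presumably used different
boundaries and are not asserted exactly.

## Cleavage annotation

Recognition motifs: SBT1.1 as the literal 10-mer RRSLVLHTDY with the
scissile bond after its sixth residue; SBT6.1 as the generalized 4-mers RXLX
and RXXL with X unrestricted (the maximal-recall reading of the two known
sites RRLR and RRAL); SBT3.8 as the DY dipeptide.  DY hits are candidate
sites, not asserted cleavages, and the SBT3.8 cut position is reported as
immediately before the D — provisional, since aspartate-specific phytaspases
cleave after Asp yet mature peptides begin with DY.  `EnzymeMotif.cut_offset`
is therefore allowed to be −1 (bond precedes the match) in addition to
within-match offsets.  No positional restriction (e.g. upstream of the
domain) is applied; hits overlapping an annotated signal peptide can be
masked with a flag.

## Conservation census

The "how many homologs keep all five conserved residues" statistic is
computed per ungapped sequence with the relaxed pattern, deliberately *not*
from MSA columns, so it does not depend on reproducing a particular multiple
aligner's output.  Failure attribution picks the 13-residue window
satisfying the most constraints (ties leftmost) and lists the missing
residues.  MSA ingest (aligned FASTA / Clustal, `.` normalized to `-`) and
per-column majority/gap statistics are provided separately for
alignment-figure style reporting.  Sequences with internal repeats are
counted once, per sequence.

## ΔΔCt analysis

Technical replicates are arithmetic means; biological replicates are the
units of analysis throughout (averaging first avoids pseudo-replication in
the stated 3×2 design).  ΔCt = Ct(target) − Ct(reference) per biological
replicate; ΔΔCt = mean ΔCt(treatment) − mean ΔCt(control); ratio =
efficiency^(−ΔΔCt) with efficiency defaulting to 2.0 (perfect doubling) and
configurable per call.  Normalization uses a single reference gene
(multi-reference geometric means are out of scope).

Inference: a fixed-reallocation randomization test permutes group labels of
whole biological replicates (jointly for target and reference), two-sided on
|ΔΔCt|, with the add-one Monte-Carlo correction
p = (1 + #{|ΔΔCt*| ≥ |ΔΔCt_obs|}) / (1 + B); deterministic given a seed.
A percentile bootstrap (resampling biological replicates within groups)
gives an interval for the ratio.

A 3-vs-3 design admits only 20 distinct label reallocations, so the smallest
attainable two-sided p-value is 0.1; the test's type-I error and the
bootstrap's coverage are therefore *validated* on simulated experiments with
10 biological replicates per group, where the permutation distribution has
enough resolution for a 5% level.  That choice concerns the validation
experiments only; the generator's default design stays 3×2.

## Synthetic data

The precursor generator emulates the screened architecture: total length
uniform in 60–200 aa, a 25-residue N-terminal leader biased (85%) toward
hydrophobic residues as a stand-in for the secretion signal, and a motif
instance (concrete residues sampled for X positions) embedded in the first
half, second half, or nowhere.  A substitution burden knocks out constrained
motif positions to create near-miss candidates.  Every record's intended
match structure is re-verified with an independent compiled regex and
resampled on violation, so truth tables never depend on the scanner under
test.  Cleavage fixtures draw their background from an alphabet without R,
D or L, making planted protease motifs provably the only ones present.

Ct tables follow `Ct = ct_base − log_eff(relative expression) + N(0, σ)` per
technical replicate with σ = 0.2 cycles by default; the expression ratio
applies to all biological replicates of the treatment group and the
reference gene is fixed at ratio 1.

What the generators do *not* emulate: real signal-peptide composition (no
predictor is involved), BLAST E-value/similarity coupling, evolutionary
divergence structure among homologs, inter-biological-replicate expression
variance beyond the technical noise term, and amplification-efficiency
drift.  Passing tests therefore demonstrate correctness of the computations
under the stated model, not performance on arbitrary real data.

## Real-sequence regressions

The published similarity percentages, protease-motif membership and the
31-of-32 census concern the 32 UniProt homolog sequences.  The package ships
only the accession manifest (names and IDs); sequences are fetched once with
`psykit fetch` and cached with fetch date and per-sequence SHA-256 checksums
(UniProt entries are versioned, so the cache metadata records provenance).
The corresponding regression tests run whenever the cache is populated and
skip otherwise; everything else in the test suite and the acceptance script
is fully offline.

## Problem sizes and numerical choices

The acceptance script uses: 500 random pairs (length ≤ 6) for the
alignment-vs-enumeration check; 500 random 200-aa sequences (half with 1–3
planted motifs) for the scanner-vs-regex check; 100 precursors
(40 pass / 30 first-half / 30 motif-free) for screen accuracy; 60 cleavage
fixtures; a 32-record census with one planted missing-P homolog; 200
simulated experiments for ratio recovery (true ratio 4.0, 3×2 design); and
500 null experiments (10 biological replicates, 500 permutations each) for
the type-I error.  All randomness derives from the `--seed` argument through
`numpy.random.SeedSequence`.

Floating-point score comparisons use an absolute tolerance of 1e-9;
permutation counting uses a 1e-12 slack on the ≥ comparison so that
regenerating the observed statistic under permutation counts as an
exceedance.  Degenerate inputs are defined rather than accidental: patterns
longer than the sequence scan to an empty match list, single-sequence MSAs
give fraction-identical 1.0, an all-identical Ct table gives p = 1.0, and
empty record collections produce empty reports.
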