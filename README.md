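# psykit

Offline analysis toolkit for the **PSY peptide family** — the small secreted
plant signaling peptides carrying a sulfated tyrosine (PSY1–8 in
*Arabidopsis thaliana*, with homologs across higher plants and the moss
*Physcomitrella patens*).  It is written for researchers who want to screen
candidate precursor sequences, compare them to known homologs, and quantify
their expression, without depending on web services.

## What it computes

**Motif scanning and homolog screening.**  PSY precursors are 60–200 aa
prepropeptides whose active peptide carries a conserved 13-residue domain
matching the PROSITE-style pattern

```
DYXXXX[AP]NXXHXP
```

(`X` = any residue, `[AP]` = A or P).  A candidate passes the homolog screen
when its BLAST expect value (if a hit table is supplied) is ≤ 20, its full
length is 60–200 aa, and a DY-anchored motif match starts in the second half
of the precursor.  A relaxed variant of the pattern, constraining only the
five conserved residues (D, Y, N, H, P at the same spacing), supports the
cross-species conserved-residue census.  A helper classifies the tyrosine
sulfation context (acidic residue at −1 or +1 of the Y, as required by
tyrosylprotein sulfotransferase).

**Pairwise similarity (Needleman–Wunsch).**  Global alignment with affine
gaps under BLOSUM62, gap open 10, gap extend 0.5, free end gaps — the EMBOSS
needle conventions, including its percentage definitions:

- identity % = identical columns / alignment length,
- similarity % = columns with positive substitution score / alignment length,

with gap columns in the denominator.  `similarity_table` reproduces the
precursor-vs-domain similarity report for a homolog collection.

**Subtilase cleavage motifs.**  Annotates the recognition motifs of three
proteases implicated in sulfated-peptide maturation: SBT1.1
(RRSLVL/HTDY, the slash marking the scissile bond), SBT6.1 (RXLX / RXXL)
and SBT3.8 (the DY motif itself; reported as candidate sites).

**qPCR ΔΔCt.**  Comparative-Ct relative expression normalized to a single
reference gene (actin-2 by default): technical replicates are averaged,
ΔCt is formed per biological replicate, and the expression ratio is
`efficiency^(−ΔΔCt)`.  Inference uses a REST-style randomization test
(biological replicates reallocated between groups) and a percentile
bootstrap interval.

**Synthetic data.**  Generators produce prepropeptide-like sequences
(hydrophobic leader, embedded motif, configurable placement and knockouts)
and replicate-structured Ct tables with known true ratios, so every stage is
testable offline with exact ground truth.

## Worked example

```
$ psykit simulate precursors --seed 11 --n 6 --out demo.fa --truth demo_truth.tsv
6 precursor(s) in demo.fa; truth in demo_truth.tsv
$ psykit screen --fasta demo.fa --out verdicts.tsv
6/6 record(s) passed; verdicts in verdicts.tsv
$ head -4 verdicts.tsv
id      passed  reasons motif_start_1based
SIM0000 True            59
SIM0001 True            146
SIM0002 True            81
```

All six generated precursors pass the screen (they were generated with the
motif in the second half); the last column is the 1-based start of the motif
match used.  Expression analysis on a simulated experiment with a true
4-fold induction and the published replicate design (3 biological × 2
technical):

```
$ psykit simulate ct --seed 11 --gene PSY4=4.0 --out ct.csv --truth ratios.tsv
$ psykit ddct --ct ct.csv --control control --treatment treatment --gene PSY4 --seed 7 --out ddct.json
PSY4: ratio 3.734 (ddCt -1.901), p = 0.09545227386306847
```

The estimated fold change 3.73 (ΔΔCt −1.90) recovers the simulated truth of
4.0 within measurement noise; with only three biological replicates per
group the randomization test cannot reach p < 0.1, which is exactly the
granularity limit of a 3-vs-3 permutation design.

Real homolog sequences are fetched once by UniProt accession (the shipped
manifest lists the 32 published homolog accessions; sequences themselves are
never redistributed):

```
psykit fetch --cache-dir accession_cache     # requires network, one time
```

Once the cache exists, the regression tests that reproduce the published
similarity table, protease-motif membership and the 31-of-32 census run
automatically; without it they are skipped.

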