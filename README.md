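# cnvlossverify

Validation of copy-number-**loss** calls (deletions) against sequencing
data, for people who have CNV callsets from SNP microarrays and/or
short-read sequencing and want to know which calls are real — without
waiting for orthogonal wet-lab confirmation.

CNV reports for the same individuals from different platforms disagree
surprisingly often, even when each report was cross-platform validated.
This package implements the three analyses needed to dissect such
disagreement and to validate a callset directly against raw alignments:

1. **Callset concordance.** Two calls are "the same" CNV when one covers at
   least 50% of the other's base pairs — directionally, against the query
   call's own length, by a *single* partner. Per-source totals, matched
   counts and percentages are reported for each ordered direction, after
   the standard preprocessing filters (≥ 5 array probes inside the call;
   overlap with gene regions).

2. **Read-depth testing.** For a candidate region with per-base depths
   giving mean μ, and an equally long background stretch, the pooled 2L
   depths are resampled without replacement R times (default R = 999).
   With σ₁…σ_R the resampled means,

        p = (1 + #{σᵢ ≤ μ}) / (R + 1),

   a one-sided permutation test of H₀: μ ≥ σ; small p means the region is
   depth-depleted (a real loss), p = 1 flags unusually *high* depth. A
   two-sample χ² test of H₀: F = G on binned depth histograms complements
   it, and both tests are also run against the upstream/downstream flanks
   (a true loss is a depth valley — "concave" against both sides).
   Pools of ≤ 12 values are enumerated exhaustively instead of resampled.

3. **Breakpoint seeking.** Reads near a candidate's boundaries plus
   locally anchored unmapped reads are assembled with a de Bruijn graph
   (canonical k-mers, k = 21 by default); contigs — and, failing them,
   individual unmapped reads — are split-aligned to the local reference.
   A query decomposing into a prefix ending at L and a suffix resuming at
   R (R − L ≥ 50 bp, adequate anchors) is direct **break-read** evidence
   for deleting [L, R). Candidates without break reads fall back to
   **paired-end** evidence (straddling pairs with inserts stretched by
   roughly the candidate length); the rest are **unsupported**.

A first-class synthetic-data generator produces the whole input bundle —
reference FASTA, paired-end alignments (BAM) with exact truth labels over
planted homozygous/heterozygous deletions, SNP-probe grids, gene regions,
and discordant callsets — so every stage is testable offline.

## Worked example

`examples/04_breakpoint_seeking.py` plants 8 homozygous deletions,
simulates 10× error-free paired reads and recovers every junction:

```
               planted                  called  evidence    support  exact
           16486-20377             16486-20377  break_read       10  True
           34972-37421             34972-37421  break_read       11  True
           74977-76324             74977-76324  break_read        4  True
           ...
evidence proportions: {'break_read': 1.0, 'paired_end': 0.0, 'unsupported': 0.0}
```

`support` counts reads carrying the junction-spanning sequence; `exact`
compares the called breakpoints with the planted ones (junctions are
left-normalized through chance microhomology).

`examples/01_simulate_and_validate.py` runs the full validation on a mixed
het/hom truth set at the study regime (4×, 1% substitution errors):

```
chrom  start    end  mean_depth  perm_p        chi2_p   evidence
 chr1   3671   6768    2.492735   0.001 1.848704e-179 break_read
 chr1   7158   9464    0.000000   0.001  0.000000e+00 break_read
 ...
permutation rejections: {'p<0.01': 1.0, 'p<0.05': 1.0, 'NA': 0.0}
```

Heterozygous losses sit near half the 4× background depth, homozygous ones
at zero; all reject at the permutation floor p = 1/(R+1) = 0.001.

The other examples demonstrate the concordance study on three discordant
callsets and the permutation test in isolation. A thin CLI wraps the same
library calls:

```
cnvlossverify simulate --outdir ds --seed 1
cnvlossverify concord --a ds/callset_arrayA.bed --b ds/callset_seqB.bed \
    --probes ds/probes.bed --genes ds/genes.bed
cnvlossverify validate --bam ds/reads.bam --ref ds/ref.fa \
    --candidates ds/truth.bed --outdir report
```

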