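# Methods

## Coordinates and matching

All internal coordinates are 0-based half-open. BED input is taken as-is;
VCF records are 1-based with a symbolic-deletion span of (POS, END],
converted to [POS, END); report-style tables default to 1-based inclusive
with a dialect flag. A single convention at the boundary removes an entire
class of off-by-one bugs; the dialect flag absorbs source variation that
cannot be verified from published tables.

Two calls match when a **single** partner covers ≥ 50% of the query's own
base pairs. The rule is deliberately directional and single-partner: the
published comparison tables report different matched counts per direction,
which only arises when the fraction is measured against each query's own
length, and "shared no less than 50% base pairs with some call" reads as
one partner, not a union. Consequences tested explicitly: two partners
covering 30% + 30% do not match; splitting a partner breaks a match only
if no single piece retains the threshold. Matching is within-sample;
a sites-only callset (sample id `*`) is compared against all samples.
Percentages are rounded half-up to two decimals for report parity.

Preprocessing filters mirror standard practice when comparing array and
sequencing calls: a sequencing call must contain ≥ 5 array probe positions
(an array caller cannot see it otherwise) and overlap a gene region
(avoiding repetitive/complex regions). Both use the half-open convention:
a probe at the interval start counts, one at the end does not.

## Read depth and the two tests

Depth is the count of reads whose alignment consumes the reference at a
base (CIGAR M/=/X), excluding duplicate, secondary, supplementary and
QC-fail records, with an optional mapping-quality floor (default 0).

**Permutation test.** H₀: μ ≥ σ, where μ is the candidate's mean per-base
depth and σ the mean of an equally long background stretch. The pooled 2L
depths are redrawn without replacement R times; p = (1 + #{σᵢ ≤ μ})/(R+1).
The add-one form is the standard finite-sample-valid permutation p: it
keeps p ≥ 1/(R+1), yields p = 1 when μ is at least every resampled mean
(flagging unusually *high* depth), and never produces p = 0 on ties. An
order-statistic formulation of the same test admits inconsistent readings
around ties and ordering; the add-one count is the unambiguous equivalent
and is what the implementation guarantees. The pooled vector is sorted
before resampling, so the p-value is a function of the pooled multiset
alone — permuting either input changes nothing, including the Monte-Carlo
draw sequence. Pools of ≤ 12 values switch to exhaustive enumeration over
all C(2L, L) subsets with p = (1 + #{mean ≤ μ})/(N + 1).

Status NA is returned when the pooled values are all identical (no
resampling variation — this subsumes the zero-depth-region-with-zero-depth
-flank case), and mirrored as an NA column in batch summaries.

**χ² test.** H₀: F = G on the two depth distributions. Depths are
histogrammed over shared integer bins 0..d_cap with d_cap the 99th
percentile of the pooled depths (larger values clamp into the top bin);
adjacent bins are merged greedily left-to-right until every expected count
reaches 5; the statistic is the usual Σ(O−E)²/E over the 2×B table with
expectations from pooled marginals, B−1 degrees of freedom. Fewer than two
merged bins → NA. The statistic is cross-checked in the tests against an
independent contingency-table implementation to 1e-10.

**Backgrounds.** The whole-chromosome background is one contiguous stretch
of equal length, placed uniformly over all positions that avoid the tested
region and (optionally, default in the pipeline) every other candidate —
sampling the null from inside another deletion would contaminate it. Flank
("concavity") tests use the immediately adjacent upstream and downstream
windows of `flank_factor` × region length (default 1; real depth
profiles show the informative window is within a few call-widths). A flank
that does not fit in the contig reports NA.

**Calibration and a known limitation.** The permutation test is exact
under exchangeability of per-base depths, and the type-I acceptance test
verifies its size on an i.i.d. Poisson(4) depth process (rejection at
α = 0.05 within 3 binomial SEs over 1000 nulls). Depth from *reads* is
autocorrelated on the read-length scale, which per-base permutation does
not model: contiguous null stretches of read-generated depth reject far
above nominal (the effective sample size is ~L/read_length, not L, so the
inflation does not vanish with region length). In practice the test is
used in the power direction — a region at zero or half depth against a
positive background hits the attainable floor p = 1/(R+1) regardless —
but its p-values on borderline regions of real alignment data should be
read as scores, not calibrated probabilities. No multiple-testing
correction is applied anywhere.

## Breakpoint seeking

For each candidate, reads overlapping `[start−flank, start+flank)` and
`[end−flank, end+flank)` (default flank 500 bp) are collected, along with
unmapped reads placed there by their mapped mates. When another candidate
deletion lies within one insert length of a boundary, additional fetch
windows cover that neighbour's far flank: the mate of a junction-crossing
read is within one insert in *sample* coordinates, and an intervening
deletion displaces it arbitrarily far in reference coordinates.

Assembly uses a de Bruijn graph over canonical k-mers (odd k, default 21;
nodes are (k−1)-mers, edges observed k-mers with read-count
multiplicities; reads are split at Ns). Edges below a multiplicity floor
are pruned — the floor auto-selects 2 when local coverage is ≥ ~8× and 1
below that, since at ~4× a floor of 2 would discard true junction k-mers.
Short dead-end branches (< k edges) are clipped as sequencing-error tips.
Contigs are maximal non-branching paths, deduplicated across strands, with
lexicographic iteration everywhere so assembly output is reproducible
without a seed.

Split alignment decomposes a query (contig, or individual unmapped read as
fallback) into a prefix matching the local reference window ending at L
and a suffix resuming at R, with R − L ≥ 50 bp (`min_deletion`, separating
deletion junctions from small-indel noise) and both pieces at least
`min_anchor` bases (default k−1 for contigs — a heterozygous junction
contig between branch nodes carries exactly k−1 bp anchors — and
max(12, (k−1)/2) for raw reads, still unique within a few-kb window).
Each piece tolerates 1 + 0.03·length mismatches. A query aligning
contiguously within budget yields no junction. The deletion length R − L
is independent of the exact split point; among equal-mismatch splits the
lowest-coordinate junction is reported, and all junctions are
left-normalized through breakpoint microhomology (deleting [L, R) and
[L−1, R−1) are the same event when ref[L−1] = ref[R−1]), so caller and
truth agree on a canonical representation. Competing junction candidates
are ranked by the number of reads containing the junction-spanning
sequence (24 bp probe) before vote count — direct read evidence
distinguishes the true join from a mismatch-tolerated shifted
decomposition.

Evidence classification is ordered: break-read (split-aligned contig,
else split-aligned unmapped read) first; otherwise paired-end — at least
2 pairs straddling the candidate whose reference-coordinate insert
exceeds the library mean by > 3 SD and is consistent with a deletion of
roughly the candidate's length (breakpoints then reported, imprecisely,
at the candidate boundaries); otherwise unsupported. Adding
junction-spanning reads can only upgrade a classification. Treating
individual unmapped reads as split-alignment queries is this package's
extension of the contig-only route: an unmapped read is precisely a
candidate break read, and at ~4× coverage assembly alone leaves many
recoverable junctions fragmented.

## Synthetic data

The generator emulates the data regime the analyses assume, not a
particular instrument: an i.i.d. uniform-ACGT reference; non-overlapping
planted deletions (kept ≥ 2 read lengths apart and one library margin from
contig ends, junctions left-normalized at planting); two haplotypes
(hom deletions on both, het on one); paired-end reads with uniform
fragment starts (≈ Poisson coverage), normal insert (default 400 ± 40 bp,
a low-coverage short-read library), constant read length (default 100 bp),
i.i.d. substitution errors (default 1%); probe grids with exponential
gaps (default mean 1 kb); and three discordant callsets derived from the
truth by boundary jitter, drops, spurious calls and minimum-size censoring
(array blindness to small events). Default mean depth is 4.0×, matching
the released alignment data the original analysis consumed.

Alignments are emitted by construction from the donor→reference coordinate
map rather than by running an aligner: reads inside retained segments get
full-match CIGARs; junction-crossing reads are emitted unmapped with a
mapped mate (probability `unmapped_junction_prob`, default 1.0 — the
premise that unmapped reads are where breakpoints hide) or soft-clipped at
the junction otherwise. This gives exact truth labels (which reads cross
which junction, expected depth per segment class) at the cost of realism
in aligner-specific behaviour. Not modelled: indels, quality-score
structure, GC bias, repeats and segmental duplications, mappability — so
passing tests demonstrate the statistical machinery is correct under the
stated model, not that real-genome complications (e.g. calls in
repetitive regions) are handled.

## Scales used in tests and the acceptance script

Simulated contigs are 60 kb–700 kb with 2–100 planted deletions per run;
the acceptance script uses 100-deletion runs at 10× (error-free,
homozygous; the exact-junction benchmark) and 4× with 1% errors and mixed
zygosity (the study regime), 500 Poisson nulls for calibration, 200
homozygous ≥ 1 kb losses for power, and a 60-deletion truth for the
concordance pair. These sizes put every rate's binomial noise well inside
the margins asserted while keeping a full run around a minute.

## Known limitations

- Per-base permutation p-values are anticonservative on autocorrelated
  real-alignment depth (discussed above).
- Split alignment assumes a single deletion junction per query; queries
  spanning two junctions of clustered deletions align to neither piece
  (mitigated by the read-level fallback, whose queries are shorter).
- Paired-end evidence localizes breakpoints only to the candidate
  boundaries.
- Gains, inversions, translocations, CRAM input and cross-assembly
  liftover are out of scope.
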