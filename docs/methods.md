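# Methods

This note documents the models behind `hapscna`: what the simulator
emulates, how each inference stage works, the parameters that matter,
and the judgment calls made where the design was genuinely open. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and containers

All coordinates are 0-based, half-open. A `ParentalKaryotype` is a
per-chromosome tiling of segments carrying non-negative integer copy
numbers for homolog A and homolog B; the tiling invariant (no gaps, no
overlaps) is checked after every mutation. Simulated truth and inferred
calls share this container, so recovery can be scored segment by
segment. Genomic bins are fixed width with the last bin truncated; the
default test genome has four chromosomes (150/120/90/60 Mb) so suites
run in seconds, and a 22-autosome genome shape is available for burden
accounting and phylogeny studies.

## The clone-evolution simulator

### Event operators

Each operator is an explicit karyotype transformation with its
conservation law built in:

- **BFB terminal break** — a chromatid-bridge breakage produces two
  daughters with reciprocal loss/gain of the segment distal of the
  breakpoint; for every bin the daughters sum to exactly twice the
  parent.
- **Paracentric / pericentric events** — internal segmental gain or loss;
  whether the segment lies within one arm or spans the centromere is
  decided by the centromere interval. Segments touching a telomere are
  rejected (those are terminal events).
- **Chromothripsis** — the region is shattered into uniform
  stick-breaking fragments (the fragment-size law is not otherwise
  constrained by anything we model), each independently retained or
  dropped one copy with probability `retention_p`, giving two-state
  oscillation on a uniform baseline.
- **BFB amplification** — the focus doubles per round and the flank
  distal of the focus (toward the nearer telomere, the broken end) is
  lost; three rounds take a single-copy focus to the 8-copy
  amplification threshold.
- **WGD, missegregation, UPD** — genome doubling, whole-homolog +-1, and
  copy-neutral homolog replacement (recipient to zero, donor doubled;
  total copy number preserved exactly).

### Clone trees

Random binary topologies grow to the requested leaf count. The first
branch off the root models biallelic TP53 inactivation and carries an
arm-scale LOH event (UPD or arm deletion), mirroring the near-universal
17p-LOH route; branches before that fixate only copy-neutral or focal
events (UPD, focal deletion/duplication), all kinds afterwards. WGD
occurs on post-TP53 branches with probability 0.5 (about half of
patients in this disease setting acquire one) and is inserted early
enough in the branch's event sequence that at least two events follow
it: most SCNAs postdate duplication, and the resulting odd copy states
are what makes a WGD genome identifiable from coverage at all. Events
producing nullisomy (total copy zero) over more than 5 Mb are rejected
as lethal. An optional `unique_targets` mode forbids two events on the
same (chromosome, homolog) along a lineage — the clean-marker regime for
phylogeny studies; UPD reserves both homologs since it rearranges both.

### Rendering

Bulk samples are mixtures of a clone (fraction = purity, default range
0.2-0.9 as in FFPE lesions), optional subclones, and diploid normal.
Expected bin counts are proportional to mixture total copy number times
a shared "recurrent bias" profile (smooth random function per patient
plus a GC-dependent term) and per-bin FFPE jitter; counts are
gamma-Poisson (negative-binomial-like, variance `mu + 0.02 mu^2`).
Allelic depths at het sites (Poisson density 1 per 3 kb) are
beta-binomial around the mixture allelic fraction; the reported phase is
the truth corrupted by a Poisson switch process at 1 per 250 kb, shared
across all samples of a patient (phasing happens once per patient). A
20x bulk sample corresponds to `mean_depth=500` per 25 kb bin and
`site_depth=8` reads per haploid copy per het site.

Single cells are rendered at fixed sequencing depth — counts reflect
copy-number *ratios* only, so a uniformly duplicated genome reads
exactly like a diploid one (the motivation for the half-integer WGD
rule) — with smooth long-range multiplicative amplification noise and
sparse (mostly 0/1) allelic depths.

What the renderer does **not** model: read-level artifacts, mappability,
sequence-resolved junctions, replication timing, and clustered (non-
Poisson) switch errors. Passing tests therefore demonstrate correctness
of the algorithms under calibrated noise, not robustness to every
real-FFPE pathology.

## Phase refinement

Statistical phasing orients each het site relative to a chromosome-level
haplotype, with switch errors between blocks. In any region where the
two homologs differ in copy number, the per-site phased depth difference
`a - b` flips sign at each switch; summing that difference across
samples (orientation-aligned against the strongest sample — switches are
shared, so relative signs are constant) gives a signal whose sign
structure localizes the switches.

The correction: windows of 50 kb (well under the 250 kb switch spacing)
score imbalance `(A-B)/(A+B)` with a minimum informative total of 50
alleles; runs of at least 4 windows where two or more samples show
|imbalance| >= 0.1 (confirmed on the region mean) become candidate
regions; within each region the aggregated per-site difference is
segmented by binary segmentation with a deliberately liberal penalty
(factor 0.4) — a spurious changepoint is harmless, a missed one leaves a
switch — and segments whose sign opposes the region majority are flipped
if their z-score exceeds 3 (ambiguous segments keep the statistical-
phasing orientation, as do exact ties). Correction only swaps the A/B
orientation; depths are never altered, and the procedure is idempotent
up to noise.

For single cells the same machinery runs in two passes: pass 1
aggregates all cells (with a conservative z >= 5, since the diploid
majority dilutes the signal) and serves to identify aneuploid cells
(some 10 Mb window with |imbalance| > 0.25); the final haplotype is then
re-derived from the raw depths of the aneuploid cells alone, so pass-1
boundary errors are not inherited. In the sparse ~1x regime, boundary
localization is limited by per-site signal-to-noise; cross-sample bulk
correction reaches 20-40x switch-rate reduction, single-cell correction
a more modest factor.

## Copy number

**Normalization.** Bin counts are converted to log fractional coverage;
a cubic polynomial of GC is removed; the median profile of the germline
panel (minimum 3 samples) is divided out; output is scaled to a
length-weighted mean of 1. The procedure is scale-invariant and masks
bins with zero panel coverage. Optionally, the projection of each
sample's centered log-coverage onto the top-k panel eigensamples
(SVD left singular vectors; k = 10) is removed — rank-k panel structure
vanishes while orthogonal copy-number signal is untouched.

**Haplotype coverage.** Each 25 kb bin splits its normalized total by
the depth-weighted corrected haplotype fraction of its het sites;
`hap_A + hap_B = total` exactly, and bins without informative sites
inherit the nearest informative fraction (flagged).

**Segmentation.** Joint penalized least-squares changepoints on the
(hap A, hap B) signal, computed with an exact PELT search (binary
segmentation misses short interior segments whose split gain is diluted
across a long chromosome — and those segments, often the only odd copy
states, decide ploidy identifiability). The penalty is BIC-like with a
configurable multiplier, default 1.8 on coverage (larger factor, fewer
changepoints).

**Purity and ploidy.** For candidate `(p, psi)` the implied allelic copy
number of a segment with coverage `c` is `q = (c D - (1-p)) / p`,
`D = p psi + 2(1-p)`. The grid (purity 0.05-1.0 step 0.01, ploidy
1.2-6.0 step 0.05) only needs to land in the right integer-assignment
basin: each candidate's assignment is re-fit by weighted least squares
of `c` on `q_int`, refining `(p, psi)` continuously. Candidates implying
nullisomy over more than 1% of the genome are discarded. Selection then
proceeds adequacy-first: fewest subclonal states (residual > 0.3
copies, counted only on segments >= 3 Mb, with a one-segment tolerance
— a denser lattice can always absorb one stray segment, and one
artifact segment must not veto the true solution), then a coverage-
residual band at twice the best adequate fit to reject genuinely worse
solutions, then the lowest ploidy (bucketed to 0.25) and best fit —
integer rescalings and +-1 shifts of the lattice fit coverage exactly,
and ploidy parsimony is the deterministic stand-in for a manual review
of the solution ladder. Genomes whose allelic states are all even, or
that lack any zero state, remain genuinely ambiguous from coverage alone;
the original analysis resolved these with histology and mutation allele
fractions, which are out of scope here. Samples without allelic
imbalance return `indeterminate` (no large SCNAs to anchor the fit), as
such samples are excluded from purity/ploidy estimation.

**Integer calls.** `q` rounded to non-negative integers; residuals above
0.3 copies are flagged subclonal with the fractional value retained.

**Single cells.** The four-step normalization: genome-mean centering;
recurrent-bias removal by fitting the cell's log-coverage in a
constant-copy region (largest arm within 0.05 of the genome arm-median,
else the lowest-SD arm) to a cubic polynomial of the log median profile
across cells; GC correction; averaging to 1 Mb. Chromosomal states are
normalized by the genome median arm-level allelic copy number; states
clustering at half-integers imply the remaining chromosomes are
duplicated (states doubled, WGD flagged); a genome is near-tetraploid
when some arm has median allelic CN in [0.2, 0.8] with allelic-coverage
SD < 0.25. A uniform (2,2) genome is indistinguishable from (1,1) by
ratios alone and is deliberately not flagged.

## SCNA classification

Per chromosome, against a germline-equivalent baseline ((1,1), or (2,2)
in WGD samples): UPD first (copy-neutral, one homolog zero, the other
compensating — required to reach a telomere or centromere boundary,
since an interior copy-neutral stretch is a coincidence of independent
gain and loss, and the known UPD examples are terminal/arm-scale); then
amplification (exactly the segments with allelic CN >= 8); oscillating
two-state runs with >= 8 switches as chromothripsis (the threshold is a
declared choice; only "oscillating copy number" is qualitative
guidance); whole-chromosome and arm-level deviations (breakpoints within
1 Mb of centromere/telomere count as arm-level, absorbing segmentation
jitter); terminal events (one breakpoint, reaching a telomere);
paracentric/pericentric internal events; and interior events under 5 Mb
as focal (the focal/segmental size boundary is a declared choice — 5 Mb
— as no principled value presents itself). The reference state per
homolog is the baseline whenever any of it survives, else the
length-weighted modal state with ties to the lower copy number: a 90 Mb
terminal loss must read as a loss from the remaining baseline, not a
gain of the other end.

Chromothripsis footprints: 'direct-bridge' when the oscillation abuts a
large terminal/internal boundary within 1 Mb; 'downstream-micronucleus'
when it spans a telomeric/centromeric segment or a whole arm;
'regional' otherwise. The two bridge footprints are acknowledged as not
strictly distinguishable; the label is a best guess, not a hard claim.

**Sloping copy number.** Candidate regions anchored at either end of an
arm (2 Mb grid, minimum span 5 Mb) are tested on each homolog for a
robust monotone trend: |Spearman rho| >= 0.5 plus a Theil-Sen fit losing
at least 0.3 copies across the region, while the other homolog stays
within 0.15 copies over the same region — the internal control that
separates genetic sloping from technical waviness. A clonal step is
rejected by requiring the linear model to explain the data at least as
well as the best single-step fit. Robust fits run on at most 300 evenly
thinned points per region (they are quadratic in point count).

**WGD inference (bulk).** WGD is called when the length-weighted genome
fraction whose major homolog has >= 2 copies exceeds 0.5 — a rule that
survives extensive post-WGD losses.

**Rearrangement filtering.** Candidates with both breakends on one
chromosome closer than 100 kb are dropped (FFPE chimera artifacts);
survivors are kept only when both breakends lie within 100 kb of a
copy-number changepoint.

## Phylogeny and timing

Breakpoints are matched across samples on the same chromosome and
homolog: identical when within 0.1 Mb with the same direction of change,
complementary when within 0.1 Mb with opposite directions (reciprocal
daughters of one breakage — a branching relation), whole-chromosome
events by category. Events shared by two or more samples become binary
characters; characters are accepted greedily in decreasing breakpoint
support when laminar-compatible, and every rejected character is
reported as a conflict (never silently dropped) — erasure of ancestral
breakpoints by later whole-chromosome loss surfaces here. The laminar
family becomes a rooted tree under a germline (all-zero) root; branch
length counts distinct altered chromosomes; private events sit on
terminal branches; samples that cannot be placed are listed rather than
forced.

Timing against duplication uses integer states: a two-copy difference
across a changepoint predates duplication (the one-copy change was
doubled with the genome), a single-copy difference postdates it;
whole-chromosome states in WGD samples follow parity — final copy
number 1 means duplicated then lost; odd states >= 3 mean duplication to
the nearest even state plus a single-copy adjustment; even deviations
predate. WGD itself is placed on the most ancestral branch whose clade
is entirely WGD-flagged; disjoint flagged clades receive independent
events. sSNV similarity (presence = 3 supporting reads;
|shared| / |own|, asymmetric) is a cross-check, not a tree builder.

## Burdens and statistics

Each altered autosomal homolog counts once (44 maximum), classed by its
most complex alteration with precedence segmental > arm-level > UPD >
local — the precedence is a declared choice where one homolog carries
several classes. Genome-fraction summaries on a 100 kb grid: deletion at
allelic CN 0; duplication at >= 2 (>= 3 in WGD samples); flagged
non-integer states split into subclonal loss/gain around the
germline-equivalent single copy. Group comparisons: two-sided
Mann-Whitney U with rank-biserial effect size and a bootstrap CI of the
median difference; Fisher's exact test with odds-ratio CI for
composition tables; Benjamini-Hochberg FDR added across reported
comparisons with raw p retained; groups under 3 observations return NA
with a reason.

## Validation studies and problem sizes

The studies in `hapscna.validation` size their simulations to run the
whole acceptance suite in a few minutes on one CPU: the classification
oracle uses 500 noiseless single-event chromosomes; purity/ploidy
recovery 20 bulk samples (purity drawn 0.3-0.9, 20x-equivalent depth) on
the 4-chromosome genome; switch-error correction 20 patients of 3
samples sharing chromosome-scale LOH on a single 150 Mb chromosome;
phylogeny recovery 20 patients of 4-8 samples with >= 3 clean markers
per branch on a 22 x 120 Mb genome; WGD timing 200 noiseless lineages;
sloping 20 telomere-anchored erosion fans (~0.5 copies per 10 Mb at
purity 0.5) against 100 flat genomes; conservation audits 1000 random
events. Mid-arm erosion fans with a distal plateau deliberately read as
subclonal steps, not sloping — progressive terminal losses reach the
telomere by definition.

## Known limitations

- Purity/ploidy is unidentifiable from coverage alone for all-even
  karyotypes and for genomes without any allelic-zero state (the
  solution-ladder ambiguity); the deterministic lowest-ploidy rule picks
  the parsimonious member.
- Switch-error correction requires allelic imbalance; balanced regions
  retain input switch rates (and are flagged untouched, never guessed).
- The classifier's decision order is heuristic on multi-event
  chromosomes: overlapping events of opposite sign can merge or mask.
- Single-cell boundary localization is limited by ~1x sparsity.
- The simulator's noise model is calibrated, not learned from real FFPE
  libraries; see the rendering section for what it omits.
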