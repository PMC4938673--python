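# Methods

## Genotype model

Reads at a SNP are treated as independent Bernoulli draws with per-read
error probability ε (default 0.01). For counts (n_ref, n_alt):

    L(A) = (1-ε)^n_ref · ε^n_alt
    L(B) = ε^n_ref · (1-ε)^n_alt
    L(H) = (1/2)^(n_ref + n_alt)

The call is the better homozygote whenever its log10 likelihood exceeds
both the other homozygote's and the heterozygote's; H requires both
alleles observed and a strictly larger likelihood than either
homozygote, so all ties resolve toward a homozygote. This is
deliberate: in a selfed RIL panel the prior odds of heterozygosity are
(1/2)^(g-1) (3.1% at F6), so population-genotype priors that assume
Hardy–Weinberg would over-call H. Flat priors within the favoured set
keep the rule simple and monotone in the counts; with ε < 0.5 an exact
homozygote/heterozygote likelihood tie is impossible, and the
n_ref = n_alt > 0 case always falls to H.

MAF is computed on allele counts of called genotypes (two per
homozygote, one of each per H). The quality filter is pass/fail at the
variant caller's maximum score (999 in classic pileup output); the
simulator reproduces that convention with a binary pass value rather
than re-implementing a caller's quality model.

## Scaffold consensus

Per line, a scaffold with support counts (nA, nH, nB) over its SNPs is
called H if nH ≥ max(nA, nB) or min(nA, nB) ≥ 0.25 × called (boundary
inclusive), otherwise the majority homozygote; exact A/B ties with
neither H condition met fall to missing. The 0.25 mixture threshold is
this package's choice: at ~2x coverage a heterozygous region yields
roughly equal numbers of apparent A and B calls, while sequencing error
at ε = 0.01 contaminates a homozygous region at ~1-2% per cell, two
orders of magnitude below the threshold.

Consensus patterns heterozygous in more than 15% of called lines are
excluded from template construction. This mirrors the SNP-level
multi-copy filter at the haplotype level and is load-bearing: the
consensus of a scaffold assembled from two unlinked loci is
heterozygous in roughly half the lines and homozygous-but-agreeing in
the rest, so such a pattern sits at recombination fraction ~0 from
*both* source regions and would otherwise bridge two linkage groups
under single-linkage clustering.

## Template map construction

Pattern distance counts lines with opposite homozygotes; H and missing
match anything. Patterns collapse when no line shows opposite
homozygotes and at least one line is called in both (missing acts as a
wildcard); representatives absorb members' calls at missing lines,
processed from most to least informative, ties by input order.

Linkage groups come from single-linkage clustering on the recombination
fraction (distance / both-homozygous lines). The threshold default is
0.20: for two unlinked patterns the observed fraction is approximately
Binomial(n, 1/2)/n over n ≈ 90 informative lines, so P(rf < 0.20) ≈
6×10⁻⁹ per pair — negligible even across the ~10⁵ unlinked pairs of a
dense map — while adjacent same-chromosome patterns a few cM apart sit
far below it. A 0.35 threshold, by contrast, admits ~1.6×10⁻³ per pair
and would chain chromosomes through chance matches once patterns number
in the hundreds.

Ordering minimises total adjacent recombination events (an open-path
TSP). Greedy nearest-neighbour paths from up to 10 evenly spaced starts
are polished by steepest-descent 2-opt (vectorised) alternating with
or-opt relocation of 1-3 pattern segments in either orientation, to a
joint local optimum; the best start wins. Ties everywhere break to the
lowest index, and the final orientation puts the lexicographically
smaller endpoint first, so results are deterministic. On random
instances of ≤8 patterns the search reproduces the exhaustive optimum
(verified against brute force in the suite); larger instances carry no
optimality guarantee, only monotone improvement over greedy.

Placement assigns each SNP the template position minimising pattern
distance; min distance > 6 → anomalous. Tied positions are reported as
the smallest enclosing window within the group holding the most tying
rows (ties to the lower group index). The build iterates: consensus →
collapse → cluster → order → place → refilter, lowering the scaffold
SNP threshold geometrically from 50 to 5 over the first ten iterations
and holding 5 for the last five (15 iterations maximum), stopping early
at a fixed point. A scaffold whose every SNP is currently anomalous
(typically because its chromosome is not yet represented in the early,
high-threshold template) falls back to all of its SNPs for consensus,
so the region can enter the map in a later cycle instead of being
dropped.

## Genetic distances

For each adjacent template interval, R = recombinant lines / scored
lines (both calls non-missing; any state change counts). Three
conventions convert R to cM: `raw_R` (100R), `half_R` (50R, default)
and `haldane_waller` (100R / 2(1-R)). The default divides by two
because in a selfed RIL the observed recombinant fraction between
tightly linked markers approaches twice the per-meiosis rate (map
expansion); the convention is exposed because no single choice
reproduces all published map figures simultaneously.

## Breakpoints and chimeras

A within-scaffold breakpoint is ≥3 consecutive homozygous SNPs of one
parent immediately followed by ≥3 of the other; missing calls are
skipped without breaking runs, H calls break them (het/hom transitions
cannot be placed at SNP resolution at this coverage and are left to the
between-scaffold map). A hit is retained only when the template shows a
*direct* A↔B adjacency for that line around the scaffold's map window —
an intervening H position vetoes it, since the template then asserts
the region is heterozygous in that line. Runs require strictly
consecutive concordant calls; `min_run` is configurable.

Localisation resolution is bounded by call quality: a single-read
miscall at a run junction shifts the reported interval by one SNP, and
a residual-heterozygosity tract shorter than the template bin spacing
can be miscalled into apparent A/B runs whose interval then lies
*between* two true crossovers. On the study-design simulation (96 F6
lines, 2.26x, ε = 0.01, ~330 corroborated breakpoints) 2-4 intervals
per run miss the true crossover through these mechanisms; with
error-free reads and near-complete inbreeding containment is exact, and
the suite asserts exactly that split: strict containment under ideal
conditions, ±1-SNP resolution otherwise.

A scaffold is chimeric when ≥5 placed SNPs fall on each of two linkage
groups, or when two such clusters on one group are separated by more
than 10 recombination events *across at least two template intervals*.
The two-interval condition matters: adjacent map positions can be
separated by many events (gap regions reach >10 recombinant lines in a
single interval), and a physically contiguous scaffold legitimately
spans one interval — that is a breakpoint scaffold, not a mis-assembly.
Event distances between clusters use the closest tie-window edges, so
ambiguous placements never inflate the separation.

## The simulator

`sim_ril` emulates the target study design; its defaults are the study
conditions, not tuning knobs: 96 lines, 12 chromosomes of 80 cM
(≈960 cM genome), selfing to F6 with single-seed descent, crossovers
per gamete Poisson(L/100) placed uniformly (Haldane, no interference),
600 scaffolds with log-normal lengths parameterised to a 2 kb N50
(length-weighted median of LogNormal(μ, σ²) is exp(μ + σ²), σ = 0.7),
10.4 SNPs/kb (one per ~96 bp), mean depth 2.26 per line, ε = 0.01.
Allele pairs are drawn uniformly from the 12 ordered distinct base
pairs. Artifact injection: a chimeric scaffold has its right half
replaced by a segment of another chromosome; a repeat-derived SNP
receives an extra Poisson(mean_depth) dose of reads from a shadow locus
on another chromosome, and artifact sites drop below the pass quality
with probability 0.3. A single root seed spawns the population,
assembly and read streams in fixed order.

What the simulator does *not* model: read-level sequences (no FASTQ),
alignment and reference bias, insert-size structure, segregation
distortion, crossover interference, varying recombination rate along a
chromosome, and scaffold orientation (all placements are forward
strand). Passing tests therefore establish the pipeline's correctness
under idealised sampling noise and the injected artifact classes, not
robustness to mapping bias or distorted segregation in real panels.

## Problem sizes and seeds in the suite

Simulation-backed tests run the full study design (96 × 12 × 600
scaffolds, ~10k SNPs; the build converges in ~10 iterations and a few
seconds) with fixed seeds shared through session fixtures. The F6
segregation check uses ~11.5k effectively independent line×locus trials
(loci spaced 200 cM apart on long chromosomes) against the exact
binomial 99% interval at that n. Ordering optimality is verified on 200
random instances of 2-8 patterns against exhaustive search. The
breakpoint-exactness property uses F12 inbreeding with ε = 0 so the run
rule's assumptions hold; the study-condition run asserts recovery of
all 12 linkage groups, zero misplaced scaffolds and ≥10:1 artifact
rejection enrichment.

## Known limitations

- Within-bin scaffold order is unidentifiable (no recombination event
  separates them); order recovery is asserted via Kendall's τ ≥ 0.95
  per group with reflections resolved.
- The iterative build is deterministic but greedy; no global optimality
  is claimed for maps with hundreds of patterns.
- cM totals depend on the chosen convention and accumulate consensus
  noise over many short intervals; absolute map length should be read
  comparatively, not as a meiotic estimate.
- The GC significance test treats bases within a sequence as
  independent, which overstates the effective sample size; its p-value
  is an approximation.
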