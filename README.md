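# rilmap

Ultradense genetic linkage maps from low-coverage whole-genome shotgun
(WGS) sequencing of recombinant inbred lines (RILs).

## The problem

Sequencing every line of a biparental RIL panel to ~2x coverage reveals
millions of segregating SNPs — three to four orders of magnitude more
markers than classic genotyping — but the data are hostile: most
individual calls are missing or unreliable, heterozygotes are usually
invisible at such depth, and with millions of loci even rare error
modes (repeat-derived SNPs, chimeric assembly scaffolds) produce huge
numbers of false markers. `rilmap` implements a complete pipeline that
turns such data, aligned to a fragmented draft assembly, into a genetic
map with per-scaffold placements, and is aimed at groups building maps
(and assembly scaffolding resources) for species without a
chromosome-level genome.

## The method

1. **RIL-aware genotype calling.** For a selfed panel at generation *g*
   the per-locus heterozygosity is het(*g*) = (1/2)^(*g*−1) — at F6 the
   AA:AB:BB expectation is 31:2:31 — so Hardy–Weinberg genotype priors
   are wrong. Each cell is called from its reference/alternate read
   counts (n_r, n_a) by comparing L(A) = (1−ε)^{n_r} ε^{n_a},
   L(B) = ε^{n_r} (1−ε)^{n_a} and L(H) = (1/2)^{n_r+n_a}, favouring the
   homozygote whenever its log10 ratio over both alternatives is
   positive.
2. **SNP filters.** Sites heterozygous in >15% of lines, with minor
   allele frequency <5%, with >50% missing data, or below the caller's
   maximum quality score are discarded.
3. **Scaffold consensus haplotypes.** SNP calls on one scaffold are
   merged into a per-line consensus that error-corrects the raw calls
   and recovers heterozygous regions (either explicit H calls or an
   A/B mixture at low depth).
4. **Template map.** Unique segregation patterns are clustered into
   linkage groups (single linkage on recombination fraction) and
   ordered to minimise the total number of adjacent recombination
   events — greedy nearest-neighbour construction polished by 2-opt and
   or-opt moves, exact on small instances. Every SNP is placed at its
   best-matching template position (H matches anything); SNPs more than
   6 mismatches from everywhere are discarded as anomalous, scaffold
   consensus is recomputed, and the cycle iterates from SNP-rich
   scaffolds (>50 SNPs) down to all scaffolds with ≥5 SNPs until the
   map stops changing.
5. **Map analysis.** Recombination events split by transition type
   (A↔B vs A↔H/B↔H), cM coordinates from adjacent recombinant
   fractions R (default 50·R, the selfed-RIL map-expansion correction),
   gap census, within-scaffold crossover breakpoints (≥3 consecutive
   homozygous SNPs of each parent, corroborated by the template),
   chimeric-scaffold detection (≥5 SNPs on each of two linkage groups,
   or far apart on one), depth/allele-class spectra and GC content near
   breakpoints.
6. **Synteny.** Genes from an external genetic map are located by best
   BLAST hit (e < 10⁻⁶) and chained into collinear segments against the
   scaffold map.

A forward simulator (`rilmap.sim_ril`) generates selfed pedigrees under
a Poisson/Haldane crossover model, fragments chromosomes into a
scaffold assembly, and draws low-coverage reads — with optional
injected repeat SNPs and chimeric scaffolds — providing full ground
truth for every stage.

## Worked example

Simulate a small panel (48 lines, 3 chromosomes, 150 scaffolds, 2.26x)
and build its map:

```bash
cat > demo.txt <<CFG
sim.n_chromosomes = 3
sim.n_scaffolds = 150
sim.n_lines = 48
map.max_iterations = 8
CFG
rilmap -v run --seed 3 --out demo_out --config demo.txt
rilmap stats demo_out/template_map.tsv --placements demo_out/scaffold_placements.tsv
```

which prints

```
INFO rilmap: calling genotypes for 2382 sites x 48 lines
INFO rilmap: filter cascade: {'input': 2382, 'retained': 2380, 'rejected_het': 2, ...}
INFO rilmap: template map: 3 groups, 132 scaffolds placed, 0/2380 SNPs rejected ...
INFO rilmap: breakpoints: 42 placed within scaffolds
recombination events: 258 (111 hom-hom + 147 hom-het); expected patterns: 261; gaps >=5 cM: 16
linkage_group  snps  patterns scaffolds length_cm
            1   746        29        40     106.2
            2   813        25        45      90.6
            3   766        24        47      71.9
        Total 2,325        78       132     268.8
```

Reading: the three simulated chromosomes come back as three linkage
groups; 132 of 150 scaffolds carried ≥5 mapped SNPs and were placed;
258 recombination events across 48 lines would explain at most
258 + 3 = 261 distinct segregation patterns, of which 78 were observed
on whole scaffolds; 42 crossovers were localised to within-scaffold
SNP intervals. Outputs land in `demo_out/` as TSV/VCF/BED.

The same driver ingests real data: set `simulate = false` and point
`vcf` at a multi-sample VCF (AD or GT+DP genotype fields) aligned to
your draft assembly.

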