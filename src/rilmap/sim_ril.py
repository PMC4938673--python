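"""Forward simulation of a selfed biparental RIL panel with full ground truth.

The simulator emulates the study design the mapping pipeline targets: a
biparental cross selfed to F6 (~96 lines), 12 chromosomes, a draft
assembly fragmented into thousands of short scaffolds (log-normal
lengths around a target N50), and low-coverage shotgun sequencing of
every line (~2.26x), with sequencing error and optional artifact
injection (repeat-derived SNPs fed by a second unlinked locus, and
chimeric scaffolds concatenated from two chromosomes).

Meiosis follows a Poisson/Haldane model without interference: each
gamete receives ``Poisson(L_cM / 100)`` crossovers placed uniformly
along the chromosome.  Each selfing generation draws two independent
gametes from the current plant and carries a single offspring forward
(single-seed descent).  All crossovers, final haplotypes, scaffold
placements and artifact injections are recorded in :class:`SimTruth` so
every downstream stage can be validated against truth.

Randomness derives from a single root seed: the population, assembly and
read stages consume child streams spawned from ``SeedSequence(seed)`` in
that fixed order, so every stage is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import GT_A, GT_B, GT_H, GT_MISS, QUAL_PASS, SNPReadMatrix

# -- configuration -----------------------------------------------------------


@dataclass
class SimConfig:
    """Study-design parameters for the simulated mapping population.

    Defaults mirror the target design: 96 F6 lines over 12 chromosomes
    (~80 cM each, i.e. a ~960 cM map), 600 scaffolds with a ~2 kb N50,
    ~10.4 SNPs per kb (one per ~96 bp) and 2.26x mean depth per line.
    """

    n_lines: int = 96
    n_chromosomes: int = 12
    chrom_length_cM: float = 80.0
    final_generation: int = 6
    n_scaffolds: int = 600
    scaffold_n50_bp: float = 2000.0
    scaffold_sigma: float = 0.7  # log-normal shape; N50 = exp(mu + sigma^2)
    snp_per_kb: float = 10.4
    mean_depth: float = 2.26
    seq_error_rate: float = 0.01
    chimera_fraction: float = 0.0
    repeat_snp_fraction: float = 0.0
    artifact_lowqual_prob: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_lines", "n_chromosomes", "final_generation", "n_scaffolds"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name} must be an integer >= 1")
        if self.chrom_length_cM <= 0:
            raise ValueError("chrom_length_cM must be positive")
        if self.scaffold_n50_bp <= 0 or self.scaffold_sigma <= 0:
            raise ValueError("scaffold length parameters must be positive")
        if self.snp_per_kb <= 0 or self.mean_depth < 0:
            raise ValueError("snp_per_kb must be positive, mean_depth >= 0")
        for name in (
            "seq_error_rate",
            "chimera_fraction",
            "repeat_snp_fraction",
            "artifact_lowqual_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


# -- selfing arithmetic ------------------------------------------------------


def selfing_het_prob(generation: int) -> float:
    """Per-locus heterozygosity after selfing an F1 down to ``generation``.

    With F1 = generation 1 fully heterozygous, each round of selfing
    halves heterozygosity, so ``het = (1/2)**(generation - 1)``; AA and
    BB each carry probability ``(1 - het) / 2``.  At F6 this gives
    2/64 — the 31:2:31 segregation ratio.
    """
    if not isinstance(generation, (int, np.integer)) or isinstance(generation, bool):
        raise ValueError("generation must be an integer")
    if generation < 1:
        raise ValueError("generation must be >= 1 (F1 = 1)")
    return 0.5 ** (generation - 1)


# -- haplotypes --------------------------------------------------------------
# A haplotype over a binary-allele chromosome is stored as its starting
# allele plus the sorted positions (cM) where the allele switches.


@dataclass
class Haplotype:
    start_allele: int
    bounds: np.ndarray  # sorted switch positions in cM, within (0, L)

    def alleles_at(self, pos: np.ndarray | float) -> np.ndarray:
        pos = np.atleast_1d(np.asarray(pos, dtype=float))
        k = np.searchsorted(self.bounds, pos, side="right")
        return (self.start_allele + k) % 2


def _make_gamete(
    h0: Haplotype, h1: Haplotype, length_cM: float, rng: np.random.Generator
) -> tuple[Haplotype, np.ndarray]:
    """One meiotic product under the Haldane (no-interference) model."""
    n_xo = rng.poisson(length_cM / 100.0)
    xovers = np.sort(rng.uniform(0.0, length_cM, n_xo))
    start_chromatid = int(rng.integers(2))
    cand = np.unique(np.concatenate([[0.0], h0.bounds, h1.bounds, xovers]))
    # sample the gamete allele at the midpoint of each inter-candidate interval
    sample = (cand + np.append(cand[1:], length_cM)) / 2.0
    chromatid = (start_chromatid + np.searchsorted(xovers, sample, side="right")) % 2
    a0 = h0.alleles_at(sample)
    a1 = h1.alleles_at(sample)
    alleles = np.where(chromatid == 0, a0, a1)
    changes = np.nonzero(alleles[1:] != alleles[:-1])[0]
    bounds = cand[changes + 1]
    return Haplotype(int(alleles[0]), bounds), xovers


# -- ground truth ------------------------------------------------------------


@dataclass
class SimTruth:
    """Everything the simulator knows: the validation oracle for the pipeline."""

    config: SimConfig
    line_ids: list[str]
    #: ``haplotypes[line][chrom] = (Haplotype, Haplotype)`` at the final generation
    haplotypes: list[list[tuple[Haplotype, Haplotype]]]
    #: ``crossovers[line][chrom][generation-2]`` = concatenated crossover
    #: positions (cM) of the two gametes formed at that selfing
    crossovers: list[list[list[np.ndarray]]]
    #: BED-like scaffold pieces: scaffold, scaf_start, scaf_end (0-based
    #: half-open within the scaffold), chrom, chrom_start, chrom_end, strand
    scaffold_placements: pd.DataFrame | None = None
    scaffold_lengths: pd.Series | None = None
    #: SNP catalog: snp_id, scaffold, pos (1-based), chrom, chrom_bp, cM,
    #: ref, alt, is_repeat, shadow_chrom, shadow_cM
    snps: pd.DataFrame | None = None
    true_genotypes: np.ndarray | None = None  # (n_snps, n_lines) int8
    artifact_registry: dict = field(default_factory=dict)

    def genotypes_at(self, chrom: int, positions_cM: np.ndarray) -> np.ndarray:
        """True genotype codes (positions x lines) at cM positions on ``chrom``."""
        positions_cM = np.asarray(positions_cM, dtype=float)
        out = np.empty((len(positions_cM), len(self.line_ids)), dtype=np.int8)
        lut = np.array([GT_A, GT_H, GT_B], dtype=np.int8)
        for j in range(len(self.line_ids)):
            h0, h1 = self.haplotypes[j][chrom]
            out[:, j] = lut[h0.alleles_at(positions_cM) + h1.alleles_at(positions_cM)]
        return out

    def genotype_boundaries(self, line: int, chrom: int) -> np.ndarray:
        """cM positions where the line's diplotype state changes on ``chrom``."""
        h0, h1 = self.haplotypes[line][chrom]
        b = np.sort(np.concatenate([h0.bounds, h1.bounds]))
        states = self.genotypes_at(chrom, np.concatenate([[0.0], b + 1e-9]))[:, line]
        return b[np.nonzero(states[1:] != states[:-1])[0]]

    @property
    def bp_per_cM(self) -> np.ndarray:
        lengths = (
            self.scaffold_placements.groupby("chrom")["chrom_end"].max()
            .reindex(range(self.config.n_chromosomes), fill_value=0)
            .to_numpy()
        )
        return lengths / self.config.chrom_length_cM


def simulate_ril_population(config: SimConfig) -> SimTruth:
    """Simulate ``config.n_lines`` selfed RILs; deterministic given the seed."""
    root = np.random.SeedSequence(config.seed)
    rng_pop, _, _ = [np.random.default_rng(s) for s in root.spawn(3)]
    L = config.chrom_length_cM
    haplotypes: list[list[tuple[Haplotype, Haplotype]]] = []
    crossovers: list[list[list[np.ndarray]]] = []
    for _ in range(config.n_lines):
        line_haps = []
        line_xo = []
        for _ in range(config.n_chromosomes):
            h0 = Haplotype(0, np.empty(0))
            h1 = Haplotype(1, np.empty(0))
            gen_xo = []
            for _gen in range(2, config.final_generation + 1):
                g0, xo0 = _make_gamete(h0, h1, L, rng_pop)
                g1, xo1 = _make_gamete(h0, h1, L, rng_pop)
                h0, h1 = g0, g1
                gen_xo.append(np.sort(np.concatenate([xo0, xo1])))
            line_haps.append((h0, h1))
            line_xo.append(gen_xo)
        haplotypes.append(line_haps)
        crossovers.append(line_xo)
    line_ids = [f"RIL{j + 1:03d}" for j in range(config.n_lines)]
    return SimTruth(config, line_ids, haplotypes, crossovers)


# -- assembly ----------------------------------------------------------------

_BASES = np.array(list("ACGT"))
# the 12 ordered distinct base pairs, drawn uniformly
_PAIRS = [(r, a) for r in "ACGT" for a in "ACGT" if r != a]


def simulate_assembly(truth: SimTruth, config: SimConfig | None = None) -> SimTruth:
    """Fragment the chromosomes into scaffolds and drop SNPs onto them.

    Scaffold lengths are log-normal with ``N50 = exp(mu + sigma^2)``
    solved for the configured target.  Scaffolds are dealt round-robin
    onto chromosomes and tiled left to right.  A ``chimera_fraction`` of
    scaffolds have their right half replaced by a segment from a
    different chromosome; a ``repeat_snp_fraction`` of SNPs are assigned
    a second, unlinked shadow locus that later contributes reads.
    """
    config = config or truth.config
    root = np.random.SeedSequence(config.seed)
    _, rng_asm, _ = [np.random.default_rng(s) for s in root.spawn(3)]

    mu = np.log(config.scaffold_n50_bp) - config.scaffold_sigma**2
    lengths = np.maximum(
        rng_asm.lognormal(mu, config.scaffold_sigma, config.n_scaffolds).astype(np.int64),
        50,
    )
    scaf_ids = [f"scaffold_{i + 1:05d}" for i in range(config.n_scaffolds)]
    chrom_of = np.arange(config.n_scaffolds) % config.n_chromosomes
    starts = np.zeros(config.n_scaffolds, dtype=np.int64)
    offset = np.zeros(config.n_chromosomes, dtype=np.int64)
    for i in range(config.n_scaffolds):
        starts[i] = offset[chrom_of[i]]
        offset[chrom_of[i]] += lengths[i]

    # chimeras: replace the right half with a donor segment from another chrom
    n_chim = int(np.round(config.chimera_fraction * config.n_scaffolds))
    eligible = np.nonzero(lengths >= 200)[0]
    chim_idx = rng_asm.choice(eligible, size=min(n_chim, len(eligible)), replace=False)
    chim_set = set(int(i) for i in chim_idx)

    pieces = []
    for i in range(config.n_scaffolds):
        sid, ln, c, s = scaf_ids[i], int(lengths[i]), int(chrom_of[i]), int(starts[i])
        if i in chim_set:
            half = ln // 2
            donor_c = int((c + 1 + rng_asm.integers(config.n_chromosomes - 1)) % config.n_chromosomes)
            donor_len = int(offset[donor_c])
            donor_s = int(rng_asm.integers(0, max(donor_len - (ln - half), 1)))
            pieces.append((sid, 0, half, c, s, s + half, "+"))
            pieces.append((sid, half, ln, donor_c, donor_s, donor_s + (ln - half), "+"))
        else:
            pieces.append((sid, 0, ln, c, s, s + ln, "+"))
    placements = pd.DataFrame(
        pieces,
        columns=["scaffold", "scaf_start", "scaf_end", "chrom", "chrom_start", "chrom_end", "strand"],
    )
    truth.scaffold_placements = placements
    truth.scaffold_lengths = pd.Series(lengths, index=scaf_ids)
    bp_per_cM = truth.bp_per_cM

    # SNPs: binomial(length, density) per scaffold, uniform offsets
    p_snp = config.snp_per_kb / 1000.0
    if p_snp > 1.0:
        raise ValueError("snp_per_kb requests more SNPs than available sites")
    seg_lists: dict[str, list[tuple[int, int, int, int]]] = {}
    for t in placements.itertuples(index=False):
        seg_lists.setdefault(t.scaffold, []).append(
            (t.scaf_start, t.scaf_end, t.chrom, t.chrom_start)
        )
    rows = []
    for i, sid in enumerate(scaf_ids):
        ln = int(lengths[i])
        k = rng_asm.binomial(ln, p_snp)
        if k == 0:
            continue
        pos = np.sort(rng_asm.choice(ln, size=k, replace=False)) + 1  # 1-based
        for p in pos:
            for s0, s1, chrom, c0 in seg_lists[sid]:
                if s0 < p <= s1:
                    chrom_bp = c0 + (int(p) - 1 - s0)
                    break
            ref, alt = _PAIRS[rng_asm.integers(len(_PAIRS))]
            rows.append((sid, int(p), chrom, chrom_bp, chrom_bp / bp_per_cM[chrom], ref, alt))
    snps = pd.DataFrame(
        rows, columns=["scaffold", "pos", "chrom", "chrom_bp", "cM", "ref", "alt"]
    )
    snps.insert(0, "snp_id", np.arange(len(snps)))
    snps["cM"] = snps["cM"].clip(upper=config.chrom_length_cM - 1e-9)

    # repeat-derived SNPs: a shadow locus on a different chromosome
    n_rep = int(np.round(config.repeat_snp_fraction * len(snps)))
    rep_idx = rng_asm.choice(len(snps), size=n_rep, replace=False) if n_rep else np.empty(0, int)
    is_rep = np.zeros(len(snps), dtype=bool)
    is_rep[rep_idx] = True
    shadow_chrom = np.full(len(snps), -1, dtype=np.int64)
    shadow_cM = np.full(len(snps), np.nan)
    if n_rep:
        sc = (
            snps["chrom"].to_numpy()[rep_idx]
            + 1
            + rng_asm.integers(config.n_chromosomes - 1, size=n_rep)
        ) % config.n_chromosomes
        shadow_chrom[rep_idx] = sc
        shadow_cM[rep_idx] = rng_asm.uniform(0, config.chrom_length_cM, size=n_rep)
    snps["is_repeat"] = is_rep
    snps["shadow_chrom"] = shadow_chrom
    snps["shadow_cM"] = shadow_cM
    truth.snps = snps

    # true genotypes, evaluated chromosome by chromosome
    geno = np.empty((len(snps), len(truth.line_ids)), dtype=np.int8)
    for c in range(config.n_chromosomes):
        m = (snps["chrom"] == c).to_numpy()
        if m.any():
            geno[m] = truth.genotypes_at(c, snps.loc[m, "cM"].to_numpy())
    truth.true_genotypes = geno

    truth.artifact_registry = {
        "chimeric_scaffolds": {scaf_ids[i] for i in chim_set},
        "repeat_snps": snps.loc[is_rep, "snp_id"].to_numpy(),
    }
    return truth


# -- reads -------------------------------------------------------------------


def simulate_reads(truth: SimTruth, config: SimConfig | None = None) -> SNPReadMatrix:
    """Draw per-cell read counts: ``depth ~ Poisson(mean_depth)`` per line.

    Reads report the true allele with probability ``1 - seq_error_rate``
    (heterozygotes emit each allele with probability 1/2 before error).
    Repeat-derived SNPs receive an extra Poisson(mean_depth) dose of
    reads from their shadow locus.  Site quality is the pass value
    except that artifact sites drop below it with probability
    ``artifact_lowqual_prob``.
    """
    config = config or truth.config
    if truth.snps is None:
        raise ValueError("simulate_assembly must run before simulate_reads")
    root = np.random.SeedSequence(config.seed)
    _, _, rng_reads = [np.random.default_rng(s) for s in root.spawn(3)]

    snps = truth.snps
    geno = truth.true_genotypes
    n_snps, n_lines = geno.shape
    e = config.seq_error_rate
    p_alt_by_code = np.array([e, 0.5, 1.0 - e])  # indexed by GT code

    depth = rng_reads.poisson(config.mean_depth, size=(n_snps, n_lines))
    n_alt = rng_reads.binomial(depth, p_alt_by_code[geno])
    n_ref = depth - n_alt

    rep = snps["is_repeat"].to_numpy()
    if rep.any():
        rep_rows = np.nonzero(rep)[0]
        shadow_geno = np.empty((len(rep_rows), n_lines), dtype=np.int8)
        sc = snps["shadow_chrom"].to_numpy()[rep_rows]
        s_cm = snps["shadow_cM"].to_numpy()[rep_rows]
        for c in np.unique(sc):
            m = sc == c
            shadow_geno[m] = truth.genotypes_at(int(c), s_cm[m])
        extra = rng_reads.poisson(config.mean_depth, size=(len(rep_rows), n_lines))
        extra_alt = rng_reads.binomial(extra, p_alt_by_code[shadow_geno])
        n_alt[rep_rows] += extra_alt
        n_ref[rep_rows] += extra - extra_alt

    qual = np.full(n_snps, QUAL_PASS, dtype=np.int64)
    if rep.any() and config.artifact_lowqual_prob > 0:
        drop = rng_reads.random(int(rep.sum())) < config.artifact_lowqual_prob
        qual[np.nonzero(rep)[0][drop]] = QUAL_PASS - 1

    sites = pd.DataFrame(
        {
            "scaffold": snps["scaffold"].to_numpy(),
            "pos": snps["pos"].to_numpy(),
            "ref": snps["ref"].to_numpy(),
            "alt": snps["alt"].to_numpy(),
            "qual": qual,
        }
    )
    return SNPReadMatrix(sites=sites, line_ids=list(truth.line_ids), n_ref=n_ref, n_alt=n_alt)


def simulate(config: SimConfig) -> tuple[SimTruth, SNPReadMatrix]:
    """Run the three simulation stages end to end."""
    truth = simulate_ril_population(config)
    simulate_assembly(truth, config)
    reads = simulate_reads(truth, config)
    return truth, reads
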