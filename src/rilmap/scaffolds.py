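"""Scaffold-level consensus haplotypes, breakpoints and chimera detection.

Merging the SNPs of a scaffold into a per-line consensus genotype is
what makes ~2x coverage usable: individual SNP calls miss heterozygotes
and carry sequencing error, but across tens of SNPs the scaffold's state
is unambiguous.  A heterozygous region manifests either as explicit H
calls or as an apparent mixture of A and B calls at low depth, so the
consensus rule accepts both signals.

Within-scaffold recombination breakpoints are located by the run rule:
three or more consecutive SNPs of one homozygous genotype immediately
followed by three or more of the other.  Runs are broken by an H call
but not by missing calls — heterozygous/homozygous transitions cannot be
placed precisely at this coverage and are left to the between-scaffold
map.  Scaffolds whose SNPs map to two linkage groups (or far apart on
one) are flagged as chimeric mis-assemblies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genotypes import GT_A, GT_B, GT_H, GT_MISS

# -- consensus ---------------------------------------------------------------


def consensus_from_counts(
    n_a: np.ndarray,
    n_h: np.ndarray,
    n_b: np.ndarray,
    het_fraction_min: float = 0.25,
) -> np.ndarray:
    """Vectorised consensus rule from per-line A/H/B support counts.

    Per line: missing if no called SNPs; H if ``n_h >= max(n_a, n_b)``
    or ``min(n_a, n_b) >= het_fraction_min * called`` (boundary
    inclusive); otherwise the majority homozygote, with exact A/B ties
    resolved to missing.
    """
    n_a = np.asarray(n_a)
    n_h = np.asarray(n_h)
    n_b = np.asarray(n_b)
    called = n_a + n_h + n_b
    out = np.full(n_a.shape, GT_MISS, dtype=np.int8)
    has = called > 0
    is_h = has & (
        (n_h >= np.maximum(n_a, n_b))
        | (np.minimum(n_a, n_b) >= het_fraction_min * called)
    )
    out[is_h] = GT_H
    out[has & ~is_h & (n_a > n_b)] = GT_A
    out[has & ~is_h & (n_b > n_a)] = GT_B
    return out


@dataclass
class ScaffoldHaplotype:
    """Per-line consensus genotype for one scaffold with SNP support."""

    scaffold: str
    consensus: np.ndarray  # (n_lines,) int8
    n_snps: int
    support: np.ndarray  # (n_lines, 4): nA, nH, nB, n_missing
    chimeric: bool = False
    has_breakpoint: bool = False


def scaffold_consensus(
    calls: np.ndarray,
    scaffold: str = "",
    het_fraction_min: float = 0.25,
) -> ScaffoldHaplotype:
    """Collapse a ``(n_snps, n_lines)`` calls block into one consensus row."""
    calls = np.atleast_2d(np.asarray(calls))
    if calls.shape[0] < 1:
        raise ValueError("scaffold must carry at least one SNP")
    n_a = (calls == GT_A).sum(axis=0)
    n_h = (calls == GT_H).sum(axis=0)
    n_b = (calls == GT_B).sum(axis=0)
    n_miss = (calls == GT_MISS).sum(axis=0)
    consensus = consensus_from_counts(n_a, n_h, n_b, het_fraction_min)
    return ScaffoldHaplotype(
        scaffold=scaffold,
        consensus=consensus,
        n_snps=calls.shape[0],
        support=np.stack([n_a, n_h, n_b, n_miss], axis=1),
    )


# -- breakpoints -------------------------------------------------------------


@dataclass
class Breakpoint:
    """A homozygote-to-homozygote transition localised within a scaffold.

    ``start``/``end`` are the 1-based positions of the last SNP of the
    first run and the first SNP of the second run.
    """

    scaffold: str
    line_id: str
    start: int
    end: int
    transition: str  # "A->B" or "B->A"
    flank_seq: str | None = None
    clipped: bool = False


def _line_breakpoints(
    states: np.ndarray, positions: np.ndarray, min_run: int
) -> list[tuple[int, int, str]]:
    """Run-rule scan of one line's homozygous calls (H breaks runs)."""
    keep = states != GT_MISS
    st = states[keep]
    pos = positions[keep]
    out = []
    # split at H calls; within each H-free block find A/B run transitions
    blocks = np.split(np.arange(len(st)), np.nonzero(st == GT_H)[0])
    for block in blocks:
        block = block[st[block] != GT_H]
        if len(block) < 2 * min_run:
            continue
        s = st[block]
        # run-length encode
        change = np.nonzero(s[1:] != s[:-1])[0] + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(s)]])
        for r in range(len(starts) - 1):
            left = ends[r] - starts[r]
            right = ends[r + 1] - starts[r + 1]
            if left >= min_run and right >= min_run:
                i_last = block[ends[r] - 1]
                i_first = block[starts[r + 1]]
                trans = "A->B" if s[starts[r]] == GT_A else "B->A"
                out.append((int(pos[i_last]), int(pos[i_first]), trans))
    return out


def detect_breakpoints(
    calls: np.ndarray,
    positions: Sequence[int],
    line_ids: Sequence[str],
    scaffold: str = "",
    template=None,
    placement=None,
    min_run: int = 3,
) -> list[Breakpoint]:
    """Find within-scaffold crossovers supported by the run rule.

    ``calls`` is ``(n_snps, n_lines)`` ordered by ``positions`` (1-based,
    strictly increasing).  When a ``template`` (a built
    :class:`~rilmap.template_map.TemplateMap`) and the scaffold's
    ``placement`` on it are supplied, only breakpoints for lines in
    which the template predicts a crossover across the scaffold's map
    window are retained; with ``template=None`` every run-rule hit is
    reported.
    """
    positions = np.asarray(positions)
    if (np.diff(positions) <= 0).any():
        raise ValueError("SNP positions must be strictly increasing")
    calls = np.atleast_2d(np.asarray(calls))
    out: list[Breakpoint] = []
    for j, line_id in enumerate(line_ids):
        hits = _line_breakpoints(calls[:, j], positions, min_run)
        if hits and template is not None and placement is not None:
            if not _template_predicts_crossover(template, placement, j):
                continue
        for start, end, trans in hits:
            out.append(Breakpoint(scaffold, str(line_id), start, end, trans))
    return out


def _template_predicts_crossover(template, placement, line: int) -> bool:
    """Does the template show a direct hom<->hom change for this line around
    the scaffold's placement window (extended one position each side)?

    Missing template calls are skipped, but an intervening H position
    vetoes corroboration: the template then says the region is
    heterozygous in this line, and a crossover there cannot be placed
    between individual SNPs.
    """
    group = template.groups[placement.group]
    lo = max(placement.pos_lo - 1, 0)
    hi = min(placement.pos_hi + 1, len(group.patterns) - 1)
    states = group.patterns[lo : hi + 1, line]
    states = states[states != GT_MISS]
    return bool(
        len(states) >= 2
        and (
            ((states[:-1] == GT_A) & (states[1:] == GT_B))
            | ((states[:-1] == GT_B) & (states[1:] == GT_A))
        ).any()
    )


# -- chimeras ----------------------------------------------------------------


@dataclass
class ChimeraEvidence:
    chimeric: bool
    reason: str  # "two_groups", "distant_on_group", or ""
    clusters: list[tuple[int, int]] = field(default_factory=list)  # (group, n SNPs)


def detect_chimeras(
    snp_groups: Sequence[int],
    snp_positions: Sequence[int] | None = None,
    adjacent_events: Mapping[int, np.ndarray] | None = None,
    snp_positions_hi: Sequence[int] | None = None,
    min_snps_per_side: int = 5,
    max_event_distance: int = 10,
) -> ChimeraEvidence:
    """Flag a scaffold as mis-assembled from its SNPs' template placements.

    ``snp_groups`` gives each placed SNP's linkage group (-1 for
    unplaced), ``snp_positions`` its position index within that group
    (``snp_positions_hi`` the upper end of a tie window, if any).  A
    scaffold is chimeric when at least ``min_snps_per_side`` SNPs fall
    on each of two groups, or when two clusters of that size on one
    group are separated by more than ``max_event_distance``
    recombination events (``adjacent_events[g][i]`` = events between
    template positions i and i+1 of group g).  Event distances between
    clusters are taken between the closest window edges, so an
    ambiguous placement never inflates the separation.
    """
    groups = np.asarray(snp_groups)
    placed = groups >= 0
    uniq, counts = np.unique(groups[placed], return_counts=True)
    big = counts >= min_snps_per_side
    if big.sum() >= 2:
        order = np.argsort(-counts[big])
        clusters = [(int(uniq[big][k]), int(counts[big][k])) for k in order[:2]]
        return ChimeraEvidence(True, "two_groups", clusters)
    if snp_positions is not None and adjacent_events is not None and big.sum() == 1:
        g = int(uniq[big][0])
        sel = placed & (groups == g)
        lo = np.asarray(snp_positions)[sel]
        hi = lo if snp_positions_hi is None else np.asarray(snp_positions_hi)[sel]
        order = np.argsort((lo + hi) / 2, kind="mergesort")
        lo, hi = lo[order], hi[order]
        ev = np.asarray(adjacent_events[g])
        cum = np.concatenate([[0], np.cumsum(ev)])
        for k in range(min_snps_per_side, len(lo) - min_snps_per_side + 1):
            left_edge = int(hi[:k].max())
            right_edge = int(lo[k:].min())
            # clusters in the same or adjacent bins span at most one
            # recombination interval — which a contiguous scaffold can
            # legitimately do (that is a breakpoint, not a mis-assembly)
            if right_edge - left_edge < 2:
                continue
            if cum[right_edge] - cum[left_edge] > max_event_distance:
                return ChimeraEvidence(
                    True, "distant_on_group", [(g, int(k)), (g, int(len(lo) - k))]
                )
    return ChimeraEvidence(False, "")


# -- breakpoint sequence context ---------------------------------------------


@dataclass
class BreakpointContext:
    sequence: str
    start: int  # 1-based inclusive, after clipping
    end: int
    clipped_left: bool
    clipped_right: bool


def extract_breakpoint_context(
    assembly: Mapping[str, str], bp: Breakpoint, flank: int = 200
) -> BreakpointContext:
    """Extract the breakpoint interval plus ``flank`` bp on each side.

    ``assembly`` maps scaffold id to sequence (a plain dict or an
    indexed FASTA such as ``pyfaidx.Fasta`` both work).  Coordinates are
    1-based inclusive and clipped at scaffold ends; clipping is
    reported.
    """
    if bp.scaffold not in assembly:
        raise KeyError(f"scaffold {bp.scaffold!r} not present in assembly")
    seq = str(assembly[bp.scaffold][:])
    n = len(seq)
    start = bp.start - flank
    end = bp.end + flank
    clipped_left = start < 1
    clipped_right = end > n
    start = max(start, 1)
    end = min(end, n)
    return BreakpointContext(
        sequence=seq[start - 1 : end],
        start=start,
        end=end,
        clipped_left=clipped_left,
        clipped_right=clipped_right,
    )
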