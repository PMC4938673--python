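"""Template genetic map: cluster, order and iteratively refine patterns.

A *segregation pattern* is the vector of genotypes across all lines at
one map position; identical patterns are genetically indistinguishable,
so the map is an ordered catalog of unique patterns per linkage group (the
*template*).  With ultradense markers most adjacent patterns differ by a
single recombination event, so the best order is the one minimising the
total number of adjacent recombination events — an open-path TSP solved
here with greedy nearest-neighbour construction from multiple starts
followed by 2-opt improvement.

Pattern comparison uses the heterozygote-matching rule: an H (or
missing) call matches anything, so only opposite homozygotes (A vs B)
count as differences.  Individual SNPs more than ``max_mismatch``
differences from every template position are discarded as anomalous —
this is the map-level filter that removes repeat-derived and chimeric
markers that survived the site-level filters.

The build is iterative: an initial template from SNP-rich scaffolds
(> ``init_min_snps``) filters all SNPs; scaffold consensus genotypes are
recomputed from surviving SNPs; the scaffold SNP threshold is lowered
stepwise to ``final_min_snps`` and the cluster/order/place cycle repeats
until the template stops changing or ``max_iterations`` is reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .genotypes import GT_A, GT_B, GT_H, GT_MISS, GenotypeMatrix, encode_calls
from .scaffolds import consensus_from_counts

CM_CONVENTIONS = ("raw_R", "half_R", "haldane_waller")


# -- configuration -----------------------------------------------------------


@dataclass
class MapBuildConfig:
    """Knobs of the iterative template-map build.

    ``cm_convention`` converts the observed recombinant fraction R of an
    adjacent interval into map distance: ``raw_R`` = 100R, ``half_R`` =
    50R (divide-by-two correction for selfed-RIL map expansion; the
    default), ``haldane_waller`` = 100R / (2(1-R)).
    """

    init_min_snps: int = 50
    final_min_snps: int = 5
    max_mismatch: int = 6
    max_iterations: int = 15
    linkage_threshold: float = 0.20
    cm_convention: str = "half_R"
    het_fraction_min: float = 0.25
    #: consensus haplotype patterns heterozygous in more than this fraction
    #: of called lines are excluded from template construction — the same
    #: multi-copy guard applied to individual SNPs, here protecting the map
    #: from chimeric/repeat scaffolds whose blended consensus would bridge
    #: linkage groups
    pattern_max_het_fraction: float = 0.15

    def __post_init__(self) -> None:
        if not self.init_min_snps >= self.final_min_snps >= 1:
            raise ValueError("need init_min_snps >= final_min_snps >= 1")
        if self.max_mismatch < 0 or self.max_iterations < 1:
            raise ValueError("max_mismatch >= 0 and max_iterations >= 1 required")
        if self.cm_convention not in CM_CONVENTIONS:
            raise ValueError(f"cm_convention must be one of {CM_CONVENTIONS}")


# -- pattern arithmetic ------------------------------------------------------


def _as_pattern(p) -> np.ndarray:
    if isinstance(p, str):
        return encode_calls(p)
    return np.asarray(p, dtype=np.int8)


def pattern_distance(p, q) -> int:
    """Lines where one pattern is A and the other B; H/missing match anything."""
    p = _as_pattern(p)
    q = _as_pattern(q)
    if p.shape != q.shape:
        raise ValueError("patterns must have equal length")
    return int(
        (((p == GT_A) & (q == GT_B)) | ((p == GT_B) & (q == GT_A))).sum()
    )


def _opposite_matrix(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Pairwise opposite-homozygote counts between pattern rows (float32 matmul)."""
    pa = (P == GT_A).astype(np.float32)
    pb = (P == GT_B).astype(np.float32)
    qa = (Q == GT_A).astype(np.float32)
    qb = (Q == GT_B).astype(np.float32)
    return (pa @ qb.T + pb @ qa.T).astype(np.int64)


def _informative_matrix(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Pairwise counts of lines homozygous in both patterns."""
    ph = ((P == GT_A) | (P == GT_B)).astype(np.float32)
    qh = ((Q == GT_A) | (Q == GT_B)).astype(np.float32)
    return (ph @ qh.T).astype(np.int64)


# -- linkage-group clustering ------------------------------------------------


def cluster_linkage_groups(
    patterns: np.ndarray, linkage_threshold: float = 0.20
) -> list[np.ndarray]:
    """Single-linkage clustering on recombination fraction.

    The pairwise fraction is opposite-homozygote count over
    both-homozygous line count (1.0 when no line is informative in
    both).  Returns index groups sorted by decreasing size (ties by
    first member).
    """
    patterns = np.atleast_2d(_as_pattern(patterns))
    n = patterns.shape[0]
    if n < 1:
        raise ValueError("need at least one pattern")
    if n == 1:
        return [np.array([0])]
    d = _opposite_matrix(patterns, patterns).astype(float)
    inf = _informative_matrix(patterns, patterns)
    rf = np.where(inf > 0, d / np.maximum(inf, 1), 1.0)
    np.fill_diagonal(rf, 0.0)
    z = linkage(squareform(rf, checks=False), method="single")
    labels = fcluster(z, t=linkage_threshold, criterion="distance")
    groups = [np.nonzero(labels == lab)[0] for lab in np.unique(labels)]
    groups.sort(key=lambda g: (-len(g), int(g[0])))
    return groups


# -- minimum-recombination ordering ------------------------------------------


def _path_cost(D: np.ndarray, order: np.ndarray) -> int:
    return int(D[order[:-1], order[1:]].sum())


def _greedy_path(D: np.ndarray, start: int) -> np.ndarray:
    n = D.shape[0]
    visited = np.zeros(n, dtype=bool)
    order = np.empty(n, dtype=np.int64)
    order[0] = start
    visited[start] = True
    for k in range(1, n):
        row = D[order[k - 1]].astype(float)
        row[visited] = np.inf
        order[k] = int(np.argmin(row))  # ties break to the lowest index
        visited[order[k]] = True
    return order


def _two_opt(D: np.ndarray, order: np.ndarray) -> np.ndarray:
    """2-opt for an open path: reverse ``order[i:j+1]`` while it helps.

    Each step evaluates every (i, j) move at once with numpy and applies
    the steepest improving reversal (deterministic tie-break via argmin),
    iterating to a local optimum.
    """
    order = order.copy()
    n = len(order)
    if n < 3:
        return order
    idx = np.arange(n)
    has_prev = (idx > 0).astype(float)[:, None]  # i has an edge (i-1, i)
    has_next = (idx < n - 1).astype(float)[None, :]  # j has an edge (j, j+1)
    upper = idx[:, None] < idx[None, :]
    while True:
        P = D[np.ix_(order, order)].astype(float)
        pm1 = P[np.maximum(idx - 1, 0)]  # pm1[i, j] = D(prev(i), j)
        pp1 = P[:, np.minimum(idx + 1, n - 1)]  # pp1[i, j] = D(i, next(j))
        old_left = np.diag(pm1)[:, None]  # D(prev(i), i)
        old_right = np.diag(pp1)[None, :]  # D(j, next(j))
        delta = (
            has_prev * (pm1 - old_left)  # new edge (prev(i), j) minus old (prev(i), i)
            + has_next * (pp1 - old_right)  # new edge (i, next(j)) minus old (j, next(j))
        )
        delta = np.where(upper, delta, np.inf)
        k = int(np.argmin(delta))
        i, j = divmod(k, n)
        if delta[i, j] >= 0:
            break
        order[i : j + 1] = order[i : j + 1][::-1]
    return order


def _or_opt(D: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Relocate short segments (length 1-3, either orientation) while it
    lowers the path cost; insertion deltas are evaluated vectorised."""
    order = np.asarray(order)
    n = len(order)
    improved = True
    while improved:
        improved = False
        for seg_len in (1, 2, 3):
            if seg_len >= n:
                continue
            i = 0
            while i + seg_len <= len(order):
                o = order
                seg = o[i : i + seg_len]
                rest = np.concatenate([o[:i], o[i + seg_len :]])
                prev = o[i - 1] if i > 0 else -1
                nxt = o[i + seg_len] if i + seg_len < len(o) else -1
                removal = (
                    (D[prev, seg[0]] if prev >= 0 else 0)
                    + (D[seg[-1], nxt] if nxt >= 0 else 0)
                    - (D[prev, nxt] if prev >= 0 and nxt >= 0 else 0)
                )
                a = np.concatenate([[-1], rest])  # left neighbour per slot
                b = np.concatenate([rest, [-1]])  # right neighbour per slot
                am, bm = np.maximum(a, 0), np.maximum(b, 0)
                d_a0 = np.where(a >= 0, D[am, seg[0]], 0)
                d_a1 = np.where(a >= 0, D[am, seg[-1]], 0)
                d_0b = np.where(b >= 0, D[seg[0], bm], 0)
                d_1b = np.where(b >= 0, D[seg[-1], bm], 0)
                d_ab = np.where((a >= 0) & (b >= 0), D[am, bm], 0)
                delta_fwd = d_a0 + d_1b - d_ab - removal
                delta_rev = d_a1 + d_0b - d_ab - removal
                jf = int(np.argmin(delta_fwd))
                jr = int(np.argmin(delta_rev))
                if delta_fwd[jf] <= delta_rev[jr]:
                    dbest, jbest, rev = delta_fwd[jf], jf, False
                else:
                    dbest, jbest, rev = delta_rev[jr], jr, True
                if dbest < 0:
                    seg2 = seg[::-1] if rev else seg
                    order = np.concatenate([rest[:jbest], seg2, rest[jbest:]])
                    improved = True
                else:
                    i += 1
    return order


def order_patterns(patterns: np.ndarray, n_starts: int = 10) -> np.ndarray:
    """Order patterns to minimise total adjacent recombination events.

    Greedy nearest-neighbour paths from up to ``n_starts`` evenly spaced
    start indices, each improved by alternating 2-opt and or-opt
    (segment relocation) to a local optimum; the best path wins
    (deterministic given the input order).  Returns the index order;
    the achieved total is never worse than greedy alone.  The
    orientation is canonicalised so the lexicographically smaller
    endpoint pattern comes first.
    """
    patterns = np.atleast_2d(_as_pattern(patterns))
    n = patterns.shape[0]
    if n == 1:
        return np.array([0])
    D = _opposite_matrix(patterns, patterns)
    starts = np.unique(np.linspace(0, n - 1, min(n_starts, n)).astype(int))
    best: np.ndarray | None = None
    best_cost = np.inf
    for s in starts:
        order = _two_opt(D, _greedy_path(D, int(s)))
        while True:
            cost = _path_cost(D, order)
            order = _two_opt(D, _or_opt(D, order))
            if _path_cost(D, order) >= cost:
                break
        cost = _path_cost(D, order)
        if cost < best_cost:
            best, best_cost = order, cost
    first = patterns[best[0]].tobytes()
    last = patterns[best[-1]].tobytes()
    if last < first:
        best = best[::-1]
    return best


# -- placement on the template ----------------------------------------------


@dataclass
class Placement:
    group: int
    pos_lo: int
    pos_hi: int
    mismatches: int
    rejected: bool = False


@dataclass
class LinkageGroup:
    patterns: np.ndarray  # (n_positions, n_lines) int8
    cm: np.ndarray | None = None
    snp_counts: np.ndarray | None = None
    scaffolds: list[list[str]] = field(default_factory=list)

    @property
    def n_positions(self) -> int:
        return self.patterns.shape[0]

    def adjacent_recombinants(self) -> tuple[np.ndarray, np.ndarray]:
        """(recombinant lines, scored lines) per adjacent position pair."""
        a, b = self.patterns[:-1], self.patterns[1:]
        scored = (a != GT_MISS) & (b != GT_MISS)
        changed = scored & (a != b)
        return changed.sum(axis=1), scored.sum(axis=1)

    def adjacent_events(self) -> np.ndarray:
        return self.adjacent_recombinants()[0]


@dataclass
class TemplateMap:
    groups: list[LinkageGroup]
    line_ids: list[str]
    cm_convention: str = "half_R"

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def all_patterns(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Concatenated patterns with parallel (group, position) arrays."""
        pats = np.concatenate([g.patterns for g in self.groups], axis=0)
        gidx = np.concatenate(
            [np.full(g.n_positions, i) for i, g in enumerate(self.groups)]
        )
        pidx = np.concatenate([np.arange(g.n_positions) for g in self.groups])
        return pats, gidx, pidx


def place_patterns(
    patterns: np.ndarray, template: TemplateMap, max_mismatch: int = 6
) -> list[Placement]:
    """Place each query pattern at its best-matching template position(s).

    A query farther than ``max_mismatch`` from every position is
    rejected as anomalous.  Ties are resolved to the group holding the
    most tying positions (then the lowest group index) and reported as
    the smallest enclosing position window within that group.
    """
    if not template.groups:
        raise ValueError("template is empty")
    patterns = np.atleast_2d(_as_pattern(patterns))
    rows, gidx, pidx = template.all_patterns()
    D = _opposite_matrix(patterns, rows)
    out: list[Placement] = []
    dmin = D.min(axis=1)
    for i in range(patterns.shape[0]):
        d = int(dmin[i])
        if d > max_mismatch:
            out.append(Placement(-1, -1, -1, d, rejected=True))
            continue
        ties = np.nonzero(D[i] == d)[0]
        tie_groups, tie_counts = np.unique(gidx[ties], return_counts=True)
        g = int(tie_groups[np.argmax(tie_counts)])
        pos = pidx[ties[gidx[ties] == g]]
        out.append(Placement(g, int(pos.min()), int(pos.max()), d))
    return out


def place_snp_on_template(
    pattern, template: TemplateMap, max_mismatch: int = 6
) -> Placement:
    """Single-pattern convenience wrapper around :func:`place_patterns`."""
    return place_patterns(np.atleast_2d(_as_pattern(pattern)), template, max_mismatch)[0]


# -- genetic distances -------------------------------------------------------


def genetic_positions(template: TemplateMap, convention: str | None = None) -> list[np.ndarray]:
    """Cumulative cM coordinates per group from adjacent recombinant fractions."""
    convention = convention or template.cm_convention
    if convention not in CM_CONVENTIONS:
        raise ValueError(f"unknown cM convention {convention!r}")
    out = []
    for g in template.groups:
        rec, scored = g.adjacent_recombinants()
        r = np.where(scored > 0, rec / np.maximum(scored, 1), 0.0)
        if convention == "raw_R":
            d = 100.0 * r
        elif convention == "half_R":
            d = 50.0 * r
        else:  # haldane_waller
            d = 100.0 * r / (2.0 * np.maximum(1.0 - r, 1e-12))
        cm = np.concatenate([[0.0], np.cumsum(d)])
        g.cm = cm
        out.append(cm)
    return out


# -- pattern collapsing ------------------------------------------------------


def collapse_patterns(
    patterns: np.ndarray, ids: Sequence[str] | None = None
) -> tuple[np.ndarray, list[list[int]]]:
    """Merge indistinguishable patterns (missing acts as a wildcard).

    Two patterns merge only if no line shows opposite homozygotes and at
    least one line is called in both.  Patterns are processed from most
    to least informative; representatives absorb members' calls at their
    missing lines.  Returns the representative matrix and member index
    lists.
    """
    patterns = np.atleast_2d(_as_pattern(patterns))
    n_called = (patterns != GT_MISS).sum(axis=1)
    order = np.lexsort((np.arange(len(patterns)), -n_called))
    reps: list[np.ndarray] = []
    members: list[list[int]] = []
    for idx in order:
        p = patterns[idx]
        hit = None
        for r, rep in enumerate(reps):
            both = (rep != GT_MISS) & (p != GT_MISS)
            if not both.any():
                continue
            opp = ((rep == GT_A) & (p == GT_B)) | ((rep == GT_B) & (p == GT_A))
            if opp.any():
                continue
            hit = r
            break
        if hit is None:
            reps.append(p.copy())
            members.append([int(idx)])
        else:
            rep = reps[hit]
            fill = (rep == GT_MISS) & (p != GT_MISS)
            rep[fill] = p[fill]
            members[hit].append(int(idx))
    return np.array(reps, dtype=np.int8), members


# -- the iterative build -----------------------------------------------------


@dataclass
class MapBuildResult:
    template: TemplateMap
    scaffold_placements: pd.DataFrame  # scaffold, group, pos_lo/hi, cm_lo/hi, n_snps
    snp_placements: list[Placement]
    rejected_snps: np.ndarray  # bool mask over the input sites
    iterations: int
    converged: bool
    #: per-iteration audit: threshold, n_groups, n_patterns, total_cm, n_rejected
    history: list[dict] = field(default_factory=list)


def _threshold_schedule(cfg: MapBuildConfig) -> list[int]:
    n_desc = max(1, cfg.max_iterations - 5)
    desc = np.unique(
        np.geomspace(cfg.init_min_snps, cfg.final_min_snps, n_desc).round().astype(int)
    )[::-1]
    tail = [cfg.final_min_snps] * (cfg.max_iterations - len(desc))
    return list(desc) + tail


def _scaffold_counts(calls: np.ndarray, scaf_idx: np.ndarray, n_scaf: int):
    """Per-scaffold, per-line counts of A/H/B/missing calls."""
    n_lines = calls.shape[1]
    counts = np.zeros((4, n_scaf, n_lines), dtype=np.int32)
    for k, code in enumerate((GT_A, GT_H, GT_B, GT_MISS)):
        np.add.at(counts[k], scaf_idx, (calls == code).astype(np.int32))
    return counts


def build_template_map(
    genotypes: GenotypeMatrix, cfg: MapBuildConfig | None = None
) -> MapBuildResult:
    """Run the iterative cluster / order / place / refilter cycle."""
    cfg = cfg or MapBuildConfig()
    calls = genotypes.calls
    scaffolds = genotypes.sites["scaffold"].to_numpy()
    scaf_ids, scaf_idx = np.unique(scaffolds, return_inverse=True)
    n_scaf = len(scaf_ids)
    total_per_scaf = np.bincount(scaf_idx, minlength=n_scaf)
    if total_per_scaf.max() < cfg.init_min_snps:
        raise ValueError(
            f"no scaffold carries >= {cfg.init_min_snps} SNPs; "
            "lower init_min_snps or supply denser data"
        )

    surviving = np.ones(len(calls), dtype=bool)
    template: TemplateMap | None = None
    placements: list[Placement] = []
    history: list[dict] = []
    prev_state = None
    iterations = 0
    converged = False
    for thr in _threshold_schedule(cfg):
        iterations += 1
        # consensus per scaffold from surviving SNPs; scaffolds whose SNPs
        # are all currently rejected fall back to all of their SNPs so the
        # region can re-enter the map later
        surv_calls = np.where(surviving[:, None], calls, GT_MISS)
        counts_surv = _scaffold_counts(surv_calls, scaf_idx, n_scaf)
        counts_all = _scaffold_counts(calls, scaf_idx, n_scaf)
        n_surv = np.bincount(scaf_idx, weights=surviving).astype(int)
        use_all = n_surv == 0
        counts = np.where(use_all[None, :, None], counts_all, counts_surv)
        eligible = np.maximum(n_surv, np.where(use_all, total_per_scaf, 0)) >= thr
        if not eligible.any():
            continue
        cons = consensus_from_counts(
            counts[0][eligible], counts[1][eligible], counts[2][eligible],
            cfg.het_fraction_min,
        )
        # the haplotype-level multi-copy guard: heterozygosity above the cap
        # marks a blended (chimeric/repeat) consensus, not a real locus
        n_het = (cons == GT_H).sum(axis=1)
        n_called = (cons != GT_MISS).sum(axis=1)
        ok = n_het <= cfg.pattern_max_het_fraction * np.maximum(n_called, 1)
        if not ok.any():
            continue
        reps, _members = collapse_patterns(cons[ok])
        group_idx = cluster_linkage_groups(reps, cfg.linkage_threshold)
        groups = []
        for gi in group_idx:
            pats = reps[gi]
            order = order_patterns(pats)
            groups.append(LinkageGroup(patterns=pats[order]))
        template = TemplateMap(groups, list(genotypes.line_ids), cfg.cm_convention)
        placements = place_patterns(calls, template, cfg.max_mismatch)
        surviving = np.array([not p.rejected for p in placements])
        cms = genetic_positions(template)
        history.append(
            {
                "threshold": int(thr),
                "n_groups": len(groups),
                "n_patterns": int(sum(g.n_positions for g in groups)),
                "total_cm": float(sum(c[-1] for c in cms)),
                "n_rejected": int((~surviving).sum()),
            }
        )
        state = (
            tuple(g.patterns.tobytes() for g in groups),
            surviving.tobytes(),
        )
        if state == prev_state:
            converged = True
            break
        prev_state = state
    if template is None:
        raise ValueError("template construction produced no linkage groups")

    genetic_positions(template)
    scaffold_rows = _place_scaffolds(
        calls, surviving, scaf_idx, scaf_ids, template, cfg
    )
    return MapBuildResult(
        template=template,
        scaffold_placements=scaffold_rows,
        snp_placements=placements,
        rejected_snps=~surviving,
        iterations=iterations,
        converged=converged,
        history=history,
    )


def _place_scaffolds(calls, surviving, scaf_idx, scaf_ids, template, cfg):
    """Final per-scaffold consensus placement plus per-position tallies."""
    n_scaf = len(scaf_ids)
    surv_calls = np.where(surviving[:, None], calls, GT_MISS)
    counts = _scaffold_counts(surv_calls, scaf_idx, n_scaf)
    n_surv = np.bincount(scaf_idx, weights=surviving).astype(int)
    for g in template.groups:
        g.snp_counts = np.zeros(g.n_positions, dtype=np.int64)
        g.scaffolds = [[] for _ in range(g.n_positions)]
    rows = []
    eligible = np.nonzero(n_surv >= cfg.final_min_snps)[0]
    if len(eligible):
        cons = consensus_from_counts(
            counts[0][eligible], counts[1][eligible], counts[2][eligible],
            cfg.het_fraction_min,
        )
        placed = place_patterns(cons, template, cfg.max_mismatch)
        for k, si in enumerate(eligible):
            p = placed[k]
            if p.rejected:
                continue
            g = template.groups[p.group]
            rows.append(
                (
                    scaf_ids[si],
                    p.group,
                    p.pos_lo,
                    p.pos_hi,
                    float(g.cm[p.pos_lo]),
                    float(g.cm[p.pos_hi]),
                    int(n_surv[si]),
                    p.mismatches,
                )
            )
            g.snp_counts[p.pos_lo] += int(n_surv[si])
            g.scaffolds[p.pos_lo].append(str(scaf_ids[si]))
    return pd.DataFrame(
        rows,
        columns=[
            "scaffold", "group", "pos_lo", "pos_hi",
            "cm_lo", "cm_hi", "n_snps", "mismatches",
        ],
    )


# -- the event ledger --------------------------------------------------------


@dataclass
class EventLedger:
    total: int
    hom_hom: int
    hom_het: int
    per_group_adjacent: list[np.ndarray]  # recombinant lines per adjacent pair


def event_ledger(template: TemplateMap) -> EventLedger:
    """Scan every line down every group, counting genotype transitions.

    Missing calls are skipped without breaking the scan; each change
    between consecutive non-missing states is one event, classified
    hom<->hom (A<->B) or hom<->het (A<->H, B<->H).
    """
    hom_hom = hom_het = 0
    per_group = []
    for g in template.groups:
        per_group.append(g.adjacent_events())
        for j in range(g.patterns.shape[1]):
            seq = g.patterns[:, j]
            seq = seq[seq != GT_MISS]
            if len(seq) < 2:
                continue
            a, b = seq[:-1], seq[1:]
            changed = a != b
            hh = changed & (((a == GT_A) & (b == GT_B)) | ((a == GT_B) & (b == GT_A)))
            hom_hom += int(hh.sum())
            hom_het += int((changed & ~hh).sum())
    return EventLedger(hom_hom + hom_het, hom_hom, hom_het, per_group)
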