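"""Shared evaluation utilities for pipeline-versus-truth comparisons."""

from __future__ import annotations

import numpy as np
import pandas as pd

from rilmap import scaffolds as sc
from rilmap import template_map as tm


def run_pipeline_on_sim(config, error_rate=0.01, map_cfg=None):
    """simulate -> call -> filter -> build; returns all intermediates."""
    import rilmap as rm

    truth, reads = rm.simulate(config)
    gm = reads.call(error_rate)
    filtered, report = rm.filter_snps(gm)
    result = rm.build_template_map(filtered, map_cfg)
    return truth, reads, gm, filtered, report, result


def group_to_chromosome(truth, placements: pd.DataFrame) -> pd.Series:
    """Majority true chromosome per inferred linkage group."""
    truemap = truth.scaffold_placements.groupby("scaffold")["chrom"].first()
    true_chrom = truemap.loc[placements["scaffold"]].to_numpy()
    return pd.crosstab(placements["group"], true_chrom).idxmax(axis=1)


def misplaced_scaffolds(truth, placements: pd.DataFrame) -> int:
    truemap = truth.scaffold_placements.groupby("scaffold")["chrom"].first()
    true_chrom = truemap.loc[placements["scaffold"]].to_numpy()
    majority = group_to_chromosome(truth, placements)
    return int((true_chrom != majority.loc[placements["group"]].to_numpy()).sum())


def detect_all_breakpoints(filtered, result, min_snps=6):
    """Run corroborated breakpoint detection over every placed scaffold."""
    surviving = ~result.rejected_snps
    placements = {
        r.scaffold: tm.Placement(r.group, r.pos_lo, r.pos_hi, r.mismatches)
        for r in result.scaffold_placements.itertuples(index=False)
    }
    out = []
    for scaf, sub in filtered.sites.groupby("scaffold", sort=False):
        if scaf not in placements:
            continue
        idx = sub.index.to_numpy()
        idx = idx[surviving[idx]]
        if len(idx) < min_snps:
            continue
        out.append(
            (
                scaf,
                idx,
                sc.detect_breakpoints(
                    filtered.calls[idx],
                    filtered.sites["pos"].to_numpy()[idx],
                    filtered.line_ids,
                    scaffold=str(scaf),
                    template=result.template,
                    placement=placements[scaf],
                ),
            )
        )
    return out


def breakpoint_truth_containment(truth, filtered, result, extend_snps=0):
    """(n breakpoints, n whose interval holds a true genotype boundary).

    ``extend_snps`` widens the checked interval by that many flanking
    SNPs on each side before testing containment.
    """
    line_index = {l: i for i, l in enumerate(filtered.line_ids)}
    snps = truth.snps.set_index(["scaffold", "pos"])
    total = contained = 0
    for scaf, idx, bps in detect_all_breakpoints(filtered, result):
        if not bps:
            continue
        pos = filtered.sites["pos"].to_numpy()[idx]
        info = snps.loc[[(scaf, p) for p in pos]]
        cm = info["cM"].to_numpy()
        chrom = info["chrom"].to_numpy()
        pos_list = list(pos)
        for bp in bps:
            total += 1
            j = line_index[bp.line_id]
            i1 = pos_list.index(bp.start)
            i2 = pos_list.index(bp.end)
            if chrom[i1] != chrom[i2]:
                continue
            e1 = max(i1 - extend_snps, 0)
            e2 = min(i2 + extend_snps, len(pos_list) - 1)
            lo = min(cm[e1], cm[i1], cm[i2], cm[e2])
            hi = max(cm[e1], cm[i1], cm[i2], cm[e2])
            bounds = truth.genotype_boundaries(j, int(chrom[i1]))
            if ((bounds >= lo) & (bounds <= hi)).any():
                contained += 1
    return total, contained


def chimera_flags(filtered, result, min_snps_per_side=5):
    """detect_chimeras over every scaffold; returns {scaffold: flagged}."""
    groups = np.array([p.group for p in result.snp_placements])
    pos_lo = np.array([p.pos_lo for p in result.snp_placements])
    pos_hi = np.array([p.pos_hi for p in result.snp_placements])
    groups[result.rejected_snps] = -1
    site_scaf = filtered.sites["scaffold"].to_numpy()
    adjacent = {
        g: grp.adjacent_events() for g, grp in enumerate(result.template.groups)
    }
    flags = {}
    for scaf in np.unique(site_scaf):
        m = site_scaf == scaf
        flags[str(scaf)] = sc.detect_chimeras(
            groups[m], pos_lo[m], adjacent, pos_hi[m],
            min_snps_per_side=min_snps_per_side,
        ).chimeric
    return flags


def eligible_chimeras(truth, min_snps_per_side=5):
    """Injected chimeric scaffolds with enough SNPs on each chromosome piece."""
    out = set()
    for scaf in truth.artifact_registry["chimeric_scaffolds"]:
        sizes = (
            truth.snps[truth.snps["scaffold"] == scaf].groupby("chrom").size()
        )
        if len(sizes) >= 2 and sorted(sizes)[-2] >= min_snps_per_side:
            out.add(scaf)
    return out
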