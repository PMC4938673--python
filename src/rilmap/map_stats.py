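"""Summary statistics on a built genetic map.

Covers the map-level accounting a mapping study reports: recombination
events split by transition type, the expected-pattern identity
(events + one baseline pattern per chromosome), per-group summary
tables, SNP density, gap census, allele-class spectrum, genotype-error
audit against scaffold consensus, and GC content near recombination
breakpoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .genotypes import (
    ALLELE_CLASSES,
    GT_A,
    GT_B,
    GT_H,
    GT_MISS,
    classify_allele_pair,
)
from .scaffolds import consensus_from_counts
from .template_map import TemplateMap

# -- recombination-event accounting ------------------------------------------


def count_recombination_events(template: TemplateMap) -> tuple[int, int, int]:
    """(total, hom<->hom, hom<->het) events across all lines and groups.

    Per line per group the ordered genotype sequence is scanned with
    missing calls skipped; every change between consecutive non-missing
    states is one event, A<->B counting as hom<->hom and any change
    involving H as hom<->het.
    """
    hom_hom = hom_het = 0
    for g in template.groups:
        for j in range(g.patterns.shape[1]):
            seq = g.patterns[:, j]
            seq = seq[seq != GT_MISS]
            if len(seq) < 2:
                continue
            a, b = seq[:-1], seq[1:]
            changed = a != b
            hh = changed & (a != GT_H) & (b != GT_H)
            hom_hom += int(hh.sum())
            hom_het += int((changed & ~hh).sum())
    return hom_hom + hom_het, hom_hom, hom_het


def expected_pattern_count(events: int, n_groups: int) -> int:
    """Patterns expected from ``events`` crossovers over ``n_groups`` groups.

    Each linkage group contributes one baseline pattern and each
    recombination event one more, so the expectation is simply
    ``events + n_groups``; the observed unique-pattern count can only
    fall below it, because multiple events between the same pair of
    mapped loci collapse into one observable pattern change.
    """
    if events < 0 or n_groups < 1:
        raise ValueError("need events >= 0 and n_groups >= 1")
    return int(events) + int(n_groups)


# -- per-group summary table -------------------------------------------------

SUMMARY_COLUMNS = ["linkage_group", "snps", "patterns", "scaffolds", "length_cm"]


def summarize_map(
    template: TemplateMap, scaffold_placements: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-linkage-group SNP / pattern / scaffold / cM summary with a totals row."""
    rows = []
    for i, g in enumerate(template.groups):
        n_snps = int(g.snp_counts.sum()) if g.snp_counts is not None else 0
        n_scaf = int(sum(len(s) for s in g.scaffolds)) if g.scaffolds else 0
        if scaffold_placements is not None and len(scaffold_placements):
            sub = scaffold_placements[scaffold_placements["group"] == i]
            n_scaf = int(len(sub))
            n_snps = int(sub["n_snps"].sum())
        length = float(g.cm[-1]) if g.cm is not None and len(g.cm) else 0.0
        rows.append((i + 1, n_snps, g.n_positions, n_scaf, length))
    df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    return add_totals(df)


def add_totals(per_group: pd.DataFrame) -> pd.DataFrame:
    """Append a ``Total`` row; cM totals are summed unrounded, rendered later."""
    totals = pd.DataFrame(
        [
            {
                "linkage_group": "Total",
                "snps": int(per_group["snps"].sum()),
                "patterns": int(per_group["patterns"].sum()),
                "scaffolds": int(per_group["scaffolds"].sum()),
                "length_cm": float(per_group["length_cm"].sum()),
            }
        ]
    )
    if len(per_group) == 0:
        return totals
    return pd.concat([per_group, totals], ignore_index=True)


def load_published_summary() -> pd.DataFrame:
    """The packaged 12-group reference summary table (per-group rows only)."""
    with resources.files("rilmap.data").joinpath("linkage_group_summary.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def format_summary(df: pd.DataFrame) -> str:
    """Aligned plain-text rendering (LG, SNPs, patterns, scaffolds, cM)."""
    out = df.copy()
    out["length_cm"] = out["length_cm"].map(lambda v: f"{v:.1f}")
    for c in ("snps", "scaffolds"):
        out[c] = out[c].map(lambda v: f"{v:,}")
    return out.to_string(index=False)


# -- density and gaps --------------------------------------------------------


def snp_density(total_non_n_bp: int, total_snps: int) -> float:
    """Base pairs of mapped sequence per mapped SNP, to one decimal."""
    if total_snps <= 0:
        raise ValueError("total_snps must be positive")
    return round(total_non_n_bp / total_snps, 1)


def find_gaps(template: TemplateMap, min_cm: float = 5.0) -> pd.DataFrame:
    """Adjacent-position intervals spanning >= ``min_cm``, widest first."""
    rows = []
    for gi, g in enumerate(template.groups):
        if g.cm is None:
            continue
        spans = np.diff(g.cm)
        rec, _scored = g.adjacent_recombinants()
        for k in np.nonzero(spans >= min_cm)[0]:
            rows.append((gi, int(k), int(k + 1), float(spans[k]), int(rec[k])))
    df = pd.DataFrame(
        rows, columns=["group", "pos_lo", "pos_hi", "span_cm", "recombinants"]
    )
    return df.sort_values("span_cm", ascending=False, ignore_index=True)


# -- allele classes ----------------------------------------------------------


def allele_class_spectrum(
    ref: Sequence[str], alt: Sequence[str]
) -> dict[str, float]:
    """Proportion of SNPs in each strand-symmetric allele class."""
    ref = list(ref)
    alt = list(alt)
    if len(ref) == 0 or len(ref) != len(alt):
        raise ValueError("need matching non-empty ref/alt sequences")
    classes = [classify_allele_pair(r, a) for r, a in zip(ref, alt)]
    n = len(classes)
    return {c: classes.count(c) / n for c in ALLELE_CLASSES}


# -- genotype-error audit ----------------------------------------------------


@dataclass
class ErrorAudit:
    """SNP-call error rates with the scaffold consensus treated as truth.

    The conditional rates are over called (non-missing) SNP cells within
    the relevant consensus state.
    """

    missing_rate: float
    het_as_hom_rate: float
    hom_as_het_rate: float
    hom_as_other_hom_rate: float


def genotype_error_audit(
    calls: np.ndarray,
    scaffold_ids: Sequence[str],
    het_fraction_min: float = 0.25,
    min_snps: int = 2,
) -> ErrorAudit:
    """Audit per-SNP calls against their scaffold consensus genotypes."""
    calls = np.asarray(calls)
    scaffold_ids = np.asarray(scaffold_ids)
    uniq, idx = np.unique(scaffold_ids, return_inverse=True)
    n_lines = calls.shape[1]
    counts = np.zeros((3, len(uniq), n_lines), dtype=np.int64)
    for k, code in enumerate((GT_A, GT_H, GT_B)):
        np.add.at(counts[k], idx, (calls == code).astype(np.int64))
    consensus = consensus_from_counts(counts[0], counts[1], counts[2], het_fraction_min)
    per_scaf = np.bincount(idx, minlength=len(uniq))
    use = per_scaf[idx] >= min_snps
    cons_cells = consensus[idx][use]
    call_cells = calls[use]

    n_cells = call_cells.size
    missing = call_cells == GT_MISS
    called = ~missing
    cons_het = cons_cells == GT_H
    cons_hom = (cons_cells == GT_A) | (cons_cells == GT_B)

    het_called = (cons_het & called).sum()
    hom_called = (cons_hom & called).sum()
    het_as_hom = (cons_het & ((call_cells == GT_A) | (call_cells == GT_B))).sum()
    hom_as_het = (cons_hom & (call_cells == GT_H)).sum()
    other_hom = (
        ((cons_cells == GT_A) & (call_cells == GT_B))
        | ((cons_cells == GT_B) & (call_cells == GT_A))
    ).sum()
    return ErrorAudit(
        missing_rate=float(missing.sum() / max(n_cells, 1)),
        het_as_hom_rate=float(het_as_hom / max(het_called, 1)),
        hom_as_het_rate=float(hom_as_het / max(hom_called, 1)),
        hom_as_other_hom_rate=float(other_hom / max(hom_called, 1)),
    )


# -- GC near breakpoints -----------------------------------------------------


def _gc_counts(seq: str) -> tuple[int, int]:
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    total = gc + s.count("A") + s.count("T")  # non-N bases only
    return gc, total


def gc_near_breakpoints(
    contexts: Iterable[str], assembly: Mapping[str, str] | tuple[int, int]
) -> tuple[float, float, float]:
    """(GC at breakpoints, GC of assembly, p-value) for the difference.

    GC proportions are over non-N bases.  The significance test is a
    two-proportion chi-square on pooled base counts (bases within a
    sequence treated as independent — a stated approximation).
    ``assembly`` is either a mapping of sequences or a precomputed
    ``(gc_count, total_count)`` pair.
    """
    gc_bp = tot_bp = 0
    for seq in contexts:
        g, t = _gc_counts(seq)
        gc_bp += g
        tot_bp += t
    if tot_bp == 0:
        raise ValueError("no breakpoint context bases supplied")
    if isinstance(assembly, tuple):
        gc_asm, tot_asm = assembly
    else:
        gc_asm = tot_asm = 0
        for seq in assembly.values():
            g, t = _gc_counts(str(seq[:]))
            gc_asm += g
            tot_asm += t
    table = np.array(
        [[gc_bp, tot_bp - gc_bp], [gc_asm, tot_asm - gc_asm]], dtype=float
    )
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0 or tot_asm == 0:
        p = 1.0
    else:
        _, p, _, _ = chi2_contingency(table, correction=False)
    return gc_bp / tot_bp, gc_asm / max(tot_asm, 1), float(p)
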