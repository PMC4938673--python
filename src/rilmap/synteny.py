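"""Cross-species synteny via best BLAST hits onto the mapped scaffolds.

Gene sequences from an external genetic map are located on the draft
assembly by their single best BLAST hit (tabular 12-column output,
e-value strictly below a threshold).  Genes whose best-hit scaffold is
genetically placed become dot-plot points (external map position vs
internal map position); runs of points collinear on both maps are
chained into syntenic segments.

Chaining is deliberately simple and transparent: within each (external
group, internal group) cell, points sorted by external position are
greedily extended while the internal position advances monotonically in
one direction (established by the chain's first step) and neither axis
jumps more than ``max_gap_cM``.  Chains with at least ``min_genes``
genes are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from os import PathLike
from typing import Iterable

import numpy as np
import pandas as pd

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_best_hits(
    source: str | PathLike | Iterable[str] | pd.DataFrame,
    evalue_max: float = 1e-6,
) -> pd.DataFrame:
    """Single best hit per query from BLAST outfmt-6 rows.

    Keeps, per query, the hit with the lowest e-value (ties: highest bit
    score, then first encountered) and drops queries whose best hit has
    e-value >= ``evalue_max`` (the threshold is strict).  Returns a
    DataFrame indexed by query with ``sseqid, evalue, bitscore``.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
        df.columns = BLAST6_COLUMNS[: len(df.columns)]
    else:
        if isinstance(source, (str, PathLike)):
            handle: object = source
        else:
            handle = StringIO("\n".join(source))
        try:
            df = pd.read_csv(
                handle, sep="\t", header=None, names=BLAST6_COLUMNS, comment="#",
                dtype={"qseqid": str, "sseqid": str},
            )
        except pd.errors.EmptyDataError:
            df = pd.DataFrame(columns=BLAST6_COLUMNS)
        except (ValueError, pd.errors.ParserError) as err:
            raise ValueError(f"malformed BLAST tabular input: {err}") from err
    if df["evalue"].isna().any() or df["bitscore"].isna().any():
        bad = int(np.nonzero(df["evalue"].isna() | df["bitscore"].isna())[0][0]) + 1
        raise ValueError(f"malformed BLAST tabular row at line {bad}")
    df["_row"] = np.arange(len(df))
    df = df.sort_values(["qseqid", "evalue", "bitscore", "_row"],
                        ascending=[True, True, False, True])
    best = df.groupby("qseqid", sort=False).first()
    best = best[best["evalue"] < evalue_max]
    return best[["sseqid", "evalue", "bitscore"]]


# -- dot plot ----------------------------------------------------------------


@dataclass
class DotplotCounts:
    n_genes_external: int
    n_hit: int
    n_placed: int

    @property
    def placed_fraction(self) -> float:
        return self.n_placed / max(self.n_hit, 1)


def build_dotplot(
    best_hits: pd.DataFrame,
    external_map: pd.DataFrame,
    placements: pd.DataFrame,
) -> tuple[pd.DataFrame, DotplotCounts]:
    """One point per gene whose best-hit scaffold is genetically placed.

    ``external_map`` needs columns ``gene, group, cm``; ``placements``
    needs ``scaffold, group, cm_lo, cm_hi`` (a scaffold's cM window is
    represented by its midpoint).  Returns the points (gene,
    ext_group, ext_cm, int_group, int_cm, evalue) and hit/placed counts.
    """
    ext = external_map.set_index("gene")
    place = placements.copy()
    place["int_cm"] = (place["cm_lo"] + place["cm_hi"]) / 2.0
    place = place.set_index("scaffold")
    rows = []
    n_hit = 0
    for gene, hit in best_hits.iterrows():
        if gene not in ext.index:
            continue
        n_hit += 1
        sid = hit["sseqid"]
        if sid not in place.index:
            continue  # hit-but-unplaced
        p = place.loc[sid]
        if isinstance(p, pd.DataFrame):
            p = p.iloc[0]
        e = ext.loc[gene]
        rows.append(
            (gene, e["group"], float(e["cm"]), int(p["group"]), float(p["int_cm"]),
             float(hit["evalue"]))
        )
    points = pd.DataFrame(
        rows, columns=["gene", "ext_group", "ext_cm", "int_group", "int_cm", "evalue"]
    )
    return points, DotplotCounts(len(ext), n_hit, len(points))


# -- segment chaining --------------------------------------------------------


@dataclass
class SyntenicSegment:
    ext_group: object
    int_group: int
    ext_span: tuple[float, float]
    int_span: tuple[float, float]
    genes: list[str] = field(default_factory=list)
    orientation: str = "collinear"  # or "inverted"

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def detect_segments(
    points: pd.DataFrame, min_genes: int = 5, max_gap_cM: float = 10.0
) -> tuple[list[SyntenicSegment], float]:
    """Greedy monotone chaining of dot-plot points into syntenic segments.

    Returns the segments and the fraction of points captured by them.
    Segment gene sets are disjoint by construction.
    """
    segments: list[SyntenicSegment] = []
    n_in_segments = 0
    if len(points) == 0:
        return segments, 0.0
    for (eg, ig), cell in points.groupby(["ext_group", "int_group"], sort=True):
        cell = cell.sort_values(["ext_cm", "int_cm"], kind="mergesort")
        ext = cell["ext_cm"].to_numpy()
        icm = cell["int_cm"].to_numpy()
        genes = cell["gene"].to_list()
        chain: list[int] = []
        direction = 0  # 0 unknown, +1 increasing internal cM, -1 decreasing

        def flush() -> None:
            nonlocal n_in_segments
            if len(chain) >= min_genes:
                lo, hi = chain[0], chain[-1]
                segments.append(
                    SyntenicSegment(
                        ext_group=eg,
                        int_group=int(ig),
                        ext_span=(float(ext[lo]), float(ext[hi])),
                        int_span=(float(min(icm[chain])), float(max(icm[chain]))),
                        genes=[genes[k] for k in chain],
                        orientation="inverted" if direction < 0 else "collinear",
                    )
                )
                n_in_segments += len(chain)

        for k in range(len(cell)):
            if not chain:
                chain = [k]
                direction = 0
                continue
            prev = chain[-1]
            d_ext = ext[k] - ext[prev]
            d_int = icm[k] - icm[prev]
            step = 0 if d_int == 0 else (1 if d_int > 0 else -1)
            ok = (
                d_ext <= max_gap_cM
                and abs(d_int) <= max_gap_cM
                and (direction == 0 or step == 0 or step == direction)
            )
            if ok:
                chain.append(k)
                if direction == 0 and step != 0:
                    direction = step
            else:
                flush()
                chain = [k]
                direction = 0
        flush()
    return segments, n_in_segments / len(points)


def plot_dotplot(points: pd.DataFrame, segments=None, path=None):
    """Optional scatter rendering of the dot plot (matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(points["ext_cm"], points["int_cm"], s=4, c="grey")
    if segments:
        for seg in segments:
            sub = points[points["gene"].isin(seg.genes)]
            ax.scatter(sub["ext_cm"], sub["int_cm"], s=6, c="red")
    ax.set_xlabel("external map (cM)")
    ax.set_ylabel("internal map (cM)")
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
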