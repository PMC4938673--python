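"""Genotype calling and SNP-level filtering for low-coverage RIL sequencing.

Genotypes are encoded as small integers throughout the package:

===========  =====  ==========================================
code         char   meaning
===========  =====  ==========================================
``GT_A``     ``A``  homozygous for the parent-1 (A) allele
``GT_H``     ``H``  heterozygous
``GT_B``     ``B``  homozygous for the parent-2 (B) allele
``GT_MISS``  ``-``  no call (no reads, or filtered)
===========  =====  ==========================================

The calling rule is tailored to inbred populations: with a selfed RIL at
F6 the expected segregation is 31:2:31 (AA:AB:BB), so Hardy–Weinberg
genotype priors are inappropriate and homozygous calls are favoured
whenever the read data permit.  Each cell is called from its reference /
alternate read counts by comparing per-read likelihoods::

    L(A) = (1-e)^n_ref * e^n_alt
    L(B) = e^n_ref * (1-e)^n_alt
    L(H) = (1/2)^(n_ref + n_alt)

where ``e`` is the per-read error rate.  The better homozygote is
returned whenever it beats the other homozygote and the heterozygote on
log10 likelihood; H is returned only when both alleles were observed and
L(H) strictly exceeds both homozygote likelihoods (ties go to the
homozygote).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# -- genotype codes ----------------------------------------------------------

GT_A: int = 0
GT_H: int = 1
GT_B: int = 2
GT_MISS: int = -1

CODE_TO_CHAR: Mapping[int, str] = {GT_A: "A", GT_H: "H", GT_B: "B", GT_MISS: "-"}
CHAR_TO_CODE: Mapping[str, int] = {"A": GT_A, "H": GT_H, "B": GT_B, "-": GT_MISS}


def encode_calls(chars: str | Sequence[str]) -> np.ndarray:
    """Encode an ``A/H/B/-`` string (or sequence of such strings) as int8."""
    if isinstance(chars, str):
        return np.array([CHAR_TO_CODE[c] for c in chars], dtype=np.int8)
    return np.array([[CHAR_TO_CODE[c] for c in row] for row in chars], dtype=np.int8)


def decode_calls(codes: np.ndarray) -> np.ndarray:
    """Inverse of :func:`encode_calls`; returns an array of single chars."""
    lut = np.array(["-", "A", "H", "B"])
    return lut[np.asarray(codes) + 1]


# -- data containers ---------------------------------------------------------

SITE_COLUMNS = ["scaffold", "pos", "ref", "alt", "qual"]

#: quality value marking a site that passed the variant caller outright
#: (mirrors the 999 cap used by classic pileup-based callers)
QUAL_PASS = 999


@dataclass
class SNPReadMatrix:
    """Per-SNP, per-line reference/alternate read counts.

    ``sites`` is a DataFrame with columns ``scaffold, pos, ref, alt, qual``
    (1-based positions, strictly increasing within a scaffold); ``n_ref``
    and ``n_alt`` are ``(n_sites, n_lines)`` integer arrays.
    """

    sites: pd.DataFrame
    line_ids: list[str]
    n_ref: np.ndarray
    n_alt: np.ndarray

    def __post_init__(self) -> None:
        self.n_ref = np.asarray(self.n_ref)
        self.n_alt = np.asarray(self.n_alt)
        if self.n_ref.shape != self.n_alt.shape:
            raise ValueError("n_ref and n_alt shapes differ")
        if (self.n_ref < 0).any() or (self.n_alt < 0).any():
            raise ValueError("read counts must be non-negative")
        if self.n_ref.shape != (len(self.sites), len(self.line_ids)):
            raise ValueError("count matrix shape does not match sites/lines")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def depth(self) -> np.ndarray:
        return self.n_ref + self.n_alt

    def call(self, error_rate: float = 0.01) -> "GenotypeMatrix":
        """Call every cell with :func:`call_genotypes`."""
        calls = call_genotypes(self.n_ref, self.n_alt, error_rate)
        return GenotypeMatrix(
            sites=self.sites.reset_index(drop=True),
            line_ids=list(self.line_ids),
            calls=calls,
            depth=self.depth.astype(np.int32),
        )


@dataclass
class GenotypeMatrix:
    """Per-SNP, per-line calls plus per-cell combined depth."""

    sites: pd.DataFrame
    line_ids: list[str]
    calls: np.ndarray  # (n_sites, n_lines) int8 in {GT_A, GT_H, GT_B, GT_MISS}
    depth: np.ndarray  # (n_sites, n_lines) combined read depth
    _stats: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def site_stats(self) -> pd.DataFrame:
        """Per-site ``maf, het_fraction, missing_fraction, combined_depth``."""
        if self._stats is None or len(self._stats) != self.n_sites:
            self._stats = site_statistics(self.calls, self.depth)
        return self._stats

    def subset(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            sites=self.sites.loc[mask].reset_index(drop=True),
            line_ids=list(self.line_ids),
            calls=self.calls[mask],
            depth=self.depth[mask],
        )


# -- genotype calling --------------------------------------------------------


def call_genotypes(
    n_ref: np.ndarray, n_alt: np.ndarray, error_rate: float = 0.01
) -> np.ndarray:
    """Vectorised homozygote-favouring genotype calling.

    Parameters
    ----------
    n_ref, n_alt
        Arrays (any matching shape) of reference / alternate read counts.
    error_rate
        Per-read error probability ``e`` with ``0 < e < 0.5``.
    """
    n_ref = np.asarray(n_ref)
    n_alt = np.asarray(n_alt)
    if (n_ref < 0).any() or (n_alt < 0).any():
        raise ValueError("read counts must be non-negative")
    if not 0 < error_rate < 0.5:
        raise ValueError("error_rate must lie in (0, 0.5)")

    depth = n_ref + n_alt
    log_e = np.log10(error_rate)
    log_1e = np.log10(1.0 - error_rate)
    log_la = n_ref * log_1e + n_alt * log_e
    log_lb = n_ref * log_e + n_alt * log_1e
    log_lh = -depth * np.log10(2.0)

    out = np.full(np.shape(depth), GT_MISS, dtype=np.int8)
    called = depth > 0
    # H only when both alleles seen and it strictly beats both homozygotes;
    # for e < 0.5 a homozygote can never tie H exactly, and the n_ref==n_alt
    # homozygote tie always falls in the H branch.
    het = called & (n_ref > 0) & (n_alt > 0) & (log_lh > np.maximum(log_la, log_lb))
    out[het] = GT_H
    out[called & ~het & (log_la >= log_lb)] = GT_A
    out[called & ~het & (log_lb > log_la)] = GT_B
    return out


def call_genotype(n_ref: int, n_alt: int, error_rate: float = 0.01) -> int:
    """Scalar convenience wrapper around :func:`call_genotypes`."""
    if n_ref < 0 or n_alt < 0:
        raise ValueError("read counts must be non-negative")
    return int(call_genotypes(np.array([n_ref]), np.array([n_alt]), error_rate)[0])


# -- per-site statistics -----------------------------------------------------


def site_statistics(calls: np.ndarray, depth: np.ndarray | None = None) -> pd.DataFrame:
    """Per-site summary statistics from a calls (and optional depth) matrix.

    MAF is computed on allele counts of called genotypes: a homozygote
    contributes two copies of its allele, a heterozygote one of each.
    ``het_fraction`` is over called lines; ``missing_fraction`` over all
    lines.  An all-missing site reports ``maf = 0``.
    """
    calls = np.atleast_2d(np.asarray(calls))
    if calls.shape[1] < 1:
        raise ValueError("need at least one line")
    n_lines = calls.shape[1]
    n_a = (calls == GT_A).sum(axis=1)
    n_h = (calls == GT_H).sum(axis=1)
    n_b = (calls == GT_B).sum(axis=1)
    called = n_a + n_h + n_b
    alleles_a = 2 * n_a + n_h
    alleles_b = 2 * n_b + n_h
    total_alleles = np.maximum(alleles_a + alleles_b, 1)
    maf = np.minimum(alleles_a, alleles_b) / total_alleles
    het_fraction = np.where(called > 0, n_h / np.maximum(called, 1), 0.0)
    missing_fraction = (n_lines - called) / n_lines
    if depth is None:
        combined_depth = np.zeros(calls.shape[0], dtype=np.int64)
    else:
        combined_depth = np.atleast_2d(np.asarray(depth)).sum(axis=1)
    return pd.DataFrame(
        {
            "maf": maf,
            "het_fraction": het_fraction,
            "missing_fraction": missing_fraction,
            "combined_depth": combined_depth,
        }
    )


# -- SNP-level filters -------------------------------------------------------


@dataclass
class FilterConfig:
    """Thresholds of the SNP filter cascade.

    Defaults follow the mapping protocol for a selfed F6 RIL panel: sites
    heterozygous in more than 15% of lines are treated as multi-copy,
    minor-allele frequencies below 5% as sequencing/mapping artifacts,
    sites missing in more than half the lines as underpowered, and only
    sites at the caller's maximum quality score are kept.
    """

    max_het_fraction: float = 0.15
    min_maf: float = 0.05
    max_missing_fraction: float = 0.50
    min_quality: float = QUAL_PASS
    error_rate: float = 0.01
    depth_flag_multiple: float = 2.0
    depth_interval: tuple[float, float] = (0.005, 0.995)

    def __post_init__(self) -> None:
        for name in ("max_het_fraction", "min_maf", "max_missing_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 < self.error_rate < 0.5:
            raise ValueError("error_rate must lie in (0, 0.5)")


@dataclass
class FilterReport:
    """Per-rule rejection counts (a site failing k rules is counted k times)."""

    n_input: int
    n_retained: int
    rejected_het: int
    rejected_maf: int
    rejected_missing: int
    rejected_quality: int
    keep_mask: np.ndarray = field(repr=False)

    def as_dict(self) -> dict[str, int]:
        return {
            "input": self.n_input,
            "retained": self.n_retained,
            "rejected_het": self.rejected_het,
            "rejected_maf": self.rejected_maf,
            "rejected_missing": self.rejected_missing,
            "rejected_quality": self.rejected_quality,
        }


def filter_snps(
    matrix: GenotypeMatrix, cfg: FilterConfig | None = None
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the heterozygosity / MAF / missingness / quality cascade."""
    cfg = cfg or FilterConfig()
    stats = matrix.site_stats()
    fail_het = (stats["het_fraction"] > cfg.max_het_fraction).to_numpy()
    fail_maf = (stats["maf"] < cfg.min_maf).to_numpy()
    fail_missing = (stats["missing_fraction"] > cfg.max_missing_fraction).to_numpy()
    qual = matrix.sites["qual"].to_numpy(dtype=float)
    fail_qual = qual < cfg.min_quality
    keep = ~(fail_het | fail_maf | fail_missing | fail_qual)
    report = FilterReport(
        n_input=matrix.n_sites,
        n_retained=int(keep.sum()),
        rejected_het=int(fail_het.sum()),
        rejected_maf=int(fail_maf.sum()),
        rejected_missing=int(fail_missing.sum()),
        rejected_quality=int(fail_qual.sum()),
        keep_mask=keep,
    )
    return matrix.subset(keep), report


# -- allele classes ----------------------------------------------------------

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_PAIR_CLASS = {
    frozenset("CT"): "C/T",
    frozenset("GA"): "C/T",
    frozenset("CG"): "C/G",
    frozenset("CA"): "C/A",
    frozenset("GT"): "C/A",
    frozenset("AT"): "A/T",
}

ALLELE_CLASSES = ("C/T", "C/G", "C/A", "A/T")


def classify_allele_pair(ref: str, alt: str) -> str:
    """Collapse a ref/alt pair into one of the four strand-symmetric classes.

    {C,T} and its complement {G,A} map to ``C/T``; {C,A} and {G,T} to
    ``C/A``; {C,G} and {A,T} are their own complements.
    """
    ref, alt = str(ref).upper(), str(alt).upper()
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        raise ValueError(f"alleles must be in ACGT, got {ref}/{alt}")
    if ref == alt:
        raise ValueError("ref and alt alleles must differ")
    return _PAIR_CLASS[frozenset((ref, alt))]


# -- combined-depth profiling ------------------------------------------------


@dataclass
class DepthProfile:
    """Modal combined depth, a central empirical interval, and repeat flags."""

    mode: int
    interval: tuple[float, float]
    flags: np.ndarray  # True where combined depth exceeds flag_multiple * mode


def depth_profile(
    matrix: GenotypeMatrix,
    flag_multiple: float = 2.0,
    quantiles: tuple[float, float] = (0.005, 0.995),
) -> DepthProfile:
    """Profile the per-site combined depth distribution.

    Sites whose combined depth exceeds ``flag_multiple`` times the modal
    depth are flagged as putative repeats.  Flagging is advisory only —
    it is not applied as a filter.
    """
    depths = matrix.site_stats()["combined_depth"].to_numpy()
    if len(depths) == 0:
        raise ValueError("empty genotype matrix")
    counts = np.bincount(depths.astype(np.int64))
    mode = int(np.argmax(counts))
    lo, hi = np.quantile(depths, quantiles)
    flags = depths > flag_multiple * mode
    return DepthProfile(mode=mode, interval=(float(lo), float(hi)), flags=flags)
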