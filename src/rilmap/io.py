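"""File formats, pipeline configuration and the end-to-end driver.

Conventions: VCF and FASTA interfaces are 1-based inclusive; BED output
is 0-based half-open.  Genotypes on disk use single characters
``A/H/B/-``.  Every run logs the fully resolved configuration, the seed
and per-stage counts, so the filter cascade is auditable.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import map_stats, scaffolds, synteny, template_map
from .genotypes import (
    FilterConfig,
    GenotypeMatrix,
    SNPReadMatrix,
    decode_calls,
    encode_calls,
    filter_snps,
)
from .sim_ril import SimConfig, simulate
from .template_map import MapBuildConfig, TemplateMap, build_template_map

log = logging.getLogger("rilmap")

# -- VCF ---------------------------------------------------------------------


def read_vcf(path: str | Path) -> tuple[SNPReadMatrix, int]:
    """Read a multi-sample VCF into per-line allele counts.

    Counts come from the AD field when present, otherwise from a
    documented GT+DP fallback (hom-ref -> all reads reference, hom-alt
    -> all alternate, het -> an even split).  Bi-allelic SNP records
    only; multi-allelic or non-SNP records are skipped and counted.
    Returns the matrix and the skipped-record count.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"VCF not found: {path}")
    try:
        vcf = VCF(str(path))
    except Exception as err:  # cyvcf2 raises bare exceptions on bad headers
        raise ValueError(f"malformed VCF header in {path}: {err}") from err
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"VCF has no sample columns: {path}")
    sites, refs_alts = [], []
    n_ref_rows, n_alt_rows = [], []
    skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            skipped += 1
            continue
        ad = v.format("AD")
        if ad is not None and ad.shape[1] >= 2:
            nr = np.clip(ad[:, 0], 0, None).astype(np.int64)
            na = np.clip(ad[:, 1], 0, None).astype(np.int64)
        else:
            dp = np.clip(v.gt_depths, 0, None).astype(np.int64)
            gt = v.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            nr = np.where(gt == 0, dp, np.where(gt == 1, dp // 2, 0))
            na = np.where(gt == 3, dp, np.where(gt == 1, dp - dp // 2, 0))
        qual = v.QUAL if v.QUAL is not None else 0.0
        sites.append((v.CHROM, v.POS, v.REF, v.ALT[0], qual))
        n_ref_rows.append(nr)
        n_alt_rows.append(na)
    sites_df = pd.DataFrame(sites, columns=["scaffold", "pos", "ref", "alt", "qual"])
    n = len(sites_df)
    shape = (n, len(samples))
    matrix = SNPReadMatrix(
        sites=sites_df,
        line_ids=samples,
        n_ref=np.array(n_ref_rows, dtype=np.int64).reshape(shape),
        n_alt=np.array(n_alt_rows, dtype=np.int64).reshape(shape),
    )
    if skipped:
        log.info("read_vcf: skipped %d multi-allelic/non-SNP records", skipped)
    return matrix, skipped


def write_vcf(matrix: SNPReadMatrix, path: str | Path) -> None:
    """Write the read matrix as a minimal multi-sample VCF 4.2 with GT:AD."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rilmap\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths (ref,alt)">\n'
        )
        for scaf in pd.unique(matrix.sites["scaffold"]):
            fh.write(f"##contig=<ID={scaf}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.line_ids)
            + "\n"
        )
        for i, site in enumerate(matrix.sites.itertuples(index=False)):
            cells = [
                f"./.:{matrix.n_ref[i, j]},{matrix.n_alt[i, j]}"
                for j in range(matrix.n_lines)
            ]
            fh.write(
                f"{site.scaffold}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t"
                f"{site.qual:g}\t.\t.\tGT:AD\t" + "\t".join(cells) + "\n"
            )


# -- genotype matrix TSV -----------------------------------------------------


def write_genotype_tsv(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Sites x lines table of A/H/B/- codes with site metadata columns."""
    chars = decode_calls(matrix.calls)
    df = matrix.sites.copy()
    for j, line in enumerate(matrix.line_ids):
        df[line] = chars[:, j]
    df.to_csv(path, sep="\t", index=False)


def read_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"scaffold": str})
    meta_cols = ["scaffold", "pos", "ref", "alt", "qual"]
    line_ids = [c for c in df.columns if c not in meta_cols]
    calls = encode_calls(["".join(row) for row in df[line_ids].to_numpy()])
    return GenotypeMatrix(
        sites=df[meta_cols],
        line_ids=line_ids,
        calls=calls,
        depth=np.zeros_like(calls, dtype=np.int32),
    )


# -- template map TSV --------------------------------------------------------


def write_template_tsv(template: TemplateMap, path: str | Path) -> None:
    """Group, position, cM, pattern string, plus per-line genotype columns."""
    rows = []
    for gi, g in enumerate(template.groups):
        chars = decode_calls(g.patterns)
        cm = g.cm if g.cm is not None else np.zeros(g.n_positions)
        snps = g.snp_counts if g.snp_counts is not None else np.zeros(g.n_positions, int)
        for k in range(g.n_positions):
            rows.append(
                [gi, k, round(float(cm[k]), 4), int(snps[k]), "".join(chars[k])]
                + list(chars[k])
            )
    cols = ["group", "position", "cm", "n_snps", "pattern"] + list(template.line_ids)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_template_tsv(path: str | Path) -> TemplateMap:
    df = pd.read_csv(path, sep="\t")
    line_ids = list(df.columns[5:])
    groups = []
    for _, sub in df.groupby("group", sort=True):
        sub = sub.sort_values("position")
        g = template_map.LinkageGroup(patterns=encode_calls(sub["pattern"].to_list()))
        g.cm = sub["cm"].to_numpy(dtype=float)
        g.snp_counts = sub["n_snps"].to_numpy(dtype=np.int64)
        g.scaffolds = [[] for _ in range(g.n_positions)]
        groups.append(g)
    return TemplateMap(groups, line_ids)


# -- breakpoints -------------------------------------------------------------


def write_breakpoints_bed(bps: list[scaffolds.Breakpoint], path: str | Path) -> None:
    """BED (0-based half-open): name = line id, score = interval width."""
    with open(path, "w") as fh:
        for bp in bps:
            fh.write(
                f"{bp.scaffold}\t{bp.start - 1}\t{bp.end}\t{bp.line_id}\t"
                f"{bp.end - bp.start}\t.\n"
            )


def read_breakpoints_bed(path: str | Path) -> list[scaffolds.Breakpoint]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        scaf, start0, end, name, _score, _strand = line.split("\t")
        out.append(
            scaffolds.Breakpoint(scaf, name, int(start0) + 1, int(end), transition="")
        )
    return out


def write_breakpoint_flanks_tsv(
    bps: list[scaffolds.Breakpoint], path: str | Path
) -> None:
    rows = [
        (b.scaffold, b.line_id, b.start, b.end, b.transition, b.flank_seq or "")
        for b in bps
    ]
    pd.DataFrame(
        rows, columns=["scaffold", "line", "start", "end", "transition", "flank_seq"]
    ).to_csv(path, sep="\t", index=False)


# -- configuration -----------------------------------------------------------


@dataclass
class PipelineConfig:
    """Flat ``key = value`` configuration covering every pipeline stage.

    Keys are namespaced by stage (``sim.n_lines``, ``filter.min_maf``,
    ``map.max_mismatch``) plus top-level paths and switches.  Unknown
    keys are rejected.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    map: MapBuildConfig = field(default_factory=MapBuildConfig)
    simulate: bool = True
    vcf: str = ""
    fasta: str = ""
    blast: str = ""
    external_map: str = ""
    out_dir: str = "rilmap_out"
    seed: int = 0

    _SECTIONS = {"sim": SimConfig, "filter": FilterConfig, "map": MapBuildConfig}

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        cfg = cls()
        overrides: dict[str, dict] = {"sim": {}, "filter": {}, "map": {}}
        top_fields = {
            f.name for f in fields(cls) if f.name not in cfg._SECTIONS
        }
        for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected 'key = value'")
            key, value = (s.strip() for s in line.split("=", 1))
            if "." in key:
                section, name = key.split(".", 1)
                if section not in cfg._SECTIONS:
                    raise ValueError(f"{path}:{ln}: unknown section {section!r}")
                sec_fields = {f.name: f for f in fields(cfg._SECTIONS[section])}
                if name not in sec_fields:
                    raise ValueError(f"{path}:{ln}: unknown key {key!r}")
                overrides[section][name] = _coerce(value, sec_fields[name].type)
            elif key in top_fields:
                setattr(cfg, key, _coerce(value, type(getattr(cfg, key)).__name__))
            else:
                raise ValueError(f"{path}:{ln}: unknown key {key!r}")
        cfg.sim = dataclasses.replace(cfg.sim, **overrides["sim"])
        cfg.filter = dataclasses.replace(cfg.filter, **overrides["filter"])
        cfg.map = dataclasses.replace(cfg.map, **overrides["map"])
        return cfg

    def to_file(self, path: str | Path) -> None:
        lines = []
        for section, obj in (("sim", self.sim), ("filter", self.filter), ("map", self.map)):
            for f in fields(obj):
                lines.append(f"{section}.{f.name} = {getattr(obj, f.name)}")
        for f in fields(self):
            if f.name in self._SECTIONS:
                continue
            lines.append(f"{f.name} = {getattr(self, f.name)}")
        Path(path).write_text("\n".join(lines) + "\n")


def _coerce(value: str, typename: str):
    t = str(typename)
    if "tuple" in t:
        return tuple(float(x) for x in value.strip("()").split(","))
    if "bool" in t:
        return value.lower() in ("1", "true", "yes")
    if "int" in t:
        return int(value)
    if "float" in t:
        return float(value)
    return value


# -- end-to-end driver -------------------------------------------------------


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """call -> filter -> consensus -> map -> stats (-> synteny), to disk."""
    if not config.simulate and not config.vcf:
        raise ValueError("config field 'vcf' is required when simulate = False")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    config.to_file(out / "config.txt")
    log.info("resolved config written to %s (seed=%d)", out / "config.txt", config.seed)

    truth = None
    if config.simulate:
        sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
        truth, reads = simulate(sim_cfg)
        write_vcf(reads, out / "simulated.vcf")
        truth.scaffold_placements.to_csv(
            out / "truth_scaffolds.tsv", sep="\t", index=False
        )
        truth.snps.to_csv(out / "truth_snps.tsv", sep="\t", index=False)
        paths["vcf"] = out / "simulated.vcf"
    else:
        reads, _ = read_vcf(config.vcf)

    log.info("calling genotypes for %d sites x %d lines", reads.n_sites, reads.n_lines)
    gm = reads.call(config.filter.error_rate)
    filtered, report = filter_snps(gm, config.filter)
    log.info("filter cascade: %s", report.as_dict())
    pd.DataFrame([report.as_dict()]).to_csv(out / "filter_report.tsv", sep="\t", index=False)
    write_genotype_tsv(filtered, out / "genotypes.tsv")

    result = build_template_map(filtered, config.map)
    log.info(
        "template map: %d groups, %d scaffolds placed, %d/%d SNPs rejected "
        "as anomalous (max_mismatch=%d), %d iterations",
        result.template.n_groups, len(result.scaffold_placements),
        int(result.rejected_snps.sum()), len(result.rejected_snps),
        config.map.max_mismatch, result.iterations,
    )
    write_template_tsv(result.template, out / "template_map.tsv")
    result.scaffold_placements.to_csv(out / "scaffold_placements.tsv", sep="\t", index=False)
    rejected = filtered.sites.loc[result.rejected_snps, ["scaffold", "pos"]].copy()
    rejected["reason"] = "anomalous"
    rejected.to_csv(out / "rejected_snps.tsv", sep="\t", index=False)

    # breakpoints on placed scaffolds
    bps = []
    placements = {
        r.scaffold: template_map.Placement(r.group, r.pos_lo, r.pos_hi, r.mismatches)
        for r in result.scaffold_placements.itertuples(index=False)
    }
    surviving = ~result.rejected_snps
    for scaf, sub in filtered.sites.groupby("scaffold", sort=False):
        if scaf not in placements:
            continue
        idx = sub.index.to_numpy()
        idx = idx[surviving[idx]]
        if len(idx) < 6:
            continue
        bps.extend(
            scaffolds.detect_breakpoints(
                filtered.calls[idx],
                filtered.sites["pos"].to_numpy()[idx],
                filtered.line_ids,
                scaffold=str(scaf),
                template=result.template,
                placement=placements[scaf],
            )
        )
    write_breakpoints_bed(bps, out / "breakpoints.bed")
    if config.fasta:
        import pyfaidx

        fasta = pyfaidx.Fasta(config.fasta)
        for bp in bps:
            bp.flank_seq = scaffolds.extract_breakpoint_context(fasta, bp).sequence
        write_breakpoint_flanks_tsv(bps, out / "breakpoint_flanks.tsv")
    log.info("breakpoints: %d placed within scaffolds", len(bps))

    summary = map_stats.summarize_map(result.template, result.scaffold_placements)
    summary.to_csv(out / "map_summary.tsv", sep="\t", index=False)
    (out / "map_summary.txt").write_text(map_stats.format_summary(summary) + "\n")
    total, hom_hom, hom_het = map_stats.count_recombination_events(result.template)
    log.info("recombination events: %d (%d hom-hom, %d hom-het)", total, hom_hom, hom_het)

    if config.blast and config.external_map:
        hits = synteny.read_best_hits(config.blast)
        ext = pd.read_csv(config.external_map, sep="\t")
        points, counts = synteny.build_dotplot(hits, ext, result.scaffold_placements)
        segments, frac = synteny.detect_segments(points)
        points.to_csv(out / "dotplot.tsv", sep="\t", index=False)
        seg_rows = [
            (s.ext_group, s.int_group, *s.ext_span, *s.int_span, s.n_genes,
             s.orientation, ",".join(map(str, s.genes)))
            for s in segments
        ]
        pd.DataFrame(
            seg_rows,
            columns=["ext_group", "int_group", "ext_lo", "ext_hi", "int_lo", "int_hi",
                     "n_genes", "orientation", "genes"],
        ).to_csv(out / "synteny_segments.tsv", sep="\t", index=False)
        log.info(
            "synteny: %d points, %d segments covering %.1f%% of genes",
            len(points), len(segments), 100 * frac,
        )

    paths.update(
        template=out / "template_map.tsv",
        placements=out / "scaffold_placements.tsv",
        summary=out / "map_summary.tsv",
        breakpoints=out / "breakpoints.bed",
        genotypes=out / "genotypes.tsv",
    )
    return paths
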