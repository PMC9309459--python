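"""End-to-end orchestration: filter -> pairwise scans -> cutoffs -> region
calls -> consensus -> F_ST / pi cross-validation -> annotation -> summary.

Stages write plain TSV/BED outputs under the configured output directory
and are resumable: existing stage outputs are reloaded instead of
recomputed when ``resume=True``.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import (
    candidate_genes,
    enriched_gene_sets,
    genes_in_regions,
    go_enrichment,
    qtl_overlap,
    region_gene_counts,
)
from .popstats import (
    mean_stat_over_intervals,
    nucleotide_diversity,
    wc_fst_per_snp,
    windowed_fst,
)
from .regions import (
    RegionCallParams,
    call_regions,
    consensus_regions,
    mask_centromeres,
    percentile_cutoff,
    region_summary,
    regions_to_intervalset,
)
from .variantio import (
    FilterParams,
    IntervalSet,
    apply_filters,
    read_effects,
    read_intervals,
    read_population_map,
    read_vcf,
)
from .windows import infer_chrom_lengths
from .xpclr import GeneticMap, ScanParams, read_track, scan, write_track

logger = logging.getLogger(__name__)


@dataclass
class GroupConfig:
    subpops: list[str]
    min_support: int


@dataclass
class PipelineConfig:
    vcf: Path
    popmap: Path
    outdir: Path
    groups: dict[str, GroupConfig]
    genes: Path | None = None
    genes_format: str = "GFF3"
    qtls: Path | None = None
    centromeres: Path | None = None
    go_map: Path | None = None
    gmap: Path | None = None
    filter_params: FilterParams = field(default_factory=FilterParams)
    scan_params: ScanParams = field(default_factory=ScanParams)
    merge_gap_bp: int = 100_000
    min_len_bp: int = 80_000
    genome_bp: int | None = None
    chrom_lengths: dict[str, int] | None = None
    fst_threshold: float = 0.5
    go_fdr: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent

        def _p(key):
            return (base / raw[key]).resolve() if raw.get(key) else None

        groups = {
            name: GroupConfig(subpops=list(g["subpops"]), min_support=int(g["min_support"]))
            for name, g in raw["groups"].items()
        }
        fp = FilterParams(**raw.get("filter", {}))
        sp = ScanParams(**raw.get("scan", {}))
        reg = raw.get("regions", {})
        return cls(
            vcf=_p("vcf"),
            popmap=_p("popmap"),
            outdir=(base / raw["outdir"]).resolve(),
            groups=groups,
            genes=_p("genes"),
            genes_format=raw.get("genes_format", "GFF3"),
            qtls=_p("qtls"),
            centromeres=_p("centromeres"),
            go_map=_p("go_map"),
            gmap=_p("gmap"),
            filter_params=fp,
            scan_params=sp,
            merge_gap_bp=int(reg.get("merge_gap_bp", 100_000)),
            min_len_bp=int(reg.get("min_len_bp", 80_000)),
            genome_bp=raw.get("genome_bp"),
            chrom_lengths=raw.get("chrom_lengths"),
            fst_threshold=float(raw.get("fst_threshold", 0.5)),
            go_fdr=float(raw.get("go_fdr", 0.05)),
            seed=int(raw.get("seed", 0)),
        )


def validate_config(config: PipelineConfig) -> dict[str, list[str]]:
    """Collect structural errors and warnings (not raised one at a time)."""
    errors: list[str] = []
    warnings_: list[str] = []
    for name in ("vcf", "popmap"):
        p = getattr(config, name)
        if p is None or not Path(p).exists():
            errors.append(f"required input {name} missing: {p}")
    for name in ("genes", "qtls", "centromeres", "go_map", "gmap"):
        p = getattr(config, name)
        if p is not None and not Path(p).exists():
            errors.append(f"configured input {name} does not exist: {p}")

    popmap = None
    if config.popmap and Path(config.popmap).exists():
        popmap = read_population_map(config.popmap)
        labels = set(popmap.labels)
        for gname, group in config.groups.items():
            missing = [s for s in group.subpops if s not in labels]
            if missing:
                errors.append(f"group {gname}: subpopulations not in popmap: {missing}")
            max_support = len(group.subpops) - 1
            if group.min_support > max_support:
                errors.append(
                    f"group {gname}: min_support={group.min_support} exceeds the "
                    f"maximum possible support {max_support}"
                )
    if popmap is not None and config.vcf and Path(config.vcf).exists():
        with open(config.vcf) as fh:
            for line in fh:
                if line.startswith("#CHROM"):
                    vcf_samples = set(line.rstrip("\n").split("\t")[9:])
                    for s in popmap:
                        if s not in vcf_samples:
                            warnings_.append(f"popmap sample {s!r} absent from VCF")
                    break
    return {"errors": errors, "warnings": warnings_}


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig, resume: bool = False) -> dict:
    """Execute the full analysis; returns the run manifest (also written to
    ``outdir/manifest.json``)."""
    report = validate_config(config)
    if report["errors"]:
        raise StageError("validate", "; ".join(report["errors"]))
    for w in report["warnings"]:
        logger.warning(w)

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "omegas": {},
        "cutoffs": {},
        "checksums": {},
        "summaries": {},
    }

    # --- filter ------------------------------------------------------------
    try:
        gm = read_vcf(config.vcf)
        popmap = read_population_map(config.popmap)
        popmap.validate_against(gm)
        gm, filt_report = apply_filters(gm, config.filter_params)
        manifest["filter"] = vars(filt_report)
    except Exception as exc:
        raise StageError("filter", str(exc)) from exc

    chrom_lengths = config.chrom_lengths or infer_chrom_lengths(
        gm.chrom, gm.pos, config.scan_params.step_bp
    )
    genome_bp = config.genome_bp or sum(chrom_lengths.values())
    gmap = GeneticMap.read(config.gmap) if config.gmap else None
    centromeres = (
        read_intervals(config.centromeres, "BED") if config.centromeres else IntervalSet()
    )

    region_params = {
        gname: RegionCallParams(
            merge_gap_bp=config.merge_gap_bp,
            min_len_bp=config.min_len_bp,
            min_support=group.min_support,
        )
        for gname, group in config.groups.items()
    }

    # --- pairwise scans ----------------------------------------------------
    scan_dir = out / "scans"
    scan_dir.mkdir(exist_ok=True)
    tracks: dict[tuple[str, str], pd.DataFrame] = {}
    for gname, group in config.groups.items():
        for test, ref in itertools.permutations(group.subpops, 2):
            path = scan_dir / f"xpclr_{test}_vs_{ref}.tsv"
            try:
                if resume and path.exists():
                    track = read_track(path)
                else:
                    track = scan(
                        gm, popmap, test, ref,
                        params=config.scan_params,
                        genetic_map=gmap,
                        chrom_lengths=chrom_lengths,
                    )
                    manifest["omegas"][f"{test}_vs_{ref}"] = track.attrs.get("omega")
                    write_track(track, path)
            except Exception as exc:
                raise StageError("scan", f"{test} vs {ref}: {exc}") from exc
            tracks[(test, ref)] = mask_centromeres(track, centromeres)

    # --- cutoffs and per-comparison calls ----------------------------------
    consensus: dict[str, pd.DataFrame] = {}
    for gname, group in config.groups.items():
        for test in group.subpops:
            mine = {
                f"{test}_vs_{ref}": tracks[(test, ref)]
                for ref in group.subpops
                if ref != test
            }
            try:
                cutoff = percentile_cutoff(mine)
            except Exception as exc:
                raise StageError("cutoff", f"{test}: {exc}") from exc
            manifest["cutoffs"][test] = {
                "cutoff": cutoff.cutoff,
                "q99": cutoff.q99_per_comparison,
            }
            calls = {
                name: call_regions(track, cutoff.cutoff, region_params[gname])
                for name, track in mine.items()
            }
            cons = consensus_regions(calls, region_params[gname])
            cons.to_csv(out / f"regions_{test}.tsv", sep="\t", index=False)
            consensus[test] = cons
            manifest["summaries"][test] = region_summary(cons, genome_bp)

    # --- FST / pi cross-validation -----------------------------------------
    stats_dir = out / "stats"
    stats_dir.mkdir(exist_ok=True)
    fst_by_pop: dict[str, object] = {}
    for gname, group in config.groups.items():
        for test in group.subpops:
            others = [s for s in group.subpops if s != test]
            samples_a = popmap.samples_for(test)
            samples_b = [s for o in others for s in popmap.samples_for(o)]
            try:
                comps = wc_fst_per_snp(gm, samples_a, samples_b)
                fst_by_pop[test] = comps
                ftrack = windowed_fst(
                    comps, config.scan_params.window_bp, config.scan_params.step_bp,
                    chrom_lengths,
                )
                ftrack.to_csv(stats_dir / f"fst_{test}.tsv", sep="\t", index=False, na_rep="NA")
                pitrack = nucleotide_diversity(
                    gm, samples_a, config.scan_params.window_bp,
                    config.scan_params.step_bp, chrom_lengths,
                )
                pitrack.to_csv(stats_dir / f"pi_{test}.tsv", sep="\t", index=False, na_rep="NA")
            except Exception as exc:
                raise StageError("popstats", f"{test}: {exc}") from exc

    # --- annotation --------------------------------------------------------
    genes = (
        read_intervals(config.genes, config.genes_format) if config.genes else None
    )
    qtls = pd.read_csv(config.qtls, sep="\t", dtype={"chrom": str}) if config.qtls else None
    go_map = (
        pd.read_csv(config.go_map, sep="\t", header=None, names=["gene_id", "go_id"])
        if config.go_map
        else None
    )
    effects = read_effects(config.vcf)
    for gname, group in config.groups.items():
        for test in group.subpops:
            regions = consensus[test]
            comps = fst_by_pop[test]
            iv = regions_to_intervalset(regions)
            region_fst = mean_stat_over_intervals(
                comps.chrom, comps.pos, comps.clamped_theta, iv
            )
            region_fst.to_csv(
                out / f"region_fst_{test}.tsv", sep="\t", index=False, na_rep="NA"
            )
            if genes is None:
                continue
            try:
                membership = genes_in_regions(regions, genes)
                region_gene_counts(membership, regions).to_csv(
                    out / f"region_genes_{test}.tsv", sep="\t", index=False
                )
                gene_ids = sorted(set(membership["gene_id"]))
                gene_iv = IntervalSet(
                    genes.df[genes.df["name"].isin(gene_ids)].reset_index(drop=True)
                )
                gene_fst = mean_stat_over_intervals(
                    comps.chrom, comps.pos, comps.clamped_theta, gene_iv
                )
                qov = qtl_overlap(regions, qtls) if qtls is not None else qtl_overlap(
                    regions, pd.DataFrame(columns=["chrom", "start", "end", "trait_id"])
                )
                enriched = (
                    enriched_gene_sets(
                        membership, go_map, list(genes.df["name"]), fdr=config.go_fdr
                    )
                    if go_map is not None
                    else None
                )
                cands = candidate_genes(
                    membership,
                    region_fst=dict(zip(region_fst["name"], region_fst["mean"])),
                    gene_fst=dict(zip(gene_fst["name"], gene_fst["mean"])),
                    effects=effects,
                    qtl_overlaps=qov,
                    enriched_genes=enriched,
                    fst_threshold=config.fst_threshold,
                )
                pd.DataFrame(
                    [
                        {
                            "gene_id": c.gene_id,
                            "region_id": c.region_id,
                            "mean_fst": c.mean_fst,
                            "has_high_impact": c.has_high_impact,
                            "qtl_traits": ";".join(c.qtl_traits),
                            "rationale": ";".join(c.rationale),
                        }
                        for c in cands
                    ]
                ).to_csv(out / f"candidates_{test}.tsv", sep="\t", index=False, na_rep="NA")
            except Exception as exc:
                raise StageError("annotate", f"{test}: {exc}") from exc

    # --- summary table -----------------------------------------------------
    summary = pd.DataFrame(
        [
            {"subpop": pop, **manifest["summaries"][pop]}
            for group in config.groups.values()
            for pop in group.subpops
        ]
    )
    summary["pct_genome"] = summary["pct_genome"].round(1)
    summary.to_csv(out / "summary.tsv", sep="\t", index=False)

    for p in sorted(out.rglob("*.tsv")):
        manifest["checksums"][str(p.relative_to(out))] = _sha256(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
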