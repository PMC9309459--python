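"""Region annotation: gene membership, QTL overlap, candidate-gene calls,
per-subpopulation allele count tables and GO-term enrichment."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, hypergeom

from .variantio import (
    MISSING,
    EffectRecord,
    GenotypeMatrix,
    IntervalSet,
    PopulationMap,
)

# IUPAC ambiguity code for an unordered base pair (heterozygote label)
IUPAC = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}


@dataclass
class CandidateGene:
    gene_id: str
    region_id: str
    mean_fst: float  # NaN when the gene has no SNPs
    has_high_impact: bool
    qtl_traits: list[str]
    rationale: list[str]  # which criteria fired: region_fst / gene_fst / high_impact / qtl


def _overlap_pairs(regions: pd.DataFrame, other: pd.DataFrame) -> list[tuple[int, int, int]]:
    """(region_row, other_row, overlap_bp) for every >=1 bp overlap."""
    out = []
    for i, r in enumerate(regions.itertuples(index=False)):
        sub = other[
            (other["chrom"].astype(str) == str(r.chrom))
            & (other["start"] < r.end)
            & (other["end"] > r.start)
        ]
        for j, o in zip(sub.index, sub.itertuples(index=False)):
            out.append((i, j, int(min(r.end, o.end) - max(r.start, o.start))))
    return out


def genes_in_regions(
    regions: pd.DataFrame, genes: IntervalSet, containment: bool = False
) -> pd.DataFrame:
    """Gene/region membership table (``>= 1`` bp overlap by default;
    ``containment=True`` demands the gene lie fully inside the region).

    Returns columns ``region_id, gene_id, overlap_bp``.
    """
    rows = []
    gdf = genes.df
    for pair in _overlap_pairs(regions, gdf):
        i, j, ov = pair
        r = regions.iloc[i]
        g = gdf.loc[j]
        if containment and not (g["start"] >= r["start"] and g["end"] <= r["end"]):
            continue
        rows.append((r["name"], g["name"], ov))
    return pd.DataFrame(rows, columns=["region_id", "gene_id", "overlap_bp"])


def region_gene_counts(membership: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    counts = membership.groupby("region_id").size()
    out = regions[["name"]].rename(columns={"name": "region_id"}).copy()
    out["n_genes"] = out["region_id"].map(counts).fillna(0).astype(int)
    return out


def qtl_overlap(regions: pd.DataFrame, qtls: pd.DataFrame) -> pd.DataFrame:
    """All (region, QTL) pairs with >= 1 bp overlap.

    Regions without any overlap appear once with empty trait fields, so the
    table enumerates every region.
    """
    rows = []
    seen = set()
    for i, j, ov in _overlap_pairs(regions, qtls):
        r = regions.iloc[i]
        q = qtls.loc[j]
        seen.add(r["name"])
        rows.append(
            (r["name"], str(r["chrom"]), q.get("trait_id", ""), q.get("source", ""),
             ov, q.get("candidate_genes", ""))
        )
    for r in regions.itertuples(index=False):
        if r.name not in seen:
            rows.append((r.name, str(r.chrom), "", "", 0, ""))
    return pd.DataFrame(
        rows,
        columns=["region_id", "chrom", "trait_id", "source", "overlap_bp", "candidate_genes"],
    )


def candidate_genes(
    membership: pd.DataFrame,
    region_fst: Mapping[str, float],
    gene_fst: Mapping[str, float],
    effects: Iterable[EffectRecord],
    qtl_overlaps: pd.DataFrame,
    enriched_genes: Mapping[str, set] | None = None,
    fst_threshold: float = 0.5,
) -> list[CandidateGene]:
    """Flag genes in selected regions meeting any of three criteria.

    1. mean F_ST above ``fst_threshold`` in the whole region, in the gene
       itself, or (when ``enriched_genes`` maps region -> functionally
       enriched gene sets) in an enriched gene;
    2. the gene carries at least one HIGH-impact effect;
    3. the gene is a named candidate of a QTL overlapping the region.
    """
    high_genes = {e.gene_id for e in effects if e.impact == "HIGH"}
    qtl_by_region: dict[str, list[tuple[str, set]]] = {}
    for row in qtl_overlaps.itertuples(index=False):
        cand = set(filter(None, str(row.candidate_genes or "").split(";")))
        if row.trait_id:
            qtl_by_region.setdefault(row.region_id, []).append((row.trait_id, cand))

    out: list[CandidateGene] = []
    for row in membership.itertuples(index=False):
        rationale = []
        rf = region_fst.get(row.region_id, np.nan)
        gf = gene_fst.get(row.gene_id, np.nan)
        in_enriched = bool(
            enriched_genes and row.gene_id in enriched_genes.get(row.region_id, set())
        )
        if np.isfinite(rf) and rf > fst_threshold:
            rationale.append("region_fst")
        if np.isfinite(gf) and gf > fst_threshold and (enriched_genes is None or in_enriched):
            rationale.append("gene_fst")
        if row.gene_id in high_genes:
            rationale.append("high_impact")
        traits = [
            t for t, cand in qtl_by_region.get(row.region_id, []) if row.gene_id in cand
        ]
        if traits:
            rationale.append("qtl")
        if rationale:
            out.append(
                CandidateGene(
                    gene_id=row.gene_id,
                    region_id=row.region_id,
                    mean_fst=float(gf) if np.isfinite(gf) else float("nan"),
                    has_high_impact=row.gene_id in high_genes,
                    qtl_traits=traits,
                    rationale=rationale,
                )
            )
    return out


def allele_count_table(
    gm: GenotypeMatrix,
    snp_keys: Sequence[tuple[str, int]],
    popmap: PopulationMap,
) -> pd.DataFrame:
    """Genotype-class base counts per SNP and subpopulation.

    Homozygotes are reported under the ref/alt base, heterozygotes under
    the IUPAC ambiguity code of the base pair.  Counts plus missing sum to
    the subpopulation's sample count.
    """
    key_index = {(str(c), int(p)): i for i, (c, p) in enumerate(zip(gm.chrom, gm.pos))}
    rows = []
    for chrom, pos in snp_keys:
        key = (str(chrom), int(pos))
        if key not in key_index:
            raise KeyError(f"SNP {key} not in matrix")
        i = key_index[key]
        ref, alt = str(gm.ref[i]), str(gm.alt[i])
        het = IUPAC.get(frozenset((ref, alt)), f"{ref}/{alt}")
        for label in popmap.labels:
            idx = gm.sample_indices(popmap.samples_for(label))
            g = gm.geno[i, idx]
            rows.append(
                {
                    "chrom": chrom, "pos": pos, "subpop": label,
                    "ref_base": ref, "alt_base": alt, "het_code": het,
                    "n_ref_hom": int((g == 0).sum()),
                    "n_het": int((g == 1).sum()),
                    "n_alt_hom": int((g == 2).sum()),
                    "n_missing": int((g == MISSING).sum()),
                }
            )
    return pd.DataFrame(rows)


def go_enrichment(
    region_genes: Sequence[str],
    go_map: Mapping[str, Sequence[str]] | pd.DataFrame,
    background_genes: Sequence[str],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per GO term with BH-FDR.

    ``go_map`` maps gene -> terms (or a two-column DataFrame gene_id,
    go_id).  Only terms annotating >= 1 region gene are tested; the
    universe is ``background_genes`` (the region genes must be a subset).
    Returns ``term, k, n, K, N, p, fdr, enriched`` sorted by p.
    """
    if isinstance(go_map, pd.DataFrame):
        mapping: dict[str, list[str]] = {}
        for g, t in zip(go_map.iloc[:, 0], go_map.iloc[:, 1]):
            mapping.setdefault(str(g), []).append(str(t))
        go_map = mapping

    background = set(background_genes)
    region = set(region_genes)
    if not region <= background:
        raise ValueError("region genes must be a subset of the background")
    if not region:
        return pd.DataFrame(
            columns=["term", "k", "n", "K", "N", "p", "fdr", "enriched"]
        )

    term_background: dict[str, set] = {}
    for gene in background:
        for term in go_map.get(gene, ()):
            term_background.setdefault(term, set()).add(gene)

    N = len(background)
    n = len(region)
    rows = []
    for term, annotated in term_background.items():
        k = len(annotated & region)
        if k == 0:
            continue
        K = len(annotated)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, n, K, N, p))
    df = pd.DataFrame(rows, columns=["term", "k", "n", "K", "N", "p"])
    if len(df):
        df["fdr"] = false_discovery_control(df["p"].to_numpy(), method="bh")
        df["enriched"] = df["fdr"] < fdr
        df = df.sort_values("p", kind="mergesort").reset_index(drop=True)
    else:
        df["fdr"] = []
        df["enriched"] = []
    return df


def enriched_gene_sets(
    membership: pd.DataFrame,
    go_map: pd.DataFrame | Mapping[str, Sequence[str]],
    background_genes: Sequence[str],
    fdr: float = 0.05,
) -> dict[str, set]:
    """Per region: genes annotated with any term enriched in that region."""
    if isinstance(go_map, pd.DataFrame):
        mapping: dict[str, list[str]] = {}
        for g, t in zip(go_map.iloc[:, 0], go_map.iloc[:, 1]):
            mapping.setdefault(str(g), []).append(str(t))
    else:
        mapping = {g: list(t) for g, t in go_map.items()}
    out: dict[str, set] = {}
    for region_id, sub in membership.groupby("region_id"):
        genes = list(sub["gene_id"])
        enr = go_enrichment(genes, mapping, background_genes, fdr=fdr)
        terms = set(enr.loc[enr["enriched"], "term"]) if len(enr) else set()
        out[region_id] = {
            g for g in genes if terms & set(mapping.get(g, ()))
        }
    return out
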