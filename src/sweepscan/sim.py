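"""Synthetic genotype data with known drift and sweep structure.

The neutral simulator draws an ancestral frequency per SNP and lets the
populations diverge along a serial chain: the first population's frequency
is the ancestral draw, and each subsequent population perturbs its
predecessor with a Normal drift kernel of variance
``drift_var * p * (1 - p)`` evaluated at the predecessor's frequency,
clipped to [0, 1] — mirroring the truncated-Normal drift kernel (with
boundary point masses) used by the scan model.  Because the kernel variance
is conditioned on the ancestor, the scan's drift calibration (mean of
``(p1 - p2)^2 / (p1 (1 - p1))``) recovers ``drift_var`` when the earlier
population of an adjacent pair is used as the reference.

Sweeps are injected with the same escape model the scan fits: a SNP at
genetic distance ``d`` Morgans from the focal site hitchhikes with
probability ``1 - c`` where ``c = 1 - exp(-d / strength)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .variantio import (
    MISSING,
    EffectRecord,
    GenotypeMatrix,
    IntervalSet,
    PopulationMap,
    SampleLookupError,
    write_bed,
    write_gff3,
    write_vcf,
)

_BASES = np.array(["A", "C", "G", "T"], dtype=object)

#: bp -> Morgans at r cM/Mb: d = bp * r * 1e-8
CM_PER_MB_TO_MORGAN_PER_BP = 1e-8


@dataclass(frozen=True)
class SimParams:
    """Parameters of the frequency-perturbation simulator."""

    n_pops: int = 2
    n_per_pop: int = 50
    seq_len: int = 1_000_000
    n_chroms: int = 1
    drift_var: float = 0.2
    snp_density: float = 1e-3
    recomb_rate: float = 1.0  # cM/Mb
    seed: int = 0
    pop_labels: tuple[str, ...] | None = None
    anc_freq_range: tuple[float, float] = (0.05, 0.95)

    def __post_init__(self) -> None:
        if not 0.0 <= self.drift_var < 1.0:
            raise ValueError(f"drift_var={self.drift_var} outside [0, 1)")
        if self.n_per_pop < 2:
            raise ValueError("n_per_pop must be >= 2")
        if self.seq_len <= 0 or self.n_chroms <= 0 or self.n_pops <= 0:
            raise ValueError("sizes must be positive")
        if self.pop_labels is not None and len(self.pop_labels) != self.n_pops:
            raise ValueError("pop_labels length != n_pops")

    @property
    def labels(self) -> tuple[str, ...]:
        if self.pop_labels is not None:
            return self.pop_labels
        return tuple(f"pop{i}" for i in range(self.n_pops))


@dataclass(frozen=True)
class SweepSpec:
    """One sweep to inject into a target population."""

    pop: str
    chrom: str
    position: int
    strength: float  # sweep scale in Morgans
    kind: str = "hard"
    soft_init_freq: float | None = None

    def __post_init__(self) -> None:
        if self.strength <= 0:
            raise ValueError("strength must be > 0")
        if self.kind not in ("hard", "soft"):
            raise ValueError(f"kind must be hard|soft, got {self.kind!r}")
        if self.kind == "soft":
            if self.soft_init_freq is None or not 0.0 < self.soft_init_freq < 1.0:
                raise ValueError("soft sweep requires soft_init_freq in (0, 1)")


@dataclass
class SweepTruth:
    """Injected sweeps plus realized focal-site frequencies."""

    specs: list[SweepSpec] = field(default_factory=list)
    focal_freqs: list[float] = field(default_factory=list)


def simulate_neutral(params: SimParams) -> tuple[GenotypeMatrix, PopulationMap]:
    """Simulate drift-structured genotypes for ``params.n_pops`` populations.

    Deterministic given ``params`` (including seed).
    """
    rng = np.random.default_rng(params.seed)
    n_snps_per_chrom = max(1, round(params.snp_density * params.seq_len))
    labels = params.labels

    chroms, poss = [], []
    for ci in range(params.n_chroms):
        name = f"chr{ci + 1}"
        pos = np.sort(rng.choice(params.seq_len, size=n_snps_per_chrom, replace=False)) + 1
        chroms.append(np.full(n_snps_per_chrom, name, dtype=object))
        poss.append(pos.astype(np.int64))
    chrom = np.concatenate(chroms)
    pos = np.concatenate(poss)
    n_snps = len(pos)

    ref_idx = rng.integers(0, 4, size=n_snps)
    alt_shift = rng.integers(1, 4, size=n_snps)
    ref = _BASES[ref_idx]
    alt = _BASES[(ref_idx + alt_shift) % 4]

    lo, hi = params.anc_freq_range
    p_anc = rng.uniform(lo, hi, size=n_snps)

    geno_cols = []
    samples = []
    mapping = {}
    p_pop = p_anc
    for label in labels:
        g = rng.binomial(2, p_pop[:, None], size=(n_snps, params.n_per_pop))
        geno_cols.append(g.astype(np.int8))
        for k in range(params.n_per_pop):
            sid = f"{label}_s{k}"
            samples.append(sid)
            mapping[sid] = label
        # drift kernel for the next population in the chain
        branch_sd = np.sqrt(params.drift_var * p_pop * (1.0 - p_pop))
        p_pop = np.clip(p_pop + rng.normal(0.0, 1.0, size=n_snps) * branch_sd, 0.0, 1.0)
    geno = np.concatenate(geno_cols, axis=1)

    gm = GenotypeMatrix(chrom=chrom, pos=pos, ref=ref, alt=alt, geno=geno, samples=samples)
    return gm, PopulationMap(mapping)


def inject_sweep(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    spec: SweepSpec,
    seed: int,
    recomb_rate: float = 1.0,
) -> tuple[GenotypeMatrix, SweepTruth]:
    """Push linked SNPs of the target population toward fixation.

    Per SNP, a hitchhike event occurs with probability ``1 - c``; on
    hitchhike the SNP's population frequency becomes the allele frequency
    among the founder haplotypes of the sweep (one founder for a hard sweep,
    ``round(soft_init_freq * 2N)`` for a soft sweep) and genotypes are
    redrawn binomially.  SNPs with ``c >= 0.999``, other chromosomes and
    other populations are untouched.
    """
    if spec.pop not in popmap.labels:
        raise SampleLookupError(f"population {spec.pop!r} not in map")
    rng = np.random.default_rng(seed)
    target_samples = popmap.samples_for(spec.pop)
    col_idx = gm.sample_indices(target_samples)
    n_dip = len(col_idx)

    geno = gm.geno.copy()
    on_chrom = gm.chrom == spec.chrom
    d = np.abs(gm.pos - spec.position) * recomb_rate * CM_PER_MB_TO_MORGAN_PER_BP
    c = 1.0 - np.exp(-d / spec.strength)
    affected = on_chrom & (c < 0.999)

    if spec.kind == "hard":
        n_founders = 1
    else:
        n_founders = max(1, round(spec.soft_init_freq * 2 * n_dip))

    sub = geno[np.ix_(affected, col_idx)]
    nonmiss = sub != MISSING
    n_alleles = 2 * nonmiss.sum(axis=1)
    alt = np.where(nonmiss, sub, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)

    hitch = rng.random(affected.sum()) < (1.0 - c[affected])
    hitch &= ~np.isnan(p)
    # allele frequency among sweep founders
    founder_alt = rng.binomial(n_founders, np.nan_to_num(p))
    q = founder_alt / n_founders
    new_geno = rng.binomial(2, q[:, None], size=(affected.sum(), n_dip)).astype(np.int8)
    new_geno[~nonmiss] = MISSING
    sub = np.where(hitch[:, None], new_geno, sub)
    geno[np.ix_(affected, col_idx)] = sub

    out = GenotypeMatrix(
        chrom=gm.chrom, pos=gm.pos, ref=gm.ref, alt=gm.alt, geno=geno, samples=gm.samples
    )
    # realized frequency at the SNP nearest the focal position
    near = np.flatnonzero(on_chrom)
    if len(near):
        j = near[np.argmin(np.abs(gm.pos[near] - spec.position))]
        col = out.geno[j, col_idx]
        nm = col != MISSING
        freq = float(col[nm].sum() / (2 * nm.sum())) if nm.any() else float("nan")
    else:
        freq = float("nan")
    return out, SweepTruth(specs=[spec], focal_freqs=[freq])


# ---------------------------------------------------------------------------
# Toy annotation fixtures
# ---------------------------------------------------------------------------


@dataclass
class ToyAnnotation:
    genes: IntervalSet
    qtls: pd.DataFrame  # chrom, start, end, trait_id, source, candidate_genes
    go_map: pd.DataFrame  # gene_id, go_id
    centromeres: IntervalSet
    effects: list[EffectRecord]
    ann_strings: dict[int, str]  # SNP row index -> ANN INFO value


def make_toy_annotation(
    chrom_lengths: Mapping[str, int],
    seed: int,
    n_genes_per_chrom: int = 100,
    n_go_terms: int = 20,
    go_genes_per_term: int = 10,
    n_qtls_per_chrom: int = 3,
    centromere_len: int = 200_000,
    gm: GenotypeMatrix | None = None,
    n_high_effect_genes: int = 5,
) -> ToyAnnotation:
    """Build deterministic toy annotation over the given chromosomes.

    Genes are non-overlapping tiles; a controlled number of genes carry each
    GO term; QTLs are broad intervals with named candidate genes; the
    centromere is a ``centromere_len`` interval at each chromosome midpoint.
    If ``gm`` is given, HIGH-impact effects are placed on SNPs inside the
    first ``n_high_effect_genes`` genes that contain a SNP.
    """
    rng = np.random.default_rng(seed)

    gene_rows = []
    for chrom, length in chrom_lengths.items():
        slot = length // n_genes_per_chrom
        glen = max(1, int(slot * 0.6))
        for i in range(n_genes_per_chrom):
            start = i * slot
            gene_rows.append((chrom, start, min(start + glen, length), f"G_{chrom}_{i:04d}"))
    genes = IntervalSet(pd.DataFrame(gene_rows, columns=IntervalSet.COLUMNS))

    gene_ids = list(genes.df["name"])
    go_rows = []
    for t in range(n_go_terms):
        term = f"GO:{7000000 + t:07d}"
        chosen = rng.choice(len(gene_ids), size=min(go_genes_per_term, len(gene_ids)),
                            replace=False)
        for gi in sorted(chosen):
            go_rows.append((gene_ids[gi], term))
    go_map = pd.DataFrame(go_rows, columns=["gene_id", "go_id"])

    traits = ["GL", "PBN", "DRP", "TIL", "SPN", "RL"]
    qtl_rows = []
    for chrom, length in chrom_lengths.items():
        for i in range(n_qtls_per_chrom):
            start = int(rng.integers(0, max(1, length - length // 5)))
            end = min(start + length // 5, length)
            in_genes = genes.df[(genes.df["chrom"] == chrom)
                                & (genes.df["start"] < end) & (genes.df["end"] > start)]
            cand = ";".join(in_genes["name"].iloc[:2]) if len(in_genes) else ""
            qtl_rows.append(
                (chrom, start, end, traits[i % len(traits)], f"study{i % 3 + 1}", cand)
            )
    qtls = pd.DataFrame(
        qtl_rows, columns=["chrom", "start", "end", "trait_id", "source", "candidate_genes"]
    )

    cen_rows = []
    for chrom, length in chrom_lengths.items():
        mid = length // 2
        half = centromere_len // 2
        cen_rows.append((chrom, max(0, mid - half), min(length, mid + half), f"cen_{chrom}"))
    centromeres = IntervalSet(pd.DataFrame(cen_rows, columns=IntervalSet.COLUMNS))

    effects: list[EffectRecord] = []
    ann_strings: dict[int, str] = {}
    if gm is not None:
        consequences = ["stop_gained", "start_lost", "splice_acceptor_variant"]
        placed = 0
        for row in genes.df.itertuples(index=False):
            if placed >= n_high_effect_genes:
                break
            hits = np.flatnonzero(
                (gm.chrom == row.chrom) & (gm.pos - 1 >= row.start) & (gm.pos - 1 < row.end)
            )
            if not len(hits):
                continue
            j = int(hits[len(hits) // 2])
            conseq = consequences[placed % len(consequences)]
            rec = EffectRecord(
                chrom=str(gm.chrom[j]), pos=int(gm.pos[j]), ref=str(gm.ref[j]),
                alt=str(gm.alt[j]), gene_id=row.name, impact="HIGH", consequence=conseq,
            )
            effects.append(rec)
            ann_strings[j] = (
                f"{rec.alt}|{conseq}|HIGH|{row.name}|{row.name}|transcript|"
                f"{row.name}.1|protein_coding|1/1|c.1A>T|p.Met1?"
            )
            placed += 1
    return ToyAnnotation(
        genes=genes, qtls=qtls, go_map=go_map, centromeres=centromeres,
        effects=effects, ann_strings=ann_strings,
    )


def write_annotation_files(toy: ToyAnnotation, outdir: str | Path) -> dict[str, Path]:
    """Write fixture annotation in standard formats; returns path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes_gff3": outdir / "genes.gff3",
        "genes_bed": outdir / "genes.bed",
        "qtls": outdir / "qtls.tsv",
        "go_map": outdir / "go_map.tsv",
        "centromeres": outdir / "centromeres.bed",
        "effects": outdir / "effects.tsv",
    }
    write_gff3(toy.genes, paths["genes_gff3"])
    write_bed(toy.genes, paths["genes_bed"])
    toy.qtls.to_csv(paths["qtls"], sep="\t", index=False)
    toy.go_map.to_csv(paths["go_map"], sep="\t", index=False, header=False)
    write_bed(toy.centromeres, paths["centromeres"])
    pd.DataFrame([vars(e) for e in toy.effects]).to_csv(
        paths["effects"], sep="\t", index=False
    )
    return paths


def write_popmap(popmap: PopulationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s, l in popmap.items():
            fh.write(f"{s}\t{l}\n")


#: sweeps planted by :func:`make_bundled_dataset`
BUNDLED_SWEEPS = (
    SweepSpec(pop="I5", chrom="chr1", position=1_250_000, strength=0.04),
    SweepSpec(pop="I2", chrom="chr2", position=3_750_000, strength=0.04),
    SweepSpec(pop="J3", chrom="chr1", position=3_750_000, strength=0.04),
)

BUNDLED_RECOMB_RATE = 10.0  # cM/Mb, shared by simulation and scan config


def make_bundled_dataset(
    outdir: str | Path,
    seed: int = 0,
    n_per_pop: int = 20,
    seq_len: int = 5_000_000,
    snp_density: float = 1e-3,
    drift_var: float = 0.08,
) -> dict[str, Path]:
    """Write the bundled 9-subpopulation dataset with three planted sweeps.

    Produces VCF (with a few HIGH-impact ANN entries), population map, toy
    annotation files and a ready-to-run pipeline ``config.yaml``; returns a
    name -> path mapping including ``"truth"`` (planted sweeps TSV).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    labels = ("I1", "I2", "I3", "I4", "I5", "J1", "J2", "J3", "J4")
    params = SimParams(
        n_pops=len(labels), n_per_pop=n_per_pop, seq_len=seq_len, n_chroms=2,
        drift_var=drift_var, snp_density=snp_density,
        recomb_rate=BUNDLED_RECOMB_RATE, seed=seed, pop_labels=labels,
    )
    gm, popmap = simulate_neutral(params)
    truths = []
    for i, spec in enumerate(BUNDLED_SWEEPS):
        gm, truth = inject_sweep(
            gm, popmap, spec, seed=seed + 1000 + i, recomb_rate=BUNDLED_RECOMB_RATE
        )
        truths.append(truth)

    chrom_lengths = {c: seq_len for c in gm.chroms()}
    toy = make_toy_annotation(chrom_lengths, seed=seed + 7, gm=gm,
                              n_high_effect_genes=6)
    paths = write_annotation_files(toy, outdir)
    paths["vcf"] = outdir / "genotypes.vcf"
    write_vcf(gm, paths["vcf"], ann=toy.ann_strings, contig_lengths=chrom_lengths)
    paths["popmap"] = outdir / "popmap.tsv"
    write_popmap(popmap, paths["popmap"])

    paths["truth"] = outdir / "sweep_truth.tsv"
    pd.DataFrame(
        [
            {
                "pop": s.pop, "chrom": s.chrom, "position": s.position,
                "strength": s.strength, "kind": s.kind,
                "focal_freq": t.focal_freqs[0],
            }
            for s, t in zip(BUNDLED_SWEEPS, truths)
        ]
    ).to_csv(paths["truth"], sep="\t", index=False)

    config = f"""\
vcf: genotypes.vcf
popmap: popmap.tsv
genes: genes.gff3
genes_format: GFF3
qtls: qtls.tsv
centromeres: centromeres.bed
go_map: go_map.tsv
outdir: results
groups:
  Indica:
    subpops: [I1, I2, I3, I4, I5]
    min_support: 3
  Japonica:
    subpops: [J1, J2, J3, J4]
    min_support: 2
filter:
  maf_min: 0.05
  het_max: 0.591
  max_missing: 0.2
scan:
  window_bp: 100000
  step_bp: 10000
  max_snps_per_window: 200
  recomb_rate_default: {BUNDLED_RECOMB_RATE}
regions:
  merge_gap_bp: 100000
  min_len_bp: 80000
chrom_lengths:
  chr1: {seq_len}
  chr2: {seq_len}
seed: {seed}
"""
    paths["config"] = outdir / "config.yaml"
    paths["config"].write_text(config)
    return paths
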