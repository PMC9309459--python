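"""Variant and interval I/O plus SNP-level filtering.

Conventions
-----------
* Genotypes are stored as alt-allele dosage (0/1/2) in an int8 SNP x sample
  matrix; missing calls are ``-1``.
* SNP positions are kept 1-based (VCF convention); all interval data is
  converted to 0-based half-open on read.  A SNP at position ``pos`` falls in
  interval ``[start, end)`` iff ``start <= pos - 1 < end``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

IMPACTS = ("HIGH", "MODERATE", "LOW", "MODIFIER")


class VariantFormatError(ValueError):
    """Raised for malformed variant/interval input."""


class SampleLookupError(KeyError):
    """Raised when a sample or population label cannot be resolved."""


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Biallelic SNP x sample matrix of diploid alt-allele dosages.

    Attributes
    ----------
    chrom, pos, ref, alt
        Per-SNP arrays; ``pos`` is 1-based.  Positions are strictly
        increasing within each chromosome.
    geno
        ``(n_snps, n_samples)`` int8 array with values {0, 1, 2, -1}.
    samples
        Sample identifiers, one per genotype column.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    geno: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.geno = np.asarray(self.geno, dtype=np.int8)
        self.samples = list(self.samples)
        if self.geno.shape != (len(self.pos), len(self.samples)):
            raise ValueError(
                f"geno shape {self.geno.shape} does not match "
                f"{len(self.pos)} SNPs x {len(self.samples)} samples"
            )

    @property
    def n_snps(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def chroms(self) -> list[str]:
        """Chromosome names in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def take(self, index) -> "GenotypeMatrix":
        """Row-subset (SNPs) by boolean mask or integer index."""
        index = np.asarray(index)
        return GenotypeMatrix(
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            geno=self.geno[index],
            samples=self.samples,
        )

    def sample_indices(self, names: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[n] for n in names], dtype=np.intp)
        except KeyError as exc:
            raise SampleLookupError(f"sample {exc.args[0]!r} not in matrix") from exc

    def subset_samples(self, names: Sequence[str]) -> "GenotypeMatrix":
        idx = self.sample_indices(names)
        return GenotypeMatrix(
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            geno=self.geno[:, idx],
            samples=[self.samples[i] for i in idx],
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.samples == other.samples
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.alt, other.alt)
            and np.array_equal(self.geno, other.geno)
        )

    def validate(self) -> None:
        """Check ordering and dosage invariants; raise on violation."""
        ok = np.isin(np.unique(self.geno), [MISSING, 0, 1, 2]).all()
        if not ok:
            raise ValueError("genotype dosages outside {0,1,2,missing}")
        for c in self.chroms():
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")


class PopulationMap(Mapping[str, str]):
    """sample_id -> subpopulation label."""

    def __init__(self, mapping: Mapping[str, str]):
        bad = [s for s, l in mapping.items() if not l]
        if bad:
            raise ValueError(f"empty population label for samples {bad[:5]}")
        self._map = dict(mapping)

    def __getitem__(self, key: str) -> str:
        return self._map[key]

    def __iter__(self):
        return iter(self._map)

    def __len__(self) -> int:
        return len(self._map)

    @property
    def labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for l in self._map.values():
            seen.setdefault(l, None)
        return list(seen)

    def samples_for(self, label: str) -> list[str]:
        out = [s for s, l in self._map.items() if l == label]
        if not out:
            raise SampleLookupError(f"no samples for population {label!r}")
        return out

    def validate_against(self, gm: GenotypeMatrix) -> None:
        missing = [s for s in gm.samples if s not in self._map]
        if missing:
            raise SampleLookupError(
                f"{len(missing)} matrix samples lack population labels "
                f"(first: {missing[:5]})"
            )


@dataclass(frozen=True)
class FilterParams:
    """SNP-level filter thresholds.

    ``het_max`` is interpreted per SNP as the fraction of non-missing
    genotype calls that are heterozygous.
    """

    maf_min: float = 0.05
    het_max: float = 0.591
    max_missing: float = 1.0

    def __post_init__(self) -> None:
        for name in ("maf_min", "het_max", "max_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class FilterReport:
    n_input: int
    n_output: int
    n_fail_maf: int
    n_fail_het: int
    n_fail_missing: int


class IntervalSet:
    """Genomic intervals, 0-based half-open, with optional name/payload."""

    COLUMNS = ["chrom", "start", "end", "name"]

    def __init__(self, df: pd.DataFrame | None = None):
        if df is None:
            df = pd.DataFrame(columns=self.COLUMNS)
        df = df.copy()
        if "name" not in df.columns:
            df["name"] = [f"iv{i}" for i in range(len(df))]
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if len(df) and (df["start"] >= df["end"]).any():
            raise ValueError("interval with start >= end")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "IntervalSet":
        rows = list(records)
        if not rows:
            return cls()
        ncol = len(rows[0])
        cols = cls.COLUMNS[:ncol]
        return cls(pd.DataFrame(rows, columns=cols))

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        return self.df.itertuples(index=False)

    def sort(self) -> "IntervalSet":
        return IntervalSet(self.df.sort_values(["chrom", "start", "end"]))

    def total_length(self) -> int:
        return int((self.df["end"] - self.df["start"]).sum())

    def merge(self, gap: int = 0) -> "IntervalSet":
        """Merge intervals whose gap is <= ``gap`` bp (overlaps always merge)."""
        out = []
        for chrom, sub in self.sort().df.groupby("chrom", sort=False):
            cur_s, cur_e = None, None
            for s, e in zip(sub["start"], sub["end"]):
                if cur_s is None:
                    cur_s, cur_e = s, e
                elif s - cur_e <= gap:
                    cur_e = max(cur_e, e)
                else:
                    out.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            if cur_s is not None:
                out.append((chrom, cur_s, cur_e))
        df = pd.DataFrame(out, columns=["chrom", "start", "end"])
        df["name"] = [f"iv{i}" for i in range(len(df))]
        return IntervalSet(df)

    def contains_positions(self, chrom: np.ndarray, pos_1based: np.ndarray) -> np.ndarray:
        """Boolean mask: which (chrom, pos) pairs fall inside any interval."""
        p0 = np.asarray(pos_1based) - 1
        mask = np.zeros(len(p0), dtype=bool)
        for c, sub in self.df.groupby("chrom", sort=False):
            sel = np.asarray(chrom) == c
            if not sel.any():
                continue
            p = p0[sel]
            hit = np.zeros(len(p), dtype=bool)
            for s, e in zip(sub["start"], sub["end"]):
                hit |= (p >= s) & (p < e)
            m = mask[sel]
            m |= hit
            mask[sel] = m
        return mask


@dataclass(frozen=True)
class EffectRecord:
    """One predicted SNP consequence (SnpEff-style)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str
    impact: str
    consequence: str

    def __post_init__(self) -> None:
        if self.impact not in IMPACTS:
            raise ValueError(f"impact {self.impact!r} not in {IMPACTS}")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_vcf(path: str | Path, region: str | None = None) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Multi-allelic records and indels are skipped (counts logged); half
    calls and missing genotypes map to missing.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # pragma: no cover - htslib error text varies
        raise VariantFormatError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    chrom, pos, ref, alt, rows = [], [], [], [], []
    n_skipped_multi = n_skipped_indel = 0
    it = vcf(region) if region else vcf
    for lineno, v in enumerate(it, start=1):
        if len(v.ALT) != 1:
            n_skipped_multi += 1
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped_indel += 1
            continue
        # gts012=True: 0/1/2 = dosage, 3 = unknown (includes half calls)
        g = np.asarray(v.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        rows.append(g)
    if n_skipped_multi or n_skipped_indel:
        logger.info(
            "read_vcf(%s): skipped %d multi-allelic and %d indel records",
            path.name, n_skipped_multi, n_skipped_indel,
        )
    geno = np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    return GenotypeMatrix(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        geno=geno,
        samples=samples,
    )


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(
    gm: GenotypeMatrix,
    path: str | Path,
    ann: Mapping[int, str] | None = None,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write a minimal VCF 4.2 with GT fields (and optional ANN INFO).

    ``ann`` maps SNP row index -> ANN INFO string value.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if contig_lengths:
            for c, l in contig_lengths.items():
                fh.write(f"##contig=<ID={c},length={l}>\n")
        else:
            for c in gm.chroms():
                fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.samples) + "\n")
        for i in range(gm.n_snps):
            info = f"ANN={ann[i]}" if ann and i in ann else "."
            gts = "\t".join(_GT_STR[int(g)] for g in gm.geno[i])
            fh.write(
                f"{gm.chrom[i]}\t{gm.pos[i]}\t.\t{gm.ref[i]}\t{gm.alt[i]}"
                f"\t.\t.\t{info}\tGT\t{gts}\n"
            )


def read_population_map(path: str | Path) -> PopulationMap:
    """Read a two-column TSV ``sample_id<TAB>subpopulation``."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "pop"], dtype=str,
                     comment="#")
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise VariantFormatError(f"duplicate sample {dup!r} in population map")
    return PopulationMap(dict(zip(df["sample"], df["pop"])))


def read_intervals(path: str | Path, fmt: str = "BED") -> IntervalSet:
    """Read intervals from BED (0-based half-open), GFF3 (1-based closed,
    converted) or a BED-like TSV with a header row."""
    fmt = fmt.upper()
    path = Path(path)
    if fmt == "BED":
        try:
            df = pd.read_csv(path, sep="\t", header=None, comment="#",
                             usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "name"],
                             dtype={0: str})
        except ValueError:
            try:
                df = pd.read_csv(path, sep="\t", header=None, comment="#",
                                 usecols=[0, 1, 2], names=["chrom", "start", "end"],
                                 dtype={0: str})
            except pd.errors.EmptyDataError:
                return IntervalSet()
        except pd.errors.EmptyDataError:
            return IntervalSet()
        return IntervalSet(df)
    if fmt == "GFF3":
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 9:
                    raise VariantFormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
                chrom, _src, ftype, start, end, _score, _strand, _phase, attrs = parts
                name = ftype
                for kv in attrs.split(";"):
                    if kv.startswith("ID="):
                        name = kv[3:]
                        break
                rows.append((chrom, int(start) - 1, int(end), name))
        return IntervalSet(pd.DataFrame(rows, columns=IntervalSet.COLUMNS))
    if fmt == "TSV":
        try:
            df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        except pd.errors.EmptyDataError:
            return IntervalSet()
        required = {"chrom", "start", "end"}
        if not required <= set(df.columns):
            raise VariantFormatError(f"{path}: TSV needs columns {sorted(required)}")
        if "name" not in df.columns:
            for cand in ("trait_id", "id"):
                if cand in df.columns:
                    df = df.rename(columns={cand: "name"})
                    break
        return IntervalSet(df)
    raise ValueError(f"unknown interval format {fmt!r}")


def write_bed(ivs: IntervalSet, path: str | Path, scores: Sequence | None = None) -> None:
    df = ivs.df[["chrom", "start", "end", "name"]].copy()
    if scores is not None:
        df["score"] = list(scores)
        df["strand"] = "."
    df.to_csv(path, sep="\t", header=False, index=False)


def write_gff3(ivs: IntervalSet, path: str | Path, feature_type: str = "gene") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in ivs.df.itertuples(index=False):
            fh.write(
                f"{row.chrom}\tsweepscan\t{feature_type}\t{row.start + 1}\t{row.end}"
                f"\t.\t+\t.\tID={row.name}\n"
            )


# SnpEff ANN sub-fields: Allele | Annotation | Impact | Gene_Name | Gene_ID | ...
_ANN_CONSEQ, _ANN_IMPACT, _ANN_GENE_ID = 1, 2, 4


def parse_ann(chrom: str, pos: int, ref: str, alt: str, ann_value: str) -> list[EffectRecord]:
    """Split one ANN INFO value into :class:`EffectRecord` entries."""
    out = []
    for entry in ann_value.split(","):
        fields = entry.split("|")
        if len(fields) <= _ANN_GENE_ID:
            raise VariantFormatError(f"ANN entry with too few fields: {entry!r}")
        out.append(
            EffectRecord(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                gene_id=fields[_ANN_GENE_ID],
                impact=fields[_ANN_IMPACT],
                consequence=fields[_ANN_CONSEQ],
            )
        )
    return out


def read_effects(path: str | Path) -> list[EffectRecord]:
    """Collect EffectRecords from the ANN INFO field of a VCF."""
    from cyvcf2 import VCF

    out: list[EffectRecord] = []
    for v in VCF(str(path)):
        ann = v.INFO.get("ANN")
        if ann is None or len(v.ALT) != 1:
            continue
        out.extend(parse_ann(v.CHROM, v.POS, v.REF, v.ALT[0], ann))
    return out


# ---------------------------------------------------------------------------
# Filtering and frequencies
# ---------------------------------------------------------------------------


def apply_filters(gm: GenotypeMatrix, fp: FilterParams | None = None) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop SNPs failing MAF / heterozygosity / missingness thresholds.

    Per-rule failure counts are evaluated independently on the input matrix;
    the dropped set is their union.  Order of retained SNPs is preserved.
    """
    fp = fp or FilterParams()
    g = gm.geno
    nonmiss = g != MISSING
    n_called = nonmiss.sum(axis=1)
    n_alleles = 2 * n_called
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_count = np.where(nonmiss, g, 0).sum(axis=1)
        p = np.where(n_alleles > 0, alt_count / np.maximum(n_alleles, 1), np.nan)
        maf = np.minimum(p, 1 - p)
        het_frac = np.where(
            n_called > 0, (g == 1).sum(axis=1) / np.maximum(n_called, 1), 0.0
        )
        miss_frac = 1.0 - n_called / max(gm.n_samples, 1)

    fail_maf = ~(maf >= fp.maf_min)  # NaN (all-missing) counts as fail
    fail_het = het_frac > fp.het_max
    fail_miss = miss_frac > fp.max_missing
    keep = ~(fail_maf | fail_het | fail_miss)

    report = FilterReport(
        n_input=gm.n_snps,
        n_output=int(keep.sum()),
        n_fail_maf=int(fail_maf.sum()),
        n_fail_het=int(fail_het.sum()),
        n_fail_missing=int(fail_miss.sum()),
    )
    if report.n_output == 0 and report.n_input > 0:
        logger.warning("apply_filters: no SNPs survive filtering")
    return gm.take(keep), report


def allele_frequencies(
    gm: GenotypeMatrix, popmap: PopulationMap, pop_label: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP alt-allele frequency and non-missing allele count for one
    subpopulation.  Frequency is NaN where no calls exist."""
    samples = popmap.samples_for(pop_label)
    idx = gm.sample_indices(samples)
    g = gm.geno[:, idx]
    nonmiss = g != MISSING
    n = 2 * nonmiss.sum(axis=1)
    alt = np.where(nonmiss, g, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    return p, n.astype(np.int64)
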