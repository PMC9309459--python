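"""Weir-Cockerham F_ST and windowed nucleotide diversity.

Two-population variance-component F_ST follows Weir & Cockerham (1984) for
diploid data: per SNP, ``a`` (among populations), ``b`` (among individuals
within populations) and ``c`` (within individuals) are computed from the
per-population sample sizes, allele frequencies and observed heterozygote
frequencies; ``theta = a / (a + b + c)``.  SNPs monomorphic across the two
populations pooled are removed; negative theta is clamped to 0 (the raw
value is kept alongside).

Windowed F_ST uses the ratio-of-sums estimator ``sum(a) / sum(a+b+c)``;
per-gene / per-region values are means of per-SNP clamped theta.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .variantio import MISSING, GenotypeMatrix, IntervalSet
from .windows import infer_chrom_lengths, tile_windows


@dataclass
class FstComponents:
    """Per-SNP WC84 variance components for retained (polymorphic) SNPs."""

    chrom: np.ndarray
    pos: np.ndarray  # 1-based
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    theta: np.ndarray
    clamped_theta: np.ndarray
    n_removed_monomorphic: int
    n_removed_degenerate: int

    def __len__(self) -> int:
        return len(self.pos)


def _pop_summaries(g: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n individuals, alt frequency, observed het frequency) per SNP."""
    nonmiss = g != MISSING
    n = nonmiss.sum(axis=1)
    alt = np.where(nonmiss, g, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(2 * n, 1), np.nan)
        h = np.where(n > 0, (g == 1).sum(axis=1) / np.maximum(n, 1), np.nan)
    return n.astype(float), p, h


def wc_fst_per_snp(
    gm: GenotypeMatrix,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
) -> FstComponents:
    """Two-population Weir & Cockerham (1984) components per SNP.

    One side may be a pooled union of subpopulations treated as a single
    population.  Sample sets must be non-empty and disjoint.
    """
    if not samples_a or not samples_b:
        raise ValueError("both sample sets must be non-empty")
    if set(samples_a) & set(samples_b):
        raise ValueError("sample sets overlap")

    ga = gm.geno[:, gm.sample_indices(samples_a)]
    gb = gm.geno[:, gm.sample_indices(samples_b)]
    n1, p1, h1 = _pop_summaries(ga)
    n2, p2, h2 = _pop_summaries(gb)

    valid = (n1 > 0) & (n2 > 0)
    # pooled-monomorphic removal
    with np.errstate(invalid="ignore"):
        p_pool = np.where(valid, (2 * n1 * p1 + 2 * n2 * p2) / (2 * n1 + 2 * n2), np.nan)
    poly = valid & (p_pool > 0.0) & (p_pool < 1.0)
    n_mono = int((valid & ~poly).sum()) + int((~valid).sum())

    r = 2.0
    n1p, n2p = n1[poly], n2[poly]
    p1p, p2p = p1[poly], p2[poly]
    h1p, h2p = h1[poly], h2[poly]

    nbar = (n1p + n2p) / r
    nc = (r * nbar - (n1p**2 + n2p**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1p * p1p + n2p * p2p) / (r * nbar)
    s2 = (n1p * (p1p - pbar) ** 2 + n2p * (p2p - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1p * h1p + n2p * h2p) / (r * nbar)

    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        cc = hbar / 2.0
        denom = a + b + cc
        theta = np.where(denom != 0, a / np.where(denom != 0, denom, 1.0), np.nan)

    nondegen = np.isfinite(theta)
    n_degen = int((~nondegen).sum())

    keep = np.flatnonzero(poly)[nondegen]
    return FstComponents(
        chrom=gm.chrom[keep],
        pos=gm.pos[keep],
        a=a[nondegen],
        b=b[nondegen],
        c=cc[nondegen],
        theta=theta[nondegen],
        clamped_theta=np.maximum(theta[nondegen], 0.0),
        n_removed_monomorphic=n_mono,
        n_removed_degenerate=n_degen,
    )


TRACK_COLUMNS = ["chrom", "start", "end", "focal_bp", "n_snps", "score", "sigma_hat"]


def _empty_track_row(chrom, start, end, n, value, partial):
    return (chrom, start, end, (start + end) // 2, n, value, np.nan, bool(partial))


def windowed_fst(
    comps: FstComponents,
    window_bp: int = 100_000,
    step_bp: int = 10_000,
    chrom_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Ratio-of-sums windowed F_ST track (clamped at 0); empty windows NaN."""
    if chrom_lengths is None:
        chrom_lengths = infer_chrom_lengths(comps.chrom, comps.pos, step_bp)
    rows = []
    for chrom in dict.fromkeys(comps.chrom):
        on = comps.chrom == chrom
        pos0 = comps.pos[on] - 1
        a = comps.a[on]
        abc = a + comps.b[on] + comps.c[on]
        for start, end, partial in tile_windows(int(chrom_lengths[str(chrom)]), window_bp, step_bp):
            lo = np.searchsorted(pos0, start, side="left")
            hi = np.searchsorted(pos0, end, side="left")
            if hi == lo:
                rows.append(_empty_track_row(chrom, start, end, 0, np.nan, partial))
                continue
            denom = abc[lo:hi].sum()
            val = max(0.0, a[lo:hi].sum() / denom) if denom != 0 else np.nan
            rows.append(_empty_track_row(chrom, start, end, hi - lo, val, partial))
    return pd.DataFrame(rows, columns=TRACK_COLUMNS + ["partial"])


def site_pi(n_alt: np.ndarray, n_total: np.ndarray) -> np.ndarray:
    """Per-site pairwise diversity ``2 k (n-k) / (n (n-1))`` of allele counts."""
    n = n_total.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(n > 1, 2.0 * n_alt * (n - n_alt) / (n * (n - 1.0)), np.nan)
    return out


def nucleotide_diversity(
    gm: GenotypeMatrix,
    pop_samples: Sequence[str],
    window_bp: int = 100_000,
    step_bp: int = 10_000,
    chrom_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Windowed per-bp nucleotide diversity track for one population.

    Window pi is the sum of per-site pi over the window divided by
    ``window_bp``; sites without any non-missing call contribute 0 but a
    window where *all* SNP sites are uncalled is flagged missing (NaN).
    """
    if not pop_samples:
        raise ValueError("population sample list is empty")
    g = gm.geno[:, gm.sample_indices(pop_samples)]
    nonmiss = g != MISSING
    n = 2 * nonmiss.sum(axis=1)
    k = np.where(nonmiss, g, 0).sum(axis=1)
    pi_site = site_pi(k, n)

    if chrom_lengths is None:
        chrom_lengths = infer_chrom_lengths(gm.chrom, gm.pos, step_bp)
    rows = []
    for chrom in gm.chroms():
        on = gm.chrom == chrom
        pos0 = gm.pos[on] - 1
        ps = pi_site[on]
        for start, end, partial in tile_windows(int(chrom_lengths[str(chrom)]), window_bp, step_bp):
            lo = np.searchsorted(pos0, start, side="left")
            hi = np.searchsorted(pos0, end, side="left")
            seg = ps[lo:hi]
            called = np.isfinite(seg)
            if hi > lo and not called.any():
                rows.append(_empty_track_row(chrom, start, end, hi - lo, np.nan, partial))
                continue
            val = float(np.nansum(seg)) / window_bp
            rows.append(_empty_track_row(chrom, start, end, hi - lo, val, partial))
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS + ["partial"])
    return df.rename(columns={"score": "pi"}).drop(columns=["sigma_hat"])


def mean_stat_over_intervals(
    chrom: np.ndarray,
    pos: np.ndarray,
    values: np.ndarray,
    intervals: IntervalSet,
) -> pd.DataFrame:
    """Arithmetic mean of per-SNP values inside each interval.

    Intervals without SNPs get NaN (flagged missing, never 0).  Positions
    are 1-based; intervals 0-based half-open.
    """
    pos0 = np.asarray(pos) - 1
    out = []
    for row in intervals.df.itertuples(index=False):
        m = (np.asarray(chrom) == row.chrom) & (pos0 >= row.start) & (pos0 < row.end)
        n = int(m.sum())
        mean = float(np.mean(values[m])) if n else np.nan
        out.append((row.chrom, row.start, row.end, row.name, n, mean))
    return pd.DataFrame(out, columns=["chrom", "start", "end", "name", "n_snps", "mean"])
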