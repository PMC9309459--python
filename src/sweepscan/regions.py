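"""Selected-region calling: percentile cutoffs, centromere masking,
merging, per-subpopulation consensus and summary arithmetic."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .variantio import IntervalSet


@dataclass(frozen=True)
class RegionCallParams:
    merge_gap_bp: int = 100_000
    min_len_bp: int = 80_000
    min_support: int = 1

    def __post_init__(self) -> None:
        if self.merge_gap_bp < 0 or self.min_len_bp < 0:
            raise ValueError("gap/length parameters must be >= 0")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")


@dataclass
class CutoffSpec:
    """Per-comparison 99th percentiles and their mean (the cutoff)."""

    q99_per_comparison: dict[str, float]
    cutoff: float
    q: float = 99.0


def percentile_cutoff(tracks: Mapping[str, pd.DataFrame], q: float = 99.0) -> CutoffSpec:
    """Mean of per-comparison score percentiles (linear interpolation).

    All-missing tracks are excluded with a warning; at least one scored
    track is required.
    """
    import warnings

    q99: dict[str, float] = {}
    for name, track in tracks.items():
        scores = track["score"].to_numpy(dtype=float)
        scores = scores[np.isfinite(scores)]
        if len(scores) == 0:
            warnings.warn(f"track {name!r} has no scored windows; excluded from cutoff")
            continue
        q99[name] = float(np.percentile(scores, q, method="linear"))
    if not q99:
        raise ValueError("no scored tracks supplied")
    return CutoffSpec(q99_per_comparison=q99, cutoff=float(np.mean(list(q99.values()))), q=q)


def mask_centromeres(track: pd.DataFrame, mask: IntervalSet) -> pd.DataFrame:
    """Set windows overlapping any mask interval to missing (NaN score)."""
    out = track.copy()
    if len(mask) == 0:
        return out
    drop = np.zeros(len(out), dtype=bool)
    for row in mask.df.itertuples(index=False):
        drop |= (
            (out["chrom"].to_numpy() == row.chrom)
            & (out["start"].to_numpy() < row.end)
            & (out["end"].to_numpy() > row.start)
        )
    out.loc[drop, "score"] = np.nan
    if "sigma_hat" in out.columns:
        out.loc[drop, "sigma_hat"] = np.nan
    return out


def call_regions(
    track: pd.DataFrame, cutoff: float, params: RegionCallParams | None = None
) -> pd.DataFrame:
    """Windows with score strictly above the cutoff, merged (gap <=
    merge_gap_bp) and length-filtered; per-region max window score kept.

    Returns a DataFrame ``chrom, start, end, name, max_score``.
    """
    params = params or RegionCallParams()
    qual = track[track["score"] > cutoff]
    rows = []
    for chrom, sub in qual.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        cur_s = cur_e = None
        cur_score = -np.inf
        for s, e, sc in zip(sub["start"], sub["end"], sub["score"]):
            if cur_s is None:
                cur_s, cur_e, cur_score = s, e, sc
            elif s - cur_e <= params.merge_gap_bp:
                cur_e = max(cur_e, e)
                cur_score = max(cur_score, sc)
            else:
                rows.append((chrom, cur_s, cur_e, cur_score))
                cur_s, cur_e, cur_score = s, e, sc
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e, cur_score))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "max_score"])
    df = df[df["end"] - df["start"] >= params.min_len_bp].reset_index(drop=True)
    df.insert(3, "name", [f"R{i + 1}" for i in range(len(df))])
    return df


def consensus_regions(
    region_sets: Mapping[str, pd.DataFrame],
    params: RegionCallParams,
    reapply_min_len: bool = True,
) -> pd.DataFrame:
    """Per-base support depth across per-comparison region sets; bases with
    depth >= min_support are kept, merged (gap <= merge_gap_bp) and
    length-filtered.  Provenance lists the comparisons overlapping each
    final interval.
    """
    if params.min_support > len(region_sets):
        raise ValueError(
            f"min_support={params.min_support} exceeds number of region sets "
            f"({len(region_sets)})"
        )
    chroms: dict[str, list[tuple[int, int]]] = {}
    for name, df in region_sets.items():
        for row in df.itertuples(index=False):
            chroms.setdefault(str(row.chrom), []).append((int(row.start), int(row.end)))

    deep_rows = []
    for chrom, ivs in chroms.items():
        events: list[tuple[int, int]] = []
        for s, e in ivs:
            events.append((s, 1))
            events.append((e, -1))
        events.sort()
        depth = 0
        open_start = None
        for xpos, delta in events:
            new_depth = depth + delta
            if depth < params.min_support <= new_depth and open_start is None:
                open_start = xpos
            elif open_start is not None and new_depth < params.min_support <= depth:
                if xpos > open_start:
                    deep_rows.append((chrom, open_start, xpos))
                open_start = None
            depth = new_depth

    deep = IntervalSet(pd.DataFrame(deep_rows, columns=["chrom", "start", "end"]))
    merged = deep.merge(gap=params.merge_gap_bp).df
    if reapply_min_len:
        merged = merged[merged["end"] - merged["start"] >= params.min_len_bp]
    merged = merged.reset_index(drop=True)

    support = []
    for row in merged.itertuples(index=False):
        names = [
            name
            for name, df in region_sets.items()
            if (
                (df["chrom"].astype(str) == row.chrom)
                & (df["start"] < row.end)
                & (df["end"] > row.start)
            ).any()
        ]
        support.append(",".join(names))
    merged["name"] = [f"C{i + 1}" for i in range(len(merged))]
    merged["support"] = support
    return merged[["chrom", "start", "end", "name", "support"]]


def region_summary(regions: pd.DataFrame, genome_bp: int) -> dict:
    """Count / mean length / total length / percent-of-genome summary.

    Mean length is rounded to the nearest integer; ``pct_genome`` is the
    exact value (callers round for display — the source tables print one
    decimal).
    """
    if genome_bp <= 0:
        raise ValueError("genome_bp must be positive")
    n = len(regions)
    total = int((regions["end"] - regions["start"]).sum()) if n else 0
    return {
        "n_regions": n,
        "mean_length_bp": int(round(total / n)) if n else 0,
        "total_length_bp": total,
        "pct_genome": 100.0 * total / genome_bp,
    }


def regions_to_intervalset(df: pd.DataFrame) -> IntervalSet:
    return IntervalSet(df[["chrom", "start", "end", "name"]])
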