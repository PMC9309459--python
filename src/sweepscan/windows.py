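"""Sliding-window grid shared by the scan and the population statistics."""

from __future__ import annotations

import numpy as np


def tile_windows(chrom_len: int, window_bp: int, step_bp: int) -> np.ndarray:
    """Window (start, end, is_partial) triples tiled from 0.

    Full windows start at 0, step_bp, ... while ``start + window_bp <=
    chrom_len``; if sequence remains past the last full window, one final
    partial window ``[last_start + step_bp, chrom_len)`` is appended and
    flagged.
    """
    if window_bp < step_bp or step_bp <= 0:
        raise ValueError("require window_bp >= step_bp > 0")
    if chrom_len <= 0:
        raise ValueError("chrom_len must be positive")
    if chrom_len < window_bp:
        return np.array([(0, chrom_len, 1)], dtype=np.int64)
    n_full = (chrom_len - window_bp) // step_bp + 1
    starts = np.arange(n_full, dtype=np.int64) * step_bp
    rows = np.column_stack([starts, starts + window_bp, np.zeros(n_full, dtype=np.int64)])
    last_end = int(rows[-1, 1])
    if last_end < chrom_len:
        rows = np.vstack([rows, [rows[-1, 0] + step_bp, chrom_len, 1]])
    return rows


def infer_chrom_lengths(chrom: np.ndarray, pos: np.ndarray, step_bp: int = 10_000) -> dict[str, int]:
    """Chromosome lengths rounded up from the last SNP to the step grid."""
    out: dict[str, int] = {}
    for c in dict.fromkeys(chrom):
        m = int(pos[chrom == c].max())
        out[str(c)] = ((m + step_bp - 1) // step_bp) * step_bp
    return out
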