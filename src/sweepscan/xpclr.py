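"""Cross-population composite likelihood ratio scan for selective sweeps.

Model
-----
Under neutral drift, the test-population allele frequency ``p2`` given the
reference frequency ``p1`` follows a Normal with mean ``p1`` and variance
``omega * p1 * (1 - p1)``, truncated to (0, 1) with the tail mass absorbed
as point masses at the boundaries.  Under a sweep of scale ``sigma_s``
(Morgans) at the focal site, a SNP at genetic distance ``d`` escapes the
sweeping haplotype with probability ``c = 1 - exp(-d / sigma_s)``; the
drift mean shifts to ``1 - c + c*p1`` or ``c*p1`` depending on which
allelic background carried the beneficial mutation, mixed with weights
``p1`` and ``1 - p1`` (so no ancestral polarization is needed).  Observed
alt counts are binomial given the population frequency; the frequency is
integrated out by fixed-node Gauss-Legendre quadrature.

Per window the composite log-likelihood ratio is maximized over a log-
spaced grid of sweep scales whose low end is effectively neutral, so window
scores are non-negative.  SNPs in high LD are down-weighted by ``1/k``
where ``k`` counts window SNPs whose genotype correlation with the SNP
exceeds a threshold in the reference population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln, ndtr

from .variantio import MISSING, GenotypeMatrix, PopulationMap, allele_frequencies
from .windows import infer_chrom_lengths, tile_windows

MORGAN_PER_BP_PER_CMMB = 1e-8  # 1 cM/Mb == 1e-8 Morgan/bp

_TINY = 1e-300
_VAR_EPS = 1e-10  # below this the drift kernel is treated as a point mass


class CalibrationError(RuntimeError):
    """Too few usable SNPs to estimate the drift coefficient."""


class ScanConfigError(ValueError):
    """Invalid scan configuration (e.g. overlapping populations)."""


def _default_sigma_grid() -> tuple[float, ...]:
    return tuple(np.geomspace(1e-6, 0.5, 20))


@dataclass(frozen=True)
class ScanParams:
    window_bp: int = 100_000
    step_bp: int = 10_000
    max_snps_per_window: int = 200
    corr_threshold: float = 0.95
    sigma_grid: tuple[float, ...] = field(default_factory=_default_sigma_grid)
    recomb_rate_default: float = 1.0  # cM/Mb
    n_quad_nodes: int = 60

    def __post_init__(self) -> None:
        if self.window_bp < self.step_bp or self.step_bp <= 0:
            raise ValueError("require window_bp >= step_bp > 0")
        if self.max_snps_per_window < 1:
            raise ValueError("max_snps_per_window must be >= 1")
        if len(self.sigma_grid) < 1 or min(self.sigma_grid) <= 0:
            raise ValueError("sigma_grid must contain positive values")


@dataclass(frozen=True)
class OmegaEstimate:
    omega: float
    n_snps_used: int


def estimate_omega(p1: np.ndarray, p2: np.ndarray, min_snps: int = 100) -> OmegaEstimate:
    """Genome-wide drift-variance coefficient.

    ``omega_hat = mean[(p1 - p2)^2 / (p1 (1 - p1))]`` over SNPs polymorphic
    in the reference population (``0 < p1 < 1``, both frequencies finite).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    ok = np.isfinite(p1) & np.isfinite(p2) & (p1 > 0.0) & (p1 < 1.0)
    n = int(ok.sum())
    if n < min_snps:
        raise CalibrationError(f"only {n} usable SNPs (< {min_snps}) for omega")
    ratio = (p1[ok] - p2[ok]) ** 2 / (p1[ok] * (1.0 - p1[ok]))
    return OmegaEstimate(omega=float(ratio.mean()), n_snps_used=n)


def thin_indices(n: int, max_snps: int) -> np.ndarray:
    """Uniformly index-spaced subset of at most ``max_snps`` of ``n`` items."""
    if n <= max_snps:
        return np.arange(n)
    return np.round(np.linspace(0, n - 1, max_snps)).astype(np.intp)


def ld_weights(geno_ref: np.ndarray, corr_threshold: float = 0.95) -> np.ndarray:
    """Per-SNP weight ``1/k_j``, ``k_j`` = number of window SNPs (self
    included) with reference-population genotype correlation ``|r| >
    corr_threshold``.  Missing dosages are mean-imputed for the correlation.
    """
    g = np.asarray(geno_ref, dtype=float)
    g[np.asarray(geno_ref) == MISSING] = np.nan
    col_mean = np.nanmean(g, axis=1, keepdims=True)
    g = np.where(np.isnan(g), col_mean, g)  # rows are SNPs
    g = g - g.mean(axis=1, keepdims=True)
    sd = np.sqrt((g**2).sum(axis=1))
    denom = np.outer(sd, sd)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (g @ g.T) / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(r, 1.0)
    k = (np.abs(r) > corr_threshold).sum(axis=1)
    return 1.0 / np.maximum(k, 1)


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------


def _gl_nodes(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    return (x + 1.0) / 2.0, w / 2.0


def _log_binom_nodes(k2: np.ndarray, n2: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    """log Binom(k2; n2, p) at each quadrature node -> (J, Q)."""
    k2 = k2[:, None]
    n2 = n2[:, None]
    coef = gammaln(n2 + 1) - gammaln(k2 + 1) - gammaln(n2 - k2 + 1)
    return coef + k2 * np.log(nodes)[None, :] + (n2 - k2) * np.log1p(-nodes)[None, :]


def _kernel_likelihood(
    mean: np.ndarray,
    var: np.ndarray,
    b_nodes: np.ndarray,
    b0: np.ndarray,
    b1: np.ndarray,
    nodes: np.ndarray,
    glw: np.ndarray,
) -> np.ndarray:
    """Integral of the truncated-Normal drift kernel against the binomial.

    ``mean`` broadcasts over leading axes with trailing SNP axis J; ``var``,
    ``b0``, ``b1`` are (J,); ``b_nodes`` is (J, Q).  Tail mass outside (0,1)
    is placed at the boundaries where the binomial is 1{k=0} / 1{k=n}.
    """
    sd = np.sqrt(var)
    z = (nodes - mean[..., None]) / sd[..., :, None]
    dens = np.exp(-0.5 * z * z) / (np.sqrt(2.0 * np.pi) * sd[..., :, None])
    interior = np.einsum("...jq,q->...j", dens * b_nodes, glw)
    mass0 = ndtr((0.0 - mean) / sd)
    mass1 = ndtr((mean - 1.0) / sd)
    return interior + mass0 * b0 + mass1 * b1


def _point_mass_likelihood(mean: np.ndarray, k2: np.ndarray, n2: np.ndarray) -> np.ndarray:
    """Degenerate (zero-variance) limit: Binom(k2; n2, mean)."""
    m = np.clip(mean, 0.0, 1.0)
    coef = gammaln(n2 + 1) - gammaln(k2 + 1) - gammaln(n2 - k2 + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        lg = np.where(k2 > 0, k2 * np.log(np.where(m > 0, m, 1.0)), 0.0)
        lg = lg + np.where(n2 - k2 > 0, (n2 - k2) * np.log1p(-np.where(m < 1, m, 0.0)), 0.0)
        lg = np.where((m == 0) & (k2 > 0), -np.inf, lg)
        lg = np.where((m == 1) & (k2 < n2), -np.inf, lg)
    return np.exp(coef + lg)


def snp_loglikelihoods(
    p1: float, k2: int, n2: int, omega: float, c: float, n_nodes: int = 60
) -> tuple[float, float]:
    """Natural-log neutral and selected likelihoods for one SNP.

    Returns ``(loglik_neutral, loglik_selected)``.  ``c`` is the escape
    probability at this SNP for the sweep scale under evaluation.
    """
    if not 0.0 <= p1 <= 1.0:
        raise ValueError("p1 outside [0, 1]")
    if not 0 <= k2 <= n2:
        raise ValueError("require 0 <= k2 <= n2")
    if n2 == 0:
        raise ValueError("n2 = 0: SNP should be skipped upstream")
    diffs, ll_neu = _window_loglik_diffs(
        p1=np.array([p1]),
        k2=np.array([k2], dtype=float),
        n2=np.array([n2], dtype=float),
        omega=omega,
        c_grid=np.array([[c]]),
        n_nodes=n_nodes,
    )
    return float(ll_neu[0]), float(ll_neu[0] + diffs[0, 0])


def _window_loglik_diffs(
    p1: np.ndarray,
    k2: np.ndarray,
    n2: np.ndarray,
    omega: float,
    c_grid: np.ndarray,
    n_nodes: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Selected-minus-neutral log-likelihoods.

    Parameters: per-SNP arrays (J,) plus escape probabilities ``c_grid``
    with shape (S, J) — one row per sweep-scale grid value.  Returns
    ``(diffs (S, J), loglik_neutral (J,))``.
    """
    v = p1 * (1.0 - p1)
    var = omega * v
    nodes, glw = _gl_nodes(n_nodes)
    b_nodes = np.exp(_log_binom_nodes(k2, n2, nodes))
    b0 = (k2 == 0).astype(float)
    b1 = (k2 == n2).astype(float)

    degenerate = var < _VAR_EPS
    if degenerate.all():
        l_neu = _point_mass_likelihood(p1, k2, n2)
    else:
        l_neu = _kernel_likelihood(p1, np.maximum(var, _VAR_EPS), b_nodes, b0, b1, nodes, glw)
        if degenerate.any():
            l_neu = np.where(degenerate, _point_mass_likelihood(p1, k2, n2), l_neu)

    mean_hi = 1.0 - c_grid + c_grid * p1  # beneficial on the alt background
    mean_lo = c_grid * p1
    if degenerate.all():
        l_hi = _point_mass_likelihood(mean_hi, k2, n2)
        l_lo = _point_mass_likelihood(mean_lo, k2, n2)
    else:
        safe_var = np.maximum(var, _VAR_EPS)
        l_hi = _kernel_likelihood(mean_hi, safe_var, b_nodes, b0, b1, nodes, glw)
        l_lo = _kernel_likelihood(mean_lo, safe_var, b_nodes, b0, b1, nodes, glw)
        if degenerate.any():
            l_hi = np.where(degenerate, _point_mass_likelihood(mean_hi, k2, n2), l_hi)
            l_lo = np.where(degenerate, _point_mass_likelihood(mean_lo, k2, n2), l_lo)
    l_sel = p1 * l_hi + (1.0 - p1) * l_lo

    ll_neu = np.log(np.maximum(l_neu, _TINY))
    ll_sel = np.log(np.maximum(l_sel, _TINY))
    return ll_sel - ll_neu, ll_neu


def window_score(
    p1: np.ndarray,
    k2: np.ndarray,
    n2: np.ndarray,
    d_morgans: np.ndarray,
    weights: np.ndarray,
    omega: float,
    params: ScanParams,
    force_escape: float | None = None,
) -> tuple[float, float]:
    """Composite likelihood ratio of one window.

    ``score = 2 * max_sigma sum_j w_j (loglik_sel_j - loglik_neu_j)``,
    clamped at 0 (the grid's smallest scale is effectively neutral).
    Returns ``(score, sigma_hat)``.
    """
    sigma = np.asarray(params.sigma_grid, dtype=float)
    if force_escape is not None:
        c_grid = np.full((len(sigma), len(p1)), float(force_escape))
    else:
        c_grid = 1.0 - np.exp(-d_morgans[None, :] / sigma[:, None])
    diffs, _ = _window_loglik_diffs(
        p1.astype(float), k2.astype(float), n2.astype(float), omega, c_grid,
        params.n_quad_nodes,
    )
    sums = diffs @ weights
    best = int(np.argmax(sums))
    score = 2.0 * max(0.0, float(sums[best]))
    sigma_hat = float(sigma[best]) if sums[best] > 0 else float(sigma[0])
    return score, sigma_hat


# ---------------------------------------------------------------------------
# Genetic distance
# ---------------------------------------------------------------------------


class GeneticMap:
    """Piecewise-linear bp -> Morgan interpolation (per chromosome).

    Input table columns: chrom, bp, cM.  Linear extrapolation beyond the
    mapped range uses the terminal segment slopes.
    """

    def __init__(self, table: pd.DataFrame):
        need = {"chrom", "bp", "cM"}
        if not need <= set(table.columns):
            raise ValueError(f"genetic map needs columns {sorted(need)}")
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, sub in table.groupby("chrom", sort=False):
            sub = sub.sort_values("bp")
            self._by_chrom[str(chrom)] = (
                sub["bp"].to_numpy(dtype=float),
                sub["cM"].to_numpy(dtype=float) / 100.0,
            )

    @classmethod
    def read(cls, path) -> "GeneticMap":
        return cls(pd.read_csv(path, sep="\t", dtype={"chrom": str}))

    def morgans(self, chrom: str, bp: np.ndarray) -> np.ndarray:
        bp = np.asarray(bp, dtype=float)
        if chrom not in self._by_chrom:
            raise KeyError(f"chromosome {chrom!r} not in genetic map")
        xs, ys = self._by_chrom[chrom]
        if len(xs) == 1:
            return np.full_like(bp, ys[0])
        out = np.interp(bp, xs, ys)
        lo = bp < xs[0]
        hi = bp > xs[-1]
        if lo.any():
            slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
            out[lo] = ys[0] + (bp[lo] - xs[0]) * slope
        if hi.any():
            slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
            out[hi] = ys[-1] + (bp[hi] - xs[-1]) * slope
        return out


# ---------------------------------------------------------------------------
# Scan driver
# ---------------------------------------------------------------------------

TRACK_COLUMNS = ["chrom", "start", "end", "focal_bp", "n_snps", "score", "sigma_hat"]


def scan(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    test_pop: str,
    ref_pop: str,
    params: ScanParams | None = None,
    genetic_map: GeneticMap | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
    force_escape: float | None = None,
) -> pd.DataFrame:
    """Score sliding windows of the whole matrix for a test/reference pair.

    Returns a track DataFrame with columns
    ``chrom, start, end, focal_bp, n_snps, score, sigma_hat`` (and a
    boolean ``partial`` flag); windows without usable SNPs get NaN scores.
    The drift coefficient is estimated once genome-wide.
    """
    params = params or ScanParams()
    test_samples = set(popmap.samples_for(test_pop))
    ref_samples = set(popmap.samples_for(ref_pop))
    shared = test_samples & ref_samples
    if shared:
        raise ScanConfigError(f"populations share samples: {sorted(shared)[:5]}")

    p_ref, _n_ref = allele_frequencies(gm, popmap, ref_pop)
    p_test, _ = allele_frequencies(gm, popmap, test_pop)
    omega = estimate_omega(p_ref, p_test).omega

    test_idx = gm.sample_indices(popmap.samples_for(test_pop))
    ref_idx = gm.sample_indices(popmap.samples_for(ref_pop))
    g_test = gm.geno[:, test_idx]
    nonmiss_t = g_test != MISSING
    n2_all = 2 * nonmiss_t.sum(axis=1)
    k2_all = np.where(nonmiss_t, g_test, 0).sum(axis=1)

    if chrom_lengths is None:
        chrom_lengths = infer_chrom_lengths(gm.chrom, gm.pos, params.step_bp)

    rows = []
    for chrom in gm.chroms():
        on = gm.chrom == chrom
        pos = gm.pos[on]
        p1 = p_ref[on]
        k2 = k2_all[on]
        n2 = n2_all[on]
        geno_ref = gm.geno[np.ix_(on, ref_idx)]
        usable = (n2 > 0) & np.isfinite(p1) & (p1 > 0.0) & (p1 < 1.0)

        if genetic_map is not None:
            gpos = genetic_map.morgans(chrom, pos)
        else:
            gpos = pos * params.recomb_rate_default * MORGAN_PER_BP_PER_CMMB

        pos0 = pos - 1  # windows are 0-based half-open
        for start, end, partial in tile_windows(
            int(chrom_lengths[str(chrom)]), params.window_bp, params.step_bp
        ):
            lo = np.searchsorted(pos0, start, side="left")
            hi = np.searchsorted(pos0, end, side="left")
            idx = np.arange(lo, hi)[usable[lo:hi]]
            focal_bp = (start + end) // 2
            if len(idx) == 0:
                rows.append((chrom, start, end, focal_bp, 0, np.nan, np.nan, bool(partial)))
                continue
            idx = idx[thin_indices(len(idx), params.max_snps_per_window)]
            w = ld_weights(geno_ref[idx], params.corr_threshold)
            if genetic_map is not None:
                focal_g = genetic_map.morgans(chrom, np.array([focal_bp + 0.5]))[0]
            else:
                focal_g = (focal_bp + 0.5) * params.recomb_rate_default * MORGAN_PER_BP_PER_CMMB
            d = np.abs(gpos[idx] - focal_g)
            score, sigma_hat = window_score(
                p1[idx], k2[idx], n2[idx], d, w, omega, params, force_escape=force_escape
            )
            rows.append((chrom, start, end, focal_bp, len(idx), score, sigma_hat, bool(partial)))

    track = pd.DataFrame(rows, columns=TRACK_COLUMNS + ["partial"])
    track.attrs["omega"] = omega
    track.attrs["test_pop"] = test_pop
    track.attrs["ref_pop"] = ref_pop
    return track


def write_track(track: pd.DataFrame, path) -> None:
    track[TRACK_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")


def read_track(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values="NA", dtype={"chrom": str})
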