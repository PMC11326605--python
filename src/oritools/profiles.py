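"""Sorted-population copy-number profiling.

The processing chain turns raw S- and G2-phase per-nucleotide coverage into
replicate-summarized S-phase copy-number profiles:

    normalize -> 1 kb bin + S/G2 ratio -> IQR outlier filter
              -> min-max scale to [1, 2] -> cubic smoothing spline
              -> replicate mean + 95% CI

Undefined bins are carried as NaN throughout.  Outlier fences and the
min-max scale are computed genome-wide (one set of ratios per sample);
smoothing is per chromosome.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.interpolate import CubicSpline

from .genome import CoverageTrack, GenomeAnnotation

__all__ = [
    "BinnedProfile",
    "ProfileSummary",
    "normalize_coverage",
    "bin_and_ratio",
    "remove_outliers",
    "scale_ratios",
    "smooth_profile",
    "summarize_replicates",
    "run_pipeline",
    "smoothing_spline_fit",
]

logger = logging.getLogger(__name__)

STAGES = ("ratio", "filtered", "scaled", "smoothed")

#: largest run of undefined bins the smoother will interpolate across
MAX_INTERP_GAP = 10


@dataclass
class BinnedProfile:
    """Per-chromosome binned values at one pipeline stage (NaN = undefined)."""

    genome: GenomeAnnotation
    bin_size: int
    stage: str
    data: dict[str, np.ndarray]
    genotype: Optional[str] = None
    replicate: Optional[str] = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        for chrom in self.genome.names:
            arr = np.asarray(self.data[chrom], dtype=float)
            expect = self.genome.n_bins(chrom, self.bin_size)
            if arr.shape != (expect,):
                raise ValueError(f"{chrom}: expected {expect} bins, got {arr.shape}")
            self.data[chrom] = arr

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.data[chrom]

    def values(self) -> np.ndarray:
        """All bin values genome-wide, chromosome order, one flat array."""
        return np.concatenate([self.data[c] for c in self.genome.names])

    def n_defined(self) -> int:
        return int(np.sum(np.isfinite(self.values())))

    def _with(self, data: dict[str, np.ndarray], stage: str) -> "BinnedProfile":
        return replace(self, data=data, stage=stage)


@dataclass
class ProfileSummary:
    """Replicate mean and 95% CI half-width per bin."""

    genome: GenomeAnnotation
    bin_size: int
    mean: dict[str, np.ndarray]
    ci_halfwidth: dict[str, np.ndarray]
    n_replicates: int
    genotype: Optional[str] = None


def normalize_coverage(raw: CoverageTrack) -> CoverageTrack:
    """Depth-normalize so the genome-wide mean coverage is exactly 1."""
    total = raw.total
    if total <= 0:
        raise ValueError("all-zero coverage: sample unusable")
    scale = total / raw.genome.total_length
    return CoverageTrack(raw.genome, {c: v / scale for c, v in raw.items()})


def _bin_means(arr: np.ndarray, bin_size: int) -> np.ndarray:
    """Per-bin means; the terminal partial bin averages its own width."""
    n = arr.shape[0]
    nbins = -(-n // bin_size)
    sums = np.add.reduceat(arr, np.arange(0, n, bin_size))
    widths = np.full(nbins, bin_size, dtype=float)
    if n % bin_size:
        widths[-1] = n % bin_size
    return sums / widths


def bin_and_ratio(
    S: CoverageTrack, G2: CoverageTrack, bin_size: int = 1000,
    genotype: Optional[str] = None, replicate: Optional[str] = None,
) -> BinnedProfile:
    """Per-bin mean(S)/mean(G2); bins with zero G2 coverage become NaN."""
    if S.genome != G2.genome:
        raise ValueError("S and G2 tracks cover different genomes")
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    data = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for chrom in S.genome.names:
            s = _bin_means(S[chrom], bin_size)
            g = _bin_means(G2[chrom], bin_size)
            r = np.where(g > 0, s / np.where(g > 0, g, 1.0), np.nan)
            data[chrom] = r
    return BinnedProfile(S.genome, bin_size, "ratio", data,
                         genotype=genotype, replicate=replicate)


def remove_outliers(profile: BinnedProfile, k: float = 1.5) -> BinnedProfile:
    """Tukey fences: drop bins beyond Q1 - k*IQR or Q3 + k*IQR (genome-wide).

    Quartiles use linear-interpolation quantiles over defined bins.  The
    inequalities are strict, so with IQR = 0 every value survives.
    """
    if profile.stage != "ratio":
        raise ValueError("remove_outliers expects a ratio-stage profile")
    vals = profile.values()
    defined = vals[np.isfinite(vals)]
    if defined.size < 4:
        raise ValueError("need at least 4 defined bins to compute fences")
    q1, q3 = np.quantile(defined, [0.25, 0.75])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    data = {}
    for chrom in profile.genome.names:
        arr = profile[chrom].copy()
        with np.errstate(invalid="ignore"):
            arr[(arr < lo) | (arr > hi)] = np.nan
        data[chrom] = arr
    return profile._with(data, "filtered")


def scale_ratios(profile: BinnedProfile) -> BinnedProfile:
    """Min-max scale defined bins into [1, 2]: (v - min)/(max - min) + 1."""
    if profile.stage != "filtered":
        raise ValueError("scale_ratios expects a filtered-stage profile")
    vals = profile.values()
    defined = vals[np.isfinite(vals)]
    if defined.size < 2:
        raise ValueError("need at least 2 defined bins")
    vmin, vmax = defined.min(), defined.max()
    if vmax == vmin:
        raise ValueError("degenerate profile: max equals min")
    data = {c: (profile[c] - vmin) / (vmax - vmin) + 1.0
            for c in profile.genome.names}
    return profile._with(data, "scaled")


# ---------------------------------------------------------------------------
# Penalized natural cubic smoothing spline (Reinsch / Green & Silverman).
#
# For knots x_1 < ... < x_n the minimizer of
#     sum_i (y_i - f(x_i))^2 + lam * int f''(t)^2 dt
# over natural cubic splines satisfies (I + lam*K) g = y with
# K = Q R^{-1} Q^T, where Q (n x n-2) and R (n-2 x n-2) are the standard
# second-difference / overlap matrices built from the knot spacings.
# ---------------------------------------------------------------------------


def _penalty_matrix(x: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    h = np.diff(x)
    Q = np.zeros((n, n - 2))
    for j in range(1, n - 1):
        Q[j - 1, j - 1] = 1.0 / h[j - 1]
        Q[j, j - 1] = -1.0 / h[j - 1] - 1.0 / h[j]
        Q[j + 1, j - 1] = 1.0 / h[j]
    R = np.zeros((n - 2, n - 2))
    for j in range(n - 2):
        R[j, j] = (h[j] + h[j + 1]) / 3.0
        if j + 1 < n - 2:
            R[j, j + 1] = R[j + 1, j] = h[j + 1] / 6.0
    return Q @ np.linalg.solve(R, Q.T)


def _gcv_lambda(x: np.ndarray, y: np.ndarray) -> float:
    """Generalized cross-validation choice of the smoothing parameter."""
    K = _penalty_matrix(x)
    # one symmetric eigendecomposition makes each GCV evaluation O(n)
    d, U = np.linalg.eigh(K)
    d = np.clip(d, 0.0, None)
    yt = U.T @ y
    n = x.shape[0]

    def gcv(log_lam: float) -> float:
        lam = 10.0 ** log_lam
        shrink = lam * d / (1.0 + lam * d)
        rss = float(np.sum((shrink * yt) ** 2))
        tr = float(np.sum(shrink))  # tr(I - A)
        if tr <= 0:
            return np.inf
        return n * rss / tr**2

    grid = np.linspace(-8.0, 8.0, 65)
    scores = np.array([gcv(g) for g in grid])
    i = int(np.argmin(scores))
    # golden-section refinement around the grid minimum
    from scipy.optimize import minimize_scalar

    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = minimize_scalar(gcv, bounds=(lo, hi), method="bounded")
    return float(10.0 ** res.x)


def smoothing_spline_fit(
    x: np.ndarray, y: np.ndarray, lam: Optional[float] = None
) -> CubicSpline:
    """Fit the penalized natural cubic smoothing spline.

    Parameters
    ----------
    x, y
        Knot abscissae (strictly increasing) and observations.
    lam
        Curvature penalty weight; ``None`` selects it by generalized
        cross-validation.

    Returns
    -------
    CubicSpline
        The natural cubic spline through the fitted knot values (which is
        exactly the penalized-least-squares minimizer).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-D and equally long")
    if x.shape[0] < 4:
        raise ValueError("need at least 4 points")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing")
    if lam is None:
        lam = _gcv_lambda(x, y)
    if lam < 0:
        raise ValueError("lam must be >= 0")
    K = _penalty_matrix(x)
    g = np.linalg.solve(np.eye(x.shape[0]) + lam * K, y)
    return CubicSpline(x, g, bc_type="natural")


def _gap_mask(defined: np.ndarray, max_gap: int) -> np.ndarray:
    """True where output should be defined: defined bins plus gaps <= max_gap."""
    out = defined.copy()
    idx = np.flatnonzero(defined)
    if idx.size == 0:
        return out
    for a, b in zip(idx[:-1], idx[1:]):
        if 1 < b - a <= max_gap + 1:
            out[a + 1 : b] = True
    return out


def smooth_profile(
    profile: BinnedProfile,
    smoothing: Optional[float] = None,
    max_gap: int = MAX_INTERP_GAP,
) -> BinnedProfile:
    """Cubic smoothing-spline fit per chromosome, evaluated at bin centers.

    Undefined bins are omitted from the fit; the fitted spline fills gaps of
    at most ``max_gap`` bins, larger gaps stay undefined.  ``smoothing`` is
    the curvature penalty lambda (x measured in bins); ``None`` uses GCV.
    """
    if profile.stage != "scaled":
        raise ValueError("smooth_profile expects a scaled-stage profile")
    data = {}
    for chrom in profile.genome.names:
        arr = profile[chrom]
        defined = np.isfinite(arr)
        out = np.full_like(arr, np.nan)
        if defined.sum() < 4:
            logger.warning(
                "%s: only %d defined bins, leaving chromosome unsmoothed",
                chrom, int(defined.sum()),
            )
            data[chrom] = out
            continue
        x = np.flatnonzero(defined).astype(float) + 0.5
        spline = smoothing_spline_fit(x, arr[defined], lam=smoothing)
        mask = _gap_mask(defined, max_gap)
        xs = np.flatnonzero(mask).astype(float) + 0.5
        out[mask] = spline(xs)
        data[chrom] = out
    return profile._with(data, "smoothed")


def summarize_replicates(profiles: Sequence[BinnedProfile]) -> ProfileSummary:
    """Per-bin mean and t-based 95% CI half-width across replicates.

    Bins defined in a single replicate keep their mean with an undefined CI.
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 replicates; skip summarization otherwise")
    first = profiles[0]
    for p in profiles[1:]:
        if p.genome != first.genome or p.bin_size != first.bin_size:
            raise ValueError("replicates must share genome and binning")
    mean, ci = {}, {}
    for chrom in first.genome.names:
        stack = np.vstack([p[chrom] for p in profiles])
        n = np.sum(np.isfinite(stack), axis=0)
        with np.errstate(invalid="ignore"):
            sums = np.nansum(stack, axis=0)
            m = np.where(n > 0, sums / np.maximum(n, 1), np.nan)
            sd = np.full(stack.shape[1], np.nan)
            multi = n >= 2
            if np.any(multi):
                sd[multi] = np.nanstd(stack[:, multi], axis=0, ddof=1)
        hw = np.full(stack.shape[1], np.nan)
        for nv in np.unique(n[n >= 2]):
            t = stats.t.ppf(0.975, int(nv) - 1)
            sel = n == nv
            hw[sel] = t * sd[sel] / math.sqrt(int(nv))
        mean[chrom] = m
        ci[chrom] = hw
    return ProfileSummary(first.genome, first.bin_size, mean, ci,
                          n_replicates=len(profiles), genotype=first.genotype)


def run_pipeline(
    S: CoverageTrack, G2: CoverageTrack, bin_size: int = 1000,
    smoothing: Optional[float] = None,
    genotype: Optional[str] = None, replicate: Optional[str] = None,
) -> BinnedProfile:
    """Full per-sample chain: normalize, bin+ratio, filter, scale, smooth."""
    ratio = bin_and_ratio(normalize_coverage(S), normalize_coverage(G2),
                          bin_size, genotype=genotype, replicate=replicate)
    return smooth_profile(scale_ratios(remove_outliers(ratio)), smoothing)
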