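"""Naive reference implementations used as independent oracles in tests.

Everything here is written as directly as possible (explicit loops, the
math module, exhaustive enumeration) and shares no code with the package
implementations it checks.
"""

from __future__ import annotations

import math
from math import comb

import numpy as np


def quantile_linear(sorted_vals, q):
    """Linear-interpolation quantile of an already sorted list."""
    n = len(sorted_vals)
    pos = (n - 1) * q
    lo = math.floor(pos)
    hi = math.ceil(pos)
    if lo == hi:
        return sorted_vals[lo]
    frac = pos - lo
    return sorted_vals[lo] * (1 - frac) + sorted_vals[hi] * frac


def naive_iqr_filter(values, k=1.5):
    """Return values with Tukey-fence outliers replaced by NaN."""
    defined = sorted(v for v in values if not math.isnan(v))
    q1 = quantile_linear(defined, 0.25)
    q3 = quantile_linear(defined, 0.75)
    lo = q1 - k * (q3 - q1)
    hi = q3 + k * (q3 - q1)
    out = []
    for v in values:
        if math.isnan(v):
            out.append(math.nan)
        elif v < lo or v > hi:
            out.append(math.nan)
        else:
            out.append(v)
    return out


def naive_minmax_scale(values):
    defined = [v for v in values if not math.isnan(v)]
    vmin, vmax = min(defined), max(defined)
    return [math.nan if math.isnan(v) else (v - vmin) / (vmax - vmin) + 1.0
            for v in values]


def naive_median(values):
    s = sorted(values)
    n = len(s)
    if n % 2:
        return s[n // 2]
    return 0.5 * (s[n // 2 - 1] + s[n // 2])


def naive_window_median(mean_track, bin_size, orc_start, window, chrom_nbins):
    """Median of bin means over the best-covering bin block.

    The block of window/bin_size consecutive bins maximizing overlap with
    [orc_start - window/2, orc_start + window/2) is found by exhaustive
    scan; ties keep the leftmost block.  NaN bins are excluded from the
    median.
    """
    nbins = window // bin_size
    w_lo = orc_start - window / 2
    w_hi = orc_start + window / 2
    best_start, best_overlap = None, -1.0
    for s in range(-nbins, chrom_nbins + nbins):
        b_lo, b_hi = s * bin_size, (s + nbins) * bin_size
        overlap = max(0.0, min(w_hi, b_hi) - max(w_lo, b_lo))
        if overlap > best_overlap:
            best_overlap, best_start = overlap, s
    vals = []
    for i in range(best_start, best_start + nbins):
        if 0 <= i < chrom_nbins and not math.isnan(mean_track[i]):
            vals.append(mean_track[i])
    return naive_median(vals) if vals else math.nan


def hypergeom_upper_tail(k, N, K, m):
    """P(X >= k) by direct summation of the hypergeometric pmf."""
    total = comb(N, m)
    return sum(comb(K, i) * comb(N - K, m - i)
               for i in range(max(k, max(0, m - (N - K))),
                              min(K, m) + 1)) / total


def hypergeom_lower_tail(k, N, K, m):
    total = comb(N, m)
    return sum(comb(K, i) * comb(N - K, m - i)
               for i in range(max(0, m - (N - K)), min(k, min(K, m)) + 1)) / total


def naive_class_signal(values, lengths, lo, hi):
    """Column sums over rows with lo <= length <= hi, by explicit loops."""
    n_cols = values.shape[1]
    out = [0.0] * n_cols
    for r, L in enumerate(lengths):
        if lo <= L <= hi:
            for c in range(n_cols):
                out[c] += values[r, c]
    return out


def naive_stability_ratio(mut_nuc, mut_sub, wt_nuc, wt_sub, psi):
    out = []
    for a, b, c, d in zip(mut_nuc, mut_sub, wt_nuc, wt_sub):
        if a + b == 0 or c + d == 0:
            out.append(math.nan)
        else:
            out.append(((a + psi) / (b + psi)) / ((c + psi) / (d + psi)))
    return out


def naive_scaled_fraction(values, lengths, lo, hi):
    cls = naive_class_signal(values, lengths, lo, hi)
    tot = naive_class_signal(values, lengths, min(lengths), max(lengths))
    raw = [c / t if t > 0 else math.nan for c, t in zip(cls, tot)]
    defined = [v for v in raw if not math.isnan(v)]
    vmin, vmax = min(defined), max(defined)
    if vmax == vmin:
        return [math.nan if math.isnan(v) else 0.0 for v in raw]
    return [math.nan if math.isnan(v) else (v - vmin) / (vmax - vmin)
            for v in raw]


def naive_pwm_scan(seq, matrix, threshold):
    """Quadratic both-strand scan; returns (start, strand, score) tuples."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    w = len(matrix)
    hits = []
    for i in range(len(seq) - w + 1):
        window = seq[i : i + w].upper()
        if any(b not in idx for b in window):
            continue
        fwd = sum(matrix[j][idx[window[j]]] for j in range(w))
        rc = "".join(comp[b] for b in reversed(window))
        rev = sum(matrix[j][idx[rc[j]]] for j in range(w))
        if fwd >= threshold:
            hits.append((i, "+", fwd))
        if rev >= threshold:
            hits.append((i, "-", rev))
    return hits


def naive_occupancy_total(fragments, loci_windows):
    """Total per-bp overlap count over all (fragment, locus window) pairs.

    ``loci_windows`` is a list of (chrom, genomic_lo, genomic_hi) inclusive
    windows; fragments are (chrom, start, end) half-open.
    """
    total = 0
    for chrom, s, e in fragments:
        for wc, lo, hi in loci_windows:
            if wc != chrom:
                continue
            total += max(0, min(e - 1, hi) - max(s, lo) + 1)
    return total


def spline_objective_minimizer(x, y, lam):
    """Minimize the penalized spline objective numerically.

    Parametrizes candidate fits by their knot values, builds the natural
    cubic interpolant through them with scipy's CubicSpline, computes
    int f''^2 exactly from the piecewise-linear second derivative, and
    minimizes with a generic quasi-Newton optimizer.
    """
    from scipy.interpolate import CubicSpline
    from scipy.optimize import minimize

    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def objective(g):
        f = CubicSpline(x, g, bc_type="natural")
        rss = float(np.sum((y - g) ** 2))
        d2 = f.derivative(2)
        penalty = 0.0
        for a, b in zip(x[:-1], x[1:]):
            fa, fb = float(d2(a)), float(d2(b))
            penalty += (b - a) / 3.0 * (fa * fa + fa * fb + fb * fb)
        return rss + lam * penalty

    res = minimize(objective, y, method="BFGS",
                   options={"gtol": 1e-13, "maxiter": 2000})
    return res.x
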