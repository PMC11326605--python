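"""Origin-aligned signal aggregation and MNase fragment-size footprints.

Signals and fragments are aggregated across a group of loci after aligning
each locus window on the ORC-site start and mirroring minus-strand loci, so
the T-rich strand always reads 5'->3' left-to-right.  The central object is
the occupancy matrix: fragment length x origin-relative position, each
fragment contributing its full protected footprint (midpoint-only mode is
available).  Fragment-size classes follow the MNase footprinting
conventions: nucleosomal protection 142-162 bp, subnucleosomal 121-141 bp,
nucleosome-consistent 147 +- 10 bp, ORC/Cdc6-consistent 80 +- 10 bp.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import CoverageTrack, OriginAnnotation

__all__ = [
    "AlignedSignalProfile",
    "OccupancyMatrix",
    "FragmentClassSpec",
    "NUCLEOSOME_STABILITY",
    "SUBNUCLEOSOME_STABILITY",
    "NUCLEOSOME_SCALED",
    "ORC_CDC6_SCALED",
    "aggregate_signal_profile",
    "normalize_track",
    "build_occupancy_matrix",
    "class_signal",
    "stability_ratio",
    "scaled_fraction_signal",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FragmentClassSpec:
    """Inclusive fragment-length interval defining a protection class."""

    name: str
    lo: int
    hi: int

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError("lo must be <= hi")


NUCLEOSOME_STABILITY = FragmentClassSpec("nucleosome_stability", 142, 162)
SUBNUCLEOSOME_STABILITY = FragmentClassSpec("subnucleosome_stability", 121, 141)
NUCLEOSOME_SCALED = FragmentClassSpec("nucleosome_scaled", 137, 157)  # 147 +- 10
ORC_CDC6_SCALED = FragmentClassSpec("orc_cdc6_scaled", 70, 90)  # 80 +- 10


@dataclass
class AlignedSignalProfile:
    """Per-rel-position mean signal with t-based 95% CI across loci."""

    rel_positions: np.ndarray  # -span..+span
    mean: np.ndarray
    ci_halfwidth: np.ndarray
    n_loci: int
    n_contributing: np.ndarray


@dataclass
class OccupancyMatrix:
    """Fragment length x rel position counts (or frequencies)."""

    lengths: np.ndarray  # row labels, lo..hi inclusive
    rel_positions: np.ndarray  # column labels, -span..+span
    values: np.ndarray  # shape (n_lengths, n_positions)
    form: str = "counts"  # counts | frequency
    sample: Optional[str] = None
    condition: Optional[str] = None

    def to_frequency(self) -> "OccupancyMatrix":
        total = self.values.sum()
        vals = self.values / total if total > 0 else self.values.copy()
        return OccupancyMatrix(self.lengths, self.rel_positions, vals,
                               "frequency", self.sample, self.condition)


def _locus_window(
    origin: OriginAnnotation, track: np.ndarray, span: int
) -> np.ndarray:
    """Signal over rel -span..+span, mirrored for minus-strand loci;
    positions beyond the chromosome are NaN."""
    n = track.shape[0]
    out = np.full(2 * span + 1, np.nan)
    if origin.orc_strand == "+":
        lo = origin.orc_start - span
        hi = origin.orc_start + span + 1
        src_lo, src_hi = max(lo, 0), min(hi, n)
        out[src_lo - lo : src_hi - lo] = track[src_lo:src_hi]
    else:
        # rel r maps to genomic orc_start - r
        lo = origin.orc_start - span  # genomic window is the same span
        hi = origin.orc_start + span + 1
        src_lo, src_hi = max(lo, 0), min(hi, n)
        window = np.full(2 * span + 1, np.nan)
        window[src_lo - lo : src_hi - lo] = track[src_lo:src_hi]
        out = window[::-1]
    return out


def aggregate_signal_profile(
    track: CoverageTrack,
    origins: Sequence[OriginAnnotation],
    span: int,
) -> AlignedSignalProfile:
    """Mean per-nucleotide signal across strand-aligned origin windows."""
    if not origins:
        raise ValueError("empty locus group")
    rows = np.vstack([
        _locus_window(o, track[o.chrom], span) for o in origins
    ])
    n = np.sum(np.isfinite(rows), axis=0)
    with np.errstate(invalid="ignore"):
        sums = np.nansum(rows, axis=0)
        mean = np.where(n > 0, sums / np.maximum(n, 1), np.nan)
        sd = np.full(rows.shape[1], np.nan)
        multi = n >= 2
        if np.any(multi):
            sd[multi] = np.nanstd(rows[:, multi], axis=0, ddof=1)
    hw = np.full(rows.shape[1], np.nan)
    for nv in np.unique(n[n >= 2]):
        t = stats.t.ppf(0.975, int(nv) - 1)
        sel = n == nv
        hw[sel] = t * sd[sel] / math.sqrt(int(nv))
    return AlignedSignalProfile(np.arange(-span, span + 1), mean, hw,
                                len(origins), n)


def normalize_track(IP: CoverageTrack, inp: CoverageTrack) -> CoverageTrack:
    """Internally normalized IP/input ratio track.

    Both tracks are depth-normalized by their own totals, the per-bp ratio
    is taken (undefined, i.e. NaN, where input is zero), and the defined
    ratios are rescaled to a genome-wide mean of exactly 1.
    """
    if IP.genome != inp.genome:
        raise ValueError("IP and input tracks cover different genomes")
    if inp.total <= 0:
        raise ValueError("all-zero input track")
    if IP.total <= 0:
        logger.warning("all-zero IP track; returning zeros")
        return CoverageTrack(IP.genome,
                             {c: np.zeros_like(v) for c, v in IP.items()})
    ratio = {}
    for chrom in IP.genome.names:
        ip = IP[chrom] / IP.total
        ref = inp[chrom] / inp.total
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(ref > 0, ip / np.where(ref > 0, ref, 1.0), np.nan)
        ratio[chrom] = r
    grand_mean = np.nanmean(np.concatenate(list(ratio.values())))
    data = {c: r / grand_mean for c, r in ratio.items()}
    # CoverageTrack forbids negatives but tolerates NaN
    track = CoverageTrack.__new__(CoverageTrack)
    track.genome = IP.genome
    track.data = data
    return track


def build_occupancy_matrix(
    fragments: pd.DataFrame,
    loci: Sequence[OriginAnnotation],
    span: int,
    length_range: tuple[int, int] = (50, 200),
    midpoint_only: bool = False,
) -> OccupancyMatrix:
    """Accumulate fragment footprints into a length x rel-position matrix.

    Each fragment whose length falls inside ``length_range`` adds +1 to its
    length's row at every rel position its genomic footprint covers inside a
    locus window (or just at its midpoint with ``midpoint_only``); windows
    of minus-strand loci are mirrored.
    """
    lo_len, hi_len = length_range
    if lo_len > hi_len:
        logger.warning("empty length range; returning empty matrix")
        lengths = np.arange(0)
        return OccupancyMatrix(lengths, np.arange(-span, span + 1),
                               np.zeros((0, 2 * span + 1)))
    lengths = np.arange(lo_len, hi_len + 1)
    ncols = 2 * span + 1
    values = np.zeros((lengths.size, ncols))
    chrom_arr = fragments["chrom"].to_numpy()
    start_arr = fragments["start"].to_numpy(dtype=np.int64)
    end_arr = fragments["end"].to_numpy(dtype=np.int64)
    frag_len = end_arr - start_arr
    keep = (frag_len >= lo_len) & (frag_len <= hi_len)
    order = {}
    for chrom in np.unique(chrom_arr):
        order[chrom] = np.flatnonzero(keep & (chrom_arr == chrom))
    for locus in loci:
        idx = order.get(locus.chrom)
        if idx is None or idx.size == 0:
            continue
        w_lo = locus.orc_start - span
        w_hi = locus.orc_start + span  # inclusive genomic window
        s = start_arr[idx]
        e = end_arr[idx] - 1  # inclusive last covered base
        if midpoint_only:
            mid = (s + e) // 2
            sel = (mid >= w_lo) & (mid <= w_hi)
            for i, m in zip(idx[sel], mid[sel]):
                rel = (m - locus.orc_start if locus.orc_strand == "+"
                       else locus.orc_start - m)
                values[frag_len[i] - lo_len, rel + span] += 1
            continue
        ov_lo = np.maximum(s, w_lo)
        ov_hi = np.minimum(e, w_hi)
        sel = ov_lo <= ov_hi
        for i, a, b in zip(idx[sel], ov_lo[sel], ov_hi[sel]):
            if locus.orc_strand == "+":
                c_lo = a - locus.orc_start + span
                c_hi = b - locus.orc_start + span
            else:
                c_lo = locus.orc_start - b + span
                c_hi = locus.orc_start - a + span
            values[frag_len[i] - lo_len, c_lo : c_hi + 1] += 1
    return OccupancyMatrix(lengths, np.arange(-span, span + 1), values)


def class_signal(matrix: OccupancyMatrix, spec: FragmentClassSpec) -> np.ndarray:
    """Column sums over the class's inclusive length interval."""
    sel = (matrix.lengths >= spec.lo) & (matrix.lengths <= spec.hi)
    if not np.any(sel):
        raise ValueError(f"class {spec.name} outside the matrix length range")
    return matrix.values[sel].sum(axis=0)


def stability_ratio(
    mutant: OccupancyMatrix,
    wildtype: OccupancyMatrix,
    nuc_spec: FragmentClassSpec = NUCLEOSOME_STABILITY,
    subnuc_spec: FragmentClassSpec = SUBNUCLEOSOME_STABILITY,
    pseudocount: float = 1.0,
) -> np.ndarray:
    """Mutant-to-wild-type ratio of per-position nucleosome:subnucleosome
    signal (the nucleosome-stability proxy).

    Positions where a genotype has zero signal in both classes are NaN.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if (mutant.values.shape[1] != wildtype.values.shape[1]
            or not np.array_equal(mutant.lengths, wildtype.lengths)):
        raise ValueError("matrices must share span and length range")
    out = np.full(mutant.values.shape[1], np.nan)
    nm, sm = class_signal(mutant, nuc_spec), class_signal(mutant, subnuc_spec)
    nw, sw = class_signal(wildtype, nuc_spec), class_signal(wildtype, subnuc_spec)
    defined = (nm + sm > 0) & (nw + sw > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_mut = (nm + pseudocount) / (sm + pseudocount)
        r_wt = (nw + pseudocount) / (sw + pseudocount)
        ratio = r_mut / r_wt
    out[defined] = ratio[defined]
    return out


def scaled_fraction_signal(
    matrix: OccupancyMatrix, spec: FragmentClassSpec
) -> np.ndarray:
    """Class share of the total signal per position, min-max scaled to [0, 1].

    raw(p) = class_signal(p) / total_signal(p), undefined where nothing was
    counted; defined values are then scaled so min -> 0 and max -> 1.
    """
    total = matrix.values.sum(axis=0)
    if total.sum() == 0:
        raise ValueError("empty occupancy matrix")
    cls = class_signal(matrix, spec)
    raw = np.full(total.shape, np.nan)
    nz = total > 0
    raw[nz] = cls[nz] / total[nz]
    defined = np.isfinite(raw)
    vmin, vmax = np.nanmin(raw), np.nanmax(raw)
    out = np.full(raw.shape, np.nan)
    if vmax == vmin:
        logger.warning("constant class fraction; scaled signal set to 0")
        out[defined] = 0.0
        return out
    out[defined] = (raw[defined] - vmin) / (vmax - vmin)
    return out
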