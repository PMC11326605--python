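"""Per-origin activity statistics and regulatory classification.

Each origin is assigned an S-phase copy-number statistic per genotype (the
median of the 1 kb bin means across a 10 kb window centered on the ORC-site
start), a log2 mutant/wild-type ratio, and a class:

* ``positive`` -- log2 ratio <= -threshold (activity reduced in the mutant,
  i.e. the wild-type domain promotes this origin),
* ``negative`` -- log2 ratio >= +threshold,
* ``other``    -- inside the dead zone.

Thresholds are inclusive, matching the +-0.1 log2 convention for calling
FHA-SORT-positive / FHA-SORT-negative origins.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .genome import GenomeAnnotation, OriginAnnotation
from .profiles import ProfileSummary

__all__ = [
    "OriginActivityRecord",
    "GroupDefinition",
    "window_bins",
    "quantify_origin_activity",
    "classify_origins",
    "timing_tertiles",
    "kde_summary",
    "overlap_test",
    "classify_cen_associated",
]

logger = logging.getLogger(__name__)

CLASS_POSITIVE = "FHA-SORT-positive"
CLASS_NEGATIVE = "FHA-SORT-negative"
CLASS_OTHER = "other"


@dataclass
class OriginActivityRecord:
    origin_id: str
    sphase_value: dict[str, float] = field(default_factory=dict)
    log2_ratio: float = math.nan
    origin_class: Optional[str] = None
    cen_associated: Optional[bool] = None
    truncated_window: bool = False
    evaluable: bool = True


@dataclass(frozen=True)
class GroupDefinition:
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))


def window_bins(
    origin: OriginAnnotation, genome: GenomeAnnotation,
    bin_size: int, window: int,
) -> tuple[np.ndarray, bool]:
    """Indices of the ``window/bin_size`` consecutive bins best covering the
    window centered on the ORC-site start.

    The bin block minimizes the symmetric difference with the ideal centered
    window; ties break leftward.  Blocks truncated by chromosome ends are
    clipped (second return value flags truncation).
    """
    if window <= 0 or window % bin_size:
        raise ValueError("window must be a positive multiple of bin_size")
    nbins = window // bin_size
    nchrom = genome.n_bins(origin.chrom, bin_size)
    ideal_start = origin.orc_start - window / 2.0
    # |block_start*bin_size - ideal_start| is minimized over integers; on a
    # tie (exact .5 offset) prefer the smaller start.
    s_float = ideal_start / bin_size
    lo = math.floor(s_float)
    cand = lo if (s_float - lo) <= 0.5 else lo + 1
    start, stop = cand, cand + nbins
    truncated = start < 0 or stop > nchrom
    start = max(start, 0)
    stop = min(stop, nchrom)
    return np.arange(start, stop), truncated


def quantify_origin_activity(
    summaries: Mapping[str, ProfileSummary],
    origin: OriginAnnotation,
    wild_type: str,
    mutant: str,
    window: int = 10_000,
) -> OriginActivityRecord:
    """Median-of-bin-means S-phase statistic per genotype and its log2 ratio.

    Only defined bins enter the median; records with fewer defined bins than
    the full window, or with a chromosome-end-truncated window, are flagged.
    Records with no defined bins at all are marked unevaluable.
    """
    rec = OriginActivityRecord(origin.origin_id)
    nbins_full = window // next(iter(summaries.values())).bin_size
    for genotype, summary in summaries.items():
        idx, truncated = window_bins(origin, summary.genome, summary.bin_size,
                                     window)
        vals = summary.mean[origin.chrom][idx]
        vals = vals[np.isfinite(vals)]
        rec.truncated_window |= truncated or vals.size < nbins_full
        if vals.size == 0:
            rec.evaluable = False
            rec.sphase_value[genotype] = math.nan
        else:
            rec.sphase_value[genotype] = float(np.median(vals))
    if rec.evaluable:
        rec.log2_ratio = float(
            np.log2(rec.sphase_value[mutant] / rec.sphase_value[wild_type])
        )
    return rec


def classify_origins(
    records: Iterable[OriginActivityRecord], threshold: float = 0.1
) -> list[OriginActivityRecord]:
    """Assign positive/negative/other classes from log2 ratios (inclusive)."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    records = list(records)
    for rec in records:
        if not rec.evaluable or not math.isfinite(rec.log2_ratio):
            rec.origin_class = None
            continue
        if rec.log2_ratio <= -threshold:
            rec.origin_class = CLASS_POSITIVE
        elif rec.log2_ratio >= threshold:
            rec.origin_class = CLASS_NEGATIVE
        else:
            rec.origin_class = CLASS_OTHER
    return records


def timing_tertiles(
    values: Sequence[float], higher_is_earlier: bool = True
) -> list[str]:
    """Split a replication measure into early/mid/late thirds.

    Boundaries sit at the 1/3 and 2/3 linear-interpolation quantiles.  With
    scaled S-phase copy numbers higher values replicate earlier
    (``higher_is_earlier=True``); with Trep minutes lower values are earlier.
    Boundary ties go to the earlier tertile.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 3:
        raise ValueError("need at least 3 values")
    q13, q23 = np.quantile(vals, [1 / 3, 2 / 3])
    if q13 == q23:
        logger.warning("degenerate timing distribution; all values tied")
    labels = []
    for v in vals:
        if higher_is_earlier:
            lab = "early" if v >= q23 else ("mid" if v >= q13 else "late")
        else:
            lab = "early" if v <= q13 else ("mid" if v <= q23 else "late")
        labels.append(lab)
    return labels


def kde_summary(
    values: Mapping[str, float],
    groups: Sequence[GroupDefinition],
    bandwidth: Optional[float] = None,
    grid_size: int = 512,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Gaussian KDE of log2 ratios per group on a shared grid.

    Bandwidth defaults to Silverman's rule per group; the grid spans the
    pooled finite values +- 3 of the largest bandwidth.  Groups with fewer
    than 2 finite values are skipped with a warning.
    """
    finite = {k: v for k, v in values.items() if math.isfinite(v)}
    usable: dict[str, np.ndarray] = {}
    for g in groups:
        vals = np.array([finite[m] for m in g.members if m in finite])
        if vals.size < 2 or np.ptp(vals) == 0:
            logger.warning("group %s: fewer than 2 usable values, skipped",
                           g.name)
            continue
        usable[g.name] = vals
    if not usable:
        raise ValueError("no group has >= 2 finite values")
    kdes = {}
    bws = []
    for name, vals in usable.items():
        kde = stats.gaussian_kde(
            vals, bw_method="silverman" if bandwidth is None else None
        )
        if bandwidth is not None:
            kde.set_bandwidth(bandwidth / vals.std(ddof=1))
        kdes[name] = kde
        bws.append(math.sqrt(kde.covariance[0, 0]))
    pooled = np.concatenate(list(usable.values()))
    pad = 3 * max(bws)
    grid = np.linspace(pooled.min() - pad, pooled.max() + pad, grid_size)
    return grid, {name: kde(grid) for name, kde in kdes.items()}


def overlap_test(
    group_a: GroupDefinition, group_b: GroupDefinition,
    universe: Iterable[str],
) -> tuple[int, float, float]:
    """Set-overlap significance via the upper-tail hypergeometric law.

    Returns (observed overlap, expected overlap, P(X >= observed)) for X
    hypergeometric with population ``|universe|``, ``|A|`` successes and
    ``|B|`` draws.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    a = group_a.members & uni
    b = group_b.members & uni
    if a != group_a.members or b != group_b.members:
        raise ValueError("groups must be subsets of the universe")
    k = len(a & b)
    n, K, m = len(uni), len(a), len(b)
    expected = K * m / n
    p = float(stats.hypergeom.sf(k - 1, n, K, m))
    return k, expected, p


def classify_cen_associated(
    origins: Sequence[OriginAnnotation],
    centromeres: Mapping[str, tuple[int, int]],
    span: int = 10_000,
) -> dict[str, bool]:
    """Flag origins whose ORC-site start lies within ``span`` bp of a
    centromere (inclusive; centromeres given as half-open intervals per
    chromosome).  Origins on chromosomes without an annotated centromere are
    False.
    """
    out = {}
    for o in origins:
        cen = centromeres.get(o.chrom)
        if cen is None:
            out[o.origin_id] = False
            continue
        cen_start, cen_end = cen
        out[o.origin_id] = (cen_start - span) <= o.orc_start <= (cen_end + span)
    return out
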