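"""Oriented motif scanning and ORC-site-relative motif architecture.

A forkhead-binding-site model enters as a per-position log-odds matrix (an
8 bp motif by default).  Both genome strands are scanned; matches are then
projected into origin-relative coordinates, where orientation is defined
relative to the ORC site's T-rich strand:

* ``FKH-T`` -- the match's motif strand equals the origin's T-rich strand,
* ``FKH-A`` -- the opposite strand.

Architecture statistics follow the three canonical origin regions
(5' FKH-T: -150..-11, 3' FKH-A: +41..+150, ORC-overlapping FKH-T:
-10..+40), with hypergeometric enrichment against a universe of origins and
cumulative nearest-match accumulation curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .genome import OriginAnnotation

__all__ = [
    "MotifModel",
    "MotifMatch",
    "ProjectedMatch",
    "RegionSpec",
    "FIVE_PRIME_FKH_T",
    "THREE_PRIME_FKH_A",
    "ORC_OVERLAPPING_FKH_T",
    "scan_motifs",
    "select_top_quantile",
    "project_matches",
    "region_motif_fraction",
    "enrichment_test",
    "cumulative_accumulation",
    "AccumulationCurve",
]

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = {0: 3, 1: 2, 2: 1, 3: 0}

ORIENT_T = "FKH-T"
ORIENT_A = "FKH-A"


@dataclass(frozen=True)
class MotifModel:
    """Log-odds scoring matrix over A/C/G/T with a score threshold."""

    matrix: np.ndarray  # shape (width, 4)
    background: np.ndarray  # shape (4,)
    score_threshold: float
    stringency_quantile: float = 0.25

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError("matrix must have shape (width, 4)")
        if bg.shape != (4,) or not math.isclose(bg.sum(), 1.0, abs_tol=1e-6):
            raise ValueError("background must be 4 probabilities summing to 1")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "background", bg)

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.matrix, axis=1))

    @classmethod
    def from_probabilities(
        cls, probs: np.ndarray, background: Optional[np.ndarray] = None,
        score_threshold: float = 0.0, pseudo: float = 1e-3, **kw,
    ) -> "MotifModel":
        """Build log-odds from per-position base probabilities."""
        probs = np.asarray(probs, dtype=float)
        bg = (np.full(4, 0.25) if background is None
              else np.asarray(background, dtype=float))
        probs = probs + pseudo
        probs = probs / probs.sum(axis=1, keepdims=True)
        return cls(np.log2(probs / bg), bg, score_threshold, **kw)


@dataclass(frozen=True)
class MotifMatch:
    chrom: str
    start: int  # 0-based, forward-strand leftmost base of the footprint
    strand: str  # strand carrying the motif
    score: float
    width: int

    @property
    def end(self) -> int:
        return self.start + self.width


@dataclass(frozen=True)
class ProjectedMatch:
    """A match in origin-relative coordinates."""

    match: MotifMatch
    origin_id: str
    rel_lo: int  # leftmost footprint position on the T-rich axis
    rel_hi: int  # rightmost (inclusive)
    orientation: str  # FKH-T or FKH-A

    def unproject(self, origin: OriginAnnotation) -> tuple[int, str]:
        """Recover (genomic start, genomic strand) from rel coordinates."""
        if origin.orc_strand == "+":
            start = origin.orc_start + self.rel_lo
            strand = "+" if self.orientation == ORIENT_T else "-"
        else:
            start = origin.orc_start - self.rel_hi
            strand = "-" if self.orientation == ORIENT_T else "+"
        return start, strand


@dataclass(frozen=True)
class RegionSpec:
    name: str
    lo: int
    hi: int  # inclusive rel interval
    orientation: str

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError("lo must be <= hi")


FIVE_PRIME_FKH_T = RegionSpec("five_prime_FKH_T", -150, -11, ORIENT_T)
THREE_PRIME_FKH_A = RegionSpec("three_prime_FKH_A", 41, 150, ORIENT_A)
ORC_OVERLAPPING_FKH_T = RegionSpec("orc_overlapping_FKH_T", -10, 40, ORIENT_T)


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    code = np.full(arr.shape, 5, dtype=np.int8)  # 5 = invalid
    for base, idx in _CODE.items():
        code[arr == ord(base)] = idx
    code[arr == ord("N")] = 4
    return code


def _window_scores(code: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Log-odds score of every window; windows containing N score -inf."""
    w = matrix.shape[0]
    n = code.shape[0] - w + 1
    if n <= 0:
        return np.empty(0)
    padded = np.hstack([matrix, np.full((w, 1), -np.inf)])  # column for N
    scores = np.zeros(n)
    for j in range(w):
        scores += padded[j, code[j : j + n]]
    return scores


def scan_motifs(
    sequences: Mapping[str, str], model: MotifModel
) -> list[MotifMatch]:
    """Score both strands everywhere; report windows >= the score threshold.

    Coordinates always refer to the forward strand of the leftmost base of
    the 8 bp footprint.  Windows containing N are skipped.
    """
    rc_matrix = model.matrix[::-1, [3, 2, 1, 0]]
    out: list[MotifMatch] = []
    for chrom in sequences:
        code = _encode(sequences[chrom])
        if np.any(code == 5):
            raise ValueError(f"{chrom}: sequence alphabet outside A/C/G/T/N")
        for strand, mat in (("+", model.matrix), ("-", rc_matrix)):
            scores = _window_scores(code, mat)
            with np.errstate(invalid="ignore"):
                hits = np.flatnonzero(scores >= model.score_threshold)
            out.extend(
                MotifMatch(chrom, int(i), strand, float(scores[i]), model.width)
                for i in hits
            )
    out.sort(key=lambda m: (m.chrom, m.start, m.strand))
    return out


def select_top_quantile(
    matches: Sequence[MotifMatch], quantile: float = 0.25
) -> list[MotifMatch]:
    """Keep the ceil(quantile * n) best-scoring matches, retaining ties at
    the cut score (the returned set may slightly exceed the quantile)."""
    if not (0 < quantile <= 1):
        raise ValueError("quantile must be in (0, 1]")
    if not matches:
        return []
    scores = np.array([m.score for m in matches])
    keep = math.ceil(quantile * len(matches))
    cut = np.sort(scores)[::-1][keep - 1]
    return [m for m in matches if m.score >= cut]


def project_matches(
    matches: Iterable[MotifMatch], origin: OriginAnnotation
) -> list[ProjectedMatch]:
    """Project matches on the origin's chromosome into rel coordinates."""
    out = []
    for m in matches:
        if m.chrom != origin.chrom:
            continue
        if origin.orc_strand == "+":
            rel_lo = m.start - origin.orc_start
            rel_hi = m.end - 1 - origin.orc_start
            orientation = ORIENT_T if m.strand == "+" else ORIENT_A
        else:
            rel_lo = origin.orc_start - (m.end - 1)
            rel_hi = origin.orc_start - m.start
            orientation = ORIENT_T if m.strand == "-" else ORIENT_A
        out.append(ProjectedMatch(m, origin.origin_id, rel_lo, rel_hi,
                                  orientation))
    return out


def _qualifies(pm: ProjectedMatch, region: RegionSpec) -> bool:
    return (pm.orientation == region.orientation
            and pm.rel_lo <= region.hi and pm.rel_hi >= region.lo)


def region_motif_fraction(
    origins: Sequence[OriginAnnotation],
    matches: Sequence[MotifMatch],
    region: RegionSpec,
) -> float:
    """Fraction of origins with >= 1 correctly oriented match whose 8 bp
    footprint overlaps the rel interval."""
    if not origins:
        raise ValueError("empty origin group")
    by_chrom: dict[str, list[MotifMatch]] = {}
    for m in matches:
        by_chrom.setdefault(m.chrom, []).append(m)
    n_hit = 0
    for o in origins:
        projected = project_matches(by_chrom.get(o.chrom, ()), o)
        if any(_qualifies(pm, region) for pm in projected):
            n_hit += 1
    return n_hit / len(origins)


def enrichment_test(
    k: int, m: int, K: int, N: int
) -> tuple[float, float, str]:
    """Hypergeometric enrichment/depletion of group hits vs the universe.

    ``k`` of ``m`` group members hit; ``K`` of ``N`` universe members hit.
    Returns (P(X >= k), P(X <= k), significance stars for the enrichment
    tail at 0.05 / 0.001 / 0.0001).
    """
    if not (0 <= k <= m <= N and k <= K <= N):
        raise ValueError("inconsistent counts")
    p_enrich = float(stats.hypergeom.sf(k - 1, N, K, m))
    p_deplete = float(stats.hypergeom.cdf(k, N, K, m))
    stars = ("***" if p_enrich < 1e-4 else
             "**" if p_enrich < 1e-3 else
             "*" if p_enrich < 0.05 else "")
    return p_enrich, p_deplete, stars


@dataclass
class AccumulationCurve:
    distances: np.ndarray  # 1..span
    fraction: np.ndarray
    pvalues: np.ndarray  # enrichment vs universe at each distance
    half_point: Optional[int]  # None means "not reached within span"
    group_size: int
    universe_size: int


def _nearest_distance(
    origin: OriginAnnotation, matches: Sequence[MotifMatch], direction: str,
) -> Optional[int]:
    start3 = origin.orc_length  # first rel position 3' of the ORC site
    best: Optional[int] = None
    for pm in project_matches(matches, origin):
        if direction == "five_prime_FKH_T":
            if pm.orientation != ORIENT_T or pm.rel_lo > -1:
                continue
            d = max(1, -pm.rel_hi)
        elif direction == "three_prime_FKH_A":
            if pm.orientation != ORIENT_A or pm.rel_hi < start3:
                continue
            d = max(1, pm.rel_lo - start3 + 1)
        else:
            raise ValueError(f"unknown direction {direction!r}")
        best = d if best is None else min(best, d)
    return best


def cumulative_accumulation(
    origins: Sequence[OriginAnnotation],
    matches: Sequence[MotifMatch],
    direction: str,
    universe: Sequence[OriginAnnotation],
    span: int = 500,
) -> AccumulationCurve:
    """Cumulative fraction of origins whose nearest oriented match lies
    within each distance 1..span of the ORC site.

    5' distances are walked leftward from rel -1; 3' distances rightward
    from the first position past the ORC site (+33 for a 33 bp site).  A
    match counts at distance d when its footprint overlaps the walked
    interval.  Per-distance significance is the hypergeometric enrichment of
    the group's cumulative count against the universe's at the same d.
    """
    if not origins:
        raise ValueError("empty origin group")
    if span < 1:
        raise ValueError("span must be >= 1")
    by_chrom: dict[str, list[MotifMatch]] = {}
    for m in matches:
        by_chrom.setdefault(m.chrom, []).append(m)

    def counts(group: Sequence[OriginAnnotation]) -> np.ndarray:
        c = np.zeros(span, dtype=int)
        for o in group:
            d = _nearest_distance(o, by_chrom.get(o.chrom, ()), direction)
            if d is not None and d <= span:
                c[d - 1 :] += 1
        return c

    grp = counts(origins)
    uni = counts(universe)
    frac = grp / len(origins)
    pvals = np.array([
        enrichment_test(int(grp[i]), len(origins), int(uni[i]), len(universe))[0]
        for i in range(span)
    ])
    above = np.flatnonzero(frac >= 0.5)
    half = int(above[0] + 1) if above.size else None
    return AccumulationCurve(np.arange(1, span + 1), frac, pvals, half,
                             len(origins), len(universe))
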