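"""Synthetic sorted-population, ChIP and MNase fragment data.

The generator plants a known replication program and chromatin architecture
so every downstream stage can be exercised and validated without any
external download:

* **Replication**: each origin fires independently (Bernoulli per-origin
  efficiency) at a fixed time; forks move at constant speed and replicate
  passively past silent origins.  Sorted-S copy number assumes uniform cell
  density across S-phase, so a locus replicated at time t has expected copy
  number ``1 + max(0, (T - t)/T)`` in the sorted population, between 1
  (unreplicated) and 2 (replicated at the start of S).  G2 coverage is
  uniform.  Counts are Poisson (or negative binomial) around the expected
  coverage.
* **Fragments**: MNase protection lengths come from a Gaussian mixture;
  nucleosome-class fragments sit on planted dyads (regular spacing,
  excluded from the NDR around each ORC site), ORC/Cdc6-class fragments sit
  on the ORC site, background is uniform.
* **Signal tracks**: ChIP IP is a Gaussian enrichment kernel per origin
  over a flat input.

Randomness: every generator derives independent substreams from one root
seed via ``numpy.random.SeedSequence([seed, stream_id])``; stream ids are
fixed small integers per track type (documented on each function), so the
same seed and configuration reproduce outputs bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genome import CoverageTrack, GenomeAnnotation, OriginAnnotation, sort_origins

__all__ = [
    "FiringParams",
    "FragmentClass",
    "SimulationConfig",
    "expected_copy_number",
    "simulate_replication_experiment",
    "simulate_fragment_experiment",
    "simulate_signal_tracks",
    "fha_replication_scenario",
    "g1_chromatin_scenario",
]

_STREAM_S = 0
_STREAM_G2 = 1
_STREAM_FIRING = 2
_STREAM_FRAGMENTS = 3
_STREAM_SIGNAL = 4


@dataclass(frozen=True)
class FiringParams:
    """Per-origin firing time (min into S) and efficiency (probability)."""

    time: float
    efficiency: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.efficiency <= 1.0):
            raise ValueError("efficiency must be in [0, 1]")


@dataclass(frozen=True)
class FragmentClass:
    """One component of the fragment-length mixture."""

    center: float  # bp
    sd: float  # bp
    weight: float
    anchor: str  # nucleosome_dyad | orc_site | background

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.anchor not in ("nucleosome_dyad", "orc_site", "background"):
            raise ValueError(f"unknown anchor {self.anchor!r}")


@dataclass(frozen=True)
class SimulationConfig:
    fork_speed: float = 1.5e3  # bp/min
    s_duration: float = 60.0  # min
    firing: Mapping[str, Mapping[str, FiringParams]] = field(default_factory=dict)
    read_depth: float = 50.0  # mean reads per bp at copy number 1
    noise_model: str = "poisson"  # poisson | negative_binomial
    nb_dispersion: float = 10.0
    fragment_mixture: tuple[FragmentClass, ...] = ()
    ndr_halfwidth: int = 80
    nucleosome_spacing: int = 165
    n_firing_draws: int = 0  # 0 = exact expectation over firing states
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_model not in ("poisson", "negative_binomial"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.fragment_mixture:
            w = sum(c.weight for c in self.fragment_mixture)
            if abs(w - 1.0) > 1e-9:
                raise ValueError("fragment mixture weights must sum to 1")

    def firing_for(self, genotype: str) -> Mapping[str, FiringParams]:
        try:
            return self.firing[genotype]
        except KeyError:
            raise KeyError(f"no firing parameters for genotype {genotype!r}")


def _rng(seed: int, stream: int, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream, extra]))


def _genotype_index(config: SimulationConfig, genotype: str) -> int:
    return sorted(config.firing).index(genotype)


def expected_copy_number(
    genome: GenomeAnnotation,
    origins: Sequence[OriginAnnotation],
    config: SimulationConfig,
    genotype: str,
) -> CoverageTrack:
    """Exact expected sorted-S copy number per bp, in [1, 2].

    For each position the fork arrival time from origin *o* is
    ``t_o + |x - pos_o| / v``; with independent firing the expectation sums
    over which origin's fork, among those that fired, arrives first:
    ``E = 1 + sum_k r(a_k) e_k prod_{j<k} (1 - e_j)`` with arrivals sorted
    ascending and ``r(t) = max(0, (T - t)/T)``.
    """
    if config.fork_speed <= 0 or config.s_duration <= 0:
        raise ValueError("fork_speed and s_duration must be positive")
    firing = config.firing_for(genotype)
    if not origins and any(p.efficiency > 0 for p in firing.values()):
        raise ValueError("positive firing efficiency requested with no origins")
    T = config.s_duration
    data = {}
    for chrom in genome.names:
        n = genome.length(chrom)
        chrom_origins = [o for o in origins if o.chrom == chrom]
        if not chrom_origins:
            data[chrom] = np.ones(n)
            continue
        x = np.arange(n, dtype=float)
        arrivals = np.empty((n, len(chrom_origins)))
        effs = np.empty(len(chrom_origins))
        for j, o in enumerate(chrom_origins):
            p = firing[o.origin_id]
            arrivals[:, j] = p.time + np.abs(x - o.orc_start) / config.fork_speed
            effs[j] = p.efficiency
        order = np.argsort(arrivals, axis=1, kind="stable")
        a_sorted = np.take_along_axis(arrivals, order, axis=1)
        e_sorted = effs[order]
        miss = np.cumprod(1.0 - e_sorted, axis=1)
        prob_first = e_sorted.copy()
        prob_first[:, 1:] *= miss[:, :-1]
        r = np.clip((T - a_sorted) / T, 0.0, 1.0)
        data[chrom] = 1.0 + np.sum(r * prob_first, axis=1)
    return CoverageTrack(genome, data)


def _sampled_copy_number(
    genome: GenomeAnnotation,
    origins: Sequence[OriginAnnotation],
    config: SimulationConfig,
    genotype: str,
) -> CoverageTrack:
    """Monte-Carlo estimate of the sorted-S copy number over
    ``config.n_firing_draws`` sampled firing configurations (stream 2)."""
    firing = config.firing_for(genotype)
    T = config.s_duration
    rng = _rng(config.seed, _STREAM_FIRING, _genotype_index(config, genotype))
    data = {c: np.zeros(genome.length(c)) for c in genome.names}
    origins = sort_origins(origins)
    effs = np.array([firing[o.origin_id].efficiency for o in origins])
    for _ in range(config.n_firing_draws):
        fired = rng.random(len(origins)) < effs
        for chrom in genome.names:
            n = genome.length(chrom)
            x = np.arange(n, dtype=float)
            t = np.full(n, np.inf)
            for o, f in zip(origins, fired):
                if f and o.chrom == chrom:
                    p = firing[o.origin_id]
                    t = np.minimum(t, p.time + np.abs(x - o.orc_start)
                                   / config.fork_speed)
            with np.errstate(invalid="ignore"):
                r = np.clip((T - t) / T, 0.0, 1.0)
            r[~np.isfinite(t)] = 0.0
            data[chrom] += r
    k = max(config.n_firing_draws, 1)
    return CoverageTrack(genome, {c: 1.0 + v / k for c, v in data.items()})


def _draw_counts(
    rng: np.random.Generator, expectation: np.ndarray, config: SimulationConfig
) -> np.ndarray:
    if config.noise_model == "poisson":
        return rng.poisson(expectation).astype(float)
    # Gamma-Poisson: variance = mu + mu^2 / dispersion
    shape = config.nb_dispersion
    lam = rng.gamma(shape, expectation / shape)
    return rng.poisson(lam).astype(float)


def simulate_replication_experiment(
    genome: GenomeAnnotation,
    origins: Sequence[OriginAnnotation],
    config: SimulationConfig,
    genotype: str,
    replicate: int = 0,
    truth: Optional[CoverageTrack] = None,
) -> tuple[CoverageTrack, CoverageTrack, CoverageTrack]:
    """Simulate one sorted S / G2 sequencing pair.

    Returns (S counts, G2 counts, truth copy number).  Expected S coverage
    is ``read_depth * truth``; expected G2 coverage is ``read_depth``.
    Streams 0 (S) and 1 (G2) keyed additionally by genotype index and
    replicate keep replicates and genotypes independent.  ``truth`` may be
    supplied to reuse an already computed expectation across replicates.
    """
    if not genome.chromosomes:
        raise ValueError("empty genome")
    firing = config.firing_for(genotype)
    if not origins and any(p.efficiency > 0 for p in firing.values()):
        raise ValueError("positive firing efficiency requested with no origins")
    if config.read_depth < 0:
        raise ValueError("read depth must be non-negative")
    for o in origins:
        o.validate(genome)
    if truth is None:
        if config.n_firing_draws > 0:
            truth = _sampled_copy_number(genome, origins, config, genotype)
        else:
            truth = expected_copy_number(genome, origins, config, genotype)
    gidx = _genotype_index(config, genotype)
    rng_s = _rng(config.seed, _STREAM_S, gidx * 1000 + replicate)
    rng_g2 = _rng(config.seed, _STREAM_G2, gidx * 1000 + replicate)
    S = {c: _draw_counts(rng_s, config.read_depth * truth[c], config)
         for c in genome.names}
    G2 = {c: _draw_counts(rng_g2, np.full(genome.length(c), config.read_depth),
                          config)
          for c in genome.names}
    return (CoverageTrack(genome, S), CoverageTrack(genome, G2), truth)


def _dyad_positions(
    genome: GenomeAnnotation,
    origins: Sequence[OriginAnnotation],
    config: SimulationConfig,
) -> dict[str, np.ndarray]:
    """Planted nucleosome dyads: regular spacing, NDR around each ORC-site
    start excluded."""
    out = {}
    for chrom in genome.names:
        n = genome.length(chrom)
        dyads = np.arange(config.nucleosome_spacing // 2, n,
                          config.nucleosome_spacing)
        for o in origins:
            if o.chrom == chrom and config.ndr_halfwidth > 0:
                dyads = dyads[np.abs(dyads - o.orc_start) > config.ndr_halfwidth]
        out[chrom] = dyads
    return out


def simulate_fragment_experiment(
    genome: GenomeAnnotation,
    origins: Sequence[OriginAnnotation],
    config: SimulationConfig,
    n_fragments: int,
) -> pd.DataFrame:
    """Draw an MNase-like fragment set (chrom, start, end) from the
    configured length mixture (stream 3).

    Lengths are rounded to the nearest integer with a floor of 1 bp.
    Midpoints follow the class anchor: planted dyads (NDR-excluded), the
    ORC site, or the uniform background; fragments are shifted to stay
    inside their chromosome.
    """
    if n_fragments <= 0:
        raise ValueError("n_fragments must be positive")
    if not config.fragment_mixture:
        raise ValueError("fragment mixture is empty")
    rng = _rng(config.seed, _STREAM_FRAGMENTS)
    classes = config.fragment_mixture
    weights = np.array([c.weight for c in classes])
    # stratified allocation: class counts follow the weights exactly
    # (largest-remainder rounding), so library composition does not drift
    # between independent draws
    raw = weights * n_fragments
    counts = np.floor(raw).astype(int)
    frac_order = np.argsort(-(raw - counts), kind="stable")
    for i in range(n_fragments - counts.sum()):
        counts[frac_order[i % len(classes)]] += 1
    dyads = _dyad_positions(genome, origins, config)
    all_dyads = [(c, d) for c in genome.names for d in dyads[c]]
    chrom_lengths = np.array([genome.length(c) for c in genome.names])
    cum = np.concatenate([[0], np.cumsum(chrom_lengths)])
    records = []
    for cls, k in zip(classes, counts):
        if k == 0:
            continue
        lengths = np.maximum(1, np.rint(rng.normal(cls.center, cls.sd, k))
                             .astype(int))
        if cls.anchor == "nucleosome_dyad":
            if not all_dyads:
                raise ValueError("no dyad positions available")
            pick = rng.integers(0, len(all_dyads), k)
            chroms = [all_dyads[i][0] for i in pick]
            mids = np.array([all_dyads[i][1] for i in pick])
        elif cls.anchor == "orc_site":
            if not origins:
                raise ValueError("orc_site anchor requires origins")
            olist = sort_origins(origins)
            pick = rng.integers(0, len(olist), k)
            chroms, mids = [], np.empty(k, dtype=int)
            for j, i in enumerate(pick):
                o = olist[i]
                lo, hi = o.orc_site_interval()
                # footprint centers cluster on the site center but always
                # stay within the site
                center = (lo + hi - 1) / 2.0
                draw = int(round(rng.normal(center, (hi - lo) / 6.0)))
                chroms.append(o.chrom)
                mids[j] = min(max(draw, lo), hi - 1)
        else:  # background
            g = rng.integers(0, genome.total_length, k)
            ci = np.searchsorted(cum, g, side="right") - 1
            chroms = [genome.names[i] for i in ci]
            mids = g - cum[ci]
        starts = mids - lengths // 2
        for chrom, s, L in zip(chroms, starts, lengths):
            n = genome.length(chrom)
            L = min(L, n)
            s = min(max(s, 0), n - L)
            records.append((chrom, int(s), int(s + L)))
    df = pd.DataFrame(records, columns=["chrom", "start", "end"])
    return df.sort_values(["chrom", "start", "end"], kind="stable",
                          ignore_index=True)


def simulate_signal_tracks(
    genome: GenomeAnnotation,
    origins: Sequence[OriginAnnotation],
    peak_height: float,
    peak_sd: float,
    depth: float,
    seed: int,
    noise: str = "poisson",
) -> tuple[CoverageTrack, CoverageTrack]:
    """ChIP-like IP and input tracks (stream 4).

    Expected IP is ``depth * (1 + (peak_height - 1) * sum of unit Gaussian
    kernels centered on each ORC-site start)``; expected input is flat
    ``depth``.  ``noise='none'`` returns the expectations directly.
    """
    if peak_height < 1:
        raise ValueError("peak_height must be >= 1")
    if peak_sd <= 0:
        raise ValueError("peak_sd must be positive")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = _rng(seed, _STREAM_SIGNAL)
    ip, inp = {}, {}
    for chrom in genome.names:
        n = genome.length(chrom)
        x = np.arange(n, dtype=float)
        kern = np.zeros(n)
        for o in origins:
            if o.chrom == chrom:
                kern += np.exp(-0.5 * ((x - o.orc_start) / peak_sd) ** 2)
        mu_ip = depth * (1.0 + (peak_height - 1.0) * kern)
        if noise == "none":
            ip[chrom] = mu_ip
            inp[chrom] = np.full(n, depth)
        elif noise == "poisson":
            ip[chrom] = rng.poisson(mu_ip).astype(float)
            inp[chrom] = rng.poisson(np.full(n, depth)).astype(float)
        else:
            raise ValueError(f"unknown noise mode {noise!r}")
    return CoverageTrack(genome, ip), CoverageTrack(genome, inp)


# ---------------------------------------------------------------------------
# Canned study designs shared by tests, examples and the acceptance script.
# ---------------------------------------------------------------------------


def fha_replication_scenario(
    seed: int = 0,
    read_depth: float = 50.0,
    chrom_length: int = 500_000,
    spacing: int = 25_000,
) -> tuple[GenomeAnnotation, list[OriginAnnotation], SimulationConfig,
           dict[str, list[str]]]:
    """Two-chromosome, 40-origin design with a planted FHA-like regulon.

    chrI carries 12 early origins whose mutant efficiency is reduced by 25%
    (expected FHA-SORT-positive calls), separated by late fillers and two
    very early anchors; chrII carries 12 late origins whose mutant
    efficiency is raised (expected negative calls) among late fillers.  The
    16 fillers/anchors are the planted neutrals.  Returns (genome, origins,
    config, roles) with roles mapping 'positive'/'negative'/'neutral' to
    origin ids.
    """
    genome = GenomeAnnotation((("chrI", chrom_length), ("chrII", chrom_length)))
    n_per = chrom_length // spacing
    # E = very early anchor (stabilizes the genome-wide maximum across
    # genotypes), P = positive target, L = negative target, n = late filler
    # (neutral).  Targets are isolated by late fillers so that, at 1 kb/min
    # forks, no neighboring origin can passively rescue them within S-phase
    # and the planted efficiency changes stay visible in sorted-S copy
    # number.
    chr1 = "EnPnPnPnPnPnPnPnPnPn"
    chr2 = "PnPnPnnLLLLLLLLLLLLn"
    assert len(chr1) == len(chr2) == n_per
    params = {
        "E": (5.0, 0.95, 5.0, 0.95),
        "P": (10.0, 0.90, 10.0, 0.675),  # mutant efficiency = 0.9 * 0.75
        "L": (42.0, 0.25, 42.0, 0.55),
        "n": (45.0, 0.30, 45.0, 0.30),
    }
    origins: list[OriginAnnotation] = []
    wt: dict[str, FiringParams] = {}
    mut: dict[str, FiringParams] = {}
    roles: dict[str, list[str]] = {"positive": [], "negative": [], "neutral": []}
    for chrom, pattern in (("chrI", chr1), ("chrII", chr2)):
        for i, kind in enumerate(pattern):
            oid = f"ori_{chrom}_{i:02d}"
            pos = spacing // 2 + i * spacing
            strand = "+" if i % 2 == 0 else "-"
            origins.append(OriginAnnotation(oid, chrom, pos, strand))
            t_wt, e_wt, t_mut, e_mut = params[kind]
            wt[oid] = FiringParams(t_wt, e_wt)
            mut[oid] = FiringParams(t_mut, e_mut)
            role = {"P": "positive", "L": "negative"}.get(kind, "neutral")
            roles[role].append(oid)
    config = SimulationConfig(
        fork_speed=1.0e3,
        s_duration=60.0,
        firing={"wild_type": wt, "mutant": mut},
        read_depth=read_depth,
        seed=seed,
    )
    return genome, origins, config, roles


def g1_chromatin_scenario(
    seed: int = 0,
    n_origins: Optional[int] = None,
    span: int = 500,
    mixture: str = "g1",
) -> tuple[GenomeAnnotation, list[OriginAnnotation], SimulationConfig]:
    """Dense origin array for MNase footprint studies.

    ``mixture='g1'`` plants the G1-like architecture (nucleosomes outside an
    NDR of +-80 bp, an 80 bp ORC/Cdc6-scale footprint on the ORC site, and
    uniform background) on 50 origins whose +-span windows exactly tile the
    chromosome, so every simulated fragment is counted once.
    ``mixture='stability'`` plants the nucleosome/subnucleosome pair used
    for digestion-stability comparisons on 100 origins spaced ``span``
    apart (overlapping windows double the per-position counts entering the
    ratio-of-ratios).  Origins alternate strands to exercise mirroring.
    """
    if mixture == "g1":
        spacing = 2 * span + 1
        if n_origins is None:
            n_origins = 50
        classes = (
            FragmentClass(150.0, 8.0, 0.55, "nucleosome_dyad"),
            FragmentClass(80.0, 5.0, 0.20, "orc_site"),
            FragmentClass(120.0, 25.0, 0.25, "background"),
        )
    elif mixture == "stability":
        spacing = span
        if n_origins is None:
            n_origins = 100
        classes = (
            FragmentClass(152.0, 6.0, 0.25, "nucleosome_dyad"),
            FragmentClass(131.0, 6.0, 0.25, "nucleosome_dyad"),
            FragmentClass(80.0, 5.0, 0.05, "orc_site"),
            FragmentClass(140.0, 15.0, 0.45, "background"),
        )
    else:
        raise ValueError(f"unknown mixture {mixture!r}")
    genome = GenomeAnnotation((("chrI", n_origins * spacing + spacing),))
    origins = [
        OriginAnnotation(f"ori_{i:02d}", "chrI", spacing // 2 + i * spacing,
                         "+" if i % 2 == 0 else "-")
        for i in range(n_origins)
    ]
    config = SimulationConfig(
        firing={},
        fragment_mixture=classes,
        ndr_halfwidth=80,
        seed=seed,
    )
    return genome, origins, config
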