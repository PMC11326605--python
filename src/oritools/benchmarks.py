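"""Planted-truth recovery studies on the canned synthetic scenarios.

These drive the whole pipeline on data where the correct answer is known by
construction: a two-genotype replication experiment with planted positively
and negatively regulated origins, and G1-like MNase fragment sets with a
planted NDR and ORC/Cdc6-scale footprint.  They are used both by the test
suite and by the acceptance script.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import activity as act
from . import footprints as fp
from . import profiles as pr
from . import simulate as sim

__all__ = [
    "replication_recovery",
    "footprint_minmax",
    "stability_noise_check",
]

REPLICATES = {"wild_type": 3, "mutant": 2}


def replication_recovery(seed: int, read_depth: float = 50.0) -> dict:
    """Run the full replication pipeline on the planted FHA-like scenario.

    Simulates 3 wild-type + 2 mutant sorted S/G2 replicate pairs, processes
    each through normalization, binning, outlier filtering, scaling and
    smoothing, summarizes replicates, quantifies and classifies every
    origin, and scores the calls against the planted roles.
    """
    genome, origins, config, roles = sim.fha_replication_scenario(
        seed=seed, read_depth=read_depth)
    smoothed: dict[str, list[pr.BinnedProfile]] = {}
    for genotype, nrep in REPLICATES.items():
        truth = sim.expected_copy_number(genome, origins, config, genotype)
        smoothed[genotype] = []
        for rep in range(nrep):
            S, G2, _ = sim.simulate_replication_experiment(
                genome, origins, config, genotype, rep, truth=truth)
            smoothed[genotype].append(
                pr.run_pipeline(S, G2, genotype=genotype, replicate=str(rep)))
    summaries = {g: pr.summarize_replicates(p) for g, p in smoothed.items()}
    records = act.classify_origins([
        act.quantify_origin_activity(summaries, o, "wild_type", "mutant")
        for o in origins
    ])
    by_id = {r.origin_id: r for r in records}
    n_pos = sum(by_id[i].origin_class == act.CLASS_POSITIVE
                for i in roles["positive"])
    n_neg = sum(by_id[i].origin_class == act.CLASS_NEGATIVE
                for i in roles["negative"])
    n_neutral_off = sum(by_id[i].origin_class != act.CLASS_OTHER
                        for i in roles["neutral"])
    return {
        "n_positive_recovered": n_pos,
        "n_positive_planted": len(roles["positive"]),
        "n_negative_recovered": n_neg,
        "n_negative_planted": len(roles["negative"]),
        "n_neutral_misclassified": n_neutral_off,
        "n_neutral_planted": len(roles["neutral"]),
        "records": records,
    }


def footprint_minmax(seed: int, n_fragments: int = 200_000,
                     span: int = 500) -> dict:
    """Locate the scaled nucleosome minimum and ORC/Cdc6 maximum on a
    simulated G1-like fragment set with a planted +-80 bp NDR."""
    genome, origins, config = sim.g1_chromatin_scenario(seed=seed, span=span)
    frags = sim.simulate_fragment_experiment(genome, origins, config,
                                             n_fragments)
    mat = fp.build_occupancy_matrix(frags, origins, span)
    nuc = fp.scaled_fraction_signal(mat, fp.NUCLEOSOME_SCALED)
    orc = fp.scaled_fraction_signal(mat, fp.ORC_CDC6_SCALED)
    return {
        "nucleosome_min_pos": int(mat.rel_positions[np.nanargmin(nuc)]),
        "orc_max_pos": int(mat.rel_positions[np.nanargmax(orc)]),
    }


def stability_noise_check(seed: int, n_fragments: int = 200_000,
                          span: int = 500) -> dict:
    """Stability ratio between two fragment sets drawn from identical
    parameters; reports the fraction of defined positions within 1 +- 0.05."""
    genome, origins, config = sim.g1_chromatin_scenario(
        seed=seed, span=span, mixture="stability")
    mats = []
    for sub in (1, 2):
        cfg = dataclasses.replace(config, seed=2 * seed + sub)
        frags = sim.simulate_fragment_experiment(genome, origins, cfg,
                                                 n_fragments)
        mats.append(fp.build_occupancy_matrix(frags, origins, span))
    ratio = fp.stability_ratio(mats[0], mats[1])
    defined = ratio[np.isfinite(ratio)]
    return {
        "fraction_within_5pct": float(np.mean(np.abs(defined - 1.0) <= 0.05)),
        "n_defined": int(defined.size),
    }
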