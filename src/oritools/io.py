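"""Plain-text genomics I/O: bedGraph, BED, FASTA, TSV tables, YAML config.

Everything in scope is a text format; bedGraph intervals are expanded to or
condensed from per-nucleotide vectors on read/write.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .genome import CoverageTrack, GenomeAnnotation, OriginAnnotation
from .motifs import MotifModel
from .profiles import BinnedProfile, ProfileSummary
from .simulate import FiringParams, FragmentClass, SimulationConfig

PathLike = Union[str, Path]


def read_fasta(path: PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: PathLike, sequences: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def genome_from_fasta(sequences: Mapping[str, str]) -> GenomeAnnotation:
    return GenomeAnnotation(tuple((n, len(s)) for n, s in sequences.items()))


def write_bedgraph(path: PathLike, track: CoverageTrack) -> None:
    """Run-length-condensed bedGraph of a per-nucleotide track."""
    with open(path, "w") as fh:
        for chrom, arr in track.items():
            vals = np.nan_to_num(arr, nan=0.0)
            change = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [vals.size]])
            for s, e in zip(starts, ends):
                v = vals[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_bedgraph(path: PathLike, genome: GenomeAnnotation) -> CoverageTrack:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"],
                     comment="t", dtype={"chrom": str})
    # 'comment="t"' skips optional "track ..." header lines
    data = {c: np.zeros(genome.length(c)) for c in genome.names}
    for row in df.itertuples(index=False):
        data[row.chrom][int(row.start) : int(row.end)] = float(row.value)
    return CoverageTrack(genome, data)


def write_origins_bed(path: PathLike, origins: Sequence[OriginAnnotation]) -> None:
    """BED6: name = origin id, strand = T-rich (ORC) strand."""
    with open(path, "w") as fh:
        for o in origins:
            lo, hi = o.orc_site_interval()
            fh.write(f"{o.chrom}\t{lo}\t{hi}\t{o.origin_id}\t0\t{o.orc_strand}\n")


def read_origins_bed(path: PathLike, orc_length: int = 33) -> list[OriginAnnotation]:
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str},
                     names=["chrom", "start", "end", "name", "score", "strand"])
    out = []
    for row in df.itertuples(index=False):
        length = int(row.end) - int(row.start)
        orc_start = int(row.start) if row.strand == "+" else int(row.end) - 1
        out.append(OriginAnnotation(str(row.name), row.chrom, orc_start,
                                    row.strand, length or orc_length))
    return out


def write_fragments_bed(path: PathLike, fragments: pd.DataFrame) -> None:
    fragments[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False,
                                                index=False)


def read_fragments(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                     names=["chrom", "start", "end"], dtype={0: str})
    return df


def read_bed3(path: PathLike) -> dict[str, tuple[int, int]]:
    """One interval per chromosome (e.g. centromeres)."""
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                     names=["chrom", "start", "end"], dtype={0: str})
    return {row.chrom: (int(row.start), int(row.end))
            for row in df.itertuples(index=False)}


def write_summary_tsv(path: PathLike, summary: ProfileSummary) -> None:
    rows = []
    for chrom in summary.genome.names:
        m = summary.mean[chrom]
        hw = summary.ci_halfwidth[chrom]
        for i in range(m.size):
            rows.append((chrom, i * summary.bin_size,
                         min((i + 1) * summary.bin_size,
                             summary.genome.length(chrom)),
                         m[i], m[i] - hw[i], m[i] + hw[i],
                         summary.n_replicates))
    pd.DataFrame(rows, columns=["chrom", "bin_start", "bin_end", "mean",
                                "ci_low", "ci_high", "n"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g")


def write_profile_bedgraph(path: PathLike, profile: BinnedProfile) -> None:
    with open(path, "w") as fh:
        for chrom in profile.genome.names:
            arr = profile[chrom]
            for i, v in enumerate(arr):
                if np.isfinite(v):
                    start = i * profile.bin_size
                    end = min(start + profile.bin_size,
                              profile.genome.length(chrom))
                    fh.write(f"{chrom}\t{start}\t{end}\t{v:.6g}\n")


def read_motif_matrix(path: PathLike) -> MotifModel:
    """Motif matrix TSV: header ``pos A C G T`` rows of log-odds, plus a
    ``background`` row of 4 probabilities and optionally a ``threshold``
    row."""
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str})
    df = df.set_index(df.columns[0])
    bg = df.loc["background", ["A", "C", "G", "T"]].to_numpy(dtype=float)
    thr = float(df.loc["threshold", "A"]) if "threshold" in df.index else 0.0
    body = df.drop(index=[i for i in ("background", "threshold")
                          if i in df.index])
    mat = body[["A", "C", "G", "T"]].to_numpy(dtype=float)
    return MotifModel(mat, bg, thr)


def write_motif_matrix(path: PathLike, model: MotifModel) -> None:
    with open(path, "w") as fh:
        fh.write("pos\tA\tC\tG\tT\n")
        for i, row in enumerate(model.matrix):
            fh.write(f"{i}\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
        fh.write("background\t"
                 + "\t".join(f"{v:.6g}" for v in model.background) + "\n")
        fh.write(f"threshold\t{model.score_threshold:.6g}\t0\t0\t0\n")


def read_group_tsv(path: PathLike) -> list[str]:
    """One origin id per line (a header line named origin_id is allowed)."""
    ids = [ln.strip() for ln in Path(path).read_text().splitlines()
           if ln.strip()]
    return [i for i in ids if i != "origin_id"]


def load_simulation_config(path: PathLike) -> SimulationConfig:
    """Build a SimulationConfig from a YAML mapping of the dataclass fields."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    firing = {
        genotype: {oid: FiringParams(float(v["time"]), float(v["efficiency"]))
                   for oid, v in per.items()}
        for genotype, per in (raw.pop("firing", {}) or {}).items()
    }
    mixture = tuple(
        FragmentClass(float(c["center"]), float(c["sd"]), float(c["weight"]),
                      str(c["anchor"]))
        for c in raw.pop("fragment_mixture", []) or []
    )
    return SimulationConfig(firing=firing, fragment_mixture=mixture, **raw)
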