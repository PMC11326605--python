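"""Genome and origin annotations.

All coordinates are 0-based, half-open, on the forward strand of the
reference, following BED conventions.  Origin-relative ("rel") coordinates
put the first nucleotide of the T-rich strand of the ORC site at position 0
and read the T-rich strand 5'->3' left-to-right, so negative rel positions
are 5' of the ORC site regardless of which genomic strand carries the
T-rich sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional

import numpy as np

__all__ = ["GenomeAnnotation", "OriginAnnotation", "CoverageTrack"]


@dataclass(frozen=True)
class GenomeAnnotation:
    """Ordered chromosome names and lengths (bp)."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        chroms = tuple((str(n), int(l)) for n, l in self.chromosomes)
        object.__setattr__(self, "chromosomes", chroms)
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for _, l in chroms):
            raise ValueError("chromosome lengths must be positive")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    @property
    def lengths(self) -> Mapping[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def check_position(self, chrom: str, pos: int) -> None:
        n = self.length(chrom)
        if not (0 <= pos < n):
            raise ValueError(f"position {pos} outside {chrom} (length {n})")

    def n_bins(self, chrom: str, bin_size: int) -> int:
        return -(-self.length(chrom) // bin_size)


@dataclass(frozen=True)
class OriginAnnotation:
    """A replication origin anchored on its ORC site.

    ``orc_start`` is the genomic coordinate of the first nucleotide of the
    T-rich strand of the ORC site (rel position 0); ``orc_strand`` is the
    genomic strand carrying the T-rich sequence.  The site spans rel
    positions 0..orc_length-1 (default 0..+32).
    """

    origin_id: str
    chrom: str
    orc_start: int
    orc_strand: str = "+"
    orc_length: int = 33
    trep: Optional[float] = None
    labels: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.orc_strand not in ("+", "-"):
            raise ValueError("orc_strand must be '+' or '-'")
        if self.orc_length < 1:
            raise ValueError("orc_length must be >= 1")
        object.__setattr__(self, "labels", frozenset(self.labels))

    def rel_position(self, genomic_pos: int) -> int:
        """Origin-relative position of a genomic coordinate."""
        if self.orc_strand == "+":
            return genomic_pos - self.orc_start
        return self.orc_start - genomic_pos

    def genomic_position(self, rel_pos: int) -> int:
        """Inverse of :meth:`rel_position`."""
        if self.orc_strand == "+":
            return self.orc_start + rel_pos
        return self.orc_start - rel_pos

    def orc_site_interval(self) -> tuple[int, int]:
        """Genomic half-open interval covered by the ORC site."""
        if self.orc_strand == "+":
            return self.orc_start, self.orc_start + self.orc_length
        return self.orc_start - self.orc_length + 1, self.orc_start + 1

    def validate(self, genome: GenomeAnnotation) -> None:
        genome.check_position(self.chrom, self.orc_start)
        lo, hi = self.orc_site_interval()
        if lo < 0 or hi > genome.length(self.chrom):
            raise ValueError(
                f"ORC site of {self.origin_id} extends outside {self.chrom}"
            )


@dataclass
class CoverageTrack:
    """Per-chromosome per-nucleotide coverage vectors."""

    genome: GenomeAnnotation
    data: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom in self.genome.names:
            if chrom not in self.data:
                raise ValueError(f"missing coverage for {chrom}")
            arr = np.asarray(self.data[chrom], dtype=float)
            if arr.shape != (self.genome.length(chrom),):
                raise ValueError(
                    f"coverage length mismatch on {chrom}: "
                    f"{arr.shape[0]} != {self.genome.length(chrom)}"
                )
            if np.any(arr < 0):
                raise ValueError(f"negative coverage on {chrom}")
            self.data[chrom] = arr

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.data[chrom]

    def items(self) -> Iterator[tuple[str, np.ndarray]]:
        return ((c, self.data[c]) for c in self.genome.names)

    @property
    def total(self) -> float:
        return float(sum(arr.sum() for arr in self.data.values()))

    @classmethod
    def from_constant(cls, genome: GenomeAnnotation, value: float) -> "CoverageTrack":
        return cls(
            genome,
            {c: np.full(genome.length(c), float(value)) for c in genome.names},
        )


def sort_origins(origins: Iterable[OriginAnnotation]) -> list[OriginAnnotation]:
    """Origins sorted by (chrom, orc_start) for reproducible iteration."""
    return sorted(origins, key=lambda o: (o.chrom, o.orc_start, o.origin_id))
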