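"""Genome model and haplotype-resolved karyotypes.

Coordinates are 0-based, half-open throughout. A :class:`ParentalKaryotype`
stores, per chromosome, an ordered tiling of segments each carrying an
integer copy number for the two parental homologs (``cnA``/``cnB``). The
same container represents simulated ground truth and inferred calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "GenomeModel",
    "ParentalKaryotype",
    "Segment",
    "simulate_genome",
    "default_genome",
    "human_autosome_genome",
]


@dataclass(frozen=True)
class Segment:
    """One constant-copy-number interval on a chromosome (half-open)."""

    start: int
    end: int
    cnA: int
    cnB: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def total(self) -> int:
        return self.cnA + self.cnB

    def cn(self, homolog: str) -> int:
        if homolog not in ("A", "B"):
            raise ValueError(f"homolog must be 'A' or 'B', got {homolog!r}")
        return self.cnA if homolog == "A" else self.cnB


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome structure plus heterozygous-site positions.

    Parameters
    ----------
    lengths
        Chromosome name -> length in bp.
    centromeres
        Chromosome name -> (start, end) of the centromeric interval, strictly
        inside the chromosome. The p-arm is ``[0, cen_start)`` and the q-arm
        ``[cen_end, length)``; telomeres sit at both chromosome ends.
    het_sites
        Chromosome name -> strictly increasing array of het-SNP positions.
    bin_width
        Width of fixed genomic bins (bp); the last bin of a chromosome is
        truncated.
    """

    lengths: Mapping[str, int]
    centromeres: Mapping[str, tuple[int, int]]
    het_sites: Mapping[str, np.ndarray]
    bin_width: int = 25_000

    def __post_init__(self) -> None:
        for chrom, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"{chrom}: non-positive length {length}")
            cs, ce = self.centromeres[chrom]
            if not (0 < cs < ce < length):
                raise ValueError(f"{chrom}: centromere ({cs},{ce}) not strictly inside [0,{length})")
            sites = np.asarray(self.het_sites.get(chrom, np.empty(0, dtype=np.int64)))
            if sites.size and np.any(np.diff(sites) <= 0):
                raise ValueError(f"{chrom}: het sites must be strictly increasing")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths)

    def arms(self, chrom: str) -> dict[str, tuple[int, int]]:
        cs, ce = self.centromeres[chrom]
        return {"p": (0, cs), "q": (ce, self.lengths[chrom])}

    def n_bins(self, chrom: str) -> int:
        return -(-self.lengths[chrom] // self.bin_width)

    def bin_edges(self, chrom: str) -> np.ndarray:
        length = self.lengths[chrom]
        edges = np.arange(0, length + self.bin_width, self.bin_width)
        edges[-1] = min(edges[-1], length)
        if edges[-1] != length:
            edges = np.append(edges, length)
        return edges[: self.n_bins(chrom) + 1]

    def total_length(self) -> int:
        return sum(self.lengths.values())


def simulate_genome(
    lengths: Mapping[str, int],
    centromeres: Mapping[str, tuple[int, int]] | None = None,
    het_density: float = 1 / 3_000,
    bin_width: int = 25_000,
    seed: int | None = None,
) -> GenomeModel:
    """Draw a genome model with het sites as a Poisson process.

    Het sites are drawn per chromosome as a homogeneous Poisson process at
    ``het_density`` sites per bp (default one per 3 kb, the density of common
    heterozygous polymorphisms after filtering). Deterministic given ``seed``.
    """
    for chrom, length in lengths.items():
        if length <= 0:
            raise ValueError(f"{chrom}: non-positive length {length}")
    if centromeres is None:
        centromeres = {c: (int(0.4 * n), int(0.42 * n)) for c, n in lengths.items()}
    rng = np.random.default_rng(seed)
    het: dict[str, np.ndarray] = {}
    for chrom, length in lengths.items():
        n = rng.poisson(length * het_density) if het_density > 0 else 0
        het[chrom] = np.sort(rng.integers(0, length, size=n)).astype(np.int64)
        # Poisson process conditioned on count = sorted uniforms; drop rare duplicates
        het[chrom] = np.unique(het[chrom])
    return GenomeModel(dict(lengths), dict(centromeres), het, bin_width)


#: default test genome: 4 synthetic chromosomes, sized so suites run in seconds
DEFAULT_LENGTHS = {"chr1": 150_000_000, "chr2": 120_000_000, "chr3": 90_000_000, "chr4": 60_000_000}


def default_genome(seed: int = 0, het_density: float = 1 / 3_000, bin_width: int = 25_000) -> GenomeModel:
    """The 4-chromosome synthetic genome used throughout the tests."""
    return simulate_genome(DEFAULT_LENGTHS, None, het_density, bin_width, seed)


def human_autosome_genome(chrom_length: int = 10_000_000, seed: int = 0, het_density: float = 0.0) -> GenomeModel:
    """A 22-autosome genome shape (uniform, scaled down) for burden accounting."""
    lengths = {f"chr{i}": chrom_length for i in range(1, 23)}
    return simulate_genome(lengths, None, het_density, 25_000, seed)


class ParentalKaryotype:
    """Haplotype-resolved integer copy number as segment tilings per chromosome.

    Segments tile ``[0, length)`` of each chromosome with no gaps or overlaps
    and carry non-negative integer copy numbers for homolog A and homolog B.
    """

    def __init__(self, genome: GenomeModel, segments: Mapping[str, list[Segment]] | None = None):
        self.genome = genome
        if segments is None:
            segments = {c: [Segment(0, genome.lengths[c], 1, 1)] for c in genome.chromosomes}
        self.segments: dict[str, list[Segment]] = {c: list(v) for c, v in segments.items()}
        self.validate()

    # ---------------------------------------------------------------- basics
    @classmethod
    def diploid(cls, genome: GenomeModel) -> "ParentalKaryotype":
        return cls(genome)

    def copy(self) -> "ParentalKaryotype":
        return ParentalKaryotype(self.genome, {c: list(v) for c, v in self.segments.items()})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ParentalKaryotype):
            return NotImplemented
        a, b = self.copy(), other.copy()
        a.simplify()
        b.simplify()
        return a.segments == b.segments

    def validate(self) -> None:
        """Check the tiling invariant and non-negative integer copy numbers."""
        for chrom, segs in self.segments.items():
            length = self.genome.lengths[chrom]
            if not segs:
                raise ValueError(f"{chrom}: empty tiling")
            if segs[0].start != 0 or segs[-1].end != length:
                raise ValueError(f"{chrom}: tiling does not span [0,{length})")
            for prev, cur in zip(segs, segs[1:]):
                if prev.end != cur.start:
                    raise ValueError(f"{chrom}: gap/overlap at {prev.end}/{cur.start}")
            for s in segs:
                if s.start >= s.end:
                    raise ValueError(f"{chrom}: empty segment {s}")
                if s.cnA < 0 or s.cnB < 0:
                    raise ValueError(f"{chrom}: negative copy number in {s}")

    def simplify(self) -> "ParentalKaryotype":
        """Merge adjacent segments with identical copy-number states, in place."""
        for chrom, segs in self.segments.items():
            merged: list[Segment] = []
            for s in segs:
                if merged and merged[-1].cnA == s.cnA and merged[-1].cnB == s.cnB:
                    merged[-1] = Segment(merged[-1].start, s.end, s.cnA, s.cnB)
                else:
                    merged.append(s)
            self.segments[chrom] = merged
        return self

    # ---------------------------------------------------------------- access
    def cn_at(self, chrom: str, pos: int, homolog: str) -> int:
        for s in self.segments[chrom]:
            if s.start <= pos < s.end:
                return s.cn(homolog)
        raise ValueError(f"position {pos} outside {chrom}")

    def min_cn(self, chrom: str, start: int, end: int, homolog: str) -> int:
        vals = [s.cn(homolog) for s in self.segments[chrom] if s.start < end and s.end > start]
        return min(vals)

    def cn_per_bin(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Length-weighted (cnA, cnB) per fixed-width bin (last bin truncated)."""
        edges = self.genome.bin_edges(chrom)
        widths = np.diff(edges).astype(float)
        a = np.zeros(len(widths))
        b = np.zeros(len(widths))
        for s in self.segments[chrom]:
            lo = np.clip(s.start, edges[:-1], edges[1:])
            hi = np.clip(s.end, edges[:-1], edges[1:])
            overlap = np.maximum(hi - lo, 0)
            a += overlap * s.cnA
            b += overlap * s.cnB
        return a / widths, b / widths

    def cn_at_sites(self, chrom: str, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(cnA, cnB) at each position (e.g. het sites)."""
        positions = np.asarray(positions)
        a = np.zeros(len(positions), dtype=np.int64)
        b = np.zeros(len(positions), dtype=np.int64)
        for s in self.segments[chrom]:
            m = (positions >= s.start) & (positions < s.end)
            a[m] = s.cnA
            b[m] = s.cnB
        return a, b

    def breakpoints(self, chrom: str) -> list[int]:
        """Interior segment boundaries (excluding 0 and the chromosome end)."""
        self.simplify()
        return [s.start for s in self.segments[chrom][1:]]

    def ploidy(self) -> float:
        """Length-weighted average total copy number across the genome."""
        tot = wsum = 0.0
        for segs in self.segments.values():
            for s in segs:
                tot += s.length * s.total
                wsum += s.length
        return tot / wsum

    # ------------------------------------------------------------- mutation
    def _split_at(self, chrom: str, pos: int) -> None:
        if pos <= 0 or pos >= self.genome.lengths[chrom]:
            return
        out: list[Segment] = []
        for s in self.segments[chrom]:
            if s.start < pos < s.end:
                out.append(Segment(s.start, pos, s.cnA, s.cnB))
                out.append(Segment(pos, s.end, s.cnA, s.cnB))
            else:
                out.append(s)
        self.segments[chrom] = out

    def add_cn(self, chrom: str, start: int, end: int, homolog: str, delta: int) -> None:
        """Shift copy number of one homolog by ``delta`` on ``[start, end)``."""
        if start >= end:
            raise ValueError("empty interval")
        self._split_at(chrom, start)
        self._split_at(chrom, end)
        out: list[Segment] = []
        for s in self.segments[chrom]:
            if s.start >= start and s.end <= end:
                cnA = s.cnA + (delta if homolog == "A" else 0)
                cnB = s.cnB + (delta if homolog == "B" else 0)
                if cnA < 0 or cnB < 0:
                    raise ValueError(
                        f"{chrom}:{s.start}-{s.end} homolog {homolog}: copy number would become negative"
                    )
                out.append(Segment(s.start, s.end, cnA, cnB))
            else:
                out.append(s)
        self.segments[chrom] = out

    def set_cn(self, chrom: str, start: int, end: int, homolog: str, value: int) -> None:
        if value < 0:
            raise ValueError("copy number must be non-negative")
        self._split_at(chrom, start)
        self._split_at(chrom, end)
        out: list[Segment] = []
        for s in self.segments[chrom]:
            if s.start >= start and s.end <= end:
                cnA = value if homolog == "A" else s.cnA
                cnB = value if homolog == "B" else s.cnB
                out.append(Segment(s.start, s.end, cnA, cnB))
            else:
                out.append(s)
        self.segments[chrom] = out

    def iter_segments(self) -> Iterator[tuple[str, Segment]]:
        for chrom, segs in self.segments.items():
            for s in segs:
                yield chrom, s

    def to_dict(self) -> dict:
        return {
            c: [[s.start, s.end, s.cnA, s.cnB] for s in segs]
            for c, segs in self.copy().simplify().segments.items()
        }

    @classmethod
    def from_dict(cls, genome: GenomeModel, d: Mapping[str, Iterable]) -> "ParentalKaryotype":
        segs = {c: [Segment(*row) for row in rows] for c, rows in d.items()}
        return cls(genome, segs)
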