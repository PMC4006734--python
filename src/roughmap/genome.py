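"""Genome coordinate system, SNP panels, and interval arithmetic.

All coordinates are 1-based and inclusive. Crossover positions are modelled
as continuous points in (0, L); SNP positions are integers in [1, L].
The default karyotype mimics *Saccharomyces cerevisiae*: 16 chromosomes,
~12.07 Mb total, with a uniform recombination rate of 3.8e-6 Morgans/bp
(~0.38 cM/kb, typical of the yeast genetic map).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomeMap",
    "SnpPanel",
    "Interval",
    "build_default_genome",
    "make_snp_panel",
    "minimal_bounded_interval",
    "DEFAULT_RECOMB_RATE",
]

#: Uniform recombination rate, Morgans per bp (~0.38 cM/kb).
DEFAULT_RECOMB_RATE = 3.8e-6

# S. cerevisiae-like chromosome lengths (bp), chromosomes I..XVI.
_YEAST_CHROM_LENGTHS = {
    "chrI": 230_218,
    "chrII": 813_184,
    "chrIII": 316_620,
    "chrIV": 1_531_933,
    "chrV": 576_874,
    "chrVI": 270_161,
    "chrVII": 1_090_940,
    "chrVIII": 562_643,
    "chrIX": 439_888,
    "chrX": 745_751,
    "chrXI": 666_816,
    "chrXII": 1_078_177,
    "chrXIII": 924_431,
    "chrXIV": 784_333,
    "chrXV": 1_091_291,
    "chrXVI": 948_066,
}


@dataclass(frozen=True)
class GenomeMap:
    """Ordered chromosomes with lengths and a uniform recombination rate.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs; names unique, lengths > 0.
    recomb_rate
        Morgans per bp, uniform along the genome.
    """

    chromosomes: tuple[tuple[str, int], ...]
    recomb_rate: float = DEFAULT_RECOMB_RATE

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(names) != len(set(names)):
            raise ValueError("chromosome names must be unique")
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be > 0")
        if self.recomb_rate <= 0:
            raise ValueError("recomb_rate must be > 0")

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome: {chrom!r}") from None

    def map_length(self, chrom: str) -> float:
        """Genetic length of a chromosome in Morgans."""
        return self.length_of(chrom) * self.recomb_rate


@dataclass(frozen=True)
class Interval:
    """1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def intersect(self, other: "Interval") -> "Interval | None":
        if not self.overlaps(other):
            return None
        return Interval(self.chrom, max(self.start, other.start), min(self.end, other.end))


@dataclass(frozen=True)
class SnpPanel:
    """Ordered biallelic SNP sites.

    ``chroms``/``pos`` are parallel arrays sorted by chromosome (in genome
    order) then by position, strictly increasing within each chromosome.
    ``allele_a``/``allele_b`` are the parent-A (BY-like) and parent-B
    (3S-like) base labels at each site.
    """

    chroms: np.ndarray  # dtype=object (str)
    pos: np.ndarray  # int64
    allele_a: np.ndarray  # dtype=object (str)
    allele_b: np.ndarray  # dtype=object (str)
    genome: GenomeMap
    _chrom_slices: dict[str, slice] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        known = set(self.genome.names)
        slices: dict[str, slice] = {}
        order = {name: i for i, name in enumerate(self.genome.names)}
        prev_order = -1
        i = 0
        n = len(self.pos)
        while i < n:
            chrom = self.chroms[i]
            if chrom not in known:
                raise ValueError(f"panel site on unknown chromosome {chrom!r}")
            if order[chrom] <= prev_order:
                raise ValueError("panel chromosomes out of genome order")
            prev_order = order[chrom]
            j = i
            while j < n and self.chroms[j] == chrom:
                j += 1
            p = self.pos[i:j]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
            if p[0] < 1 or p[-1] > self.genome.length_of(chrom):
                raise ValueError(f"position outside {chrom} bounds")
            slices[chrom] = slice(i, j)
            i = j
        object.__setattr__(self, "_chrom_slices", slices)

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def sites(self) -> list[tuple[str, int, str, str]]:
        return list(zip(self.chroms, self.pos.tolist(), self.allele_a, self.allele_b))

    def chrom_slice(self, chrom: str) -> slice:
        """Index slice of this chromosome's sites (empty if none)."""
        return self._chrom_slices.get(chrom, slice(0, 0))

    def chrom_positions(self, chrom: str) -> np.ndarray:
        return self.pos[self.chrom_slice(chrom)]

    def site_index(self, chrom: str, pos: int) -> int:
        """Index of the panel site nearest to ``pos`` on ``chrom``."""
        sl = self.chrom_slice(chrom)
        p = self.pos[sl]
        if len(p) == 0:
            raise ValueError(f"no panel sites on {chrom}")
        k = int(np.argmin(np.abs(p - pos)))
        return sl.start + k


def build_default_genome(scale: float = 1.0, seed: int | None = None) -> GenomeMap:
    """Sixteen-chromosome yeast-like genome, optionally scaled down.

    ``scale=1`` gives ~12.07 Mb total; every chromosome length scales
    linearly. Deterministic (``seed`` accepted for interface uniformity).
    """
    if scale <= 0 or scale > 1:
        raise ValueError("scale must be in (0, 1]")
    chroms = tuple(
        (name, max(1, int(round(length * scale))))
        for name, length in _YEAST_CHROM_LENGTHS.items()
    )
    return GenomeMap(chromosomes=chroms)


_BASES = np.array(["A", "C", "G", "T"], dtype=object)


def make_snp_panel(
    genome: GenomeMap,
    n_snps: int,
    seed: int | None = None,
    include: list[tuple[str, int]] | None = None,
) -> SnpPanel:
    """Place ``n_snps`` biallelic sites uniformly at random over the genome.

    Sites are sorted and deduplicated; duplicates are redrawn so exactly
    ``n_snps`` unique positions result. Per-chromosome counts are
    length-proportional in expectation. ``include`` forces sites at the
    given (chrom, pos) coordinates within the ``n_snps`` budget — real
    panels are ascertained from the cross's own polymorphisms and so
    always contain the causal variants themselves.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if n_snps > genome.total_length:
        raise ValueError("n_snps exceeds total genome length")
    rng = np.random.default_rng(seed)
    total = genome.total_length
    offsets = np.cumsum([0] + [length for _, length in genome.chromosomes])
    chrom_offset = {name: offsets[i] for i, name in enumerate(genome.names)}
    forced = np.array(
        sorted(
            {chrom_offset[c] + p - 1 for c, p in (include or [])}
        ),
        dtype=np.int64,
    )
    if len(forced) > n_snps:
        raise ValueError("more forced sites than the panel budget")
    # global 0-based coordinates, redrawn until unique
    coords = np.unique(np.concatenate([forced, rng.integers(0, total, size=n_snps - len(forced))]))
    while len(coords) < n_snps:
        extra = rng.integers(0, total, size=n_snps - len(coords))
        coords = np.unique(np.concatenate([coords, extra]))
    coords.sort()
    chrom_idx = np.searchsorted(offsets, coords, side="right") - 1
    pos = coords - offsets[chrom_idx] + 1
    names = np.array(genome.names, dtype=object)
    chroms = names[chrom_idx]
    a_idx = rng.integers(0, 4, size=n_snps)
    b_idx = (a_idx + rng.integers(1, 4, size=n_snps)) % 4
    return SnpPanel(
        chroms=chroms,
        pos=pos.astype(np.int64),
        allele_a=_BASES[a_idx],
        allele_b=_BASES[b_idx],
        genome=genome,
    )


def minimal_bounded_interval(carrier_intervals: list[Interval]) -> Interval:
    """Intersection of per-carrier intervals around a shared peak.

    Each carrier interval is the maximal region over which that carrier
    holds the enriched allele; the minimal region delimited by
    recombination breakpoints is their intersection.
    """
    if not carrier_intervals:
        raise ValueError("no carrier intervals given")
    chroms = {iv.chrom for iv in carrier_intervals}
    if len(chroms) > 1:
        raise ValueError(f"carrier intervals span multiple chromosomes: {sorted(chroms)}")
    start = max(iv.start for iv in carrier_intervals)
    end = min(iv.end for iv in carrier_intervals)
    if start > end:
        raise ValueError("empty intersection: inconsistent carrier set or wrong peak")
    return Interval(chrom=carrier_intervals[0].chrom, start=start, end=end)
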