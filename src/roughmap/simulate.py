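"""Meiosis, backcross-cohort, and low-coverage read simulation.

The generator emulates haploid recombinant progeny of a BY×3S-like yeast
cross segregating a rough-colony phenotype controlled by a five-locus
epistatic interaction, plus an alternate two-locus complementation of the
END3 allele. Key features modelled:

* Poisson crossovers (no interference), Haldane map-distance behaviour.
* Tetrads with exact 2:2 segregation at every site.
* A spontaneous third allele at IRA2 ('mut', same parental origin as the
  3S allele but functionally distinct) carried by a fraction of F1 spores.
* Phenotype assignment from a disjunction of multi-locus requirement
  clauses with per-clause penetrance.
* Poisson-depth binomial read counts at low coverage, with optional
  aneuploidy/contamination artifacts and pooled control populations with
  selectable-marker distortions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .genome import GenomeMap, SnpPanel

__all__ = [
    "OriginTrack",
    "SegregantGenotype",
    "PhenotypeClause",
    "PhenotypeModel",
    "CrossDesign",
    "ReadCountMatrix",
    "Cohort",
    "ArtifactSpec",
    "founder",
    "default_causal_loci",
    "default_phenotype_model",
    "rough_founder_segregant",
    "simulate_meiosis",
    "simulate_tetrad",
    "assign_phenotype",
    "simulate_backcross_cohort",
    "simulate_reads",
    "inject_artifacts",
    "simulate_pooled_control",
]

ORIGIN_A = 0  # BY-like parent
ORIGIN_B = 1  # 3S-like parent

# Named causal loci as fractions of their chromosome's length. The gene
# positions roughly follow their real genomic locations; 'VII' and 'XV2'
# are the chromosome VII and second chromosome XV loci that jointly
# complement the 3S allele of END3.
_CAUSAL_LOCUS_FRACTIONS: dict[str, tuple[str, float]] = {
    "TRR1": ("chrIV", 0.424),
    "FLO8": ("chrV", 0.650),
    "MSS11": ("chrXIII", 0.636),
    "END3": ("chrXIV", 0.740),
    "IRA2": ("chrXV", 0.160),
    "VII": ("chrVII", 0.370),
    "XV2": ("chrXV", 0.917),
}


def default_causal_loci(genome: GenomeMap) -> dict[str, tuple[str, int]]:
    """Map causal locus name -> (chrom, position) on this genome."""
    out = {}
    for name, (chrom, frac) in _CAUSAL_LOCUS_FRACTIONS.items():
        L = genome.length_of(chrom)
        out[name] = (chrom, max(1, int(round(frac * L))))
    return out


def sga_marker_loci(genome: GenomeMap) -> list[tuple[str, int, int]]:
    """The MATa-selection marker: a BY-engineered cassette at the CAN1
    position on chromosome V. Every plated segregant carries the
    BY-origin allele there, which distorts local allele frequencies in
    mapping and control populations alike."""
    frac = 31_694 / 576_874
    pos = max(1, int(round(frac * genome.length_of("chrV"))))
    return [("chrV", pos, ORIGIN_A)]


@dataclass(frozen=True)
class OriginTrack:
    """Parental origin along one chromosome as a breakpoint list.

    Origin at position ``x`` is ``start`` flipped once per breakpoint
    ``b <= x`` (breakpoints are continuous crossover positions, so ties
    with integer SNP positions have measure zero).
    """

    start: int  # ORIGIN_A or ORIGIN_B
    breakpoints: np.ndarray  # sorted float positions in (0, L)

    def origin_at(self, pos) -> np.ndarray | int:
        k = np.searchsorted(self.breakpoints, pos, side="right")
        return self.start ^ (k & 1)


@dataclass
class SegregantGenotype:
    """A haploid recombinant genotype.

    ``origin`` maps chromosome name -> :class:`OriginTrack`; it may be
    ``None`` for genotypes sampled on causal loci only. ``causal_alleles``
    maps locus name -> 'A' | 'B' | 'mut', consistent with the origin track
    at the locus position ('mut' shares parental origin with 'B').
    """

    id: str
    causal_alleles: dict[str, str]
    origin: dict[str, OriginTrack] | None = None
    generation: str = ""

    def origin_matrix_row(self, panel: SnpPanel) -> np.ndarray:
        """Per-panel-site parental origin (0=A, 1=B)."""
        if self.origin is None:
            raise ValueError(f"segregant {self.id} has no full origin track")
        out = np.empty(len(panel), dtype=np.int8)
        for chrom in panel.genome.names:
            sl = panel.chrom_slice(chrom)
            if sl.stop > sl.start:
                out[sl] = self.origin[chrom].origin_at(panel.pos[sl])
        return out


def founder(which: str, genome: GenomeMap, causal_loci: dict | None = None) -> SegregantGenotype:
    """A non-recombinant founder haploid: 'BY' (all A) or '3S' (all B)."""
    if which not in ("BY", "3S"):
        raise ValueError("founder must be 'BY' or '3S'")
    org = ORIGIN_A if which == "BY" else ORIGIN_B
    allele = "A" if which == "BY" else "B"
    loci = causal_loci if causal_loci is not None else default_causal_loci(genome)
    tracks = {
        name: OriginTrack(start=org, breakpoints=np.empty(0)) for name in genome.names
    }
    return SegregantGenotype(
        id=which,
        causal_alleles={k: allele for k in loci},
        origin=tracks,
        generation="P0",
    )


# ---------------------------------------------------------------------------
# Phenotype model


@dataclass(frozen=True)
class PhenotypeClause:
    """One multi-locus requirement with a penetrance."""

    requirements: dict[str, str]  # locus -> required allele ('A'|'B'|'mut')
    penetrance: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError("penetrance must be in [0, 1]")

    def satisfied_by(self, alleles: dict[str, str]) -> bool:
        for locus, req in self.requirements.items():
            if locus not in alleles:
                raise KeyError(f"genotype lacks an allele at model locus {locus!r}")
            if alleles[locus] != req:
                return False
        return True


@dataclass(frozen=True)
class PhenotypeModel:
    """Disjunction of requirement clauses (evaluated in order; at most one
    applies because the clauses disagree at END3), plus an optional bumpy
    sub-phenotype rule."""

    clauses: tuple[PhenotypeClause, ...]
    bumpy_rule: PhenotypeClause | None = None

    def __post_init__(self) -> None:
        if not self.clauses:
            raise ValueError("clause list must be non-empty")

    @property
    def loci(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.clauses:
            for locus in c.requirements:
                seen.setdefault(locus)
        if self.bumpy_rule is not None:
            for locus in self.bumpy_rule.requirements:
                seen.setdefault(locus)
        return list(seen)


def default_phenotype_model(pi_alt: float = 0.2, include_bumpy: bool = False) -> PhenotypeModel:
    """The cross's rough-morphology architecture.

    Clause 1 (fully penetrant): END3^BY, FLO8^3S, IRA2 'mut', MSS11^BY,
    TRR1^3S. Clause 2: the same background with END3^3S complemented by BY
    alleles at the chromosome VII and second chromosome XV loci, with
    penetrance ``pi_alt`` (default 0.2, calibrated so roughly 4 of 88
    rough segregants in a 3S backcross carry END3^3S). The optional bumpy
    rule swaps TRR1 to the BY allele.
    """
    clauses = (
        PhenotypeClause(
            {"END3": "A", "FLO8": "B", "IRA2": "mut", "MSS11": "A", "TRR1": "B"},
            penetrance=1.0,
        ),
        PhenotypeClause(
            {
                "END3": "B",
                "VII": "A",
                "XV2": "A",
                "FLO8": "B",
                "IRA2": "mut",
                "MSS11": "A",
                "TRR1": "B",
            },
            penetrance=pi_alt,
        ),
    )
    bumpy = (
        PhenotypeClause(
            {"END3": "A", "FLO8": "B", "IRA2": "mut", "MSS11": "A", "TRR1": "A"},
            penetrance=1.0,
        )
        if include_bumpy
        else None
    )
    return PhenotypeModel(clauses=clauses, bumpy_rule=bumpy)


def rough_founder_segregant(
    genome: GenomeMap, causal_loci: dict | None = None, seed: int = 20_140_501
) -> SegregantGenotype:
    """The canonical rough segregant used for backcrossing.

    A genuine F1 meiotic product of the two founders (so roughly half of
    its genome derives from each parent), rejection-sampled under a fixed
    internal seed until it carries the rough-specifying allele set
    END3^BY FLO8^3S IRA2^3S MSS11^BY TRR1^3S plus BY alleles at the VII
    and XV2 complementing loci; the spontaneous IRA2 frameshift ('mut')
    is then applied to its 3S-origin IRA2 allele.
    """
    loci = causal_loci if causal_loci is not None else default_causal_loci(genome)
    required = {"END3": "A", "FLO8": "B", "IRA2": "B", "MSS11": "A",
                "TRR1": "B", "VII": "A", "XV2": "A"}
    rng = np.random.default_rng(seed)
    by = founder("BY", genome, loci)
    s3 = founder("3S", genome, loci)
    markers = sga_marker_loci(genome)
    for _ in range(100_000):
        g = simulate_meiosis(by, s3, genome, rng, loci, _id="rough-founder")
        if not all(g.causal_alleles.get(k) == v for k, v in required.items()):
            continue
        if all(int(g.origin[c].origin_at(p)) == sel for c, p, sel in markers):
            g.causal_alleles["IRA2"] = "mut"
            g.generation = "F1"
            return g
    raise RuntimeError("could not sample a rough F1 segregant")  # pragma: no cover


# ---------------------------------------------------------------------------
# Meiosis


def _recombine_chrom(
    t1: OriginTrack, t2: OriginTrack, L: int, rate: float, rng: np.random.Generator
) -> tuple[OriginTrack, np.ndarray, int]:
    """One meiotic product for one chromosome of the diploid t1/t2.

    Returns the offspring origin track, the crossover positions, and which
    parent (0/1) transmits the leftmost segment.
    """
    k = rng.poisson(rate * L)
    xpos = np.sort(rng.uniform(0.0, L, size=k)) if k else np.empty(0)
    first = int(rng.integers(2))
    bounds = np.concatenate([[0.0], xpos, [float(L)]])
    cur_origin = -1
    out_bps: list[float] = []
    for i in range(len(bounds) - 1):
        lo, hi = bounds[i], bounds[i + 1]
        t = t1 if (first + i) % 2 == 0 else t2
        o_lo = int(t.origin_at(lo))
        if cur_origin == -1:
            cur_origin = o_lo
        elif o_lo != cur_origin:
            out_bps.append(lo)
            cur_origin = o_lo
        seg = t.breakpoints[(t.breakpoints > lo) & (t.breakpoints <= hi)]
        for b in seg:
            out_bps.append(float(b))
            cur_origin ^= 1
    start = int(t1.origin_at(0.0)) if first == 0 else int(t2.origin_at(0.0))
    return OriginTrack(start=start, breakpoints=np.asarray(out_bps)), xpos, first


def _transmitting_parent(xpos: np.ndarray, first: int, pos: float) -> int:
    """Which parent (0/1) transmits position ``pos`` given crossovers."""
    k = int(np.searchsorted(xpos, pos, side="right"))
    return (first + k) % 2


def simulate_meiosis(
    parent1: SegregantGenotype,
    parent2: SegregantGenotype,
    genome: GenomeMap,
    seed=None,
    causal_loci: dict | None = None,
    _id: str = "spore",
) -> SegregantGenotype:
    """One haploid meiotic product of the parent1 × parent2 diploid.

    Crossover counts are Poisson(map length in Morgans) per chromosome with
    uniform positions and no interference; each causal allele (including
    'mut') is transmitted with its chromosomal position.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if parent1.origin is None or parent2.origin is None:
        raise ValueError("parents must carry full origin tracks")
    if set(parent1.origin) != set(genome.names) or set(parent2.origin) != set(genome.names):
        raise ValueError("parent chromosomes do not match the genome")
    loci = causal_loci if causal_loci is not None else default_causal_loci(genome)
    tracks: dict[str, OriginTrack] = {}
    meta: dict[str, tuple[np.ndarray, int]] = {}
    for chrom in genome.names:
        L = genome.length_of(chrom)
        track, xpos, first = _recombine_chrom(
            parent1.origin[chrom], parent2.origin[chrom], L, genome.recomb_rate, rng
        )
        tracks[chrom] = track
        meta[chrom] = (xpos, first)
    alleles: dict[str, str] = {}
    for name, (chrom, pos) in loci.items():
        xpos, first = meta[chrom]
        src = parent1 if _transmitting_parent(xpos, first, pos) == 0 else parent2
        alleles[name] = src.causal_alleles[name]
    return SegregantGenotype(id=_id, causal_alleles=alleles, origin=tracks)


def simulate_tetrad(
    parent1: SegregantGenotype,
    parent2: SegregantGenotype,
    genome: GenomeMap,
    seed=None,
    causal_loci: dict | None = None,
    id_prefix: str = "tetrad",
) -> list[SegregantGenotype]:
    """Four spores of one meiosis with exact 2:2 segregation.

    Built as two independent meiotic products plus their complements
    (four-strand chromatid sampling is not modelled; downstream statistics
    depend only on marginal recombination fractions and 2:2 segregation).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    loci = causal_loci if causal_loci is not None else default_causal_loci(genome)
    spores: list[SegregantGenotype] = []
    for rep in range(2):
        tracks1: dict[str, OriginTrack] = {}
        tracks2: dict[str, OriginTrack] = {}
        meta: dict[str, tuple[np.ndarray, int]] = {}
        for chrom in genome.names:
            L = genome.length_of(chrom)
            t, xpos, first = _recombine_chrom(
                parent1.origin[chrom], parent2.origin[chrom], L, genome.recomb_rate, rng
            )
            tracks1[chrom] = t
            meta[chrom] = (xpos, first)
            # complement: identical crossovers, opposite starting parent
            bounds = np.concatenate([[0.0], xpos, [float(L)]])
            comp_first = 1 - first
            cur = -1
            bps: list[float] = []
            p1t, p2t = parent1.origin[chrom], parent2.origin[chrom]
            for i in range(len(bounds) - 1):
                lo, hi = bounds[i], bounds[i + 1]
                tt = p1t if (comp_first + i) % 2 == 0 else p2t
                o_lo = int(tt.origin_at(lo))
                if cur == -1:
                    cur = o_lo
                elif o_lo != cur:
                    bps.append(lo)
                    cur = o_lo
                for b in tt.breakpoints[(tt.breakpoints > lo) & (tt.breakpoints <= hi)]:
                    bps.append(float(b))
                    cur ^= 1
            start = int(p1t.origin_at(0.0)) if comp_first == 0 else int(p2t.origin_at(0.0))
            tracks2[chrom] = OriginTrack(start=start, breakpoints=np.asarray(bps))
        for which, tracks in ((0, tracks1), (1, tracks2)):
            alleles = {}
            for name, (chrom, pos) in loci.items():
                xpos, first = meta[chrom]
                f = first if which == 0 else 1 - first
                src = parent1 if _transmitting_parent(xpos, f, pos) == 0 else parent2
                alleles[name] = src.causal_alleles[name]
            spores.append(
                SegregantGenotype(
                    id=f"{id_prefix}-{2 * rep + which + 1}",
                    causal_alleles=alleles,
                    origin=tracks,
                )
            )
    return spores


# ---------------------------------------------------------------------------
# Phenotype assignment


def assign_phenotype(
    g: SegregantGenotype, model: PhenotypeModel, rng: np.random.Generator
) -> str:
    """'rough' with the penetrance of the first satisfied clause; 'bumpy'
    if the bumpy rule matches and no rough clause fired; else 'smooth'."""
    for clause in model.clauses:
        if clause.satisfied_by(g.causal_alleles):
            if rng.random() < clause.penetrance:
                return "rough"
            break
    if model.bumpy_rule is not None and model.bumpy_rule.satisfied_by(g.causal_alleles):
        return "bumpy"
    return "smooth"


# ---------------------------------------------------------------------------
# Cohorts


@dataclass(frozen=True)
class CrossDesign:
    """A (possibly recurrent) backcross with optional phenotypic selection.

    ``mut_carrier_fraction`` models the spontaneous IRA2 allele arising
    during outgrowth of the original F1 diploid: each spore inheriting the
    B-origin IRA2 allele carries 'mut' with this probability. It is 0 for
    crosses whose parents already carry explicit 'mut'/'B' alleles.
    """

    parent1: SegregantGenotype
    parent2: SegregantGenotype
    n_offspring: int
    selection: str = "none"  # 'none' | 'rough' | 'smooth' | 'bumpy'
    coverage: float = 4.0
    mut_carrier_fraction: float = 0.0
    rounds: int = 1

    def __post_init__(self) -> None:
        if self.n_offspring < 1:
            raise ValueError("n_offspring must be >= 1")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if not 0.0 <= self.mut_carrier_fraction <= 1.0:
            raise ValueError("mut_carrier_fraction must be in [0, 1]")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")


@dataclass
class Cohort:
    """Simulated segregants with phenotypes and provenance."""

    genotypes: list[SegregantGenotype]
    phenotypes: list[str]
    n_attempted: int
    design: CrossDesign
    causal_loci: dict[str, tuple[str, int]]

    def __len__(self) -> int:
        return len(self.genotypes)

    @property
    def raw_phenotype_frequency(self) -> float:
        """Selected-class frequency among all meioses attempted."""
        if self.design.selection == "none":
            raise ValueError("raw frequency only defined for selected cohorts")
        return len(self.genotypes) / self.n_attempted

    def phenotype_frequency(self, label: str) -> float:
        return sum(p == label for p in self.phenotypes) / len(self.phenotypes)


def _apply_f1_mut(g: SegregantGenotype, f: float, rng: np.random.Generator) -> None:
    if f > 0 and g.causal_alleles.get("IRA2") == "B" and rng.random() < f:
        g.causal_alleles["IRA2"] = "mut"


def _selection_probability(design: CrossDesign, model: PhenotypeModel, genome: GenomeMap) -> float:
    from .evaluate import expected_phenotype_frequency  # local: avoids cycle

    return expected_phenotype_frequency(design, model, genome, phenotype=design.selection)


def simulate_backcross_cohort(
    design: CrossDesign,
    model: PhenotypeModel,
    genome: GenomeMap,
    panel: SnpPanel | None = None,
    seed=None,
    track: str = "full",
    causal_loci: dict | None = None,
    marker_loci: list[tuple[str, int, int]] | None = None,
) -> Cohort:
    """Simulate a cohort of backcross progeny under the phenotype model.

    With ``selection != 'none'`` meioses are drawn until ``n_offspring``
    individuals of the selected class are collected; the total number of
    meioses attempted is recorded so the raw phenotype frequency stays
    recoverable. ``rounds > 1`` performs recurrent backcrossing: each
    offspring is the end of a chain of ``rounds`` selected backcrosses to
    ``parent2``.

    ``track='causal'`` samples parental transmission at the model loci
    only (exact under the Poisson-crossover model, using the Haldane
    recombination fraction between same-chromosome loci); it supports
    large unselected cohorts without materialising whole genomes.

    ``marker_loci`` (full track only) are selectable markers as
    (chrom, pos, selected origin): offspring not carrying the selected
    origin at every marker are discarded before phenotype selection and
    do not count toward the attempted-meiosis total, mimicking plating
    on selective medium.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    loci = causal_loci if causal_loci is not None else default_causal_loci(genome)
    if design.selection != "none":
        p_sel = _selection_probability(design, model, genome)
        if p_sel <= 0.0:
            raise ValueError(
                f"selected class {design.selection!r} has probability 0 under the model"
            )
    if track == "causal":
        if design.rounds != 1:
            raise ValueError("causal-only track does not support recurrent designs")
        if marker_loci:
            raise ValueError("marker selection requires full origin tracks")
        return _simulate_cohort_causal(design, model, genome, loci, rng)
    if track != "full":
        raise ValueError("track must be 'full' or 'causal'")
    markers = marker_loci or []

    genotypes: list[SegregantGenotype] = []
    phenotypes: list[str] = []
    attempted = 0
    i = 0
    while len(genotypes) < design.n_offspring:
        if design.rounds == 1:
            g = simulate_meiosis(
                design.parent1, design.parent2, genome, rng, loci, _id=f"seg{i:05d}"
            )
            if markers and not all(
                int(g.origin[chrom].origin_at(pos)) == sel for chrom, pos, sel in markers
            ):
                continue
            _apply_f1_mut(g, design.mut_carrier_fraction, rng)
            attempted += 1
            ph = assign_phenotype(g, model, rng)
        else:
            # recurrent backcrossing with per-round selection
            current = design.parent1
            for r in range(design.rounds):
                while True:
                    cand = simulate_meiosis(
                        current, design.parent2, genome, rng, loci, _id=f"seg{i:05d}r{r}"
                    )
                    _apply_f1_mut(cand, design.mut_carrier_fraction, rng)
                    attempted += 1
                    ph = assign_phenotype(cand, model, rng)
                    if design.selection == "none" or ph == design.selection:
                        break
                current = cand
            g = current
            g.generation = f"BC{design.rounds}"
        if design.selection == "none" or ph == design.selection:
            genotypes.append(g)
            phenotypes.append(ph)
        i += 1
    return Cohort(genotypes, phenotypes, attempted, design, loci)


def _haldane_r(d_bp: float, rate: float) -> float:
    return 0.5 * (1.0 - np.exp(-2.0 * rate * d_bp))


def _simulate_cohort_causal(
    design: CrossDesign,
    model: PhenotypeModel,
    genome: GenomeMap,
    loci: dict[str, tuple[str, int]],
    rng: np.random.Generator,
) -> Cohort:
    """Vectorised transmission sampling at the model loci only."""
    names = [n for n in loci if n in model.loci or True]  # all named loci
    by_chrom: dict[str, list[str]] = {}
    for n in names:
        by_chrom.setdefault(loci[n][0], []).append(n)
    for group in by_chrom.values():
        group.sort(key=lambda n: loci[n][1])
    n = design.n_offspring
    if design.selection != "none":
        # oversample in blocks until enough selected individuals
        p_sel = _selection_probability(design, model, genome)
        block = int(np.ceil(n / max(p_sel, 1e-12) * 1.3)) + 100
    else:
        block = n
    collected_alleles: list[dict[str, str]] = []
    collected_ph: list[str] = []
    attempted = 0
    while len(collected_alleles) < n:
        src = np.empty((block, len(names)), dtype=np.int8)  # 0=parent1, 1=parent2
        col = {nm: j for j, nm in enumerate(names)}
        for chrom, group in by_chrom.items():
            state = rng.integers(0, 2, size=block).astype(np.int8)
            src[:, col[group[0]]] = state
            for a, b in zip(group, group[1:]):
                r = _haldane_r(loci[b][1] - loci[a][1], genome.recomb_rate)
                flip = rng.random(block) < r
                state = np.where(flip, 1 - state, state).astype(np.int8)
                src[:, col[b]] = state
        p1a = design.parent1.causal_alleles
        p2a = design.parent2.causal_alleles
        mut_draw = rng.random(block)
        pheno_draw = rng.random(block)
        for irow in range(block):
            alleles = {
                nm: (p1a[nm] if src[irow, col[nm]] == 0 else p2a[nm]) for nm in names
            }
            if (
                design.mut_carrier_fraction > 0
                and alleles.get("IRA2") == "B"
                and mut_draw[irow] < design.mut_carrier_fraction
            ):
                alleles["IRA2"] = "mut"
            ph = "smooth"
            fired = False
            for clause in model.clauses:
                if clause.satisfied_by(alleles):
                    fired = True
                    if pheno_draw[irow] < clause.penetrance:
                        ph = "rough"
                    break
            if ph != "rough" and model.bumpy_rule is not None and model.bumpy_rule.satisfied_by(alleles):
                ph = "bumpy"
            attempted += 1
            if design.selection == "none" or ph == design.selection:
                collected_alleles.append(alleles)
                collected_ph.append(ph)
                if len(collected_alleles) >= n:
                    break
        if design.selection == "none":
            break
    genotypes = [
        SegregantGenotype(id=f"seg{i:06d}", causal_alleles=a, origin=None)
        for i, a in enumerate(collected_alleles[:n])
    ]
    return Cohort(genotypes, collected_ph[:n], attempted, design, loci)


# ---------------------------------------------------------------------------
# Reads


@dataclass
class ReadCountMatrix:
    """Per segregant × SNP allele depths from low-coverage sequencing."""

    depth_a: np.ndarray  # (n_seg, n_snp) int32
    depth_b: np.ndarray
    ids: list[str]
    mean_depth: float
    error_rate: float

    def __post_init__(self) -> None:
        if self.depth_a.shape != self.depth_b.shape:
            raise ValueError("depth matrices must have matching shapes")
        if (self.depth_a < 0).any() or (self.depth_b < 0).any():
            raise ValueError("read counts must be non-negative")

    @property
    def n_segregants(self) -> int:
        return self.depth_a.shape[0]

    @property
    def n_snps(self) -> int:
        return self.depth_a.shape[1]

    def total_depth(self) -> np.ndarray:
        return self.depth_a + self.depth_b


def _reads_for_origin(
    origin: np.ndarray, lam: float, eps: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    depth = rng.poisson(lam, size=origin.shape)
    correct = rng.binomial(depth, 1.0 - eps)
    wrong = depth - correct
    da = np.where(origin == ORIGIN_A, correct, wrong)
    db = depth - da
    return da.astype(np.int32), db.astype(np.int32)


def simulate_reads(
    cohort: Cohort,
    panel: SnpPanel,
    lam: float = 4.0,
    eps: float = 0.005,
    seed=None,
) -> ReadCountMatrix:
    """Poisson-depth, binomial-error allele counts over the SNP panel.

    Per site, total depth ~ Poisson(``lam``); reads supporting the true
    parental origin ~ Binomial(depth, 1-``eps``).
    """
    if lam <= 0:
        raise ValueError("mean depth must be > 0")
    if not 0.0 <= eps < 0.5:
        raise ValueError("error rate must be in [0, 0.5)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_seg, n_snp = len(cohort), len(panel)
    da = np.empty((n_seg, n_snp), dtype=np.int32)
    db = np.empty((n_seg, n_snp), dtype=np.int32)
    for i, g in enumerate(cohort.genotypes):
        origin = g.origin_matrix_row(panel)
        da[i], db[i] = _reads_for_origin(origin, lam, eps, rng)
    return ReadCountMatrix(
        depth_a=da,
        depth_b=db,
        ids=[g.id for g in cohort.genotypes],
        mean_depth=lam,
        error_rate=eps,
    )


@dataclass(frozen=True)
class ArtifactSpec:
    """QC-failure artifacts to inject into a read-count matrix.

    ``aneuploidies``: (segregant index, chromosome, copy factor) — the
    chromosome's Poisson depth is scaled by the copy factor.
    ``contaminations``: (segregant index, mix fraction, contaminant
    genotype or None) — the sample's reads are thinned to (1-m) and topped
    up with reads drawn from the contaminant at fraction m; ``None`` uses
    an opposite-origin contaminant.
    """

    aneuploidies: tuple[tuple[int, str, float], ...] = ()
    contaminations: tuple[tuple[int, float, SegregantGenotype | None], ...] = ()


def inject_artifacts(
    matrix: ReadCountMatrix,
    spec: ArtifactSpec,
    cohort: Cohort,
    panel: SnpPanel,
    seed=None,
) -> ReadCountMatrix:
    """Return a copy of ``matrix`` with aneuploidy/contamination injected."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    da = matrix.depth_a.copy()
    db = matrix.depth_b.copy()
    lam, eps = matrix.mean_depth, matrix.error_rate
    for idx, chrom, factor in spec.aneuploidies:
        if factor <= 0:
            raise ValueError("copy factor must be > 0")
        if not 0 <= idx < matrix.n_segregants:
            raise IndexError(f"no segregant at index {idx}")
        sl = panel.chrom_slice(chrom)
        origin = cohort.genotypes[idx].origin_matrix_row(panel)[sl]
        if factor >= 1.0:
            xa, xb = _reads_for_origin(origin, lam * (factor - 1.0), eps, rng)
            da[idx, sl] += xa
            db[idx, sl] += xb
        else:
            da[idx, sl] = rng.binomial(da[idx, sl], factor)
            db[idx, sl] = rng.binomial(db[idx, sl], factor)
    for idx, frac, contaminant in spec.contaminations:
        if not 0.0 <= frac <= 1.0:
            raise ValueError("mix fraction must be in [0, 1]")
        if not 0 <= idx < matrix.n_segregants:
            raise IndexError(f"no segregant at index {idx}")
        if frac == 0.0:
            continue
        own = cohort.genotypes[idx].origin_matrix_row(panel)
        other = (
            contaminant.origin_matrix_row(panel) if contaminant is not None else 1 - own
        )
        da[idx] = rng.binomial(da[idx], 1.0 - frac)
        db[idx] = rng.binomial(db[idx], 1.0 - frac)
        xa, xb = _reads_for_origin(other, lam * frac, eps, rng)
        da[idx] += xa
        db[idx] += xb
    return replace(matrix, depth_a=da, depth_b=db)


# ---------------------------------------------------------------------------
# Pooled controls


def simulate_pooled_control(
    design: CrossDesign,
    genome: GenomeMap,
    panel: SnpPanel,
    lam_pool: float = 200.0,
    seed=None,
    marker_loci: list[tuple[str, int, int]] | None = None,
    n_pool: int = 2000,
    causal_loci: dict | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled sequencing of an unselected control population.

    ``marker_loci`` are selectable markers as (chrom, pos, selected
    origin 0/1): only offspring carrying the selected origin at every
    marker contribute to the pool, distorting local allele frequencies the
    way MATa-selection markers do. Returns per-site (count of B-origin
    reads, total depth) with depth ~ Poisson(``lam_pool``).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    loci = causal_loci if causal_loci is not None else default_causal_loci(genome)
    markers = marker_loci or []
    rows = []
    kept = 0
    while kept < n_pool:
        g = simulate_meiosis(design.parent1, design.parent2, genome, rng, loci)
        ok = all(
            int(g.origin[chrom].origin_at(pos)) == sel for chrom, pos, sel in markers
        )
        if not ok:
            continue
        rows.append(g.origin_matrix_row(panel))
        kept += 1
    origin = np.asarray(rows)
    freq_b = origin.mean(axis=0)
    depth = rng.poisson(lam_pool, size=len(panel))
    count_b = rng.binomial(depth, freq_b)
    return count_b.astype(np.int64), depth.astype(np.int64)
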