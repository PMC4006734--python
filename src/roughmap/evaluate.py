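"""Exact expectation engine and concordance/recovery reporting.

``expected_phenotype_frequency`` enumerates the genotype distribution of a
cross exactly: loci fixed between the two parents contribute no factor;
segregating loci transmit each parental allele with probability 1/2, with
same-chromosome model loci handled jointly through the Haldane
recombination fraction between them. Clause penetrances then weight each
genotype's phenotype probability.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .genome import GenomeMap, Interval
from .simulate import (
    Cohort,
    CrossDesign,
    PhenotypeModel,
    default_causal_loci,
)

__all__ = [
    "expected_phenotype_frequency",
    "concordance_table",
    "locus_recovery_report",
    "GenotypeClassTable",
    "RecoveryReport",
]


def _haldane_r(d_bp: float, rate: float) -> float:
    return 0.5 * (1.0 - np.exp(-2.0 * rate * d_bp))


def _genotype_distribution(
    design: CrossDesign,
    model: PhenotypeModel,
    genome: GenomeMap,
    causal_loci: dict[str, tuple[str, int]],
) -> list[tuple[dict[str, str], float]]:
    """All offspring genotypes over the model loci with probabilities."""
    loci = model.loci
    p1 = design.parent1.causal_alleles
    p2 = design.parent2.causal_alleles
    for locus in loci:
        if locus not in p1 or locus not in p2:
            raise ValueError(f"unknown allele at model locus {locus!r} in a parent")
    fixed = {l: p1[l] for l in loci if p1[l] == p2[l]}
    seg = [l for l in loci if p1[l] != p2[l]]
    by_chrom: dict[str, list[str]] = {}
    for l in seg:
        by_chrom.setdefault(causal_loci[l][0], []).append(l)
    for group in by_chrom.values():
        group.sort(key=lambda l: causal_loci[l][1])

    # per chromosome: enumerate transmission patterns with joint probability
    chrom_tables: list[list[tuple[dict[str, str], float]]] = []
    for chrom, group in by_chrom.items():
        rs = [
            _haldane_r(
                causal_loci[b][1] - causal_loci[a][1], genome.recomb_rate
            )
            for a, b in zip(group, group[1:])
        ]
        table: list[tuple[dict[str, str], float]] = []
        for pattern in product((0, 1), repeat=len(group)):
            prob = 0.5
            for i, r in enumerate(rs):
                prob *= r if pattern[i] != pattern[i + 1] else 1.0 - r
            alleles = {
                l: (p1[l] if side == 0 else p2[l]) for l, side in zip(group, pattern)
            }
            table.append((alleles, prob))
        chrom_tables.append(table)

    out: list[tuple[dict[str, str], float]] = []
    for combo in product(*chrom_tables) if chrom_tables else [()]:
        alleles = dict(fixed)
        prob = 1.0
        for part, p in combo:
            alleles.update(part)
            prob *= p
        out.append((alleles, prob))

    # the spontaneous IRA2 allele arising at F1 sporulation splits 'B'
    # outcomes into 'mut' (fraction f) vs plain 'B'
    f = design.mut_carrier_fraction
    if f > 0 and "IRA2" in loci:
        split: list[tuple[dict[str, str], float]] = []
        for alleles, prob in out:
            if alleles.get("IRA2") == "B":
                mut = dict(alleles)
                mut["IRA2"] = "mut"
                if f < 1.0:
                    split.append((alleles, prob * (1.0 - f)))
                split.append((mut, prob * f))
            else:
                split.append((alleles, prob))
        out = split
    return out


def expected_phenotype_frequency(
    design: CrossDesign,
    model: PhenotypeModel,
    genome: GenomeMap,
    causal_loci: dict[str, tuple[str, int]] | None = None,
    phenotype: str = "rough",
) -> float:
    """Exact probability that an offspring of ``design`` shows ``phenotype``."""
    loci = causal_loci if causal_loci is not None else default_causal_loci(genome)
    dist = _genotype_distribution(design, model, genome, loci)
    p_rough = 0.0
    p_bumpy = 0.0
    for alleles, prob in dist:
        pen = 0.0
        for clause in model.clauses:
            if clause.satisfied_by(alleles):
                pen = clause.penetrance
                break
        p_rough += prob * pen
        if model.bumpy_rule is not None and model.bumpy_rule.satisfied_by(alleles):
            p_bumpy += prob * (1.0 - pen)
    if phenotype == "rough":
        return p_rough
    if phenotype == "bumpy":
        return p_bumpy
    if phenotype == "smooth":
        return 1.0 - p_rough - p_bumpy
    raise ValueError(f"unknown phenotype {phenotype!r}")


@dataclass
class GenotypeClassTable:
    """Cross-tabulation of multi-locus genotypes against phenotypes."""

    table: pd.DataFrame  # index: genotype tuple; columns: phenotype counts
    loci: list[str]
    discordant: pd.DataFrame  # rows flagged as inconsistent with the model
    penetrance: pd.DataFrame  # rough fraction per genotype with exact CI


def concordance_table(
    cohort: Cohort,
    model: PhenotypeModel,
    loci: list[str] | None = None,
    hide_mut: bool = False,
) -> GenotypeClassTable:
    """Genotype-by-phenotype table over the causal loci.

    ``hide_mut=True`` scores IRA2 by parental origin only (the spontaneous
    allele reads as the plain 3S allele), reproducing how genotyping that
    is blind to the mutation creates apparently discordant smooth
    individuals in the fully causal genotype class.
    """
    loci = loci or model.loci
    rows = []
    for g, ph in zip(cohort.genotypes, cohort.phenotypes):
        if ph is None:
            raise ValueError(f"segregant {g.id} has no phenotype label")
        alleles = dict(g.causal_alleles)
        if hide_mut and alleles.get("IRA2") == "mut":
            alleles["IRA2"] = "B"
        rows.append({**{l: alleles[l] for l in loci}, "phenotype": ph})
    if not rows:
        empty = pd.DataFrame()
        return GenotypeClassTable(empty, loci, empty, empty)
    df = pd.DataFrame(rows)
    table = df.groupby(loci)["phenotype"].value_counts().unstack(fill_value=0)

    def _expected_rough(alleles: dict[str, str]) -> float | None:
        for clause in model.clauses:
            reqs = clause.requirements
            if hide_mut:
                # a scorer blind to the spontaneous mutation sees the
                # 3S-origin IRA2 allele as the causal one
                reqs = {k: ("B" if v == "mut" else v) for k, v in reqs.items()}
            try:
                if all(alleles[k] == v for k, v in reqs.items()):
                    return clause.penetrance
            except KeyError:
                return None
        return 0.0

    disc_rows = []
    pen_rows = []
    for key, sub in df.groupby(loci):
        alleles = dict(zip(loci, key if isinstance(key, tuple) else (key,)))
        pen = _expected_rough(alleles)
        n = len(sub)
        k = int((sub["phenotype"] == "rough").sum())
        ci = binomtest(k, n).proportion_ci(confidence_level=0.95)
        pen_rows.append(
            {**alleles, "n": n, "rough": k, "penetrance_hat": k / n,
             "ci_low": ci.low, "ci_high": ci.high}
        )
        if pen == 1.0 and k < n:
            disc_rows.append({**alleles, "n": n, "issue": "smooth despite penetrance-1 genotype"})
        if pen == 0.0 and k > 0:
            disc_rows.append({**alleles, "n": n, "issue": "rough without a satisfied clause"})
    return GenotypeClassTable(
        table=table,
        loci=loci,
        discordant=pd.DataFrame(disc_rows),
        penetrance=pd.DataFrame(pen_rows),
    )


@dataclass
class RecoveryReport:
    precision: float | None
    recall: float
    hits: dict[str, bool]  # truth locus name -> contained in some detected interval
    n_detected: int


def locus_recovery_report(
    detected: list, truth: dict[str, tuple[str, int]]
) -> RecoveryReport:
    """Score detected loci against simulated truth positions.

    A truth locus is hit if any detected interval contains its position;
    a detected interval is a true positive if it contains any truth locus.
    Precision is ``None`` when nothing was detected.
    """
    intervals: list[Interval] = [
        lc.interval if hasattr(lc, "interval") else lc for lc in detected
    ]
    hits = {
        name: any(iv.contains(chrom, pos) for iv in intervals)
        for name, (chrom, pos) in truth.items()
    }
    tp_detected = sum(
        any(iv.contains(c, p) for c, p in truth.values()) for iv in intervals
    )
    precision = tp_detected / len(intervals) if intervals else None
    recall = sum(hits.values()) / len(truth) if truth else 1.0
    return RecoveryReport(
        precision=precision, recall=recall, hits=hits, n_detected=len(intervals)
    )
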