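"""Conditional scans for alternate genetic architectures.

Phenotype-selected segregants are partitioned by their genotype at a
focal locus (END3 in the motivating cross); the minor class is screened
for previously unidentified regions where every member carries the same
parent's allele. Candidates are whittled down with additional genotyped
individuals and confirmed in a second-generation backcross: a region is
causal if its shared allele is fixed among rough progeny but not among
smooth controls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .genome import Interval, SnpPanel
from .hmm import CALL_MISSING, GenotypeCallSet
from .mapping import _merged_runs

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateRegion",
    "CandidateRegionSet",
    "partition_by_focal_genotype",
    "shared_allele_scan",
    "refine_candidates",
    "second_generation_test",
]

STATUS_CANDIDATE = "candidate"
STATUS_REFUTED = "refuted"
STATUS_CONFIRMED = "confirmed"


@dataclass(frozen=True)
class CandidateRegion:
    interval: Interval
    allele_state: int  # hard-call state shared by the defining subset
    support: tuple[str, ...]  # defining segregant ids
    status: str = STATUS_CANDIDATE
    history: tuple[str, ...] = ()


@dataclass
class CandidateRegionSet:
    regions: list[CandidateRegion] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.regions)

    def with_status(self, status: str) -> list[CandidateRegion]:
        return [r for r in self.regions if r.status == status]

    def report(self) -> str:
        lines = []
        for r in self.regions:
            trail = " -> ".join((STATUS_CANDIDATE,) + r.history) or r.status
            lines.append(
                f"{r.interval.chrom}:{r.interval.start}-{r.interval.end} "
                f"state={r.allele_state} n_support={len(r.support)} "
                f"status={r.status} ({trail})"
            )
        return "\n".join(lines)


def partition_by_focal_genotype(
    subset: list[int], calls: GenotypeCallSet, focal: tuple[str, int]
) -> dict[int, list[int]]:
    """Split a cohort subset by hard call at the panel site nearest the
    focal locus; missing-call individuals are excluded."""
    chrom, pos = focal
    idx = calls.panel.site_index(chrom, pos)
    col = calls.hard_calls[:, idx]
    if all(col[i] == CALL_MISSING for i in subset):
        raise ValueError("focal locus is entirely missing in the subset")
    out: dict[int, list[int]] = {}
    for i in subset:
        if col[i] != CALL_MISSING:
            out.setdefault(int(col[i]), []).append(i)
    return out


def _subtract_intervals(
    run: tuple[int, int], pos: np.ndarray, excluded: list[Interval], chrom: str
) -> list[tuple[int, int]]:
    """Remove excluded-interval overlaps from a run of panel site indices."""
    pieces = [run]
    for ex in excluded:
        if ex.chrom != chrom:
            continue
        nxt: list[tuple[int, int]] = []
        for s, e in pieces:
            inside = (pos[s : e + 1] >= ex.start) & (pos[s : e + 1] <= ex.end)
            if not inside.any():
                nxt.append((s, e))
                continue
            hits = np.flatnonzero(inside) + s
            if hits[0] > s:
                nxt.append((s, hits[0] - 1))
            if hits[-1] < e:
                nxt.append((hits[-1] + 1, e))
        pieces = nxt
    return pieces


def shared_allele_scan(
    subset: list[int],
    calls: GenotypeCallSet,
    allele_state: int,
    min_run: int = 5,
    exclude: list[Interval] | None = None,
) -> CandidateRegionSet:
    """Regions where every subset member carries ``allele_state``.

    Maximal runs of >= ``min_run`` panel sites at which all members'
    hard calls equal the state (missing breaks the run); intervals
    overlapping ``exclude`` (previously identified causal loci and
    marker-artifact regions) are subtracted, and remaining pieces must
    still span ``min_run`` sites.
    """
    if not subset:
        raise ValueError("empty subset")
    panel = calls.panel
    hc = calls.hard_calls[subset]
    shared = (hc == allele_state).all(axis=0)
    ids = tuple(calls.ids[i] for i in subset)
    regions: list[CandidateRegion] = []
    for chrom in panel.genome.names:
        sl = panel.chrom_slice(chrom)
        if sl.stop == sl.start:
            continue
        pos = panel.pos[sl]
        for s, e in _merged_runs(shared[sl], min_run):
            for ps, pe in _subtract_intervals((s, e), pos, exclude or [], chrom):
                if pe - ps + 1 < min_run:
                    continue
                regions.append(
                    CandidateRegion(
                        interval=Interval(chrom, int(pos[ps]), int(pos[pe])),
                        allele_state=allele_state,
                        support=ids,
                    )
                )
    return CandidateRegionSet(regions=regions)


def refine_candidates(
    candidates: CandidateRegionSet,
    extra_genotypes: list[dict[int, np.ndarray]],
    panel: SnpPanel,
) -> CandidateRegionSet:
    """Shrink or refute regions using additional same-phenotype individuals
    typed at markers across each region.

    ``extra_genotypes``: one dict per extra individual mapping region
    index -> array of hard-call states at the region's panel sites (in
    panel order). A region is refuted when an extra individual carries a
    different allele at every marker in it; otherwise it shrinks to the
    span of markers the extras still share (the causal site must be
    shared by every individual, so non-shared flanks can be trimmed). An
    extra individual with no genotypes for a region leaves it unchanged
    (with a logged warning). Candidate regions are wide relative to any
    causal position, so single-marker typing would refute true regions
    whenever an extra individual recombined within the region; typing
    multiple markers keeps refinement sound.
    """
    out: list[CandidateRegion] = []
    for j, region in enumerate(candidates.regions):
        status = region.status
        history = region.history
        interval = region.interval
        if status == STATUS_CANDIDATE:
            sl = panel.chrom_slice(interval.chrom)
            pos = panel.pos[sl]
            inside = np.flatnonzero((pos >= interval.start) & (pos <= interval.end))
            keep = np.ones(len(inside), dtype=bool)
            for k, geno in enumerate(extra_genotypes):
                if j not in geno:
                    logger.warning(
                        "extra individual %d lacks genotypes for region %d; left unchanged",
                        k, j,
                    )
                    continue
                states = np.asarray(geno[j])
                if len(states) != len(inside):
                    raise ValueError(
                        f"extra individual {k}: {len(states)} genotypes for "
                        f"{len(inside)} markers in region {j}"
                    )
                keep &= states == region.allele_state
            if not keep.any():
                status = STATUS_REFUTED
                history = history + ("refuted by additional progeny",)
            elif not keep.all():
                shared = np.flatnonzero(keep)
                interval = Interval(
                    interval.chrom,
                    int(pos[inside[shared[0]]]),
                    int(pos[inside[shared[-1]]]),
                )
                history = history + ("narrowed by additional progeny",)
        out.append(
            replace(region, status=status, history=history, interval=interval)
        )
    return CandidateRegionSet(regions=out)


def second_generation_test(
    candidates: CandidateRegionSet,
    rough_subset: list[int],
    smooth_subset: list[int],
    calls: GenotypeCallSet,
) -> CandidateRegionSet:
    """Confirm candidates in a second-generation backcross.

    Progeny are typed at every marker site inside each candidate region.
    A surviving candidate is confirmed iff the shared allele reaches
    frequency exactly 1 among rough individuals at some site where it is
    below 1 among smooth controls; fixed-in-both sites are uninformative.
    Candidate regions are wide relative to the causal position, so any
    single marker can sit tens of kb from the causal site, where
    recombinants among the rough class are near-certain; scanning all
    region markers keeps the fixation rule usable while a neutral site
    still fixes among n rough progeny only with probability 2^-n.
    """
    if not rough_subset:
        raise ValueError("empty rough cohort")
    panel = calls.panel
    out: list[CandidateRegion] = []
    for region in candidates.regions:
        if region.status != STATUS_CANDIDATE:
            out.append(region)
            continue
        sl = panel.chrom_slice(region.interval.chrom)
        pos = panel.pos[sl]
        inside = np.flatnonzero(
            (pos >= region.interval.start) & (pos <= region.interval.end)
        ) + sl.start
        if len(inside) == 0:
            inside = np.array([panel.site_index(
                region.interval.chrom,
                (region.interval.start + region.interval.end) // 2,
            )])

        def _freq(subset: list[int], idx: int) -> float:
            col = calls.hard_calls[subset, idx]
            ok = col != CALL_MISSING
            if ok.sum() == 0:
                return np.nan
            return float((col[ok] == region.allele_state).mean())

        f_rough = np.nan
        f_smooth = 1.0
        for idx in inside:
            fr = _freq(rough_subset, idx)
            fs = _freq(smooth_subset, idx) if smooth_subset else 0.0
            if fr == 1.0 and not fs == 1.0:
                f_rough, f_smooth = fr, fs
                break
            if np.isnan(f_rough) or (not np.isnan(fr) and fr > f_rough):
                f_rough, f_smooth = fr, fs
        if f_rough == 1.0 and not f_smooth == 1.0:
            out.append(
                replace(
                    region,
                    status=STATUS_CONFIRMED,
                    history=region.history + ("confirmed in second-generation backcross",),
                )
            )
        else:
            why = (
                "fixed in smooth controls too"
                if f_rough == 1.0
                else "not fixed among rough progeny"
            )
            out.append(
                replace(
                    region,
                    status=STATUS_REFUTED,
                    history=region.history + (f"refuted: {why}",),
                )
            )
    return CandidateRegionSet(regions=out)
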