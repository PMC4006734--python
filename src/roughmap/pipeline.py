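"""End-to-end pipeline: simulate cohorts, genotype, map, screen, and
confirm the alternate architecture.

Stage seeds are fanned out deterministically from one global seed so any
stage can be re-run in isolation and two identical invocations produce
byte-identical summaries.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from pathlib import Path

import numpy as np

from .conditional import (
    partition_by_focal_genotype,
    refine_candidates,
    second_generation_test,
    shared_allele_scan,
)
from .evaluate import (
    concordance_table,
    expected_phenotype_frequency,
    locus_recovery_report,
)
from .genome import Interval, build_default_genome, make_snp_panel
from .hmm import CALL_A, CALL_B, HmmParams, calls_from_truth, infer_genotypes
from .io import PipelineConfig
from .mapping import (
    allele_frequency_scan,
    delimit_locus,
    detect_loci,
    screen_against_control,
)
from .simulate import (
    Cohort,
    CrossDesign,
    default_causal_loci,
    default_phenotype_model,
    founder,
    rough_founder_segregant,
    sga_marker_loci,
    simulate_backcross_cohort,
    simulate_pooled_control,
    simulate_reads,
    simulate_tetrad,
)

logger = logging.getLogger(__name__)

__all__ = ["child_seed", "run_pipeline", "sga_marker_loci"]


def child_seed(base: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    return (int(base) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)




def _map_backcross(
    cohort, panel, genome, config, backcross_parent, control_counts, seed
):
    reads = simulate_reads(
        cohort, panel, lam=config.coverage, eps=config.error_rate,
        seed=child_seed(seed, f"reads-{backcross_parent}"),
    )
    params = HmmParams(eps=config.error_rate, min_posterior=config.min_posterior)
    calls = infer_genotypes(reads, panel, genome, params)
    passing = calls.passing()
    track = allele_frequency_scan(calls, passing, backcross_parent)
    loci = detect_loci(track, threshold=config.detect_threshold, min_run=config.min_run)
    loci = screen_against_control(
        loci, control_counts, panel,
        threshold=config.control_threshold, window=config.smooth_window,
    )
    delimited = []
    for lc in loci:
        iv = delimit_locus(lc, calls, passing, genome)
        delimited.append(
            {
                "chrom": lc.chrom,
                "peak_pos": lc.peak_pos,
                "peak_frequency": lc.peak_frequency,
                "is_fixed": lc.is_fixed,
                "artifact": lc.artifact,
                "interval": [iv.start, iv.end],
            }
        )
    return reads, calls, track, loci, delimited


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run every stage on the default study design; return the summary.

    When ``out_dir`` is given, stage outputs (panel, genotypes, loci,
    summary JSON) are written there through the package's own writers.
    """
    t0 = time.time()
    seed = config.seed
    genome = build_default_genome(scale=config.genome_scale)
    loci_pos = default_causal_loci(genome)
    # the panel is ascertained from the cross's own polymorphisms, so the
    # causal variants and the engineered marker are themselves sites
    include = list(loci_pos.values()) + [(c, p) for c, p, _ in sga_marker_loci(genome)]
    panel = make_snp_panel(
        genome, config.n_snps, seed=child_seed(seed, "panel"), include=include
    )
    model = default_phenotype_model(pi_alt=config.pi_alt)
    by, s3 = founder("BY", genome), founder("3S", genome)
    rough = rough_founder_segregant(genome)
    markers = sga_marker_loci(genome)

    design_by = CrossDesign(
        parent1=rough, parent2=by, n_offspring=config.n_rough_by,
        selection="rough", coverage=config.coverage,
    )
    design_3s = CrossDesign(
        parent1=rough, parent2=s3, n_offspring=config.n_rough_3s,
        selection="rough", coverage=config.coverage,
    )
    exp_by = expected_phenotype_frequency(design_by, model, genome)
    exp_3s = expected_phenotype_frequency(design_3s, model, genome)
    # the original cross, with the spontaneous IRA2 allele arising in a
    # fraction of F1 spores
    design_f1 = CrossDesign(
        parent1=by, parent2=s3, n_offspring=1,
        mut_carrier_fraction=config.mut_carrier_fraction,
    )
    exp_f1 = expected_phenotype_frequency(design_f1, model, genome)

    logger.info("simulating backcross cohorts")
    coh_by = simulate_backcross_cohort(
        design_by, model, genome, panel, seed=child_seed(seed, "cohort-BY"),
        marker_loci=markers,
    )
    coh_3s = simulate_backcross_cohort(
        design_3s, model, genome, panel, seed=child_seed(seed, "cohort-3S"),
        marker_loci=markers,
    )

    logger.info("simulating pooled controls")
    ctrl_design_by = CrossDesign(parent1=rough, parent2=by, n_offspring=1)
    ctrl_design_3s = CrossDesign(parent1=rough, parent2=s3, n_offspring=1)
    ctrl_by = simulate_pooled_control(
        ctrl_design_by, genome, panel, lam_pool=config.pool_coverage,
        seed=child_seed(seed, "control-BY"), marker_loci=markers, n_pool=config.n_pool,
    )
    ctrl_3s = simulate_pooled_control(
        ctrl_design_3s, genome, panel, lam_pool=config.pool_coverage,
        seed=child_seed(seed, "control-3S"), marker_loci=markers, n_pool=config.n_pool,
    )

    logger.info("genotyping and mapping")
    _, calls_by, track_by, loci_by, delim_by = _map_backcross(
        coh_by, panel, genome, config, "BY", ctrl_by, seed
    )
    _, calls_3s, track_3s, loci_3s, delim_3s = _map_backcross(
        coh_3s, panel, genome, config, "3S", ctrl_3s, seed
    )

    # conditional scan in the 3S backcross, partitioned at END3
    logger.info("conditional mapping at END3")
    passing_3s = calls_3s.passing()
    parts = partition_by_focal_genotype(passing_3s, calls_3s, loci_pos["END3"])
    # confirm minor-class membership by targeted typing at the gene itself:
    # panel spacing leaves ~2 kb to the nearest SNP, so occasional
    # recombinants between the gene and that site would otherwise poison
    # the all-members-share rule
    end3_chrom, end3_pos = loci_pos["END3"]
    minor = [
        i
        for i in parts.get(CALL_B, [])
        if coh_3s.genotypes[i].causal_alleles["END3"] == "B"
    ]
    conditional_summary: dict = {"minor_class_size": len(minor)}
    confirmed_chroms: list[str] = []
    if minor:
        # exclude known causal loci and marker artifacts with a 50 kb pad:
        # the detected >=95% run understates the neighbourhood linked to a
        # locus that is fixed among rough progeny
        pad = int(round(50_000 * config.genome_scale))
        exclude = [
            Interval(
                lc.chrom,
                max(1, lc.interval.start - pad),
                min(genome.length_of(lc.chrom), lc.interval.end + pad),
            )
            for lc in loci_3s
        ]
        cands = shared_allele_scan(
            minor, calls_3s, CALL_A, min_run=config.min_run, exclude=exclude
        )
        conditional_summary["n_candidate_regions"] = len(cands)
        # additional rough END3-3S segregants, typed at region midpoints
        rng = np.random.default_rng(child_seed(seed, "extra-minor"))
        extras = []
        while len(extras) < 2:
            extra = simulate_backcross_cohort(
                CrossDesign(parent1=rough, parent2=s3, n_offspring=1, selection="rough"),
                model, genome, panel, seed=rng, marker_loci=markers,
            ).genotypes[0]
            if extra.causal_alleles["END3"] == "B":
                extras.append(extra)
        extra_typed = []
        for g in extras:
            typed = {}
            for j, region in enumerate(cands.regions):
                sl = panel.chrom_slice(region.interval.chrom)
                pos = panel.pos[sl]
                inside = pos[(pos >= region.interval.start) & (pos <= region.interval.end)]
                typed[j] = g.origin[region.interval.chrom].origin_at(inside)
            extra_typed.append(typed)
        cands = refine_candidates(cands, extra_typed, panel)
        conditional_summary["n_after_refinement"] = len(cands.with_status("candidate"))

        # second-generation backcross of a minor-class segregant to 3S
        parent = coh_3s.genotypes[minor[0]]
        rough2 = simulate_backcross_cohort(
            CrossDesign(parent1=parent, parent2=s3,
                        n_offspring=config.n_second_gen_rough, selection="rough"),
            model, genome, panel, seed=child_seed(seed, "secondgen-rough"),
            marker_loci=markers,
        )
        smooth2 = simulate_backcross_cohort(
            CrossDesign(parent1=parent, parent2=s3,
                        n_offspring=config.n_second_gen_smooth, selection="smooth"),
            model, genome, panel, seed=child_seed(seed, "secondgen-smooth"),
            marker_loci=markers,
        )
        combined = Cohort(
            genotypes=rough2.genotypes + smooth2.genotypes,
            phenotypes=rough2.phenotypes + smooth2.phenotypes,
            n_attempted=rough2.n_attempted + smooth2.n_attempted,
            design=rough2.design,
            causal_loci=coh_3s.causal_loci,
        )
        # second-generation progeny are typed at region markers (the
        # original study used PCR/Sanger marker typing, not low-coverage
        # sequencing), so candidate confirmation sees exact genotypes
        calls2 = calls_from_truth(combined, panel, genome)
        n_rough2 = len(rough2.genotypes)
        cands = second_generation_test(
            cands,
            rough_subset=list(range(n_rough2)),
            smooth_subset=list(range(n_rough2, len(combined.genotypes))),
            calls=calls2,
        )
        confirmed = cands.with_status("confirmed")
        confirmed_chroms = sorted({r.interval.chrom for r in confirmed})
        conditional_summary["confirmed_regions"] = [
            {"chrom": r.interval.chrom, "start": r.interval.start, "end": r.interval.end}
            for r in confirmed
        ]
        conditional_summary["report"] = cands.report()

    # concordance on dissected tetrads (both directions)
    rng_t = np.random.default_rng(child_seed(seed, "tetrads"))
    tet_genos, tet_phenos = [], []
    from .simulate import assign_phenotype

    for k in range(14):
        for sp in simulate_tetrad(rough, by, genome, rng_t, id_prefix=f"tetBY{k}"):
            tet_genos.append(sp)
            tet_phenos.append(assign_phenotype(sp, model, rng_t))
    tet_cohort = Cohort(tet_genos, tet_phenos, 4 * 14, design_by, loci_pos)
    conc = concordance_table(tet_cohort, model)
    conc_hidden = concordance_table(tet_cohort, model, hide_mut=True)

    truth_by = {k: loci_pos[k] for k in ("TRR1", "FLO8", "IRA2")}
    truth_3s = {k: loci_pos[k] for k in ("MSS11", "END3")}
    causal_by = [lc for lc in loci_by if not lc.artifact]
    causal_3s = [lc for lc in loci_3s if not lc.artifact]
    rec_by = locus_recovery_report(causal_by, truth_by)
    rec_3s = locus_recovery_report(causal_3s, truth_3s)

    summary = {
        "seed": seed,
        "config": {k: getattr(config, k) for k in sorted(config.__dataclass_fields__)},
        "expected_rough_frequency": {
            "BY_backcross": exp_by,
            "3S_backcross": exp_3s,
            "original_cross": exp_f1,
        },
        "raw_rough_frequency": {
            "BY_backcross": coh_by.raw_phenotype_frequency,
            "3S_backcross": coh_3s.raw_phenotype_frequency,
        },
        "loci": {"BY_backcross": delim_by, "3S_backcross": delim_3s},
        "n_causal_loci_detected": len(causal_by) + len(causal_3s),
        "recovery": {
            "BY_backcross": {"recall": rec_by.recall, "precision": rec_by.precision},
            "3S_backcross": {"recall": rec_3s.recall, "precision": rec_3s.precision},
        },
        "conditional": conditional_summary,
        "confirmed_complementing_chromosomes": confirmed_chroms,
        "tetrad_concordance": {
            "n_spores": len(tet_cohort),
            "n_discordant": int(len(conc.discordant)),
            "n_discordant_mut_hidden": int(len(conc_hidden.discordant)),
        },
    }
    logger.info("pipeline finished in %.1f s", time.time() - t0)

    if out_dir is not None:
        from . import io as rio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rio.write_snp_panel(panel, out / "panel.tsv")
        rio.write_genotype_matrix(
            calls_by.hard_calls, calls_by.ids, panel, out / "genotypes_BY.tsv"
        )
        rio.write_genotype_matrix(
            calls_3s.hard_calls, calls_3s.ids, panel, out / "genotypes_3S.tsv"
        )
        rio.write_loci_tsv(loci_by + loci_3s, out / "loci.tsv")
        rio.write_loci_bed(loci_by + loci_3s, out / "loci.bed")
        rio.write_phenotypes(
            [g.id for g in coh_by.genotypes] + [g.id for g in coh_3s.genotypes],
            coh_by.phenotypes + coh_3s.phenotypes,
            out / "phenotypes.tsv",
        )
        summary_path = out / "summary.json"
        summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
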