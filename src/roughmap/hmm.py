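"""Two-state HMM genotype inference from low-coverage allele counts.

Each segregant's chromosome is decoded independently. Hidden states are
the two parental origins {A, B}; emissions are binomial read counts with
a per-read error rate; transitions between adjacent SNPs follow the
Haldane map function r = (1 - exp(-2 c d)) / 2 at the genome's uniform
recombination rate, floored so a true breakpoint between distant SNPs
never becomes numerically impossible. Posterior decoding (forward-
backward) produces per-site posteriors and thresholded hard calls; a
Viterbi path supplies breakpoints for interval delimitation. Per-sample
QC flags contamination/diploidy (excess sites with both alleles well
supported) and aneuploidy (chromosome coverage ratio out of range).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genome import GenomeMap, SnpPanel
from .simulate import ReadCountMatrix

__all__ = [
    "HmmParams",
    "GenotypeCallSet",
    "emission_loglik",
    "transition_prob",
    "infer_genotypes",
    "qc_segregant",
    "chromosome_coverage_profile",
    "CALL_A",
    "CALL_B",
    "CALL_MISSING",
]

CALL_A = 0
CALL_B = 1
CALL_MISSING = -1

FLAG_CONTAMINATED = "contaminated_or_diploid"
FLAG_ANEUPLOID = "aneuploid"
FLAG_NO_DATA = "no_data"


@dataclass(frozen=True)
class HmmParams:
    """Emission/transition parameters and the hard-call threshold."""

    eps: float = 0.005  # per-read error probability
    recomb_rate: float | None = None  # Morgans/bp; None -> genome's rate
    min_posterior: float = 0.95
    switch_floor: float = 1e-6
    # QC thresholds: fraction of depth>=4 sites with minor fraction >= 0.25
    # allowed before a contamination/diploidy flag; coverage-ratio band
    # outside which a chromosome is called aneuploid.
    het_site_fraction: float = 0.05
    coverage_ratio_bounds: tuple[float, float] = (0.5, 1.6)

    def __post_init__(self) -> None:
        if not 0.0 <= self.eps < 0.5:
            raise ValueError("eps must be in [0, 0.5)")
        if not 0.5 < self.min_posterior <= 1.0:
            raise ValueError("min_posterior must be in (0.5, 1]")
        if self.recomb_rate is not None and self.recomb_rate <= 0:
            raise ValueError("recomb_rate must be > 0")


def emission_loglik(depth_a, depth_b, state: int, eps: float):
    """log P(reads | state) under a binomial error model.

    For state A the A-supporting count is Binomial(n, 1-eps); symmetric
    for B. Zero-depth sites are uninformative (log 1 = 0). Vectorised
    over count arrays.
    """
    if not 0.0 <= eps < 0.5:
        raise ValueError("eps must be in [0, 0.5)")
    da = np.asarray(depth_a, dtype=np.float64)
    db = np.asarray(depth_b, dtype=np.float64)
    if (da < 0).any() or (db < 0).any():
        raise ValueError("read counts must be non-negative")
    n = da + db
    k = da if state == CALL_A else db
    # log C(n, k) + k log(1-eps) + (n-k) log(eps); eps=0 handled by masking
    coef = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = coef + k * np.log1p(-eps) + np.where(
            n - k > 0, (n - k) * (np.log(eps) if eps > 0 else -np.inf), 0.0
        )
    return np.where(n == 0, 0.0, ll)


def transition_prob(d, c: float, floor: float = 1e-6):
    """Switch probability between adjacent sites at map distance c*d.

    Haldane map function r = (1 - exp(-2 c d)) / 2, floored at ``floor``.
    """
    d = np.asarray(d, dtype=np.float64)
    if (d < 0).any():
        raise ValueError("distances must be >= 0")
    r = 0.5 * (1.0 - np.exp(-2.0 * c * d))
    return np.clip(r, floor, 0.5)


@dataclass
class GenotypeCallSet:
    """Posteriors, hard calls, Viterbi paths, and QC for a cohort."""

    posterior_a: np.ndarray  # (n_seg, n_snp) P(state = A)
    hard_calls: np.ndarray  # int8: 0=A, 1=B, -1=missing
    viterbi: np.ndarray  # int8 most-likely path
    qc_flags: list[set[str]]  # per segregant; empty set = pass
    coverage: pd.DataFrame  # per segregant x chromosome coverage ratios
    log_likelihood: np.ndarray  # per segregant total data log-likelihood
    ids: list[str]
    panel: SnpPanel = field(repr=False)
    params: HmmParams = field(repr=False)

    @property
    def n_segregants(self) -> int:
        return self.posterior_a.shape[0]

    def passing(self) -> list[int]:
        """Indices of segregants with no QC flag."""
        return [i for i, f in enumerate(self.qc_flags) if not f]

    def breakpoint_runs(self, seg: int, chrom: str) -> np.ndarray:
        """Viterbi state per panel site on one chromosome."""
        return self.viterbi[seg, self.panel.chrom_slice(chrom)]


def _forward_backward(
    em: np.ndarray, r: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scaled forward-backward for a batch of segregants on one chromosome.

    ``em``: (n_seg, n_snp, 2) emission log-likelihoods; ``r``: (n_snp-1,)
    switch probabilities. Returns (posterior over states, log-likelihood
    per segregant, viterbi path).
    """
    n_seg, n_snp, _ = em.shape
    b = np.exp(em - em.max(axis=2, keepdims=True))  # scaled linear emissions
    loglik = em.max(axis=2).sum(axis=1)

    alpha = np.empty_like(b)
    scale = np.empty((n_seg, n_snp))
    a0 = 0.5 * b[:, 0, :]
    scale[:, 0] = a0.sum(axis=1)
    alpha[:, 0, :] = a0 / scale[:, 0, None]
    for t in range(1, n_snp):
        stay, sw = 1.0 - r[t - 1], r[t - 1]
        pred = alpha[:, t - 1, :] @ np.array([[stay, sw], [sw, stay]])
        at = pred * b[:, t, :]
        scale[:, t] = at.sum(axis=1)
        alpha[:, t, :] = at / scale[:, t, None]
    loglik = loglik + np.log(scale).sum(axis=1)

    beta = np.empty_like(b)
    beta[:, -1, :] = 1.0
    for t in range(n_snp - 2, -1, -1):
        stay, sw = 1.0 - r[t], r[t]
        nxt = beta[:, t + 1, :] * b[:, t + 1, :]
        beta[:, t, :] = (nxt @ np.array([[stay, sw], [sw, stay]])) / scale[:, t + 1, None]
    post = alpha * beta
    post /= post.sum(axis=2, keepdims=True)

    # Viterbi in log space
    logr = np.log(np.stack([1.0 - r, r]))  # (2, n_snp-1): [stay, switch]
    delta = em[:, 0, :] + np.log(0.5)
    psi = np.zeros((n_seg, n_snp, 2), dtype=np.int8)
    for t in range(1, n_snp):
        stay, sw = logr[0, t - 1], logr[1, t - 1]
        # cand[s_prev, s_cur]
        c0 = np.stack([delta[:, 0] + stay, delta[:, 1] + sw], axis=1)  # to state 0
        c1 = np.stack([delta[:, 0] + sw, delta[:, 1] + stay], axis=1)  # to state 1
        psi[:, t, 0] = np.argmax(c0, axis=1)
        psi[:, t, 1] = np.argmax(c1, axis=1)
        delta = np.stack([c0.max(axis=1), c1.max(axis=1)], axis=1) + em[:, t, :]
    path = np.empty((n_seg, n_snp), dtype=np.int8)
    path[:, -1] = np.argmax(delta, axis=1)
    for t in range(n_snp - 2, -1, -1):
        path[:, t] = psi[np.arange(n_seg), t + 1, path[:, t + 1]]
    return post, loglik, path


def infer_genotypes(
    matrix: ReadCountMatrix,
    panel: SnpPanel,
    genome: GenomeMap,
    params: HmmParams | None = None,
) -> GenotypeCallSet:
    """Posterior-decode parental origin chromosome-by-chromosome.

    Uniform initial state distribution; hard calls require posterior >=
    ``min_posterior`` (ties at the threshold call the state); segregants
    with no reads at all are fully missing and flagged.
    """
    params = params or HmmParams()
    if matrix.n_snps != len(panel):
        raise ValueError("read-count matrix and panel dimensions differ")
    c = params.recomb_rate if params.recomb_rate is not None else genome.recomb_rate
    n_seg, n_snp = matrix.n_segregants, matrix.n_snps
    post_a = np.empty((n_seg, n_snp))
    viterbi = np.empty((n_seg, n_snp), dtype=np.int8)
    loglik = np.zeros(n_seg)
    for chrom in genome.names:
        sl = panel.chrom_slice(chrom)
        if sl.stop == sl.start:
            continue
        da = matrix.depth_a[:, sl]
        db = matrix.depth_b[:, sl]
        em = np.stack(
            [
                emission_loglik(da, db, CALL_A, params.eps),
                emission_loglik(da, db, CALL_B, params.eps),
            ],
            axis=2,
        )
        pos = panel.pos[sl]
        if len(pos) == 1:
            b = np.exp(em[:, 0, :] - em[:, 0, :].max(axis=1, keepdims=True)) * 0.5
            p = b / b.sum(axis=1, keepdims=True)
            post_a[:, sl.start] = p[:, 0]
            viterbi[:, sl.start] = np.argmax(p, axis=1)
            loglik += np.log(b.sum(axis=1)) + em[:, 0, :].max(axis=1)
            continue
        r = transition_prob(np.diff(pos), c, params.switch_floor)
        post, ll, path = _forward_backward(em, r)
        post_a[:, sl] = post[:, :, 0]
        viterbi[:, sl] = path
        loglik += ll

    hard = np.full((n_seg, n_snp), CALL_MISSING, dtype=np.int8)
    hard[post_a >= params.min_posterior] = CALL_A
    hard[1.0 - post_a >= params.min_posterior] = CALL_B

    coverage = chromosome_coverage_profile(matrix, panel, genome)
    flags: list[set[str]] = []
    for i in range(n_seg):
        f = qc_segregant(
            matrix.depth_a[i], matrix.depth_b[i], panel, genome, params,
            coverage_row=coverage.loc[matrix.ids[i]],
        )
        if matrix.total_depth()[i].sum() == 0:
            hard[i] = CALL_MISSING
            f = f | {FLAG_NO_DATA}
        flags.append(f)
    return GenotypeCallSet(
        posterior_a=post_a,
        hard_calls=hard,
        viterbi=viterbi,
        qc_flags=flags,
        coverage=coverage,
        log_likelihood=loglik,
        ids=list(matrix.ids),
        panel=panel,
        params=params,
    )


def qc_segregant(
    depth_a: np.ndarray,
    depth_b: np.ndarray,
    panel: SnpPanel,
    genome: GenomeMap,
    params: HmmParams | None = None,
    coverage_row: pd.Series | None = None,
) -> set[str]:
    """QC flags for one segregant's read counts.

    Contamination/diploidy: more than ``het_site_fraction`` of sites with
    depth >= 4 show a minor-allele read fraction >= 0.25. Aneuploidy: any
    chromosome's mean depth over the genome-wide mean leaves
    ``coverage_ratio_bounds``.
    """
    params = params or HmmParams()
    flags: set[str] = set()
    total = depth_a + depth_b
    deep = total >= 4
    if deep.sum() > 0:
        minor = np.minimum(depth_a[deep], depth_b[deep]) / total[deep]
        if (minor >= 0.25).mean() > params.het_site_fraction:
            flags.add(FLAG_CONTAMINATED)
    if coverage_row is None:
        coverage_row = _coverage_row(depth_a, depth_b, panel, genome)
    lo, hi = params.coverage_ratio_bounds
    ratios = coverage_row.dropna()
    if len(ratios) and ((ratios < lo) | (ratios > hi)).any():
        flags.add(FLAG_ANEUPLOID)
    return flags


def _coverage_row(depth_a, depth_b, panel, genome) -> pd.Series:
    total = depth_a + depth_b
    gmean = total.mean() if len(total) else 0.0
    vals = {}
    for chrom in genome.names:
        sl = panel.chrom_slice(chrom)
        if sl.stop == sl.start or gmean == 0:
            vals[chrom] = np.nan
        else:
            vals[chrom] = total[sl].mean() / gmean
    return pd.Series(vals)


def calls_from_truth(cohort, panel: SnpPanel, genome: GenomeMap) -> GenotypeCallSet:
    """A perfect-information call set built from simulated origin tracks.

    Useful for isolating mapping-stage behaviour from genotyping noise:
    posteriors are 0/1, Viterbi equals truth, and every segregant passes
    QC. Only meaningful for simulated cohorts.
    """
    n_seg, n_snp = len(cohort), len(panel)
    hard = np.empty((n_seg, n_snp), dtype=np.int8)
    for i, g in enumerate(cohort.genotypes):
        hard[i] = g.origin_matrix_row(panel)
    post_a = (hard == CALL_A).astype(np.float64)
    ids = [g.id for g in cohort.genotypes]
    coverage = pd.DataFrame(
        1.0, index=ids, columns=genome.names
    )
    return GenotypeCallSet(
        posterior_a=post_a,
        hard_calls=hard.copy(),
        viterbi=hard.copy(),
        qc_flags=[set() for _ in range(n_seg)],
        coverage=coverage,
        log_likelihood=np.zeros(n_seg),
        ids=ids,
        panel=panel,
        params=HmmParams(),
    )


def chromosome_coverage_profile(
    matrix: ReadCountMatrix, panel: SnpPanel, genome: GenomeMap
) -> pd.DataFrame:
    """Per-segregant, per-chromosome mean depth over genome-wide mean.

    Chromosomes with no panel sites are reported missing (NaN), never 0.
    A segregant with zero total depth raises, matching the contract that
    a coverage profile needs data.
    """
    total = matrix.total_depth()
    rows = {}
    for i, sid in enumerate(matrix.ids):
        rows[sid] = _coverage_row(matrix.depth_a[i], matrix.depth_b[i], panel, genome)
    return pd.DataFrame(rows).T
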