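# Methods

## The phenotype model

Rough colony morphology is modelled as a disjunction of multi-locus
requirement clauses, evaluated in order, each with a penetrance:

* **Clause 1** (penetrance 1.0): `END3`=BY, `FLO8`=3S, `IRA2`=mut,
  `MSS11`=BY, `TRR1`=3S.
* **Clause 2** (penetrance π_alt, default 0.2): the same background with
  `END3`=3S complemented by BY alleles at the chromosome VII locus and a
  second chromosome XV locus ("XV2").

The clauses are mutually exclusive (they disagree at `END3`), so at most
one applies to any genotype. An optional "bumpy" rule (off by default)
swaps `TRR1` to the BY allele and produces the bumpy sub-phenotype when
no rough clause fires. `IRA2`-mut is a third allele: it shares parental
origin with the 3S allele (sequencing reads support the 3S haplotype)
but is functionally distinct; genotyping that only sees parental origin
reads it as plain 3S, which is exactly how apparently discordant smooth
individuals arise in genotype–phenotype tables (`concordance_table`
reproduces this with `hide_mut=True`).

**Why π_alt = 0.2.** The penetrance of the complementing clause is not
directly observable from a single cohort; it is set so that the
expected minor class — rough segregants of the 3S backcross carrying
`END3`=3S — is ≈ 4 of 88 (enumeration gives
88 × (π_alt/32)/(1/8 + π_alt/32) = 4.19 at π_alt = 0.2), matching the
size of the minor class the design is built around.

**Mutation carrier fraction f = 0.8.** The spontaneous `IRA2` frameshift
arose during outgrowth of the original F1 diploid, so a fraction of F1
spores inheriting the 3S-origin `IRA2` allele carry it; f = 0.8
corresponds to four of five rough F1 segregants being carriers. In
backcrosses from a carrier segregant, mut versus the plain 3S allele
segregates 1:1 automatically, so f applies only to the original cross.

## Exact expectations

`expected_phenotype_frequency` enumerates offspring genotypes exactly:
loci where the two parents share an allele are fixed and contribute no
factor; each chromosome's segregating model loci are enumerated jointly,
with transmission pattern probability ½·∏(rᵢ or 1−rᵢ) using the Haldane
recombination fraction r = ½(1 − e^(−2cd)) between consecutive loci.
This matters for `IRA2` and XV2, which share chromosome XV: at the
default positions their separation gives r ≈ 0.4995, so results differ
from the unlinked approximation only in the fourth decimal (e.g. the 3S
backcross at π_alt = 1 gives 0.15631 rather than 5/32 = 0.15625). When
f > 0, 3S outcomes at `IRA2` are split into mut (weight f) and plain 3S
(weight 1−f) inside the enumeration.

Key values under the defaults: BY backcross 12.5 % (exact), 3S
backcross 13.13 %, original cross 2.62 %.

## The synthetic genome and cohorts

* **Genome**: 16 chromosomes with *S. cerevisiae*-like lengths
  (~12.07 Mb total), uniform recombination rate 3.8×10⁻⁶ Morgans/bp
  (≈ 0.38 cM/kb, the yeast-typical map density; the genome is "hot":
  ~46 crossovers per meiosis). A `scale` parameter shrinks every
  chromosome linearly for fast tests.
* **Meiosis**: per chromosome, crossover count ~ Poisson(map length in
  Morgans), positions uniform, no interference and no obligate
  crossover. Tetrads are two independent meioses plus their complements,
  which forces exact 2:2 segregation at every segregating site;
  four-strand chromatid sampling is not modelled because downstream
  statistics depend only on marginal recombination fractions and 2:2
  segregation.
* **The rough founder segregant** is a genuine F1 meiotic product
  (rejection-sampled under a fixed internal seed) carrying the clause-1
  alleles, BY alleles at VII/XV2, and the selectable marker; roughly
  half its genome derives from each parent, so unselected backcross
  pools sit at allele frequency ~0.5 at segregating sites.
* **SNP panel**: 5,000 sites placed uniformly (the real panel's spatial
  clumping is not emulated; nothing downstream depends on spacing
  distribution). Panels are ascertained from the cross's own
  polymorphisms, so the causal variants and the engineered marker are
  forced to be panel sites (`make_snp_panel(..., include=...)`).
* **Selectable marker**: a BY-engineered cassette at the CAN1-like
  position on chromosome V. Every plated segregant carries the BY
  origin there — in mapping cohorts *and* control pools — producing the
  non-causal fixed signal on chromosome V in 3S-backcross scans that
  the control screen must catch.
* **Reads**: per site, depth ~ Poisson(λ = 4, matching low-coverage
  selective genotyping); reads supporting the true origin ~
  Binomial(depth, 1 − ε) with ε = 0.005. Aneuploidy multiplies one
  chromosome's Poisson rate by a copy factor; contamination thins a
  sample's reads to (1 − m) and adds Poisson(mλ) reads from a second
  genotype.
* **Large unselected cohorts** (the 100,000-meiosis Monte-Carlo) use a
  causal-loci-only sampler: a Bernoulli(½) start per chromosome and
  Haldane switch probabilities between consecutive model loci, which is
  the exact marginal of the Poisson-crossover model at those positions.
  Mapping-scale cohorts always materialise full genomes.

## HMM genotyping

Two states (BY/3S origin), decoded chromosome by chromosome with a
uniform initial distribution. Emissions are binomial on allele counts —
the information-preserving refinement of a read-fraction statistic, to
which it reduces at fixed depth; zero-depth sites are uninformative.
Transitions use the Haldane map function at the genome's rate, floored
at 10⁻⁶ so a true breakpoint between adjacent distant SNPs is never
numerically impossible. Forward–backward runs in scaled linear space
(scaling constants retained, so the total data log-likelihood is
reported); Viterbi paths supply breakpoints for interval delimitation.
Hard calls require posterior ≥ 0.95, ties calling the state; at λ = 4
and ε = 0.005 hard-call accuracy exceeds 99 % and missing calls are
~0.04 %.

QC (the thresholds are this package's own calibration; clean λ = 4
haploids pass in all of 300 simulated replicates per test run):

* *contaminated/diploid*: > 5 % of sites with depth ≥ 4 show a
  minor-allele read fraction ≥ 0.25 (clean haploids sit near 2 % from
  sequencing error alone; 50 % mixtures near 44 %);
* *aneuploid*: any chromosome's mean depth over the genome mean leaves
  [0.5, 1.6] (a whole-chromosome duplication sits near 2.0; the
  smallest chromosome's sampling SD at λ = 4 is ~0.05);
* chromosomes without panel sites report missing coverage ratios, never
  zero; all-zero-depth samples are fully missing and flagged.

## Locus mapping

The scan computes, per site, the frequency of the non-backcross-parent
allele over non-missing hard calls (missing calls leave the
denominator). Loci are maximal runs of at least `min_run` consecutive
sites at ≥ 95 % frequency; runs separated by fewer than `min_run`
sub-threshold sites merge; the peak is the leftmost maximal site, and a
locus is *fixed* iff its peak frequency is exactly 1.

**Why min_run = 5.** With ~90 selected segregants on this genome the
region at ≥ 95 % frequency around a causal locus spans only ~±14 kb
(the distance at which ≥ 5 % of carriers have recombined), holding
Poisson(~11.6) panel sites. Five consecutive enriched sites cannot
arise from sampling noise (the per-site neutral tail at n = 92 is
< 10⁻¹⁵), while a true locus presents fewer than five enriched sites in
under 1 % of panels. The 100-cohort null scan in the test suite detects
zero loci.

Intervals: each carrier of the enriched allele at the peak contributes
the maximal interval over which its Viterbi path keeps that state
(extended to the chromosome end when the run touches the first or last
panel site); the reported interval is the intersection — the smallest
region bounded by recombination breakpoints among carriers. The
chromosome XIV locus is expected *not* to be fixed: the minor
`END3`-3S class keeps its peak near 84/88 ≈ 0.955, right at the
threshold, so it is detected in roughly the fraction of cohorts whose
binomial draw gives ≤ 4 minor carriers (~0.59; the canonical seed-1 run
detects all five loci).

The control screen smooths the pooled-control frequency of each locus's
allele with a 50-SNP centred moving average (even windows put the extra
tap forward, as R's `filter(sides = 2)` does; incomplete edge windows
are missing) and flags the locus as an artifact if the smoothed control
frequency reaches 0.75 anywhere inside it — a selectable marker is
fixed in the control pool, a causal locus sits near 0.5.

Introgression fine-mapping types every prior-interval site in each
recurrently backcrossed strain and returns the longest run of sites at
which all strains retain the donor allele; after six selected rounds
the neutral donor fraction decays as 2⁻⁶ (verified against the dilution
oracle), leaving short donor segments centred on the selected loci.

## Conditional mapping

The 3S-backcross rough cohort is partitioned by hard call at the panel
site nearest `END3`; minor-class membership is then verified by exact
typing at the gene itself, because ~2 kb of panel spacing puts a
recombination breakpoint between the gene and its nearest site in ~1 %
of segregants — enough to poison an all-members-share rule. The minor
class is scanned for runs where every member carries the BY allele,
subtracting previously detected loci and marker artifacts padded by
50 kb (the detected ≥ 95 % run understates the neighbourhood linked to
a locus fixed among rough progeny). Candidates are refined with
additional minor-class progeny typed at markers across each region:
a region is refuted only when an extra individual matches at *no*
marker, and otherwise shrinks to the span the extras still share —
single-marker typing would refute true regions whenever an extra
recombined inside a wide region. Confirmation in the second-generation
backcross (39 rough + 12 smooth, typed at region markers) requires the
shared allele fixed among rough at some site where it is not fixed
among smooth; a neutral site fixes among 39 progeny with probability
2⁻³⁹, so chance confirmations are negligible, and across 50 simulated
studies the pipeline confirms exactly the chromosome VII and XV regions
in ≥ 90 % of seeds.

## Reproducibility and problem sizes

All randomness flows from one seed; the pipeline fans it out to stages
by a CRC-based hash, so identical configurations produce byte-identical
summaries and any stage can be re-run in isolation. The default study
sizes — 92 and 88 rough segregants, 5,000 SNPs, λ = 4, 1,000-member
control pools, 39 + 12 second-generation progeny — run in well under a
minute; the test suite's repeated-simulation properties (100 null
cohorts, 50 conditional seeds, 10,000-meiosis crossover checks on
scaled genomes) are sized to keep the full suite in a few minutes.

## What passing tests do and do not show

The generator reproduces the *genetic* structure of the study —
Mendelian transmission with a hot map, epistatic penetrance, marker
selection, low-coverage binomial reads, whole-chromosome aneuploidy and
mixture contamination — but not sequence-level reality: no read
mapping or alignment bias, no base-quality structure, no clumped SNP
ascertainment, no crossover interference, no segmental aneuploidy, and
chromatids are sampled independently rather than as four-strand
tetrads. Results on synthetic data therefore validate the inference and
mapping logic, not robustness to alignment artifacts.

## Known limitations

* Interval delimitation intersects across *all* carriers; with noisy
  HMM calls a single carrier whose Viterbi path has a spurious switch
  near the peak can collapse the interval to the peak site. Truth-call
  analyses give realistic widths; a robust variant (dropping outlier
  carriers) is future work.
* The chromosome XIV locus straddles the 95 % threshold by
  construction, so five-locus recovery at a random seed succeeds in
  roughly 59 % of runs (seed 1 is canonical and succeeds); this is a
  property of the design, not of the detector.
* π_alt and f are set by the calibrations above, not estimated from
  data; the package deliberately contains no likelihood machinery for
  fitting architectures.
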