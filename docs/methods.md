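# Methods

`evoscape` models the quantitative analysis of an asexual, glucose-limited
chemostat evolution experiment in haploid *Saccharomyces cerevisiae*: how fit
individual adaptive mutations are, how they interact, and why two of the most
common adaptive solutions — loss-of-function of *MTH1* and tandem
amplification of the *HXT6*/*HXT7* glucose-transporter array — never co-occur.
This note records the models, the defaults and the design choices behind each
stage, and what the synthetic data do and do not establish about real data.

## Selection coefficients from pairwise competition

**Model.** A mutant and an otherwise-isogenic reference strain compete in a
chemostat.  With constant per-generation selection coefficient *s*, the log
abundance ratio is linear in generations:

    ln(N_mut/N_ref)(g) = ln(N_mut/N_ref)(0) + s·g.

*s* is the ordinary-least-squares slope of the log ratio (natural log; the
choice is fixed and recorded) against generations.  The single-assay 95% CI
uses the slope standard error with the *t* distribution at *n*−2 df.
Replicates are pooled as mean ± SEM with a z-based (±1.96·SEM) CI — the same
convention the pooled qPCR CIs use.  Mutant estimates are normalised by
subtracting the wild-type-vs-wild-type control's mean coefficient, with SEs
combined in quadrature.  Relative fitness uses the linear convention
**w = 1 + s** (recorded in output metadata); the exponential alternative
e^s differs by <2% over the range of effects modelled here (s ≤ 0.45).

**Time axis.** Generations accrue in a chemostat as g = D·t/ln 2 with dilution
rate D (volume turnovers per hour).  Defaults: D = 0.2 h⁻¹, sampling every
6 h, ≈24 generations per assay — the cadence of the modelled experiment.

**Linear-phase selection** maximises regression R² over contiguous windows
with ≥ `min_points` samples, dropping at most `max_dropped_fraction` of the
points, and excluding samples with a zero count.  Ties prefer the longer,
then earlier, window, so an already-linear series is returned whole.  This
max-R² criterion is this package's operationalisation; the assay literature
states only that the linear phase is chosen.

**Equal-slope (ANCOVA) test.** Whether a mutant's slope differs from its
control's is tested by comparing `ln_ratio ~ g + group` against
`ln_ratio ~ g × group` with a nested-model F test, F ~ F(1, n−4).

**Zero counts** inside a fitted window are an error by default, with an
optional +0.5 pseudocount mode; saturated tails should normally be removed by
windowing instead.

**Calibration and a known limitation.** On binomially sampled synthetic
assays (30,000 cytometry events/sample) the 95% CI covers the true
coefficient at the nominal rate for small-to-moderate effects (~94–95% at
s = 0.05).  At the largest effects in the modelled range (s ≈ 0.2) a 50:50
start drives the mutant proportion near fixation within the 24-generation
window; the log-ratio noise variance, ≈1/(n·p(1−p)), then grows ~20-fold
across the series, and the homoscedastic OLS CI undercovers (≈91%).  This is
a property of slope-based fitness assays, not of the implementation; the
calibration suite therefore checks nominal coverage in the moderate-effect
regime and checks a ≥90% hit rate at s = 0.2.  Post-selection caveat:
applying the max-R² window to an *entirely* linear noisy series narrows CIs
by selection and worsens coverage, so windowing should be reserved for series
with genuine non-linear phases.

## Epistasis

For mutant alleles x and y with wild-type-normalised coefficients,

    ε = s_xy − (s_x + s_y),     se_ε = √(se_x² + se_y² + se_xy²).

The interaction is significant when ε lies outside the 95% interval
±1.96·se_ε centred on the null value 0 — equivalent to |ε| > 1.96·se_ε, and
identical in decision to centring the interval on ε and asking whether it
excludes 0.  Classification is significance-gated (no sign call is ever made
from a non-significant ε) and then read off the four genotype fitnesses:
a mutation *flips* when its fitness effect changes sign between the wild-type
background and the other mutant's background; one flip is **sign** epistasis,
two flips **reciprocal sign** epistasis (both singles beneficial, the double
less fit than either single and than wild type in the paradigm case);
otherwise the sign of ε gives **negative** or **positive** magnitude
epistasis.  A consistency check rejects fitness inputs that contradict the
supplied ε beyond a tolerance (10⁻⁹ relative for exact inputs; raise it for
independently estimated noisy inputs).

The same statistic drives the clone additivity test
ε = s_clone − Σ s_singles: significantly positive means unexplained adaptive
effect in the clone; negative means sub-additivity between its identified
mutations.

## Fitness landscapes and dynamics

Genotypes are binary strings over the mutated loci with Hamming-1 adjacency.
Local optima are *strict* (fitter than every neighbour); exact ties are
surfaced, never silently broken.  Accessible paths are, by default, Hamming
geodesics along which fitness strictly increases at each step (no
back-mutation), matching the two-locus framing; a flag enables non-revisiting
monotone walks for larger landscapes.  Enumeration is guarded at 20 loci.

Dynamics are deterministic replicator–mutation updates in discrete
generations: selection multiplies each frequency by fitness and renormalises
by mean fitness; mutation then moves probability mass μ per locus to each
neighbour.  The infinite-population limit is appropriate because the modelled
chemostat holds ~2×10⁹ cells, making drift negligible at the frequencies of
interest; stochastic dynamics are out of scope.  Frequencies are asserted to
remain a probability vector each generation, and with μ = 0 mean fitness is
non-decreasing (replicator property).  In the reciprocal-sign scenario the
double mutant stays below mutation–selection balance (≈μ/cost, well under
10μ) while the fitter single mutant sweeps — the mutual-exclusivity pattern.

## Variant filters

The filters are a post-caller layer over per-site allele counts for an
ancestor/evolved pair (alignment and primary calling are out of scope).  SNP
rules: N-base proportion < 0.1 (denominator: all reads at the site, checked
in both samples); majority non-reference base > 80% of non-reference bases
(evaluated in the strain carrying the candidate allele); non-reference
proportion < 0.1 in one strain and > 0.5 in the other (denominator: non-N
reads — N is handled by its own rule, a convention stated in the audit
header); and differing consensus between ancestor and evolved.  Indel rules:
evolved coverage strictly > 10; indel calls > 50% of coverage; top-two indel
alleles > 80% of indel calls; reference matches < 50% of coverage; and every
shared allele's proportion differing by > 0.3 between samples (vacuously true
with no shared allele).  All thresholds are config-exposed dataclasses with
these defaults immutable; every decision carries a per-rule audit row with
the value, denominator convention and verdict.  Positions are 1-based
inclusive throughout.

## Copy number

**Depth route.** ratio_i = (clone_i · mean(anc)/mean(clone)) / anc_i, which
is invariant to global scaling of either profile; a centred running median
(default window 1,001 bases — the source analysis does not state a window,
and plateaus much wider than the window make the choice immaterial) smooths
the ratio; the median inside the queried region is the estimate, with the
flanking median reported as baseline.  Because the amplified mass inflates
mean(clone), the estimate systematically undershoots the true copy number by
the factor 1 + (c−1)·f for segment fraction f — ~3.5% for the default
fixture — mirroring the depth route's known tendency to undercount relative
to qPCR.  BedGraph I/O converts 0-based half-open intervals to the 1-based
internal convention at the boundary.

**qPCR route.** Per replicate ΔCt = Ct_target − Ct_reference (reference: a
non-varying locus controlling for input DNA); ΔΔCt subtracts the
calibrator's mean ΔCt; copies = calibrator_copies · E^(−ΔΔCt) with
amplification efficiency E = 2.0 by default (config knob; no standard-curve
calibration is modelled).  Replicates summarise as mean ± 1.96·SEM; a single
replicate yields a point estimate with the CI flagged undefined.

**Recombination bound.** Under the unequal-crossover model in which one
mitotic recombination event can at most double the promoter count of a
tandem array starting from one copy, the minimum number of events is
⌈log₂(promoters)⌉ — 9 promoters need 4 events, 7 need 3.  The array model
predicts ORFs = promoters + 1, validated (with a warning, not an error) when
both counts are given.  This doubling model is a reconstruction: it is the
simplest unequal-crossover scheme consistent with both printed event counts.

## Neutral-mutation statistics

λ = G·μ·g with genome size G = 1.2×10⁷ bp and per-base rate
μ = 5.12×10⁻¹⁰ bp⁻¹ gen⁻¹; tail probabilities come from the Poisson survival
function at full-precision λ (feeding the rounded one-decimal λ in changes
the tails by ~5%, so full precision is the default and the displayed 1.6/2.4
are rounds).  Population mutation supply is N·G·μ with N = 2×10⁹.  The codon
scan marks a sense codon stop-reachable if any of its nine single-nucleotide
variants is TAA/TAG/TGA, excluding the terminal stop from both counts and
excluding (with a warning) internal stops; a codon counts once regardless of
how many stop-reaching substitutions it has.  Co-occurrence counting is an
exact partition (with an explicit unknown bin); no exclusivity test is
fitted — the observation of zero double mutants is reported as counts, with
an optional hypergeometric P(no overlap | margins) provided as clearly
auxiliary plumbing.

Because the real *MTH1* coding sequence is an external download, the package
ships a **synthetic stand-in** CDS (`data/mth1_standin_synthetic.fasta`),
constructed with 434 sense codons of which exactly 169 are one substitution
from a stop — the same length and capacity as the study gene — so the scan is
exercised at study scale without network access.  It is not the real gene,
and results on it say nothing about *MTH1*'s actual sequence beyond the scan
machinery being correct (which is separately verified against a
translation-based brute-force oracle on random sequences).

## Synthetic data: what it does and does not show

The generators draw binomial counts for two-colour proportions and Poisson
counts for depth — the simplest models consistent with flow cytometry and
shotgun coverage — with defaults matching the modelled design: triplicates,
30,000 events/sample (typical cytometry throughput; the assay fixes no
value), D = 0.2 h⁻¹, 6 h sampling over 24 generations, 30× mean depth
(within the study's 21–45× range).  All randomness flows from one seed
through named, order-independent substreams, so outputs are bit-identical
for a fixed seed and adding a generator never perturbs another.  Every
generator has a noise-off mode that reproduces its closed-form expectation
exactly.  Variant fixtures are *constructed* to pass or fail specific rules,
with noise draws capped below the rule margins at true sites, so the emitted
truth labels partition the sites exactly — by design, which is what makes
them a calibration instrument rather than a realism claim.

What passing these suites does **not** show: robustness to gating artefacts
or autofluorescence drift in real cytometry, mapping bias and GC-dependent
coverage in real sequencing, PCR inhibition or efficiency ≠ 2 in qPCR, or
clonal interference effects beyond the deterministic two-locus dynamics.

## Numerical choices

Exactly collinear regression input yields se = 0 rather than NaN; flat
log-ratio windows count as perfect fits in window selection (zero residual)
and lose ties to longer windows.  The degenerate F statistic on
zero-residual ANCOVA input is reported as (0, 1).  Optima use strict
inequality; path enumeration breaks no ties.  Replicator updates renormalise
each generation to absorb float drift and assert non-negativity.  Ratio
profiles emit NaN (never ±inf) where the ancestor has zero depth, and all
medians ignore NaNs.  Competition series that reach a proportion of exactly
0 or 1 (in floating point) are truncated and flagged, never divided by zero.

## Problem sizes

The calibration suites use 500 simulated assays for CI coverage, 10⁴
Monte-Carlo draws for the ε error-propagation check, a 500 kb genome with a
2 kb amplified segment for the depth route, and 400-site variant tables —
sizes chosen so each check is statistically meaningful while the whole suite
runs in seconds.
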