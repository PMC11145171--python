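# Methods

## Catalogs and channels

Single-base substitutions are binned into the 96 pyrimidine-centered
trinucleotide channels in the canonical catalog order (substitution classes
C>A, C>G, C>T, T>A, T>C, T>G alphabetically; within each class the sixteen
5'/3' flank combinations alphabetically).  A purine-reference change is
reverse-complemented together with its flanks before binning, so the catalog
is strand-symmetric by construction (a property test reverse-complements an
entire simulated genome and asserts an identical catalog).  Reference
matching is case-insensitive and accepts soft-masked bases; a variant whose
flanking context contains an ambiguous base is excluded with a logged count,
while a reference-allele mismatch raises — the former is expected noise, the
latter indicates corrupted inputs.  Indels and multi-nucleotide variants are
skipped: every analysis here is SBS-only.

## Clonality from VAF

A diploid heterozygous mutation carried by every tumor cell is expected at
VAF = purity/2.  A variant is called clonal when a two-sided binomial test of
its alt/total read counts against that expectation is *not* rejected
(default alpha 0.01), or when its VAF is at or above the expectation;
otherwise subclonal.  Purity defaults to twice the median VAF, capped at 1.
This is deliberately the simplest defensible VAF-only rule, fully
parameterized and recorded in the partition's `method_parameters`
(`rule="binomial-stand-in"`); copy-number-aware cancer-cell-fraction
estimation is out of scope, so the rule misbehaves on aneuploid regions.  On
labeled simulations (500 clonal variants with beta-distributed VAF around
purity/2 plus 500 subclonal at VAF <= 0.1, depth 120) misclassification is
below 5%.

## Signature activity model

A catalog `x` is modeled as independent Poisson channel counts with
intensity `mu_c = sum_s e_s p_s(c)`, equivalent to a multinomial profile
with free total intensity.  The Poisson form is chosen because it makes
"does adding a signature improve the reconstruction?" a *nested* hypothesis
with a likelihood-ratio test, which least-squares refitting does not give.

Activities are fitted with multiplicative EM updates
`e_s <- e_s * sum_c p_s(c) x_c / mu_c`, monotone in the log-likelihood and
nonnegativity-preserving.  Convergence is declared when the largest
per-iteration activity change falls below `tol * max(n_total, 1)` (default
tol 1e-8, max 10,000 iterations); for a coordinate decaying geometrically to
the boundary this same quantity bounds its remaining first-order
log-likelihood gap, so the criterion is a log-likelihood guarantee, not just
a step-size heuristic.  If the iteration cap is reached while the first-order
gap bound exceeds 1e-4, the fit raises with the last iterate and gradient
norm.  Internal bootstrap and calibration batches reuse the same update with
three speedups that do not change results beyond ~1e-2 log-likelihood units:
warm starts at the parent fit, tolerance 1e-6, and over-relaxed updates
(ratio raised to omega = 1.8).  The optimizer is validated against a nested
brute-force grid search (integer grid, then local refinement to step 1e-4)
on 3-signature problems with n <= 50, agreeing to 1e-6 in log-likelihood.

## Presence test

`LR = 2 (loglik_with - loglik_without)` for a candidate signature added to a
baseline set.  Because the null value of the candidate activity (zero) lies
on the boundary of the parameter space, the asymptotic null is the 50:50
mixture `0.5 chi2_0 + 0.5 chi2_1`; the p-value is `0.5 P(chi2_1 > LR)`.  A
parametric bootstrap mode (default 1000 catalogs simulated from the
without-candidate fit) is the assumption-free reference.  Measured under a
pure-SBS5 null at n = 2000 over 1000 replicates, rejection at alpha = 0.05
is ~0.06 asymptotic and ~0.05 bootstrap.  The default baseline is the
clock-like set {SBS1, SBS5, SBS40}; SBS31 and SBS35 are tested separately,
never jointly — their profiles are strongly collinear and they act as
alternative descriptions of the same exposure, so a joint fit would split
one activity arbitrarily between them.

## Synthetic-sample calibration

To turn a fitted candidate activity into a bias-corrected estimate with an
interval, the sample's fitted baseline background is perturbed with injected
candidate activities on an 11-point grid spanning [0, n_total], 100 Poisson
replicates per point, each refitted with the full signature set.  The point
estimate maps the observed activity through the inverse of the monotonized
mean injected→recovered curve; the interval inverts the central-coverage
quantile band of the recovered distribution along the grid (a Neyman
construction, so the coverage statement holds by design up to Monte Carlo
error in the quantile curves).  An observation outside the calibrated
response range sets an extrapolation flag.  With no true candidate activity
at n = 2231, the interval covers zero in ~98% of replicates (nominal 95%).

## Per-mutation attribution

The posterior that signature *s* generated a mutation at channel *c* is
`e_s p_s(c) / sum_t e_t p_t(c)`, using the exposures of the mutation's own
clonality stratum.  When SBS31 and SBS35 are alternatives, attribution is
reported once per alternative fit, yielding a range.  Posteriors normalize
at every channel with positive intensity and are monotone in the activity.

## Duplex-panel burden extrapolation

Duplex calls are unique molecular events: a variant seen in several duplex
families at one site counts once, and sites whose VAF against the duplex
depth exceeds 0.05 are dropped as clonal/germline leakage.  Per channel,
`r_c = m_c / D_c` (calls per duplex base interrogated at the channel's
trinucleotide context) is scaled by the genome context count `G_c` to a
per-genome channel burden `g_c`; channel-level (not aggregate) correction
removes residual composition bias of a panel that is only similar to the
genome.  The genome default is a diploid 6.2e9 bp with the haploid context
table doubled; both size and composition are configurable since real panels
come with their own genome build.  Decomposing `{g_c}` over signatures
yields per-process burdens; intervals come from a parametric bootstrap
(default 1000 draws) of the per-channel call counts from the fitted
reconstruction, which smooths zero-count channels; with zero calls the
per-signature upper bound is the exact Poisson zero-count bound mapped to
burden scale.  Per-day rates divide the platinum burden by treatment days
and the age-related burden by days of life (365.25 days/year).

At the study's panel scale (48 kb, 20 intervals, ~20,000X) a per-genome
burden B yields about `B * 9.6e8 / 6.2e9` expected calls — ~10.5 at B = 68 —
so the point estimate at the lowest burden is information-limited: Poisson
noise alone implies ~25% mean absolute relative error there before any
background separation, improving to ~10% at B = 388.  The recovery
experiment adds an age-related background of 150 SNVs/genome (SBS5 120 +
SBS1 30, roughly 15/year for a ~10-year-old's tissue — a conservative
figure; blood-lineage clocks would suggest several-fold more), which
further widens the low-burden error.  Interval coverage stays near nominal
at all three burdens.

## Timing verdicts

The verdict reads the candidate footprint's presence in the two strata:
clonal presence (regardless of subclonal) means a post-exposure clonal
sweep; subclonal-only presence means the tumor pre-existed exposure as a
multicellular clone; neither means indeterminate, with an explicit note that
the footprint may be below detection or the founding clone shielded from the
drug.  The two strata feed one joint rule, so no multiple-testing correction
is applied across them.  The end-to-end pipeline defaults to *strict mode*:
a stratum is footprint-positive only when the test rejects **and** the
calibrated activity interval excludes zero.  Its default alpha is 0.01
rather than the single-test convention of 0.05: the verdict combines two
decisions and a single spurious "present" misclassifies the case, so each
stratum's false-presence rate is held near 1%; the platinum activities the
pipeline targets (hundreds of mutations in a stratum) give LR statistics far
beyond either threshold, leaving power untouched.  On synthetic
reconstructions at the observed strata scales (clonal 2231 with platinum
fraction 932/2231; clonal 89 + subclonal 1000 with subclonal platinum; no
platinum anywhere) the correct verdict is returned in >= 95% of seeded runs.

## Lineage comparison

Variant identity is (chrom, pos, ref, alt); multiallelic records are
decomposed on reading.  Two tumors sharing no clonal SNVs are independent
lineages; shared clonal variants absent (fewer than 2 alt reads, matching
bulk-WGS sensitivity at ~120X) from the reference normal indicate a common
early founder clone; a single shared variant detected at low VAF across all
normals cannot be distinguished from a de novo germline or very early mosaic
variant and is reported as ambiguous.  A normal tissue carrying more than
100 of one tumor's clonal variants at low VAF is flagged as metastatic
infiltration rather than lineage evidence.  Trio sites classify as inherited
(parental VAF >= 0.05), de novo germline (parents negative, child VAF in the
heterozygous [0.35, 0.65] or homozygous [0.85, 1.0] band in every tissue),
or mosaic (below the het band in at least one tissue); missing parental data
downgrades to ambiguous.

## Synthetic data

The generators produce every input the pipeline consumes: a random reference
at configurable GC (default 0.41), mixture catalogs with realized
per-signature truth tables, paired tumors with planted shared
early-embryonic mutations and clonal/subclonal VAF structure (clonal reads
binomial at purity/2, subclonal at half the configured cell fraction; depth
default 120), and duplex panels (48 kb, 20 intervals, ~20,000X overdispersed
depth) with Poisson calls at configured per-genome burdens.  A single
top-level seed fans out to per-stage seeds via `numpy.random.SeedSequence`
spawning, so stages are independently reproducible; generators are
deterministic given (config, seed).  The simulation reference is
megabase-scale: its trinucleotide composition is rescaled to the configured
genome size, so panel call rates are at true genome scale while sequence
bookkeeping stays cheap.

What the generators deliberately do not model: sequencing error (reads are
binomial at the true VAF — there are no false-positive alt reads), mapping
artifacts, copy-number alteration (clonal VAF is purity/2 everywhere),
clustered mutations, and inter-signature correlation of burdens.  Passing
tests therefore demonstrate correctness of the inference given the model's
assumptions, not robustness to caller artifacts or aneuploidy.

The bundled signature matrix (`data/sbs96_synthetic_v1.tsv`, version
`chemotrace-synthetic-v1`, regenerated by
`scripts/build_signature_fixtures.py`) contains *synthetic stand-in*
profiles, not published reference vectors: deterministic constructions
reproducing each process's documented qualitative structure — SBS1
concentrated at N[C>T]G (CpG deamination); SBS5/SBS40 broad clock-like
spectra built to be strongly collinear (cosine ~0.95) as the real pair is;
SBS31 with its maxima at C[C>T]T and C[C>T]C and 5'C enrichment; SBS35
broader platinum with substantial C>A.  Quantities that depend on exact
published values (e.g. the KRAS-context attribution percentages) are
therefore checked as orderings or tolerance bands, and real-data use should
load a published matrix.

## Simulation scales used by tests and the reproduction script

Null size: 1000 replicates at n = 2000 (bootstrap arm: 1000 resamples per
replicate, with curtailed sampling that reproduces the full test's decision
exactly).  Power and zero-activity calibration coverage: 200 replicates at
n = 2231.  Exposure recovery: 200 replicates at n = 2000.  Duplex recovery:
100 replicates per burden level on one 48 kb panel.  Verdicts: 100
reconstructions per pattern.  Lineage: 120-mutation tumor pairs on a 100 kb
reference, 40 noisy replicates per planted count.

## Known limitations

VAF-only clonality ignores copy number; the duplex burden assumes calls are
independent single-molecule events (no clustered artifacts); the asymptotic
presence test is mildly anticonservative (~0.06 at nominal 0.05) when the
baseline contains collinear signatures — the bootstrap mode is the reference
where exactness matters; the synthetic signature profiles are stand-ins, so
absolute activity values on real data require a published matrix; and the
low-burden duplex point estimate (~70 mutations/genome at 48 kb × 20,000X)
is information-limited to ~25-35% relative error regardless of estimator.
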