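# chemotrace

Chemotherapy leaves recognizable mutational footprints in the genomes of
exposed cells.  `chemotrace` implements the inference chain needed to read
those footprints in a cancer survivor's tumors and normal tissues and answer
two questions that matter for children who develop a second malignancy years
after being cured of a first one:

1. **When did the second tumor's clonal expansion happen, relative to the
   chemotherapy?**  If the platinum footprint (SBS31/SBS35) appears among a
   tumor's *clonal* mutations, every tumor cell descends from one exposed
   cell — the expansion happened after treatment.  A footprint restricted to
   *subclonal* mutations means the tumor already existed as a multicellular
   clone at exposure time.  No footprint at all leaves the timing open.
2. **How many mutations did the therapy add to normal tissues?**  From
   error-corrected duplex sequencing of a small genome-representative panel,
   the package extrapolates per-cell genome-wide mutation burdens and per-day
   mutation rates.

It also compares two tumors' clonal mutation sets to classify their
developmental relationship (independent lineages, a shared early-embryonic
founder clone, or an ambiguous de novo/mosaic variant), and attributes
individual driver mutations to the signatures that most plausibly generated
them.

## The model

A sample's single-base substitutions are summarized as a catalog
`x = (x_1, ..., x_96)` over the 96 pyrimidine-centered trinucleotide channels.
Given signature profiles `p_s` (96-channel probability vectors) with
nonnegative activities `e_s`, channels are modeled as independent Poisson
counts:

    x_c ~ Poisson(mu_c),   mu_c = sum_s e_s * p_s(c)

Activities are estimated by maximum likelihood (multiplicative EM updates;
the problem is convex).  Whether a candidate signature is *present* is a
nested likelihood-ratio test: `LR = 2 * (loglik_with - loglik_without)`,
referred to the boundary-corrected null `0.5*chi2_0 + 0.5*chi2_1` (the null
activity sits on the boundary `e >= 0`), or to a parametric bootstrap.  A
synthetic-sample calibration maps fitted activities through an injected →
recovered response curve to a bias-corrected activity with a
Neyman-inversion interval.  Clonality is partitioned from VAF alone (binomial
test against the expected clonal VAF `purity / 2`).  Duplex-panel calls are
extrapolated channel-wise: `g_c = m_c / D_c * G_c`, with `D_c` the duplex
bases interrogated at channel *c*'s trinucleotide context and `G_c` that
context's genome count; decomposing `{g_c}` over signatures gives per-process
per-genome burdens.

The bundled signature profiles (SBS1, SBS5, SBS40 — clock-like; SBS31, SBS35
— platinum) are **synthetic stand-ins** that reproduce the documented
qualitative structure of the published signatures (see
`docs/methods.md`); swap in a published matrix TSV via
`SignatureSet.from_tsv` for real-data work.

## Worked example

Simulate a therapy-related-AML-like clonal catalog (2231 mutations, 932 of
them platinum-made), fit activities, and run the timing analysis:

```python
from chemotrace import (MutationCatalog96, SignatureActivityModel,
                        analyze_footprint_timing, load_bundled_signatures,
                        per_day_rates, ExposureHistory)
from chemotrace.simulate import simulate_catalogs

sigs = load_bundled_signatures()
baseline = sigs.subset(["SBS1", "SBS5", "SBS40"])

mix = {"SBS1": 0.1165, "SBS5": 0.3494, "SBS40": 0.1164, "SBS31": 0.4177}
counts, _ = simulate_catalogs(mix, 2231, 1, seed=7)
clonal = MutationCatalog96(counts[0], label="tAML-clonal")
sub, _ = simulate_catalogs({"SBS1": .2, "SBS5": .6, "SBS40": .2}, 300, 1, seed=8)
subclonal = MutationCatalog96(sub[0], label="tAML-subclonal")

fit = SignatureActivityModel(clonal, baseline.with_profile(sigs["SBS31"])).fit()
print(fit.summary())
verdict = analyze_footprint_timing(clonal, subclonal, candidate="SBS31", seed=1)
print(verdict.verdict)
rates = per_day_rates(fit.exposures,
                      ExposureHistory.from_years(treatment_days=4, age_years=17))
print(f"platinum per treatment day: {rates['platinum_per_treatment_day']:.2f}")
print(f"age-related per life day: {rates['age_related_per_life_day']:.2f}")
```

Output:

```
Signature activity fit (Poisson MLE)
============================================
sample:           tAML-clonal
mutations:        2231
log-likelihood:   -253.172
reconstruction r: 0.9965
--------------------------------------------
signature       activity    fraction
SBS1               266.2       0.119
SBS5               784.0       0.351
SBS40              214.2       0.096
SBS31              966.6       0.433
--------------------------------------------
total             2231.0
post_exposure_clonal_sweep
platinum per treatment day: 241.66
age-related per life day: 0.20
```

The fit recovers the planted platinum activity (967 vs 932 injected, within
Poisson noise), the clonal footprint forces the `post_exposure_clonal_sweep`
verdict (clonal p ≈ 0, subclonal p ≈ 1), and dividing the platinum activity
by the 4 treatment days gives ~242 platinum mutations per day of treatment —
three orders of magnitude above the ~0.2/day age-related rate.  With the
true activity of 932 the platinum rate is 233.0/day.

A command-line interface mirrors the library: `chemotrace simulate`,
`build-catalog`, `fit`, `presence-test`, `attribute`, `duplex-burden`,
`rates`, `timing`, `compare` (see `chemotrace --help`).

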