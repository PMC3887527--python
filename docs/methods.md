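# Methods

## The two-interval meiosis model

The package works at the level of meiotic products (gametes) of a
cis-phase triple heterozygote: three ordered recessive markers with all
mutant alleles on one homolog. Two intervals (L, R) are parameterised by
recombination fractions `p_L`, `p_R` and a single interference value `I`
per gamete type, entering through the coefficient of coincidence
`c = 1 − I/100` applied multiplicatively: the double-crossover gamete
frequency is `c·p_L·p_R`. This is exactly the inverse of the reported
interference statistic `(1 − observed/expected)·100`, so a counts table
generated at interference `I` analyses back to `I` without bias in the
infinite-population limit (asserted exactly in the tests on analytic
integer counts).

Assumptions built into the model:

- **Recombination fractions, not map distances.** No mapping function
  (Haldane/Kosambi) is applied anywhere; all arithmetic is on raw
  fractions, matching how such experiments are reported.
- **Mendelian transmission.** Reciprocal gamete classes are equifrequent;
  no segregation distortion and no viability differences among marker
  genotypes (the source experiments report no correction for either).
- **Cis phase only.** Trans-phase configurations, dominant markers, and
  >3 loci are rejected at construction rather than silently mishandled.
- **Two intervals only.** No chromosome-wide crossover placement,
  obligate-chiasma or gamma/counting interference models; the model's
  `I` is a per-gamete-type constant, which is all the three-marker
  design can identify.

## Parameters and defaults

| parameter | units | default | why |
|---|---|---|---|
| `p_L`, `p_R` | fraction in [0, 0.5] | — (per dataset) | interval recombination fractions |
| `interference` | percent in [0, 100] | 0 | independence unless stated |
| oocyte defaults (selfing) | — | 13.1%, 36.2%, I=100 | measured oogenesis values; zero doubles observed |
| sperm defaults (selfing) | — | 15.0%, 37.8%, I=69.2 | measured male-spermatogenesis values, assumed to apply to hermaphrodite sperm |
| `alpha` | — | 0.05 | conventional 95% intervals |

Whether hermaphrodite spermatogenesis truly shares male-sperm
recombination parameters is an assumption of the study design the
selfing expectation reproduces, not an established fact; all four values
are configurable.

## What the simulator emulates — and what it does not

`simulate_outcross` draws the informative parent's gametes from the
eight-haplotype frequency table and pairs each with an all-wild tester
gamete. The real experiments guarantee cross progeny with GFP arrays,
a *tra-2(gf)* feminising mutation or *pha-1(ts)* counterselection; these
are orthogonal to the interference question and are abstracted as a
perfect cross-progeny filter. `simulate_selfing` draws oocyte and sperm
haplotypes independently from separate parameter sets and generates
progeny until the requested number of phenotypically wild-type animals
has been "singled"; non-wild-type progeny appear in the output flagged
as failing selection, so the empirical singling rate can be checked
against the exact 8×8 pairing enumeration.

Not modelled: genotype-scoring error (brood phenotyping is treated as
perfectly revealing the F1 genotype), temperature effects on
recombination, brood structure or age, X-chromosome dosage mechanics,
and gene conversion. Gene conversion can mimic an apparent double
crossover; published two-point bounds make it negligible here, and every
report carries a fixed caveat string rather than a correction. Passing
tests therefore demonstrate correctness of the inference machinery under
idealised Mendelian sampling, not robustness to scoring error or
viability selection in real broods.

## Estimators and numerical choices

- **Interval estimates.** `p̂ = k/n` with Clopper–Pearson exact bounds
  (inverting the binomial tail tests at `alpha/2` per side; `k=0` gives a
  lower bound of exactly 0, `k=n` an upper bound of exactly 1). Bounds are
  computed via the beta-quantile form and verified in tests against a
  bisection oracle on the tail probabilities to 1e-9.
- **Expected doubles.** `n·p̂_L·p̂_R`, reported unrounded and rounded to
  the nearest integer (the form such results are quoted in).
- **Interference CI.** No standard exact recipe exists. The report
  transforms the Clopper–Pearson CI of the observed-doubles proportion
  through `I = (1 − p/p̂_L p̂_R)·100`, clipped to [0, 100], and emits both
  the two-sided version and a one-sided version (each bound from a full-
  `alpha` tail). For the shipped datasets these bracket, but do not
  exactly match, the originally published interference intervals, whose
  derivation is ambiguous; neither variant is asserted against them.
- **Bookkeeping conventions.** A double-crossover gamete contributes two
  crossover *events* (total-recombination percentage) but one crossover
  *product* (doubles-of-products percentage); only this pairing makes the
  two percentages mutually consistent. Interval recombinant counts are
  `single + double`.
- **Fisher exact test.** Two-sided by the probability-mass rule (sum of
  point hypergeometric probabilities ≤ the observed table's, with a 1e-7
  relative tie tolerance), delegated to `scipy.stats.fisher_exact` and
  cross-checked in tests against exact rational enumeration.
- **Count reconstruction.** The shipped dataset stores interval
  recombinant counts reconstructed from published one-decimal frequencies
  as `k = round(freq·n)` (65, 179 of 495; 103, 260 of 687); each
  reconstruction round-trips to the printed frequency at one decimal.
- **Degenerate inputs.** Interference is reported as undefined (an error)
  when either interval shows no recombinants; the doubles-of-products
  share is undefined without crossover products; empty record lists tally
  to an all-zero table.

## Selfing detectability

Brood phenotyping observes a progeny animal's per-locus zygosity, not
its haplotype phase. A zygosity class is *detectable* as a double
crossover iff (a) it is phenotypically wild-type (it survives the
wild-type singling filter) and (b) every unordered gamete pair whose
union yields that zygosity contains at least one double-crossover
gamete. This set is derived by brute enumeration of all 36 unordered
gamete pairs rather than hard-coded; for the chromosome-V triple it
contains exactly the *dpy-11/+* (otherwise homozygous wild-type) class.
The expected count among `n` wild-type singled animals is
`n · P(detectable)/P(wild-type)` over the 8×8 product distribution of
oocyte and sperm haplotypes — conditioned on wild-type because only
wild-type progeny are singled. At the default parameters this gives
3.49, i.e. three expected detectable doubles among 845 animals, and the
forward simulator's replicate mean agrees within Monte-Carlo error.

Genotype inference from brood phenotypes (`infer_genotype_from_broods`)
matches an observed set of F2 phenotype classes against each candidate
F1 genotype's producible class set, enumerating the genotype's full
gamete repertoire (any per-locus combination of the two homologs'
alleles). Recombination *frequencies* are ignored — only which classes
can occur at all — so a rare class that failed to appear in a small
brood can make a call ambiguous or wrong; calls are sets, with
singletons flagged as unambiguous.

## Problem sizes

Simulation-backed checks use 100,000 meioses for parameter recovery
(three binomial standard errors), 200 replicates of the 845-animal
selfing experiment for the expectation cross-check, and 500 replicates
of the 687-meiosis spermatocyte experiment in the acceptance script —
sizes at which Monte-Carlo error is comfortably below the assertion
tolerances while the whole suite runs in seconds.

## Known limitations

- The interference CI is a transformed binomial CI, not a joint interval:
  uncertainty in `p̂_L p̂_R` is ignored in the transform (only the doubles
  proportion is treated as random). This mirrors how the headline numbers
  are computed but understates total uncertainty slightly.
- The selfing tally can only identify the diagnostic double class; single
  crossover categories are structurally zero under genotype-class scoring
  and the non-diagnostic remainder is reported as parental.
- The model is two-interval by construction; it cannot express distance-
  dependent interference within an interval.
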