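"""Crossover-interference estimation and the selfing detectability model.

The central quantity is crossover interference, reported as

    I = (1 - observed doubles / expected doubles) * 100

where the expected double count under independence is ``n * p_L * p_R``
with the interval recombination fractions estimated from the same counts
table (``p_L = (single_L + double)/n``, likewise R).  The coefficient of
coincidence is ``c = observed/expected = 1 - I/100``.

Interval estimates carry Clopper–Pearson exact binomial confidence
intervals.  Because no published recipe exists for an exact interference
CI, the report transforms the Clopper–Pearson CI of the observed-doubles
proportion through the interference formula and emits both the two-sided
and the one-sided variants, clipped to [0, 100].

The selfing design can only reveal a subset of double-crossover events:
a progeny genotype is *detectable* iff it is phenotypically wild-type yet
every gamete pair able to produce its (observable) zygosity contains a
double-crossover gamete.  ``derive_detectable`` derives that set from
first principles by enumerating all 8x8 gamete pairings, and
``expected_selfing_doubles`` turns it into an expected count among
wild-type singled progeny by exact arithmetic over the pairing
distribution.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from .model import (
    CHROMOSOME_V_MARKERS,
    HAPLOTYPES,
    Category,
    DiploidGenotype,
    Haplotype,
    MarkerTriplet,
    RecombinationParams,
    Zygosity,
    classify_gamete,
    gamete_frequencies,
    phenotype_of,
)
from .simulate import CrossoverCounts

__all__ = [
    "IntervalEstimate",
    "InterferenceReport",
    "SelfingExpectation",
    "Fisher2x2",
    "estimate_interval",
    "interference_report",
    "total_recombination_pct",
    "doubles_of_crossover_products_pct",
    "fisher_exact",
    "infer_genotype_from_broods",
    "derive_detectable",
    "expected_selfing_doubles",
    "GENE_CONVERSION_CAVEAT",
]

#: Carried on every interference report: apparent doubles could in
#: principle include gene-conversion events, though two-point mapping data
#: bound these as negligible for the markers used here.
GENE_CONVERSION_CAVEAT = (
    "Apparent double crossovers may include rare gene-conversion events; "
    "published two-point mapping bounds indicate these are negligible for "
    "the unc-60/dpy-11/rol-9 region."
)


@dataclass(frozen=True)
class IntervalEstimate:
    """A recombination-fraction estimate with exact binomial CI."""

    k: int
    n: int
    p_hat: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.ci_low <= self.p_hat <= self.ci_high <= 1.0:
            raise ValueError("CI bounds must bracket the point estimate in [0, 1]")


def estimate_interval(k: int, n: int, alpha: float = 0.05) -> IntervalEstimate:
    """Clopper–Pearson exact binomial estimate of a recombination fraction.

    The interval inverts the exact binomial tail tests at level alpha/2
    per side; by convention ``k=0`` gives ``ci_low=0`` and ``k=n`` gives
    ``ci_high=1``.
    """
    if not (isinstance(k, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise ValueError("k and n must be integers")
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    ci = stats.binomtest(int(k), int(n)).proportion_ci(
        confidence_level=1.0 - alpha, method="exact"
    )
    return IntervalEstimate(
        k=int(k), n=int(n), p_hat=k / n, ci_low=ci.low, ci_high=ci.high, alpha=alpha
    )


@dataclass(frozen=True)
class InterferenceReport:
    """Everything the three-point analysis derives from one counts table."""

    counts: CrossoverCounts
    interval_L: IntervalEstimate
    interval_R: IntervalEstimate
    observed_doubles: int
    expected_double_freq: float
    expected_doubles: float
    expected_doubles_int: int
    coincidence_hat: float
    interference_pct: float
    #: two-sided Clopper–Pearson CI on the doubles proportion, pushed
    #: through the interference transform and clipped to [0, 100]
    interference_ci: Tuple[float, float]
    #: one-sided variant (each bound from a one-sided tail at level alpha)
    interference_ci_one_sided: Tuple[float, float]
    total_recombination_pct: float
    doubles_of_crossover_products_pct: float
    alpha: float = 0.05
    caveat: str = GENE_CONVERSION_CAVEAT


def _interference_from_prop(p: float, expected_freq: float) -> float:
    return float(np.clip((1.0 - p / expected_freq) * 100.0, 0.0, 100.0))


def total_recombination_pct(counts: CrossoverCounts) -> float:
    """Total crossover events per hundred meiotic products.

    Each double-crossover gamete carries two crossover events, so the
    numerator is ``single_L + single_R + 2*double``; the result equals
    ``(p_L + p_R) * 100``.
    """
    if counts.n == 0:
        raise ValueError("empty counts table")
    events = counts.single_L + counts.single_R + 2 * counts.double
    return 100.0 * events / counts.n


def doubles_of_crossover_products_pct(counts: CrossoverCounts) -> float:
    """Share of crossover-bearing gametes that are doubles.

    A double gamete is one crossover *product*; the denominator is
    ``single_L + single_R + double``.
    """
    products = counts.single_L + counts.single_R + counts.double
    if products == 0:
        raise ValueError("no crossover products: fraction undefined")
    return 100.0 * counts.double / products


def interference_report(
    counts: CrossoverCounts, alpha: float = 0.05
) -> InterferenceReport:
    """Full three-point interference analysis of one crossover counts table."""
    n = counts.n
    if n == 0:
        raise ValueError("empty counts table")
    k_L = counts.single_L + counts.double
    k_R = counts.single_R + counts.double
    est_L = estimate_interval(k_L, n, alpha)
    est_R = estimate_interval(k_R, n, alpha)
    if est_L.p_hat == 0.0 or est_R.p_hat == 0.0:
        raise ValueError(
            "interference undefined: an interval shows no recombinants "
            "(expected double frequency is zero)"
        )
    expected_freq = est_L.p_hat * est_R.p_hat
    expected = n * expected_freq
    k_D = counts.double
    coincidence = k_D / expected
    interference = (1.0 - coincidence) * 100.0

    d_ci = estimate_interval(k_D, n, alpha)
    two_sided = (
        _interference_from_prop(d_ci.ci_high, expected_freq),
        _interference_from_prop(d_ci.ci_low, expected_freq),
    )
    # one-sided bounds: each tail at full level alpha
    lo_1s = _interference_from_prop(
        float(stats.beta.ppf(1.0 - alpha, k_D + 1, n - k_D)) if k_D < n else 1.0,
        expected_freq,
    )
    hi_1s = _interference_from_prop(
        float(stats.beta.ppf(alpha, k_D, n - k_D + 1)) if k_D > 0 else 0.0,
        expected_freq,
    )
    return InterferenceReport(
        counts=counts,
        interval_L=est_L,
        interval_R=est_R,
        observed_doubles=k_D,
        expected_double_freq=expected_freq,
        expected_doubles=expected,
        expected_doubles_int=int(round(expected)),
        coincidence_hat=coincidence,
        interference_pct=interference,
        interference_ci=two_sided,
        interference_ci_one_sided=(lo_1s, hi_1s),
        total_recombination_pct=total_recombination_pct(counts),
        doubles_of_crossover_products_pct=doubles_of_crossover_products_pct(counts),
        alpha=alpha,
    )


@dataclass(frozen=True)
class Fisher2x2:
    table: Tuple[Tuple[int, int], Tuple[int, int]]
    p_two_sided: float


def fisher_exact(table: Sequence[Sequence[int]]) -> Fisher2x2:
    """Two-sided Fisher exact test for independence on a 2x2 table.

    Two-sided p-value by the probability-mass rule: the sum of point
    hypergeometric probabilities of all tables with the observed margins
    that are no more probable than the observed table.
    """
    t = np.asarray(table, dtype=object)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    t = np.asarray(table, dtype=np.int64)
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("degenerate margin: a row or column sums to zero")
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return Fisher2x2(
        table=tuple(tuple(int(x) for x in row) for row in t),
        p_two_sided=float(p),
    )


# ---------------------------------------------------------------------------
# Genotype inference from brood phenotypes, and selfing detectability
# ---------------------------------------------------------------------------

def _all_unordered_genotypes() -> List[DiploidGenotype]:
    return [
        DiploidGenotype((a, b))
        for a, b in itertools.combinations_with_replacement(HAPLOTYPES, 2)
    ]


def _selfing_phenotype_classes(
    genotype: DiploidGenotype, markers: MarkerTriplet
) -> FrozenSet[FrozenSet[str]]:
    """Phenotype classes observable among an F1 genotype's selfed brood.

    Enumerates the genotype's full gamete repertoire (any per-locus
    combination of the two homologs' alleles, i.e. recombinants included)
    and every gamete pairing; recombination frequencies play no role,
    only which classes can appear at all.
    """
    gametes = genotype.possible_gametes()
    return frozenset(
        phenotype_of(DiploidGenotype((g1, g2)), markers).visible_traits
        for g1, g2 in itertools.combinations_with_replacement(sorted(gametes), 2)
    )


def infer_genotype_from_broods(
    observed_f2_phenotype_classes: Set[FrozenSet[str]],
    markers: MarkerTriplet = CHROMOSOME_V_MARKERS,
    phase: str = "cis",
) -> Set[DiploidGenotype]:
    """All F1 genotypes whose selfed brood shows exactly the observed classes.

    ``observed_f2_phenotype_classes`` is a set of trait sets (the empty
    frozenset is the wild-type class).  A singleton result is an
    unambiguous genotype call; an empty match raises, since no genotype
    can explain the observation.
    """
    if phase != "cis":
        raise ValueError("only cis phase is supported")
    observed = frozenset(frozenset(c) for c in observed_f2_phenotype_classes)
    valid_traits = set(markers.mutant_phenotypes)
    for cls in observed:
        if not set(cls) <= valid_traits:
            raise ValueError(f"unknown trait labels in class {set(cls)!r}")
    matches = {
        g
        for g in _all_unordered_genotypes()
        if _selfing_phenotype_classes(g, markers) == observed
    }
    if not matches:
        raise ValueError(
            "observed phenotype-class set is producible by no F1 genotype"
        )
    return matches


def _zygosity_of_pair(pair: Tuple[Haplotype, Haplotype]) -> Zygosity:
    return DiploidGenotype(pair).zygosity


def derive_detectable(
    markers: MarkerTriplet = CHROMOSOME_V_MARKERS,
) -> Set[Zygosity]:
    """Zygosity classes that unambiguously reveal a double crossover.

    A progeny class from selfing is scored by its zygosity (what brood
    phenotyping can observe).  It is *detectable* iff (a) it is
    phenotypically wild-type, so it survives the wild-type singling
    filter, and (b) every unordered gamete pair whose union produces that
    zygosity contains at least one double-category gamete.  Derived by
    brute enumeration of all 36 unordered gamete pairs; for the cis
    chromosome-V triple the result is the dpy-11/+ (otherwise homozygous
    wild-type) class.
    """
    producers: Dict[Zygosity, List[Tuple[Haplotype, Haplotype]]] = {}
    for pair in itertools.combinations_with_replacement(HAPLOTYPES, 2):
        producers.setdefault(_zygosity_of_pair(pair), []).append(pair)
    detectable: Set[Zygosity] = set()
    for zyg, pairs in producers.items():
        if "hom_mut" in zyg:
            continue  # shows a visible trait: removed by wild-type singling
        if all(
            any(classify_gamete(h) is Category.DOUBLE for h in pair)
            for pair in pairs
        ):
            detectable.add(zyg)
    return detectable


@dataclass(frozen=True)
class SelfingExpectation:
    """Expected unambiguously-detectable doubles among wild-type selfed progeny."""

    detectable_zygosities: FrozenSet[Zygosity]
    prob_detectable: float
    prob_wild_type: float
    prob_detectable_given_wildtype: float
    n_wildtype: int
    expected_detectable: float
    expected_detectable_int: int


def expected_selfing_doubles(
    oocyte_params: RecombinationParams,
    sperm_params: RecombinationParams,
    n_wildtype: int,
    markers: MarkerTriplet = CHROMOSOME_V_MARKERS,
) -> SelfingExpectation:
    """Exact expected count of detectable doubles among wild-type progeny.

    Works over the product distribution of the 8x8 ordered (oocyte, sperm)
    haplotype pairings: the detectable probability is conditioned on the
    wild-type phenotype because the experimental design singles only
    phenotypically wild-type progeny (denominator ``n_wildtype``).
    """
    if n_wildtype < 0:
        raise ValueError("n_wildtype must be >= 0")
    oo = gamete_frequencies(oocyte_params).freq
    sp = gamete_frequencies(sperm_params).freq
    detectable = frozenset(derive_detectable(markers))
    p_wt = 0.0
    p_det = 0.0
    for m in HAPLOTYPES:
        for p in HAPLOTYPES:
            prob = oo[m] * sp[p]
            if prob == 0.0:
                continue
            geno = DiploidGenotype((m, p))
            if phenotype_of(geno, markers).is_wild_type:
                p_wt += prob
                if geno.zygosity in detectable:
                    p_det += prob
    cond = p_det / p_wt if p_wt > 0 else 0.0
    expected = n_wildtype * cond
    return SelfingExpectation(
        detectable_zygosities=detectable,
        prob_detectable=p_det,
        prob_wild_type=p_wt,
        prob_detectable_given_wildtype=cond,
        n_wildtype=n_wildtype,
        expected_detectable=expected,
        expected_detectable_int=int(round(expected)),
    )
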