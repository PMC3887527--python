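"""Estimators and exact tests, checked against independent oracles.

Oracles used here and nowhere in the implementation:
- Clopper–Pearson: root-finding (brentq) on the exact binomial tail
  probabilities.
- Fisher exact: full hypergeometric enumeration in exact rational
  arithmetic (Fractions over math.comb).
- Selfing detectability: brute-force 8x8 gamete-pair enumeration.
"""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import binom

from triplecross.model import (
    CHROMOSOME_V_MARKERS,
    HAPLOTYPES,
    Category,
    DiploidGenotype,
    RecombinationParams,
    classify_gamete,
)
from triplecross.analysis import (
    derive_detectable,
    doubles_of_crossover_products_pct,
    estimate_interval,
    expected_selfing_doubles,
    fisher_exact,
    infer_genotype_from_broods,
    interference_report,
    total_recombination_pct,
)
from triplecross.simulate import CrossoverCounts, simulate_selfing, tally_counts


# ---------------------------------------------------------------------------
# Clopper–Pearson
# ---------------------------------------------------------------------------

def cp_bounds_by_bisection(k, n, alpha=0.05):
    """Invert the exact binomial tail tests by root finding."""
    if k == 0:
        low = 0.0
    else:
        low = brentq(lambda p: binom.sf(k - 1, n, p) - alpha / 2, 1e-12, 1 - 1e-12,
                     xtol=1e-13)
    if k == n:
        high = 1.0
    else:
        high = brentq(lambda p: binom.cdf(k, n, p) - alpha / 2, 1e-12, 1 - 1e-12,
                      xtol=1e-13)
    return low, high


class TestClopperPearson:
    GRID = [(0, 1), (1, 1), (0, 10), (3, 10), (0, 495), (65, 495), (179, 495),
            (12, 687), (103, 687), (260, 687), (1, 2000), (1000, 2000), (1999, 2000)]

    @pytest.mark.parametrize("k,n", GRID)
    def test_matches_bisection_oracle(self, k, n):
        est = estimate_interval(k, n)
        low, high = cp_bounds_by_bisection(k, n)
        assert est.ci_low == pytest.approx(low, abs=1e-9)
        assert est.ci_high == pytest.approx(high, abs=1e-9)

    def test_zero_successes_closed_form(self):
        est = estimate_interval(0, 495)
        assert est.ci_low == 0.0
        assert est.ci_high == pytest.approx(1 - 0.025 ** (1 / 495), abs=1e-12)

    def test_all_successes_upper_bound_is_one(self):
        assert estimate_interval(10, 10).ci_high == 1.0

    def test_published_interval_cis(self):
        """Reconstructed counts reproduce the published 95% interval CIs."""
        est_L = estimate_interval(65, 495)
        assert 100 * est_L.p_hat == pytest.approx(13.13, abs=0.01)
        assert (round(100 * est_L.ci_low, 1), round(100 * est_L.ci_high, 2)) == \
            (10.3, 16.43)
        est_R = estimate_interval(179, 495)
        assert (round(100 * est_R.ci_low, 1), round(100 * est_R.ci_high, 1)) == \
            (31.9, 40.6)

    @pytest.mark.parametrize("k,n", [(-1, 10), (11, 10), (0, 0)])
    def test_invalid_inputs_rejected(self, k, n):
        with pytest.raises(ValueError):
            estimate_interval(k, n)


# ---------------------------------------------------------------------------
# Fisher exact
# ---------------------------------------------------------------------------

def fisher_p_by_enumeration(table):
    """Two-sided p by exact rational enumeration over fixed margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    N = r1 + r2

    def point(x):
        return Fraction(math.comb(r1, x) * math.comb(r2, c1 - x),
                        math.comb(N, c1))

    p_obs = point(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = point(x)
        if px <= p_obs * (1 + Fraction(1, 10**7)):
            total += px
    return float(min(total, 1))


class TestFisherExact:
    def test_perfect_independence(self):
        assert fisher_exact([[5, 5], [5, 5]]).p_two_sided == pytest.approx(1.0)

    def test_two_table_support(self):
        # only two tables share these margins; both have probability 1/2
        assert fisher_exact([[1, 0], [0, 1]]).p_two_sided == pytest.approx(1.0)

    def test_matches_enumeration_on_random_small_tables(self):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            t = rng.integers(0, 15, size=(2, 2))
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            got = fisher_exact(t).p_two_sided
            want = fisher_p_by_enumeration(t.tolist())
            assert got == pytest.approx(want, rel=1e-7), t

    def test_symmetric_under_transposition(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            t = rng.integers(1, 20, size=(2, 2))
            assert fisher_exact(t).p_two_sided == pytest.approx(
                fisher_exact(t.T).p_two_sided, rel=1e-9
            )

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_exact([[0, 0], [3, 4]])

    def test_oocyte_vs_sperm_crossover_products(self):
        """Doubles vs singles among crossover products differ by gamete line."""
        res = fisher_exact([[0, 244], [12, 339]])
        assert res.p_two_sided == pytest.approx(0.002, abs=5e-4)
        assert res.p_two_sided == pytest.approx(
            fisher_p_by_enumeration([[0, 244], [12, 339]]), rel=1e-7
        )


# ---------------------------------------------------------------------------
# Interference report and derived percentages
# ---------------------------------------------------------------------------

class TestInterferenceReport:
    def test_analytic_counts_recover_interference_exactly(self):
        # counts proportional to the model's category frequencies at I=25:
        # p_L=0.2, p_R=0.4, c=0.75 -> double=0.06, n=1000 gives integers
        counts = CrossoverCounts(
            n=1000, parental=460, single_L=140, single_R=340, double=60
        )
        report = interference_report(counts)
        assert report.interval_L.p_hat == pytest.approx(0.2)
        assert report.interval_R.p_hat == pytest.approx(0.4)
        assert report.expected_doubles == pytest.approx(80.0)
        assert report.coincidence_hat == pytest.approx(0.75)
        assert report.interference_pct == pytest.approx(25.0, abs=1e-12)

    def test_observed_equals_expected_gives_zero_interference(self):
        counts = CrossoverCounts(
            n=1000, parental=480, single_L=120, single_R=320, double=80
        )
        assert interference_report(counts).interference_pct == pytest.approx(
            0.0, abs=1e-12
        )

    def test_zero_doubles_gives_complete_interference(self):
        counts = CrossoverCounts(
            n=495, parental=251, single_L=65, single_R=179, double=0
        )
        report = interference_report(counts)
        assert report.interference_pct == 100.0
        assert report.expected_doubles_int == 24

    def test_interference_ci_ordering_and_clipping(self):
        counts = CrossoverCounts(
            n=687, parental=336, single_L=91, single_R=248, double=12
        )
        report = interference_report(counts)
        lo, hi = report.interference_ci
        assert 0.0 <= lo < report.interference_pct < hi <= 100.0
        lo1, hi1 = report.interference_ci_one_sided
        assert lo < lo1 and hi1 < hi  # one-sided bounds are tighter per side

    def test_no_recombinants_interference_undefined(self):
        counts = CrossoverCounts(n=10, parental=10, single_L=0, single_R=0, double=0)
        with pytest.raises(ValueError, match="undefined"):
            interference_report(counts)

    def test_total_recombination_counts_doubles_twice(self):
        counts = CrossoverCounts(n=10, parental=7, single_L=1, single_R=0, double=2)
        assert total_recombination_pct(counts) == pytest.approx(50.0)

    def test_total_recombination_all_parental_is_zero(self):
        counts = CrossoverCounts(n=5, parental=5, single_L=0, single_R=0, double=0)
        assert total_recombination_pct(counts) == 0.0

    def test_doubles_share_counts_doubles_once(self):
        counts = CrossoverCounts(n=10, parental=8, single_L=1, single_R=0, double=1)
        assert doubles_of_crossover_products_pct(counts) == pytest.approx(50.0)

    def test_doubles_share_undefined_without_products(self):
        counts = CrossoverCounts(n=5, parental=5, single_L=0, single_R=0, double=0)
        with pytest.raises(ValueError, match="undefined"):
            doubles_of_crossover_products_pct(counts)


# ---------------------------------------------------------------------------
# Genotype inference from brood phenotypes
# ---------------------------------------------------------------------------

class TestGenotypeInference:
    def test_all_wild_brood_includes_wild_homozygote(self):
        wt = frozenset()
        result = infer_genotype_from_broods({wt})
        assert DiploidGenotype((("w",) * 3, ("w",) * 3)) in result

    def test_wild_plus_dpy_brood_is_the_diagnostic_class(self):
        result = infer_genotype_from_broods({frozenset(), frozenset({"Dpy"})})
        assert result == {DiploidGenotype((("w", "m", "w"), ("w", "w", "w")))}

    def test_full_phenotype_set_maps_to_triple_heterozygotes(self):
        traits = ("Unc", "Dpy", "Rol")
        full = {
            frozenset(c)
            for r in range(4)
            for c in itertools.combinations(traits, r)
        }
        result = infer_genotype_from_broods(full)
        assert DiploidGenotype((("m",) * 3, ("w",) * 3)) in result
        assert all(g.zygosity == ("het", "het", "het") for g in result)

    def test_impossible_observation_raises(self):
        # a Dpy class without a wild-type class cannot come from any selfing
        # parent that also shows wild-types... use a genuinely unproducible set:
        with pytest.raises(ValueError, match="no F1 genotype"):
            infer_genotype_from_broods({frozenset(), frozenset({"Unc", "Rol"})})

    def test_unknown_trait_rejected(self):
        with pytest.raises(ValueError, match="unknown trait"):
            infer_genotype_from_broods({frozenset({"Lon"})})


# ---------------------------------------------------------------------------
# Selfing detectability and expectation
# ---------------------------------------------------------------------------

def detectable_by_bruteforce():
    """Independent oracle: group all 36 unordered gamete pairs by zygosity."""
    def zygosity(pair):
        return tuple(
            "het" if x != y else ("hom_mut" if x == "m" else "hom_wild")
            for x, y in zip(*pair)
        )

    producers = {}
    for pair in itertools.combinations_with_replacement(HAPLOTYPES, 2):
        producers.setdefault(zygosity(pair), []).append(pair)
    out = set()
    for zyg, pairs in producers.items():
        if "hom_mut" in zyg:
            continue
        if all(any(classify_gamete(h) is Category.DOUBLE for h in p) for p in pairs):
            out.add(zyg)
    return out


class TestSelfingDetectability:
    def test_matches_bruteforce_oracle(self):
        assert derive_detectable(CHROMOSOME_V_MARKERS) == detectable_by_bruteforce()

    def test_contains_dpy_het_class(self):
        assert ("hom_wild", "het", "hom_wild") in derive_detectable()

    def test_double_single_combination_not_detectable(self):
        # (m,w,w)/(w,m,w) shares its zygosity with (m,m,w)/(w,w,w), which
        # needs no double gamete, so the class is ambiguous
        zyg = DiploidGenotype((("m", "w", "w"), ("w", "m", "w"))).zygosity
        assert zyg not in derive_detectable()

    def test_visible_mutants_excluded(self):
        assert all("hom_mut" not in z for z in derive_detectable())


class TestSelfingExpectation:
    def test_complete_interference_both_lines_gives_zero(self):
        p = RecombinationParams(0.131, 0.362, 100.0)
        q = RecombinationParams(0.150, 0.378, 100.0)
        exp = expected_selfing_doubles(p, q, 845)
        assert exp.expected_detectable == 0.0

    def test_study_conditions_expect_three(self, oocyte_params, sperm_params):
        exp = expected_selfing_doubles(oocyte_params, sperm_params, 845)
        assert exp.expected_detectable_int == 3
        assert 0 < exp.prob_detectable_given_wildtype < 0.01

    def test_agrees_with_simulator(self, oocyte_params, sperm_params):
        """Analytic expectation vs empirical simulator mean, 3 Monte-Carlo SE."""
        exp = expected_selfing_doubles(oocyte_params, sperm_params, 845)
        n_reps = 60
        counts = []
        for rep in range(n_reps):
            records = simulate_selfing(oocyte_params, sperm_params, 845, seed=500 + rep)
            counts.append(tally_counts(records, scoring="by_genotype_class").double)
        counts = np.asarray(counts, dtype=float)
        se = counts.std(ddof=1) / np.sqrt(n_reps)
        assert abs(counts.mean() - exp.expected_detectable) < 3 * se
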