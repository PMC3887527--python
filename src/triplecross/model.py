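"""Gamete-frequency algebra for a cis-phase triple heterozygote.

A parent heterozygous for three linked recessive markers (``u d r / + + +``,
all mutant alleles on one homolog) produces eight gamete haplotypes that
fall into four crossover categories: parental, single crossover in the left
interval (L), single crossover in the right interval (R), and double
crossover.  With recombination fractions ``p_L`` and ``p_R`` per interval
and crossover interference ``I`` (percent), the coefficient of coincidence
is ``c = 1 - I/100`` and the double-crossover gamete frequency is
``c * p_L * p_R``.  This module holds the domain types and the exact
(infinite-population) category and haplotype frequencies that the
simulators and estimators are built on.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Mapping, Tuple

__all__ = [
    "MUTANT",
    "WILD",
    "Haplotype",
    "HAPLOTYPES",
    "Category",
    "MarkerTriplet",
    "RecombinationParams",
    "GameteFrequencies",
    "DiploidGenotype",
    "Zygosity",
    "PhenotypeProfile",
    "classify_gamete",
    "category_frequencies",
    "gamete_frequencies",
    "phenotype_of",
    "CHROMOSOME_V_MARKERS",
]

#: Allele symbols.  A haplotype is a triple over {MUTANT, WILD}, ordered
#: left-to-right along the chromosome.
MUTANT = "m"
WILD = "w"

Haplotype = Tuple[str, str, str]

#: All eight three-locus haplotypes, in a fixed deterministic order.
HAPLOTYPES: Tuple[Haplotype, ...] = tuple(
    itertools.product((MUTANT, WILD), repeat=3)
)


class Category(str, Enum):
    """Crossover category of a three-locus gamete (cis-phase parent)."""

    PARENTAL = "parental"
    SINGLE_L = "single_L"
    SINGLE_R = "single_R"
    DOUBLE = "double"


class InfeasibleParams(ValueError):
    """Raised when recombination parameters imply a negative category frequency."""


@dataclass(frozen=True)
class MarkerTriplet:
    """Three ordered recessive markers and their visible phenotypes.

    Parameters
    ----------
    names : tuple of str
        Locus identifiers in chromosomal order.
    mutant_phenotypes : tuple of str
        Visible trait shown by a homozygous mutant at each locus.
    recessive : tuple of bool
        All markers must be recessive; dominant markers are rejected.
    phase : str
        Linkage phase of the triple heterozygote.  Only ``"cis"`` (all
        mutant alleles on one homolog) is supported; ``"trans"`` is
        rejected rather than silently mishandled.
    """

    names: Tuple[str, str, str]
    mutant_phenotypes: Tuple[str, str, str]
    recessive: Tuple[bool, bool, bool] = (True, True, True)
    phase: str = "cis"

    def __post_init__(self) -> None:
        if len(self.names) != 3 or len(self.mutant_phenotypes) != 3:
            raise ValueError("exactly three loci are required")
        if len(set(self.names)) != 3:
            raise ValueError("locus names must be distinct")
        if not all(self.recessive):
            raise ValueError("only fully recessive marker triplets are supported")
        if self.phase != "cis":
            raise ValueError(
                f"phase {self.phase!r} not supported: the model assumes cis phase "
                "(all mutant alleles on one homolog)"
            )


#: The chromosome V triple used throughout: unc-60 (Unc), dpy-11 (Dpy),
#: rol-9 (Rol); interval L is unc-60..dpy-11, interval R is dpy-11..rol-9.
CHROMOSOME_V_MARKERS = MarkerTriplet(
    names=("unc-60", "dpy-11", "rol-9"),
    mutant_phenotypes=("Unc", "Dpy", "Rol"),
)


@dataclass(frozen=True)
class RecombinationParams:
    """Recombination fractions of the two intervals plus interference.

    ``p_L`` and ``p_R`` are recombination fractions (dimensionless, in
    [0, 0.5]); ``interference`` is a percentage in [0, 100].  The implied
    coefficient of coincidence is ``c = 1 - interference/100`` and the
    double-crossover frequency ``c * p_L * p_R``.
    """

    p_L: float
    p_R: float
    interference: float = 0.0

    def __post_init__(self) -> None:
        for name, p in (("p_L", self.p_L), ("p_R", self.p_R)):
            if not 0.0 <= p <= 0.5:
                raise InfeasibleParams(
                    f"{name}={p} outside [0, 0.5]: recombination fractions "
                    "cannot exceed one half"
                )
        if not 0.0 <= self.interference <= 100.0:
            raise InfeasibleParams(
                f"interference={self.interference} outside [0, 100] percent"
            )
        # With p in [0, 0.5] and c in [0, 1] every category frequency is
        # automatically nonnegative and p_D <= min(p_L, p_R); guard anyway
        # so a future relaxation cannot slip through silently.
        for cat, freq in self._raw_category_freqs().items():
            if freq < -1e-15:
                raise InfeasibleParams(
                    f"category {cat.value!r} has negative frequency {freq}"
                )

    @property
    def coincidence(self) -> float:
        return 1.0 - self.interference / 100.0

    @property
    def double_freq(self) -> float:
        return self.coincidence * self.p_L * self.p_R

    def _raw_category_freqs(self) -> Dict[Category, float]:
        d = self.double_freq
        return {
            Category.PARENTAL: 1.0 - self.p_L - self.p_R + d,
            Category.SINGLE_L: self.p_L - d,
            Category.SINGLE_R: self.p_R - d,
            Category.DOUBLE: d,
        }


def classify_gamete(alleles: Haplotype, phase: str = "cis") -> Category:
    """Classify a three-locus gamete haplotype into its crossover category.

    For a cis-phase parent (``m m m / w w w``) a gamete is recombinant in
    interval L iff its alleles at loci 1 and 2 come from different
    homologs, i.e. differ; likewise for interval R at loci 2 and 3.
    """
    if phase != "cis":
        raise ValueError("only cis phase is supported")
    if len(alleles) != 3 or any(a not in (MUTANT, WILD) for a in alleles):
        raise ValueError(f"not a three-locus haplotype over {{m, w}}: {alleles!r}")
    rec_L = alleles[0] != alleles[1]
    rec_R = alleles[1] != alleles[2]
    if rec_L and rec_R:
        return Category.DOUBLE
    if rec_L:
        return Category.SINGLE_L
    if rec_R:
        return Category.SINGLE_R
    return Category.PARENTAL


def category_frequencies(params: RecombinationParams) -> Dict[Category, float]:
    """Exact frequencies of the four crossover categories.

    ``double = c*p_L*p_R``, ``single_L = p_L - double``,
    ``single_R = p_R - double``, ``parental = 1 - p_L - p_R + double``;
    the four values sum to 1.
    """
    return params._raw_category_freqs()


@dataclass(frozen=True)
class GameteFrequencies:
    """Probability of each of the eight gamete haplotypes.

    Reciprocal haplotypes within a category are equifrequent (standard
    Mendelian transmission, no segregation distortion), so each haplotype
    carries half its category's frequency.
    """

    freq: Mapping[Haplotype, float]

    def __post_init__(self) -> None:
        total = sum(self.freq.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"haplotype frequencies sum to {total}, not 1")

    def as_arrays(self) -> Tuple[Tuple[Haplotype, ...], Tuple[float, ...]]:
        """Haplotypes and probabilities in the fixed ``HAPLOTYPES`` order."""
        return HAPLOTYPES, tuple(self.freq[h] for h in HAPLOTYPES)

    def category_marginal(self, category: Category) -> float:
        return sum(
            p for h, p in self.freq.items() if classify_gamete(h) is category
        )


def gamete_frequencies(
    params: RecombinationParams, phase: str = "cis"
) -> GameteFrequencies:
    """Split each category frequency equally over its two reciprocal haplotypes."""
    cat_freq = category_frequencies(params)
    freq = {h: cat_freq[classify_gamete(h, phase)] / 2.0 for h in HAPLOTYPES}
    return GameteFrequencies(freq=freq)


Zygosity = Tuple[str, str, str]  # per-locus: "hom_mut" | "het" | "hom_wild"


@dataclass(frozen=True)
class DiploidGenotype:
    """An unordered pair of gamete haplotypes.

    The pair is canonicalised on construction so that a genotype and its
    swap compare equal and hash identically.
    """

    haplotype_pair: Tuple[Haplotype, Haplotype]

    def __post_init__(self) -> None:
        a, b = self.haplotype_pair
        for h in (a, b):
            if len(h) != 3 or any(x not in (MUTANT, WILD) for x in h):
                raise ValueError(f"invalid haplotype {h!r}")
        object.__setattr__(self, "haplotype_pair", tuple(sorted((a, b))))

    @property
    def zygosity(self) -> Zygosity:
        a, b = self.haplotype_pair
        out = []
        for x, y in zip(a, b):
            if x == y:
                out.append("hom_mut" if x == MUTANT else "hom_wild")
            else:
                out.append("het")
        return tuple(out)

    def possible_gametes(self) -> frozenset:
        """Every haplotype formable by drawing one allele per locus from
        either homolog — the full recombinant gamete repertoire, rates
        ignored."""
        a, b = self.haplotype_pair
        return frozenset(
            itertools.product(*({x, y} for x, y in zip(a, b)))
        )


@dataclass(frozen=True)
class PhenotypeProfile:
    """The set of visible traits an animal shows.

    With all-recessive markers a trait appears iff the locus is homozygous
    mutant; an empty set is phenotypically wild-type.
    """

    visible_traits: frozenset = field(default_factory=frozenset)

    @property
    def is_wild_type(self) -> bool:
        return not self.visible_traits


def phenotype_of(
    genotype: DiploidGenotype, markers: MarkerTriplet = CHROMOSOME_V_MARKERS
) -> PhenotypeProfile:
    """Visible phenotype of a diploid genotype under recessive markers."""
    traits = frozenset(
        trait
        for z, trait in zip(genotype.zygosity, markers.mutant_phenotypes)
        if z == "hom_mut"
    )
    return PhenotypeProfile(visible_traits=traits)
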