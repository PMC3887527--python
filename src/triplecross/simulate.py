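"""Forward simulation of the three cross designs.

Three designs are modelled, matching the experiments the analysis is built
for:

* ``oocyte_outcross`` — a triple-heterozygous hermaphrodite crossed to
  wild-type males; the informative (recombinant-revealing) gamete is the
  oocyte, the paternal tester gamete is all-wild.
* ``male_sperm_outcross`` — triple-heterozygous males crossed to an
  uninformative hermaphrodite; the informative gamete is the sperm.
* ``self_fertilization`` — a triple heterozygote selfs; oocytes and sperm
  each carry their own recombination parameters, and only phenotypically
  wild-type progeny are singled (retained).

The experimental cross-progeny-selection tricks (GFP arrays, tra-2(gf)
feminisation, pha-1(ts) counterselection) are abstracted as a perfect
"cross progeny only" filter, so every outcross record passes selection.
Each simulation call takes an explicit seed and owns one generator: the
same seed always reproduces the same record list bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Optional, Sequence

import numpy as np

from .model import (
    CHROMOSOME_V_MARKERS,
    HAPLOTYPES,
    WILD,
    Category,
    DiploidGenotype,
    GameteFrequencies,
    Haplotype,
    MarkerTriplet,
    PhenotypeProfile,
    RecombinationParams,
    classify_gamete,
    gamete_frequencies,
    phenotype_of,
)

__all__ = [
    "DesignId",
    "CrossDesign",
    "SimulatedProgenyRecord",
    "CrossoverCounts",
    "simulate_outcross",
    "simulate_selfing",
    "tally_counts",
    "OOCYTE_OUTCROSS",
    "MALE_SPERM_OUTCROSS",
    "SELF_FERTILIZATION",
]

TESTER_HAPLOTYPE: Haplotype = (WILD, WILD, WILD)


class DesignId(str, Enum):
    OOCYTE_OUTCROSS = "oocyte_outcross"
    MALE_SPERM_OUTCROSS = "male_sperm_outcross"
    SELF_FERTILIZATION = "self_fertilization"


@dataclass(frozen=True)
class CrossDesign:
    """Which parent is informative and how progeny are selected.

    ``informative_gamete_types`` names the gamete pool(s) that carry
    recombination parameters ("oocyte", "sperm", or both for selfing);
    outcrosses contribute an all-wild tester gamete from the other parent.
    ``selection`` is "cross_progeny_only" for outcrosses (a perfect filter
    here) and "wild_type_only" for the selfing design.
    """

    design_id: DesignId
    informative_gamete_types: tuple
    tester_haplotype: Optional[Haplotype]
    selection: str

    def __post_init__(self) -> None:
        if self.design_id is DesignId.SELF_FERTILIZATION:
            if self.informative_gamete_types != ("oocyte", "sperm"):
                raise ValueError("selfing is informative through both gamete pools")
            if self.tester_haplotype is not None:
                raise ValueError("selfing has no tester parent")
        else:
            if len(self.informative_gamete_types) != 1:
                raise ValueError("an outcross has exactly one informative gamete pool")
            if self.tester_haplotype is None:
                raise ValueError("an outcross needs a tester haplotype")


OOCYTE_OUTCROSS = CrossDesign(
    DesignId.OOCYTE_OUTCROSS, ("oocyte",), TESTER_HAPLOTYPE, "cross_progeny_only"
)
MALE_SPERM_OUTCROSS = CrossDesign(
    DesignId.MALE_SPERM_OUTCROSS, ("sperm",), TESTER_HAPLOTYPE, "cross_progeny_only"
)
SELF_FERTILIZATION = CrossDesign(
    DesignId.SELF_FERTILIZATION, ("oocyte", "sperm"), None, "wild_type_only"
)

_DESIGNS = {
    DesignId.OOCYTE_OUTCROSS: OOCYTE_OUTCROSS,
    DesignId.MALE_SPERM_OUTCROSS: MALE_SPERM_OUTCROSS,
    DesignId.SELF_FERTILIZATION: SELF_FERTILIZATION,
}


@dataclass(frozen=True)
class SimulatedProgenyRecord:
    design_id: DesignId
    maternal_gamete: Haplotype
    paternal_gamete: Haplotype
    passed_selection: bool

    @property
    def genotype(self) -> DiploidGenotype:
        return DiploidGenotype((self.maternal_gamete, self.paternal_gamete))

    def phenotype(
        self, markers: MarkerTriplet = CHROMOSOME_V_MARKERS
    ) -> PhenotypeProfile:
        return phenotype_of(self.genotype, markers)

    def informative_gamete(self) -> Haplotype:
        if self.design_id is DesignId.OOCYTE_OUTCROSS:
            return self.maternal_gamete
        if self.design_id is DesignId.MALE_SPERM_OUTCROSS:
            return self.paternal_gamete
        raise ValueError(
            "selfing records have two informative gametes; score by genotype class"
        )


@dataclass(frozen=True)
class CrossoverCounts:
    """Observed counts per crossover category with total n."""

    n: int
    parental: int
    single_L: int
    single_R: int
    double: int

    def __post_init__(self) -> None:
        cats = (self.parental, self.single_L, self.single_R, self.double)
        if any(c < 0 for c in cats) or self.n < 0:
            raise ValueError("counts must be nonnegative")
        if sum(cats) != self.n:
            raise ValueError(f"category counts sum to {sum(cats)}, n={self.n}")

    def as_dict(self) -> Dict[str, int]:
        return {
            "parental": self.parental,
            "single_L": self.single_L,
            "single_R": self.single_R,
            "double": self.double,
        }

    @classmethod
    def from_dict(cls, counts: Dict[str, int]) -> "CrossoverCounts":
        vals = {c.value: int(counts.get(c.value, 0)) for c in Category}
        return cls(n=sum(vals.values()), **{
            "parental": vals["parental"],
            "single_L": vals["single_L"],
            "single_R": vals["single_R"],
            "double": vals["double"],
        })


def _draw_haplotypes(
    freqs: GameteFrequencies, size: int, rng: np.random.Generator
) -> List[Haplotype]:
    _, probs = freqs.as_arrays()
    idx = rng.choice(len(HAPLOTYPES), size=size, p=np.asarray(probs))
    return [HAPLOTYPES[i] for i in idx]


def simulate_outcross(
    params: RecombinationParams,
    n_progeny: int,
    seed: int,
    design: CrossDesign = OOCYTE_OUTCROSS,
) -> List[SimulatedProgenyRecord]:
    """Simulate cross progeny of a triple-heterozygote outcross.

    The informative gamete is drawn from the haplotype frequency table
    implied by ``params``; the tester parent always contributes the
    all-wild haplotype.  Selection of cross progeny is modelled as
    perfect, so every record has ``passed_selection=True``.
    """
    if n_progeny < 1:
        raise ValueError("n_progeny must be >= 1")
    if design.design_id is DesignId.SELF_FERTILIZATION:
        raise ValueError("use simulate_selfing for the self-fertilization design")
    rng = np.random.default_rng(seed)
    informative = _draw_haplotypes(gamete_frequencies(params), n_progeny, rng)
    tester = design.tester_haplotype
    maternal_informative = design.design_id is DesignId.OOCYTE_OUTCROSS
    return [
        SimulatedProgenyRecord(
            design_id=design.design_id,
            maternal_gamete=h if maternal_informative else tester,
            paternal_gamete=tester if maternal_informative else h,
            passed_selection=True,
        )
        for h in informative
    ]


def simulate_selfing(
    oocyte_params: RecombinationParams,
    sperm_params: RecombinationParams,
    n_wildtype_singled: int,
    seed: int,
    markers: MarkerTriplet = CHROMOSOME_V_MARKERS,
    _batch: int = 1024,
) -> List[SimulatedProgenyRecord]:
    """Simulate selfing progeny until ``n_wildtype_singled`` wild-types pass.

    Oocyte and sperm haplotypes are drawn independently from their own
    frequency tables.  All progeny generated up to (and including) the
    n-th phenotypically wild-type animal are returned; ``passed_selection``
    marks the wild-type (singled) ones.  ``n_wildtype_singled=0`` returns
    an empty list.
    """
    if n_wildtype_singled < 0:
        raise ValueError("n_wildtype_singled must be >= 0")
    if n_wildtype_singled == 0:
        return []
    rng = np.random.default_rng(seed)
    oo_freq = gamete_frequencies(oocyte_params)
    sp_freq = gamete_frequencies(sperm_params)

    records: List[SimulatedProgenyRecord] = []
    n_passed = 0
    while n_passed < n_wildtype_singled:
        mats = _draw_haplotypes(oo_freq, _batch, rng)
        pats = _draw_haplotypes(sp_freq, _batch, rng)
        for m, p in zip(mats, pats):
            # wild-type iff no locus is homozygous mutant
            wt = not any(a == b == "m" for a, b in zip(m, p))
            records.append(
                SimulatedProgenyRecord(
                    design_id=DesignId.SELF_FERTILIZATION,
                    maternal_gamete=m,
                    paternal_gamete=p,
                    passed_selection=wt,
                )
            )
            if wt:
                n_passed += 1
                if n_passed == n_wildtype_singled:
                    return records
    return records


def tally_counts(
    records: Sequence[SimulatedProgenyRecord],
    scoring: str = "by_informative_gamete",
    markers: MarkerTriplet = CHROMOSOME_V_MARKERS,
) -> CrossoverCounts:
    """Tally progeny records into a crossover-category counts table.

    ``by_informative_gamete`` (outcrosses): classify each record's
    informative gamete into parental / single_L / single_R / double.

    ``by_genotype_class`` (selfing): among retained (wild-type singled)
    records, count the diagnostic genotype classes — those whose zygosity
    can only arise from a gamete pair containing a double-crossover gamete
    (for the cis chromosome-V triple: the dpy-11/+, otherwise homozygous
    wild-type class).  Only the double category is identifiable this way;
    the remaining retained records are reported as parental and the single
    categories are structurally zero.
    """
    designs = {r.design_id for r in records}
    if len(designs) > 1:
        raise ValueError(f"records mix designs: {sorted(d.value for d in designs)}")
    counts = {c: 0 for c in Category}
    if scoring == "by_informative_gamete":
        for r in records:
            counts[classify_gamete(r.informative_gamete())] += 1
    elif scoring == "by_genotype_class":
        # local import: analysis depends on model only, not on this module
        from .analysis import derive_detectable

        detectable = derive_detectable(markers)
        retained = [r for r in records if r.passed_selection]
        for r in retained:
            if r.genotype.zygosity in detectable:
                counts[Category.DOUBLE] += 1
            else:
                counts[Category.PARENTAL] += 1
    else:
        raise ValueError(f"unknown scoring {scoring!r}")
    total = sum(counts.values())
    return CrossoverCounts(
        n=total,
        parental=counts[Category.PARENTAL],
        single_L=counts[Category.SINGLE_L],
        single_R=counts[Category.SINGLE_R],
        double=counts[Category.DOUBLE],
    )
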