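"""The published chromosome-V three-marker dataset used as reference input.

The study this package reproduces scored three crosses over the
unc-60(e723) dpy-11(e224) rol-9(sc148) region of *C. elegans* LGV and
reported interval recombination frequencies rather than raw interval
counts.  Counts are reconstructed as ``k = round(freq * n)``; the
reconstruction round-trips (``k/n`` reprints the published one-decimal
frequency in every case).

* Oogenesis outcross: n = 495, intervals 13.1% and 36.2%, 0 doubles
  (recombinant counts 65 and 179).
* Male spermatogenesis outcross: n = 687, intervals 15.0% and 37.8%,
  12 doubles (recombinant counts 103 and 260, hence singles 91 and 248).
* Self-fertilization: 845 wild-type singled progeny, 2 detected
  double-recombinant animals.
"""

from __future__ import annotations

from .model import RecombinationParams
from .simulate import CrossoverCounts

__all__ = [
    "OOCYTE_COUNTS",
    "SPERM_COUNTS",
    "OOCYTE_PARAMS",
    "SPERM_PARAMS",
    "SELFING_N_WILDTYPE",
    "SELFING_OBSERVED_DOUBLES",
    "REFERENCE_VALUES",
]

# Oogenesis: k_L = round(0.131*495) = 65, k_R = round(0.362*495) = 179,
# doubles = 0, so singles equal the interval recombinant counts.
OOCYTE_COUNTS = CrossoverCounts(
    n=495, parental=251, single_L=65, single_R=179, double=0
)

# Male spermatogenesis: k_L = round(0.150*687) = 103, k_R = round(0.378*687)
# = 260, doubles = 12; singles are interval recombinants minus doubles.
SPERM_COUNTS = CrossoverCounts(
    n=687, parental=336, single_L=91, single_R=248, double=12
)

#: Published oocyte parameters: complete interference (no doubles seen).
OOCYTE_PARAMS = RecombinationParams(p_L=0.131, p_R=0.362, interference=100.0)

#: Published spermatocyte parameters, interference at the fitted 69.2%.
SPERM_PARAMS = RecombinationParams(p_L=0.150, p_R=0.378, interference=69.2)

SELFING_N_WILDTYPE = 845
SELFING_OBSERVED_DOUBLES = 2

#: Published headline values, used by the reproduction pipeline's
#: pass/fail flags (keys are descriptive; values as printed).
REFERENCE_VALUES = {
    "oocyte_total_recombination_pct": 49.3,
    "sperm_total_recombination_pct": 52.8,
    "oocyte_expected_double_pct_no_interference": 4.75,
    "oocyte_expected_doubles": 24,
    "sperm_expected_doubles": 39,
    "sperm_interference_pct": 69.2,
    "sperm_doubles_of_products_pct": 3.4,
    "selfing_expected_detectable": 3,
    "fisher_doubles_vs_singles_p": 0.002,
}
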