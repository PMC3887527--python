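"""File I/O and run configuration.

Canonical tabular dialect: TSV with a header row, UTF-8, Unix newlines.
Per-animal record tables have columns (design, maternal_haplotype,
paternal_haplotype, category, phenotype, passed_selection); haplotypes are
written as three-character strings over {m, w} and phenotypes as
'+'-joined trait labels ('' for wild-type).  Counts tables have columns
(category, count).  Reports serialise to JSON at full precision.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import List, Optional, Sequence, Union

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .model import CHROMOSOME_V_MARKERS, MarkerTriplet, RecombinationParams
from .simulate import (
    CrossoverCounts,
    DesignId,
    SimulatedProgenyRecord,
)
from .analysis import InterferenceReport

__all__ = [
    "RunConfig",
    "load_config",
    "load_markers",
    "default_markers_path",
    "write_records_tsv",
    "read_records_tsv",
    "write_counts_tsv",
    "read_counts_tsv",
    "report_to_dict",
    "write_report_json",
    "format_report_text",
]

_RECORD_COLUMNS = [
    "design",
    "maternal_haplotype",
    "paternal_haplotype",
    "category",
    "phenotype",
    "passed_selection",
]


class GameteParams(BaseModel):
    """Recombination parameters for one gamete pool, as configured."""

    model_config = ConfigDict(extra="forbid")

    p_L: float
    p_R: float
    interference: float = 0.0

    def to_params(self) -> RecombinationParams:
        return RecombinationParams(
            p_L=self.p_L, p_R=self.p_R, interference=self.interference
        )


class RunConfig(BaseModel):
    """Schema-validated simulation/analysis run configuration.

    Unknown keys are rejected.  ``seed`` is mandatory for simulation
    designs; selfing requires both gamete parameter blocks, outcrosses
    exactly one (matching the design's informative pool).
    """

    model_config = ConfigDict(extra="forbid")

    design_id: DesignId
    oocyte: Optional[GameteParams] = None
    sperm: Optional[GameteParams] = None
    n: int = Field(gt=0)
    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)
    seed: int
    out_records: Optional[str] = None
    out_counts: Optional[str] = None

    @model_validator(mode="after")
    def _check_params_for_design(self) -> "RunConfig":
        if self.design_id is DesignId.SELF_FERTILIZATION:
            if self.oocyte is None or self.sperm is None:
                raise ValueError(
                    "self_fertilization requires both 'oocyte' and 'sperm' blocks"
                )
        elif self.design_id is DesignId.OOCYTE_OUTCROSS:
            if self.oocyte is None or self.sperm is not None:
                raise ValueError("oocyte_outcross takes exactly the 'oocyte' block")
        else:
            if self.sperm is None or self.oocyte is not None:
                raise ValueError(
                    "male_sperm_outcross takes exactly the 'sperm' block"
                )
        return self


def load_config(path: Union[str, Path]) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        return RunConfig.model_validate(json.load(fh))


def default_markers_path() -> Path:
    return Path(__file__).parent / "data" / "chrV_markers.json"


def load_markers(path: Optional[Union[str, Path]] = None) -> MarkerTriplet:
    """Load a marker triplet from JSON (the shipped chromosome-V triple by default)."""
    path = Path(path) if path is not None else default_markers_path()
    with open(path, "r", encoding="utf-8") as fh:
        raw = json.load(fh)
    allowed = {"names", "mutant_phenotypes", "recessive", "phase"}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown marker-config keys: {sorted(unknown)}")
    return MarkerTriplet(
        names=tuple(raw["names"]),
        mutant_phenotypes=tuple(raw["mutant_phenotypes"]),
        recessive=tuple(raw.get("recessive", (True, True, True))),
        phase=raw.get("phase", "cis"),
    )


def _haplotype_str(h) -> str:
    return "".join(h)


def _parse_haplotype(s: str):
    if len(s) != 3 or any(c not in "mw" for c in s):
        raise ValueError(f"bad haplotype string {s!r}")
    return tuple(s)


def records_to_frame(
    records: Sequence[SimulatedProgenyRecord],
    markers: MarkerTriplet = CHROMOSOME_V_MARKERS,
) -> pd.DataFrame:
    from .model import classify_gamete

    rows = []
    for r in records:
        try:
            cat = classify_gamete(r.informative_gamete()).value
        except ValueError:  # selfing: no single informative gamete
            cat = ""
        rows.append(
            {
                "design": r.design_id.value,
                "maternal_haplotype": _haplotype_str(r.maternal_gamete),
                "paternal_haplotype": _haplotype_str(r.paternal_gamete),
                "category": cat,
                "phenotype": "+".join(sorted(r.phenotype(markers).visible_traits)),
                "passed_selection": r.passed_selection,
            }
        )
    return pd.DataFrame(rows, columns=_RECORD_COLUMNS)


def write_records_tsv(
    records: Sequence[SimulatedProgenyRecord],
    path: Union[str, Path],
    markers: MarkerTriplet = CHROMOSOME_V_MARKERS,
) -> None:
    records_to_frame(records, markers).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_records_tsv(path: Union[str, Path]) -> List[SimulatedProgenyRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"record TSV missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            SimulatedProgenyRecord(
                design_id=DesignId(row.design),
                maternal_gamete=_parse_haplotype(row.maternal_haplotype),
                paternal_gamete=_parse_haplotype(row.paternal_haplotype),
                passed_selection=row.passed_selection in ("True", "true", "1"),
            )
        )
    return out


def write_counts_tsv(counts: CrossoverCounts, path: Union[str, Path]) -> None:
    pd.DataFrame(
        {"category": list(counts.as_dict()), "count": list(counts.as_dict().values())}
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_counts_tsv(path: Union[str, Path]) -> CrossoverCounts:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["category", "count"]:
        raise ValueError(
            f"counts TSV must have columns [category, count], got {list(df.columns)}"
        )
    if (df["count"] < 0).any():
        raise ValueError("negative counts in counts TSV")
    return CrossoverCounts.from_dict(dict(zip(df["category"], df["count"])))


def report_to_dict(report: InterferenceReport) -> dict:
    d = dataclasses.asdict(report)
    d["counts"] = report.counts.as_dict() | {"n": report.counts.n}
    return d


def write_report_json(report: InterferenceReport, path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report_to_dict(report), fh, indent=2)
        fh.write("\n")


def format_report_text(report: InterferenceReport) -> str:
    """Human-readable one-experiment summary, percentages to one decimal."""
    r = report
    lines = [
        f"n meiotic products analyzed       {r.counts.n}",
        f"interval L recombination %        {100 * r.interval_L.p_hat:.1f}"
        f"  (95% CI {100 * r.interval_L.ci_low:.1f}-{100 * r.interval_L.ci_high:.1f})",
        f"interval R recombination %        {100 * r.interval_R.p_hat:.1f}"
        f"  (95% CI {100 * r.interval_R.ci_low:.1f}-{100 * r.interval_R.ci_high:.1f})",
        f"total recombination %             {r.total_recombination_pct:.1f}",
        f"observed double crossovers        {r.observed_doubles}",
        f"expected doubles (no interference) {r.expected_doubles:.2f} (~{r.expected_doubles_int})",
        f"doubles of crossover products %   {r.doubles_of_crossover_products_pct:.1f}",
        f"interference %                    {r.interference_pct:.1f}",
        f"interference CI (two-sided)       {r.interference_ci[0]:.1f}-{r.interference_ci[1]:.1f}",
        f"interference CI (one-sided)       {r.interference_ci_one_sided[0]:.1f}-{r.interference_ci_one_sided[1]:.1f}",
        f"caveat: {r.caveat}",
    ]
    return "\n".join(lines)
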