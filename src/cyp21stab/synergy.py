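"""Combined effect of two variants in cis: additivity, synergy, scenarios.

Two variants on the same allele damage the same protein molecule. The
additive expectation for the combined destabilization is the sum of the two
single-variant ∆∆G values; a combined estimate from a double-mutant
predictor run can deviate from that sum, and the deviation
(``ddg_double − (ddg_1 + ddg_2)``, positive = worse than additive) is the
synergy score. Classification relative to the 1.6 kcal/mol destabilization
cutoff distinguishes trivially pathogenic pairs, additive pathogenicity,
rescue by a stabilizing partner, and genuine positive/negative synergy.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .stability_adapter import AnalysisConfig
from .variants_io import ProteinVariant

#: Default |synergy| (kcal/mol) below which a deviation from additivity is
#: within predictor noise: one predictor SD (the 1.6 kcal/mol cutoff is two).
DEFAULT_SYNERGY_TOLERANCE = 0.8


class Scenario(enum.Enum):
    BOTH_ABOVE = "both_above"
    ADDITIVE_PATHOGENIC = "additive_pathogenic"
    COMBINED_RESCUE = "combined_rescue"
    NEGATIVE_SYNERGY = "negative_synergy"
    POSITIVE_SYNERGY = "positive_synergy"
    SYNERGY_SUBTHRESHOLD_PATHOGENIC = "synergy_subthreshold_pathogenic"
    ADDITIVE_NONPATHOGENIC = "additive_nonpathogenic"


@dataclass
class DoubleVariantRecord:
    variant_1: Optional[ProteinVariant]
    variant_2: Optional[ProteinVariant]
    ddg_1: float
    ddg_2: float
    ddg_double: Optional[float] = None
    additive_sum: float = field(init=False)
    synergy: Optional[float] = field(init=False)
    scenario: Optional[Scenario] = None
    pathogenic_combined: Optional[bool] = None
    near_cutoff: Optional[bool] = None

    def __post_init__(self) -> None:
        self.additive_sum = additive_baseline(self.ddg_1, self.ddg_2)
        self.synergy = (
            synergy_score(self.ddg_double, self.ddg_1, self.ddg_2)
            if self.ddg_double is not None
            else None
        )

    @property
    def effective_ddg(self) -> float:
        """Combined estimate when available, otherwise the additive sum."""
        return self.ddg_double if self.ddg_double is not None else self.additive_sum


def additive_baseline(ddg_1: float, ddg_2: float) -> float:
    """Expected combined ∆∆G under no interaction: the exact sum."""
    if not (math.isfinite(ddg_1) and math.isfinite(ddg_2)):
        raise ValueError("single-variant ∆∆G values must be finite")
    return ddg_1 + ddg_2


def synergy_score(ddg_double: float, ddg_1: float, ddg_2: float) -> float:
    """Deviation of the combined estimate from additivity.

    Positive = the double mutant is more destabilized than the sum of its
    parts; zero = no interaction.
    """
    if not math.isfinite(ddg_double):
        raise ValueError("ddg_double must be finite")
    return ddg_double - additive_baseline(ddg_1, ddg_2)


def classify_double(
    record: DoubleVariantRecord,
    cfg: AnalysisConfig = AnalysisConfig(),
    synergy_tolerance: float = DEFAULT_SYNERGY_TOLERANCE,
) -> DoubleVariantRecord:
    """Assign the scenario, combined pathogenicity and near-cutoff flag.

    The decision cascade (first match wins; T = destabilization cutoff):

    1. both singles > T                       -> both_above
    2. >=1 single > T, combined estimate <= T -> combined_rescue
    3. no single > T, sum <= T, combined > T  -> synergy_subthreshold_pathogenic
    4. sum > T, combined <= T, |synergy| > tolerance -> negative_synergy
    5. sum <= T, combined > T, |synergy| > tolerance -> positive_synergy
    6. otherwise: additive_pathogenic when the effective combined ∆∆G > T,
       else additive_nonpathogenic.

    Without a combined estimate the effective ∆∆G is the additive sum and
    only the additive subset of scenarios (1, 2, 6) can fire. A combined
    estimate exactly equal to the sum has zero synergy and can never produce
    a synergy scenario.
    """
    threshold = cfg.destabilization_threshold
    d1_above = record.ddg_1 > threshold
    d2_above = record.ddg_2 > threshold
    sum_above = record.additive_sum > threshold
    effective = record.effective_ddg
    effective_above = effective > threshold

    if d1_above and d2_above:
        scenario = Scenario.BOTH_ABOVE
    elif (d1_above or d2_above) and not effective_above:
        scenario = Scenario.COMBINED_RESCUE
    elif record.ddg_double is not None:
        comb_above = record.ddg_double > threshold
        big_synergy = abs(record.synergy) > synergy_tolerance
        if not d1_above and not d2_above and not sum_above and comb_above:
            scenario = Scenario.SYNERGY_SUBTHRESHOLD_PATHOGENIC
        elif sum_above and not comb_above and big_synergy:
            scenario = Scenario.NEGATIVE_SYNERGY
        elif not sum_above and comb_above and big_synergy:
            scenario = Scenario.POSITIVE_SYNERGY
        elif effective_above:
            scenario = Scenario.ADDITIVE_PATHOGENIC
        else:
            scenario = Scenario.ADDITIVE_NONPATHOGENIC
    elif effective_above:
        scenario = Scenario.ADDITIVE_PATHOGENIC
    else:
        scenario = Scenario.ADDITIVE_NONPATHOGENIC

    record.scenario = scenario
    record.pathogenic_combined = effective_above
    record.near_cutoff = abs(effective - threshold) <= synergy_tolerance / 2
    return record


def analyze_double_table(
    records: Sequence[DoubleVariantRecord],
    cfg: AnalysisConfig = AnalysisConfig(),
    synergy_tolerance: float = DEFAULT_SYNERGY_TOLERANCE,
) -> pd.DataFrame:
    """Classify a batch of in-cis pairs into a report table."""
    rows = []
    for record in records:
        classify_double(record, cfg, synergy_tolerance)
        rows.append(
            {
                "variant_1": record.variant_1.label if record.variant_1 else "",
                "variant_2": record.variant_2.label if record.variant_2 else "",
                "ddg_1": record.ddg_1,
                "ddg_2": record.ddg_2,
                "ddg_double": record.ddg_double,
                "additive_sum": record.additive_sum,
                "synergy": record.synergy,
                "scenario": record.scenario.value,
                "pathogenic_combined": record.pathogenic_combined,
                "near_cutoff": record.near_cutoff,
            }
        )
    return pd.DataFrame(rows)
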