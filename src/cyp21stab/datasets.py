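"""Published reference values for CYP21A2 stability variants.

Two small tables from the published survey of CYP21A2 coding variants are
shipped in-package so the calibration can be reconstructed and checked
offline:

* the in-silico survey: 32 stability-class missense variants lacking
  functional assays, with the bovine-template mean ∆∆G (kcal/mol) and the
  published in-silico residual activity (% of wild type, display-rounded);
* the validation set: variants with post-2013 in vitro assays, with
  published activities for both templates.

Also included: the two common polymorphisms whose in-cis combination
approaches the destabilization cutoff, and the bovine-template ∆∆G of the
novel stabilizing variant p.P335L.
"""

from __future__ import annotations

import pandas as pd

from .calibration import CalibrationPair
from .stability_adapter import AnalysisConfig, Template
from .variants_io import parse_protein_variant

# (variant, bovine-template mean ddG kcal/mol, published in-silico activity %)
_STABILITY_SURVEY = [
    ("p.H38L", -1.64, 100.0),
    ("p.Y47C", -1.64, 100.0),
    ("p.Y59N", 2.54, 4.4),
    ("p.V69L", 1.47, 22.5),
    ("p.S113Y", 0.79, 63.3),
    ("p.S113F", 1.05, 42.6),
    ("p.Q144P", 0.61, 83.2),
    ("p.F164S", 1.37, 26.2),
    ("p.S165P", 4.94, 0.1),
    ("p.T168N", 3.41, 1.2),
    ("p.V211L", -0.91, 100.0),
    ("p.E238K", -0.33, 100.0),
    ("p.V249A", 0.45, 100.0),
    ("p.L261P", 8.95, 0.01),
    ("p.M283L", -0.3, 100.0),
    ("p.S301Y", 12.31, 0.00),
    ("p.V304E", 2.44, 5.1),
    ("p.V305D", 0.99, 46.6),
    ("p.F306V", 1.87, 12.2),
    ("p.L307V", 2.8, 2.9),
    ("p.R316L", 0.03, 100.0),
    ("p.L317M", -0.8, 100.0),
    ("p.L317V", 2.42, 5.3),
    ("p.L321P", 9.84, 0.0),
    ("p.G381S", 3.51, 1.0),
    ("p.N387K", 7.55, 0.0),
    ("p.F404S", 5.34, 0.06),
    ("p.F404L", 2.51, 4.6),
    ("p.T450P", 9.35, 0.0),
    ("p.P459H", 4.44, 0.2),
    ("p.P459S", 2.68, 3.6),
    ("p.P459L", 1.29, 29.5),
]

# (variant, in vitro 17-OHP activity %, SD %, in-silico bovine %, bovine
# capped, in-silico human %, human capped); None = not determined.
_VALIDATION_ASSAYS = [
    ("p.P45L", 105.0, 10.0, 0.74, False, 1.46, False),
    ("p.K102R", 119.7, 25.0, 63.16, False, 100.0, True),
    ("p.L122P", 1.4, 2.1, 0.11, False, 0.25, False),
    ("p.R149C", 35.8, 14.6, 100.0, True, 100.0, True),
    ("p.M150R", 17.7, 1.9, 0.9, False, 4.4, False),
    ("p.A159T", 126.6, 29.9, 100.0, True, 100.0, True),
    ("p.V211M", 99.5, 32.4, 100.0, True, 100.0, True),
    ("p.A265S", 90.0, 9.0, 100.0, True, 100.0, True),
    ("p.M283V", 16.2, 9.3, 41.8, False, 38.14, False),
    ("p.M473I", 85.0, 7.0, 100.0, True, 64.12, False),
]

#: Single-variant mean ∆∆G (bovine template, kcal/mol) of the two common
#: polymorphisms whose in-cis combination approaches the 1.6 kcal/mol cutoff.
SNP_PAIR_DDG = {"p.K102R": 0.81, "p.S268T": 0.74}
SNP_PAIR_COMBINED_DDG = 1.55

#: Bovine-template ∆∆G of the novel stabilizing variant (predicted ≥100%).
NOVEL_P335L_DDG_BOVINE = -2.16
NOVEL_P335L_DDG_SD = 0.15


def stability_survey() -> pd.DataFrame:
    """The 32-variant in-silico survey (bovine template)."""
    return pd.DataFrame(
        _STABILITY_SURVEY, columns=["variant", "ddg", "insilico_activity_pct"]
    )


def validation_assays() -> pd.DataFrame:
    """The post-2013 in vitro validation set with both templates' predictions."""
    return pd.DataFrame(
        _VALIDATION_ASSAYS,
        columns=[
            "variant", "invitro_17ohp_pct", "invitro_sd_pct",
            "insilico_bovine_pct", "bovine_capped",
            "insilico_human_pct", "human_capped",
        ],
    )


def calibration_fit_set(cfg: AnalysisConfig = AnalysisConfig()) -> list[CalibrationPair]:
    """Informative survey rows for refitting the published calibration line.

    Rows with activity printed as 100 are cap-saturated and rows below 0.05
    are rounding-degenerate; neither constrains the line, so the fit keeps
    activities in [0.05, 100) with ∆∆G at most the fitting cap (19 rows).
    """
    pairs = []
    for label, ddg, activity in _STABILITY_SURVEY:
        if 0.05 <= activity < 100.0 and ddg <= cfg.ddg_fit_cap:
            pairs.append(
                CalibrationPair(
                    ddg=ddg,
                    activity_pct=activity,
                    variant=parse_protein_variant(label),
                    template=Template.BOVINE_3QZ1_MODEL,
                )
            )
    return pairs
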