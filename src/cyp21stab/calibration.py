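"""Log-linear calibration of residual enzyme activity against ∆∆G.

The model is ln(activity%) = a + b·∆∆G fitted by unweighted least squares,
with ∆∆G clamped at a cap (default 5.5 kcal/mol) before fitting because
mutants destabilized beyond that point all sit at ~0% activity and carry no
information about the line. Predictions for new variants use the raw ∆∆G
(the cap applies to fitting only) and clamp at 100% activity, reported as
"≥100". Monotonicity of the relation is summarised by Spearman's rank
correlation; significance of both the correlation and the regression slope
comes from label-permutation tests (exhaustive for small n, seeded sampling
otherwise).

Predicted activities map onto clinical severity bands of 21-hydroxylase
deficiency: near-complete loss (<1%) behaves like salt-wasting (SW) alleles,
~1–5% like simple-virilizing (SV), 10–60% like non-classical (NC), and
predictions above 75% are considered non-pathogenic.
"""

from __future__ import annotations

import enum
import itertools
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .stability_adapter import AnalysisConfig, Template
from .variants_io import ProteinVariant, Substrate

logger = logging.getLogger(__name__)

DEFAULT_N_PERMUTATIONS = 10_000
EXHAUSTIVE_N_MAX = 7  # at most 7! = 5040 permutations enumerated exactly


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationPair:
    """One (∆∆G, activity) point for fitting; activity must be positive."""

    ddg: float
    activity_pct: float
    variant: Optional[ProteinVariant] = None
    substrate: Optional[Substrate] = None
    template: Optional[Template] = None
    capped: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.ddg):
            raise ValueError("ddg must be finite")
        if not math.isfinite(self.activity_pct) or self.activity_pct <= 0:
            raise ValueError(
                f"activity_pct must be positive and finite, got {self.activity_pct}"
            )


@dataclass
class CalibrationModel:
    intercept_a: float  # ln(percent)
    slope_b: float  # per kcal/mol
    ddg_fit_cap: float
    n_pairs: int
    r_squared: float
    spearman_rho: Optional[float]
    p_spearman: Optional[float]
    p_slope: Optional[float]
    template: Optional[Template] = None
    substrate: Optional[Substrate] = None
    seed: Optional[int] = None


class Pathogenicity(enum.Enum):
    NON_PATHOGENIC = "non_pathogenic"
    PATHOGENIC_CANDIDATE = "pathogenic_candidate"


class SeverityBand(enum.Enum):
    SW_LIKE = "SW_like"
    SV_LIKE = "SV_like"
    NC_LIKE = "NC_like"
    INDETERMINATE = "indeterminate"
    NORMAL_LIKE = "normal_like"


@dataclass(frozen=True)
class SeverityBands:
    """Activity (%) edges of the clinical severity bands; all configurable."""

    sw_max: float = 1.0      # below this: SW-like (near-total loss)
    sv_min: float = 1.0      # [sv_min, sv_max]: SV-like
    sv_max: float = 5.0
    nc_min: float = 10.0     # [nc_min, nc_max]: NC-like
    nc_max: float = 60.0
    normal_min: float = 75.0  # above this: normal-like / non-pathogenic


@dataclass
class PredictionResult:
    ddg_mean: float
    activity_pred_pct: float  # clamped at the cap
    capped_flag: bool
    activity_raw_pct: float  # before clamping
    variant: Optional[ProteinVariant] = None
    template: Optional[Template] = None
    pathogenicity_call: Optional[Pathogenicity] = None
    severity_band: Optional[SeverityBand] = None


@dataclass
class SpearmanResult:
    rho: Optional[float]
    degenerate: bool = False
    reason: str = ""


# --------------------------------------------------------------------------
# Rank correlation
# --------------------------------------------------------------------------

def spearman_rho(pairs: Sequence[CalibrationPair]) -> SpearmanResult:
    """Spearman rank correlation (midrank ties) of ln(activity) against ∆∆G.

    Constant x or y makes the statistic undefined; an explicit degenerate
    result is returned instead of a number.
    """
    if len(pairs) < 3:
        raise CalibrationError("spearman_rho needs at least 3 pairs")
    x = np.array([p.ddg for p in pairs])
    y = np.array([p.activity_pct for p in pairs])
    if np.all(x == x[0]):
        return SpearmanResult(None, degenerate=True, reason="constant ddg")
    if np.all(y == y[0]):
        return SpearmanResult(None, degenerate=True, reason="constant activity")
    rho = float(stats.spearmanr(x, y).statistic)
    return SpearmanResult(rho)


def _spearman_xy(x: np.ndarray, y: np.ndarray) -> Optional[float]:
    if np.all(x == x[0]) or np.all(y == y[0]):
        return None
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float((rx ** 2).sum() * (ry ** 2).sum()))
    if denom == 0:
        return None
    return float((rx * ry).sum() / denom)


def _slope_xy(x: np.ndarray, y: np.ndarray) -> Optional[float]:
    if np.all(x == x[0]):
        return None
    xc = x - x.mean()
    return float((xc * (y - y.mean())).sum() / (xc ** 2).sum())


# --------------------------------------------------------------------------
# Permutation tests
# --------------------------------------------------------------------------

def permutation_pvalue(
    pairs: Sequence[CalibrationPair],
    statistic: str = "rho",
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
) -> float:
    """Two-sided label-permutation p-value for Spearman rho or the LS slope.

    Activity labels are permuted against the ∆∆G values. For n ≤ 7 all n!
    permutations are enumerated and the p-value is exact
    (#{|stat| ≥ |observed|} / n!); otherwise ``n_perm`` seeded draws are used
    with the add-one estimator (1 + #extreme) / (1 + n_perm). A degenerate
    observed statistic yields p = 1.0.
    """
    if len(pairs) < 3:
        raise CalibrationError("permutation test needs at least 3 pairs")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    stat_fn = {"rho": _spearman_xy, "slope": _slope_xy}[statistic]
    x = np.array([p.ddg for p in pairs])
    y = np.array(
        [math.log(p.activity_pct) for p in pairs]
        if statistic == "slope"
        else [p.activity_pct for p in pairs]
    )
    observed = stat_fn(x, y)
    if observed is None:
        return 1.0
    n = len(x)
    if n <= EXHAUSTIVE_N_MAX:
        extreme = total = 0
        for perm in itertools.permutations(range(n)):
            value = stat_fn(x, y[list(perm)])
            total += 1
            if value is not None and abs(value) >= abs(observed) - 1e-12:
                extreme += 1
        return extreme / total
    rng = np.random.default_rng(seed)
    extreme = 0
    for _ in range(n_perm):
        value = stat_fn(x, rng.permutation(y))
        if value is not None and abs(value) >= abs(observed) - 1e-12:
            extreme += 1
    return (1 + extreme) / (1 + n_perm)


# --------------------------------------------------------------------------
# Fitting and prediction
# --------------------------------------------------------------------------

def fit_calibration(
    pairs: Iterable[CalibrationPair],
    cfg: AnalysisConfig = AnalysisConfig(),
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    template: Optional[Template] = None,
    substrate: Optional[Substrate] = None,
) -> CalibrationModel:
    """Least-squares fit of ln(activity%) on cap-clamped ∆∆G.

    Each ∆∆G is replaced by min(∆∆G, cfg.ddg_fit_cap) before fitting.
    Diagnostics: R² of the fit, Spearman rho on the capped pairs, and
    permutation p-values for rho and the slope.
    """
    usable = list(pairs)
    if len(usable) < 3:
        raise CalibrationError(
            f"calibration needs at least 3 pairs with positive activity, "
            f"got {len(usable)}"
        )
    capped = [replace(p, ddg=min(p.ddg, cfg.ddg_fit_cap)) for p in usable]
    x = np.array([p.ddg for p in capped])
    y = np.log([p.activity_pct for p in capped])
    if np.all(x == x[0]):
        raise CalibrationError("all ∆∆G values identical; slope undefined")
    result = stats.linregress(x, y)
    slope, intercept = float(result.slope), float(result.intercept)
    r_squared = float(result.rvalue ** 2)
    if slope >= 0:
        logger.warning(
            "fitted slope %.3f is non-negative; destabilization should "
            "reduce activity", slope,
        )
    rho_result = spearman_rho(capped)
    p_rho = p_slope = None
    if not rho_result.degenerate:
        p_rho = permutation_pvalue(capped, "rho", n_perm, seed)
        p_slope = permutation_pvalue(capped, "slope", n_perm, seed)
    return CalibrationModel(
        intercept_a=intercept,
        slope_b=slope,
        ddg_fit_cap=cfg.ddg_fit_cap,
        n_pairs=len(capped),
        r_squared=r_squared,
        spearman_rho=rho_result.rho,
        p_spearman=p_rho,
        p_slope=p_slope,
        template=template,
        substrate=substrate,
        seed=seed,
    )


def build_pairs(
    ddg_activity: Iterable[tuple[float, float]], **kwargs
) -> list[CalibrationPair]:
    """Convenience: pairs from raw (∆∆G, activity%) tuples, dropping
    non-positive activities with a logged reason (ln undefined)."""
    pairs = []
    for ddg, activity in ddg_activity:
        if activity <= 0:
            logger.info("dropping pair (ddg=%.3g, activity=%.3g): "
                        "non-positive activity has no logarithm", ddg, activity)
            continue
        pairs.append(CalibrationPair(ddg, activity, **kwargs))
    return pairs


def predict_activity(
    model: CalibrationModel,
    ddg_mean: float,
    cfg: AnalysisConfig = AnalysisConfig(),
    variant: Optional[ProteinVariant] = None,
) -> PredictionResult:
    """Predicted residual activity exp(a + b·∆∆G), clamped at the activity cap.

    The fitting cap does not apply here: predictions use the raw ∆∆G, so two
    strongly destabilized variants with different ∆∆G get distinct (tiny)
    activities.
    """
    if model is None:
        raise ValueError("model must be fitted before predicting")
    raw = math.exp(model.intercept_a + model.slope_b * ddg_mean)
    capped = raw > cfg.activity_cap
    value = min(raw, cfg.activity_cap)
    return PredictionResult(
        ddg_mean=ddg_mean,
        activity_pred_pct=value,
        capped_flag=capped,
        activity_raw_pct=raw,
        variant=variant,
        template=model.template,
    )


def call_pathogenicity(
    prediction: PredictionResult,
    cfg: AnalysisConfig = AnalysisConfig(),
    bands: SeverityBands = SeverityBands(),
) -> PredictionResult:
    """Attach the pathogenicity call and clinical severity band.

    Non-pathogenic iff predicted activity strictly exceeds the 75% threshold.
    Severity: <1% SW-like, 1–5% SV-like, 10–60% NC-like, >75% normal-like;
    the gaps between bands are indeterminate.
    """
    activity = prediction.activity_pred_pct
    call = (
        Pathogenicity.NON_PATHOGENIC
        if activity > cfg.nonpathogenic_activity_threshold
        else Pathogenicity.PATHOGENIC_CANDIDATE
    )
    if activity > bands.normal_min:
        band = SeverityBand.NORMAL_LIKE
    elif activity < bands.sw_max:
        band = SeverityBand.SW_LIKE
    elif bands.sv_min <= activity <= bands.sv_max:
        band = SeverityBand.SV_LIKE
    elif bands.nc_min <= activity <= bands.nc_max:
        band = SeverityBand.NC_LIKE
    else:
        band = SeverityBand.INDETERMINATE
    prediction.pathogenicity_call = call
    prediction.severity_band = band
    return prediction
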