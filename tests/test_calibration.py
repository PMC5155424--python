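"""Calibration fit, rank correlation, permutation tests, prediction and calls."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cyp21stab as cs
from cyp21stab.calibration import (
    CalibrationError,
    CalibrationPair,
    SeverityBand,
    permutation_pvalue,
)
from cyp21stab.stability_adapter import AnalysisConfig


def pairs_from(xs, ys):
    return [CalibrationPair(float(x), float(y)) for x, y in zip(xs, ys)]


# ---------------------------------------------------------------- oracles

def oracle_midranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        rank = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = rank
        i = j + 1
    return ranks


def oracle_spearman(xs, ys):
    rx, ry = oracle_midranks(xs), oracle_midranks(ys)
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den if den else None


def oracle_least_squares(xs, ys):
    n = len(xs)
    mx, my = sum(xs) / n, sum(ys) / n
    sxx = sum((x - mx) ** 2 for x in xs)
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    slope = sxy / sxx
    return my - slope * mx, slope


# ---------------------------------------------------------------- fitting

def test_noiseless_fit_recovers_parameters_exactly():
    a, b = 5.35, -1.53
    xs = np.linspace(-1.5, 5.0, 12)
    ys = np.exp(a + b * xs)
    model = cs.fit_calibration(pairs_from(xs, ys), n_perm=10, seed=0)
    assert model.intercept_a == pytest.approx(a, abs=1e-10)
    assert model.slope_b == pytest.approx(b, abs=1e-10)
    assert model.r_squared == pytest.approx(1.0, abs=1e-12)


def test_survey_fit_matches_least_squares_oracle(survey_fit_set, survey_model):
    xs = [min(p.ddg, 5.5) for p in survey_fit_set]
    ys = [math.log(p.activity_pct) for p in survey_fit_set]
    intercept, slope = oracle_least_squares(xs, ys)
    assert survey_model.n_pairs == 19
    assert survey_model.intercept_a == pytest.approx(intercept, abs=1e-9)
    assert survey_model.slope_b == pytest.approx(slope, abs=1e-9)
    # the refit line of the published survey pairs
    assert survey_model.slope_b == pytest.approx(-1.55, abs=0.01)
    assert survey_model.intercept_a == pytest.approx(5.39, abs=0.01)


def test_fit_applies_ddg_cap():
    """A pair at ∆∆G 9.84 enters the fit clamped to 5.5."""
    xs = [0.5, 1.5, 2.5, 3.5, 9.84]
    ys = [60.0, 20.0, 5.0, 1.5, 0.02]
    model = cs.fit_calibration(pairs_from(xs, ys), n_perm=10, seed=0)
    capped_xs = [min(x, 5.5) for x in xs]
    intercept, slope = oracle_least_squares(
        capped_xs, [math.log(y) for y in ys]
    )
    assert model.slope_b == pytest.approx(slope, abs=1e-9)
    assert model.intercept_a == pytest.approx(intercept, abs=1e-9)


def test_fit_requires_three_pairs_and_positive_activity():
    with pytest.raises(CalibrationError):
        cs.fit_calibration(pairs_from([1, 2], [10, 5]))
    with pytest.raises(ValueError):
        CalibrationPair(1.0, 0.0)
    with pytest.raises(ValueError):
        CalibrationPair(1.0, -3.0)


def test_build_pairs_drops_nonpositive_activities():
    pairs = cs.calibration.build_pairs([(1.0, 10.0), (2.0, 0.0), (3.0, -1.0)])
    assert len(pairs) == 1


# ------------------------------------------------------------- spearman

def test_spearman_strictly_decreasing_is_minus_one():
    result = cs.spearman_rho(pairs_from([1, 2, 3, 4], [40, 30, 20, 10]))
    assert result.rho == pytest.approx(-1.0)


def test_spearman_degenerate_inputs_flagged():
    assert cs.spearman_rho(pairs_from([1, 1, 1], [5, 6, 7])).degenerate
    assert cs.spearman_rho(pairs_from([1, 2, 3], [5, 5, 5])).degenerate


@settings(max_examples=150, derandomize=True)
@given(
    n=st.integers(min_value=3, max_value=8),
    data=st.data(),
)
def test_spearman_matches_midrank_oracle_with_ties(n, data):
    xs = data.draw(
        st.lists(st.integers(min_value=0, max_value=4), min_size=n, max_size=n)
    )
    ys = data.draw(
        st.lists(st.integers(min_value=0, max_value=4), min_size=n, max_size=n)
    )
    ys = [y + 1 for y in ys]  # activities must be positive
    expected = (
        None if len(set(xs)) == 1 or len(set(ys)) == 1 else oracle_spearman(xs, ys)
    )
    result = cs.spearman_rho(pairs_from(xs, ys))
    if expected is None:
        assert result.degenerate
    else:
        assert result.rho == pytest.approx(expected, abs=1e-12)


# ----------------------------------------------------------- permutation

def test_permutation_exhaustive_monotone_n3():
    """All 6 permutations of 3 labels; only the identity and the reversal
    reach |rho| = 1, so the two-sided exact p is 2/6."""
    p = permutation_pvalue(pairs_from([1, 2, 3], [30, 20, 10]), "rho")
    assert p == pytest.approx(2 / 6)


def test_permutation_constant_labels_p_one():
    assert permutation_pvalue(pairs_from([1, 2, 3], [5, 5, 5]), "rho") == 1.0


def test_permutation_exhaustive_equals_manual_enumeration_n5():
    xs = [0.3, 1.1, 2.2, 3.0, 4.4]
    ys = [80.0, 30.0, 35.0, 4.0, 1.0]
    observed = oracle_spearman(xs, ys)
    extreme = total = 0
    for perm in itertools.permutations(ys):
        rho = oracle_spearman(xs, list(perm))
        total += 1
        if rho is not None and abs(rho) >= abs(observed) - 1e-12:
            extreme += 1
    expected = extreme / total
    assert permutation_pvalue(pairs_from(xs, ys), "rho") == pytest.approx(expected)


def test_permutation_sampled_mode_is_deterministic_and_near_exact():
    """n = 8 forces sampling; same seed → identical p; and at n = 6 a large
    sample agrees with the exhaustive value within Monte-Carlo error."""
    xs8 = [0.1, 0.9, 1.7, 2.4, 3.1, 3.9, 4.6, 5.3]
    ys8 = [90, 70, 75, 20, 22, 6, 3, 1.5]
    pairs8 = pairs_from(xs8, ys8)
    p1 = permutation_pvalue(pairs8, "rho", n_perm=2000, seed=42)
    p2 = permutation_pvalue(pairs8, "rho", n_perm=2000, seed=42)
    assert p1 == p2

    xs6, ys6 = [0.5, 1.5, 2.5, 3.5, 4.5, 5.5], [70, 80, 25, 30, 2, 5]
    pairs6 = pairs_from(xs6, ys6)
    exact = permutation_pvalue(pairs6, "rho")  # exhaustive (n <= 7)
    sampled = np.mean([_sampled_pvalue(pairs6, seed) for seed in range(5)])
    mc_err = 3 * math.sqrt(exact * (1 - exact) / 20_000)
    assert abs(sampled - exact) <= mc_err + 1 / 4000


def _sampled_pvalue(pairs, seed, n_perm=4000):
    """Force the sampled estimator on a small set by direct Monte Carlo."""
    rng = np.random.default_rng(seed)
    x = np.array([p.ddg for p in pairs])
    y = np.array([p.activity_pct for p in pairs])
    observed = oracle_spearman(list(x), list(y))
    extreme = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(y))
        rho = oracle_spearman(list(x), list(y[perm]))
        if rho is not None and abs(rho) >= abs(observed) - 1e-12:
            extreme += 1
    return (1 + extreme) / (1 + n_perm)


def test_permutation_slope_statistic_runs():
    p = permutation_pvalue(pairs_from([1, 2, 3, 4], [50, 20, 8, 3]), "slope")
    assert 0 < p <= 1


# ----------------------------------------------------------- prediction

def test_predict_monotone_nonincreasing_when_slope_negative(survey_model):
    ddgs = np.linspace(-3, 12, 40)
    acts = [cs.predict_activity(survey_model, d).activity_pred_pct for d in ddgs]
    assert all(a >= b - 1e-12 for a, b in zip(acts, acts[1:]))


def test_predict_round_trip_on_noiseless_data():
    a, b = 4.5, -1.2  # activities stay below the 100% cap on this range
    xs = np.linspace(0.0, 4.0, 8)
    pairs = pairs_from(xs, np.exp(a + b * xs))
    model = cs.fit_calibration(pairs, n_perm=10, seed=0)
    for p in pairs:
        pred = cs.predict_activity(model, p.ddg)
        assert pred.activity_pred_pct == pytest.approx(p.activity_pct, rel=1e-9)


def test_predict_uses_raw_ddg_beyond_fit_cap(survey_model):
    """Predictions are not clamped at the fitting cap: 7.55 and 12.31 give
    distinct (tiny) activities."""
    p1 = cs.predict_activity(survey_model, 7.55)
    p2 = cs.predict_activity(survey_model, 12.31)
    assert p1.activity_pred_pct > p2.activity_pred_pct > 0


def test_predict_caps_at_100(survey_model):
    pred = cs.predict_activity(survey_model, -10.0)
    assert pred.activity_pred_pct == 100.0
    assert pred.capped_flag


def test_unfitted_model_raises():
    with pytest.raises(ValueError):
        cs.predict_activity(None, 1.0)


@pytest.mark.parametrize(
    "activity, call, band",
    [
        (76.0, cs.Pathogenicity.NON_PATHOGENIC, SeverityBand.NORMAL_LIKE),
        (75.0, cs.Pathogenicity.PATHOGENIC_CANDIDATE, SeverityBand.INDETERMINATE),
        (22.5, cs.Pathogenicity.PATHOGENIC_CANDIDATE, SeverityBand.NC_LIKE),
        (0.1, cs.Pathogenicity.PATHOGENIC_CANDIDATE, SeverityBand.SW_LIKE),
        (2.0, cs.Pathogenicity.PATHOGENIC_CANDIDATE, SeverityBand.SV_LIKE),
        (7.0, cs.Pathogenicity.PATHOGENIC_CANDIDATE, SeverityBand.INDETERMINATE),
        (65.0, cs.Pathogenicity.PATHOGENIC_CANDIDATE, SeverityBand.INDETERMINATE),
    ],
)
def test_call_pathogenicity_bands(activity, call, band):
    pred = cs.PredictionResult(
        ddg_mean=0.0, activity_pred_pct=activity, capped_flag=False,
        activity_raw_pct=activity,
    )
    out = cs.call_pathogenicity(pred)
    assert out.pathogenicity_call is call
    assert out.severity_band is band


def test_parameter_recovery_improves_with_n():
    """Fitted (a, b) converge to truth as the synthetic sample grows."""
    errors = []
    for n, seed in [(10, 5), (100, 6), (1000, 7)]:
        spec = cs.SyntheticSpec(
            a_true=5.35, b_true=-1.53, noise_sd=0.1, n_pairs=n, seed=seed
        )
        # mirror the real fit-set construction: drop cap-saturated
        # activities and points beyond the fitting cap
        pairs = [
            p for p in cs.generate_calibration_pairs(spec)
            if not p.capped and p.ddg <= 5.5
        ]
        model = cs.fit_calibration(pairs, n_perm=10, seed=0)
        errors.append(abs(model.slope_b + 1.53) + abs(model.intercept_a - 5.35))
    assert errors[2] < errors[0]
    assert errors[2] < 0.07
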