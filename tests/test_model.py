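"""Unit and property tests for the core fitness model."""

import math

import pytest
from hypothesis import given, settings, strategies as st

import conflictsim as cs
from conflictsim import ModelParameters

ages = st.floats(min_value=15.0, max_value=34.0)
wide_ages = st.floats(min_value=15.0, max_value=60.0)


# ---------------------------------------------------------------- single ops

@pytest.mark.parametrize(
    "op, m, kwargs, expected",
    [
        # inter-birth interval: 2 y at 15 rising to 3.25 y at 20
        (cs.inter_birth_interval, 15.0, {}, 2.0),
        (cs.inter_birth_interval, 20.0, {}, 3.25),
        (cs.inter_birth_interval, 17.0, {"ibi_override": 3.0}, 3.0),
        # age at first pregnancy = marriage age + 1
        (cs.age_first_pregnancy, 15.0, {}, 16.0),
        (cs.age_first_pregnancy, 17.6, {}, 18.6),
        (cs.age_first_pregnancy, 34.0, {}, 35.0),
        # total fertility (35 - AFP)/IBI, floored at 0
        (cs.total_fertility, 15.0, {}, 9.5),
        (cs.total_fertility, 16.4, {}, 17.6 / 2.35),
        (cs.total_fertility, 34.0, {}, 0.0),
        # low-birth-weight ramp 0.9 -> 0.4 over 15 -> 20, clipped below at 24
        (cs.lbw_risk, 15.0, {}, 0.9),
        (cs.lbw_risk, 20.0, {}, 0.4),
        (cs.lbw_risk, 24.0, {}, 0.0),
        # composite child mortality LBW x (k2 - 0.065(M-15))
        (cs.child_mortality_rate, 17.6, {}, 0.33984),
        (cs.child_mortality_rate, 16.4, {}, 0.46284),
        (cs.child_mortality_rate, 16.7, {"mortality_multiplier": 0.9}, 0.3873015),
        # stunting = 0.75 x LBW (x scenario multiplier)
        (cs.stunting_rate, 17.6, {}, 0.48),
        (cs.stunting_rate, 16.4, {}, 0.57),
        (cs.stunting_rate, 22.1, {"stunting_multiplier": 3.0}, 0.4275),
        # paternity uncertainty ramp 0 at 15 -> 0.25 at 20, or fixed
        (cs.paternity_uncertainty, 15.0, {}, 0.0),
        (cs.paternity_uncertainty, 20.0, {}, 0.25),
        (cs.paternity_uncertainty, 23.0, {"pu_override": 0.01}, 0.01),
        # maternal mortality: off by default, cubic when enabled
        (cs.maternal_mortality_risk, 15.0, {}, 0.0),
        (cs.maternal_mortality_risk, 15.0,
         {"maternal_mortality_enabled": True}, 0.067625),
        (cs.maternal_mortality_risk, 20.0,
         {"maternal_mortality_enabled": True}, 0.009),
        # lifetime fitness
        (cs.maternal_lrf, 17.6, {}, (16.4 / 2.65) * (1 - 0.33984)),
        (cs.maternal_lrf, 34.0, {}, 0.0),
        (cs.paternal_lrf, 18.2, {"ibi_override": 3.0},
         (15.8 / 3) * (1 - 0.28536) * (1 - 0.16)),
    ],
)
def test_operation_anchor_values(op, m, kwargs, expected):
    """Each operation reproduces its closed-form value at anchor ages."""
    params = ModelParameters().with_overrides(**kwargs)
    assert op(m, params) == pytest.approx(expected, abs=1e-12)


def test_monitoring_with_support_fitness(scenario_params):
    """Fixed IBI=2 and PU=0.01 give maternal/paternal LRF 6.0/5.9 at 20.2 y."""
    params = scenario_params("monitoring_with_support")
    assert cs.maternal_lrf(20.2, params) == pytest.approx(6.9 * (1 - 0.13756))
    assert cs.paternal_lrf(20.2, params) == pytest.approx(6.9 * (1 - 0.13756) * 0.99)
    assert round(cs.maternal_lrf(20.2, params), 1) == 6.0
    assert round(cs.paternal_lrf(20.2, params), 1) == 5.9


# ------------------------------------------------------------------- errors

def test_nonfinite_age_rejected(defaults):
    for bad in (math.nan, math.inf, "seventeen"):
        with pytest.raises(cs.InputError):
            cs.inter_birth_interval(bad, defaults)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"ibi_override": 0.0},
        {"ibi_intercept": -1.0},
        {"mortality_multiplier": -0.1},
        {"reproductive_end_age": 15.5},
        {"lbw_slope": math.nan},
    ],
)
def test_invalid_parameters_rejected(kwargs):
    with pytest.raises(cs.ParameterError):
        ModelParameters().with_overrides(**kwargs)


def test_unknown_field_rejected():
    with pytest.raises(cs.ParameterError, match="bogus_field"):
        ModelParameters().with_overrides(bogus_field=1)


def test_negative_ramp_ibi_is_error():
    """A ramp driven non-positive (steep negative slope) raises, not returns."""
    params = ModelParameters(ibi_slope=-1.0)
    with pytest.raises(cs.ParameterError):
        cs.inter_birth_interval(20.0, params)


# --------------------------------------------------------------- properties

@settings(derandomize=True, max_examples=200)
@given(m=wide_ages)
def test_probability_fields_bounded(m):
    """All probability outputs stay in [0,1] even far outside the 15-20 band."""
    out = cs.evaluate(m, ModelParameters(maternal_mortality_enabled=True))
    for name in ("lbw_risk", "child_mortality_rate", "stunting_rate",
                 "paternity_uncertainty", "maternal_mortality_risk"):
        assert 0.0 <= getattr(out, name) <= 1.0
    assert out.total_fertility >= 0.0


@settings(derandomize=True, max_examples=200)
@given(m=ages)
def test_paternal_never_exceeds_maternal(m):
    """Paternal LRF <= maternal LRF, with equality exactly when PU = 0."""
    params = ModelParameters()
    pat, mat = cs.paternal_lrf(m, params), cs.maternal_lrf(m, params)
    assert pat <= mat + 1e-12
    if cs.paternity_uncertainty(m, params) == 0.0:
        assert pat == mat
    elif mat > 0:
        assert pat < mat


@settings(derandomize=True, max_examples=100)
@given(m=st.floats(min_value=15.0, max_value=33.8), dm=st.floats(0.01, 1.0))
def test_monotone_ramps(m, dm):
    """TF, LBW, MR, S non-increasing and PU non-decreasing in marriage age."""
    params = ModelParameters()
    lo, hi = m, m + dm
    assert cs.total_fertility(hi, params) <= cs.total_fertility(lo, params) + 1e-12
    for op in (cs.lbw_risk, cs.child_mortality_rate, cs.stunting_rate,
               cs.postnatal_factor):
        assert op(hi, params) <= op(lo, params) + 1e-12
    assert cs.paternity_uncertainty(hi, params) >= (
        cs.paternity_uncertainty(lo, params) - 1e-12
    )


@settings(derandomize=True, max_examples=100)
@given(m=st.floats(min_value=15.0, max_value=19.0), mult=st.floats(0.0, 1.5))
def test_mortality_multiplier_scales_linearly(m, mult):
    """MR with multiplier m equals m x MR(multiplier 1) while un-clipped."""
    base = cs.child_mortality_rate(m, ModelParameters())
    scaled = cs.child_mortality_rate(
        m, ModelParameters(mortality_multiplier=mult)
    )
    if base * mult <= 1.0:
        assert scaled == pytest.approx(base * mult, abs=1e-12)


@settings(derandomize=True, max_examples=100)
@given(m=st.floats(min_value=15.0, max_value=21.0))
def test_stunting_tracks_lbw(m):
    """S / LBW equals catchup x multiplier wherever neither is clipped."""
    params = ModelParameters(stunting_multiplier=1.2)
    lbw = cs.lbw_risk(m, params)
    if 0 < lbw and lbw * 0.75 * 1.2 < 1:
        assert cs.stunting_rate(m, params) / lbw == pytest.approx(0.9)


@settings(derandomize=True, max_examples=150)
@given(m=wide_ages, mm=st.booleans())
def test_evaluate_composition(m, mm):
    """evaluate() agrees field-by-field with the single-operation functions."""
    params = ModelParameters(maternal_mortality_enabled=mm)
    out = cs.evaluate(m, params)
    assert out.marriage_age == m
    assert out.afp == cs.age_first_pregnancy(m, params)
    assert out.ibi == cs.inter_birth_interval(m, params)
    assert out.total_fertility == cs.total_fertility(m, params)
    assert out.lbw_risk == cs.lbw_risk(m, params)
    assert out.postnatal_factor == cs.postnatal_factor(m, params)
    assert out.child_mortality_rate == cs.child_mortality_rate(m, params)
    assert out.stunting_rate == cs.stunting_rate(m, params)
    assert out.paternity_uncertainty == cs.paternity_uncertainty(m, params)
    assert out.maternal_mortality_risk == cs.maternal_mortality_risk(m, params)
    assert out.maternal_lrf == cs.maternal_lrf(m, params)
    assert out.paternal_lrf == cs.paternal_lrf(m, params)


def test_neutral_overrides_reproduce_basic_model(defaults):
    """Multipliers at 1 and no overrides give the identical basic model."""
    neutral = defaults.with_overrides(
        mortality_multiplier=1.0, stunting_multiplier=1.0,
        ibi_override=None, pu_override=None,
    )
    for m in (15.0, 17.6, 20.0, 25.0):
        assert cs.evaluate(m, neutral) == cs.evaluate(m, defaults)
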