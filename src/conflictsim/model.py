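"""Core life-history fitness model.

Deterministic, closed-form model of how a woman's age at marriage (M, years)
shapes maternal and paternal lifetime reproductive fitness (LRF, offspring
surviving to age 5) in a patrilocal agricultural setting.  Marriage age drives
five linear dose-response ramps, anchored at a reference age of 15 years:

* inter-birth interval (IBI) lengthens with M (greater autonomy, contraception),
* low-birth-weight risk (LBW) falls with M,
* the post-natal survival deficit falls with M,
* paternity uncertainty (PU) rises with M,
* (optionally) maternal mortality risk (MMR) falls with M, cubic in M.

From these, total fertility TF = (k1 - AFP) / IBI with AFP = M + lag and
reproductive cessation at k1 = 35 y; child mortality MR = LBW x (k2 - 0.065 k3)
with k3 = M - 15; stunting S = 0.75 x LBW; maternal LRF = TF (1 - MR) (1 - MMR);
paternal LRF = maternal LRF x (1 - PU).

All probabilities are clipped to [0, 1] and the post-natal factor floored at 0,
so the ramps extrapolate safely outside the illustrative 15-20 y range.  The
model has no stochastic element; every function is a pure map from (M, params).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace


class ParameterError(ValueError):
    """A model parameter violates its invariant."""


class InputError(ValueError):
    """A marriage-age input is invalid (non-finite or non-numeric)."""


def _clip01(x: float) -> float:
    return 0.0 if x < 0.0 else (1.0 if x > 1.0 else x)


def _check_age(m: float) -> float:
    try:
        m = float(m)
    except (TypeError, ValueError) as exc:
        raise InputError(f"marriage age must be a real number, got {m!r}") from exc
    if not math.isfinite(m):
        raise InputError(f"marriage age must be finite, got {m}")
    return m


@dataclass(frozen=True)
class ModelParameters:
    """All constants of the fitness model, with the basic-model defaults.

    Ramps are parameterised as ``intercept + slope * (M - reference_age)``;
    ``ibi_override`` and ``pu_override`` replace their ramp with a fixed value
    when set (how the intervention scenarios freeze a quantity across all
    marital ages).  ``mortality_multiplier`` scales child mortality as a whole
    and ``stunting_multiplier`` scales stunting, both before clipping.
    """

    reproductive_end_age: float = 35.0   # k1, years
    reference_age: float = 15.0          # anchor of every linear ramp, years
    first_birth_lag: float = 1.0         # AFP - M, years
    ibi_intercept: float = 2.0           # years at the reference age
    ibi_slope: float = 0.25              # years per year of marriage age
    ibi_override: float | None = None    # fixed IBI, years (scenario use)
    lbw_intercept: float = 0.9           # probability at the reference age
    lbw_slope: float = 0.1               # probability decrease per year
    postnatal_intercept: float = 0.7     # k2, dimensionless
    postnatal_slope: float = 0.065       # per year of k3 = M - reference_age
    mortality_multiplier: float = 1.0
    stunting_catchup_factor: float = 0.75
    stunting_multiplier: float = 1.0
    pu_slope: float = 0.05               # fraction per year (0 at 15 -> 0.25 at 20)
    pu_override: float | None = None     # fixed PU fraction (scenario use)
    maternal_mortality_enabled: bool = False
    mm_k4: float = 0.485                 # MMR = k4 - k5 M + k6 M^3
    mm_k5: float = 0.033                 # per year
    mm_k6: float = 0.000023              # per year^3

    def __post_init__(self) -> None:
        numeric = [
            (f.name, getattr(self, f.name))
            for f in fields(self)
            if f.name != "maternal_mortality_enabled"
        ]
        for name, value in numeric:
            if value is None:
                continue
            if not isinstance(value, (int, float)) or not math.isfinite(float(value)):
                raise ParameterError(f"{name} must be a finite number, got {value!r}")
        if self.reproductive_end_age <= self.reference_age + self.first_birth_lag:
            raise ParameterError(
                "reproductive_end_age must exceed reference_age + first_birth_lag "
                f"({self.reproductive_end_age} <= "
                f"{self.reference_age + self.first_birth_lag})"
            )
        if self.ibi_intercept <= 0:
            raise ParameterError(f"ibi_intercept must be > 0, got {self.ibi_intercept}")
        if self.ibi_override is not None and self.ibi_override <= 0:
            raise ParameterError(f"ibi_override must be > 0, got {self.ibi_override}")
        if self.mortality_multiplier < 0:
            raise ParameterError(
                f"mortality_multiplier must be >= 0, got {self.mortality_multiplier}"
            )

    def with_overrides(self, **overrides: object) -> "ModelParameters":
        """Return a copy with the given fields replaced (validates names)."""
        valid = {f.name for f in fields(self)}
        unknown = set(overrides) - valid
        if unknown:
            raise ParameterError(
                f"unknown parameter field(s): {', '.join(sorted(unknown))}"
            )
        return replace(self, **overrides)


@dataclass(frozen=True)
class FitnessOutcome:
    """Every intermediate and final model quantity at one marriage age."""

    marriage_age: float
    afp: float
    ibi: float
    total_fertility: float
    lbw_risk: float
    postnatal_factor: float
    child_mortality_rate: float
    stunting_rate: float
    paternity_uncertainty: float
    maternal_mortality_risk: float
    maternal_lrf: float
    paternal_lrf: float

    FIELDS = (
        "marriage_age", "afp", "ibi", "total_fertility", "lbw_risk",
        "postnatal_factor", "child_mortality_rate", "stunting_rate",
        "paternity_uncertainty", "maternal_mortality_risk",
        "maternal_lrf", "paternal_lrf",
    )

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.FIELDS}


def inter_birth_interval(m: float, params: ModelParameters) -> float:
    """Inter-birth interval in years: the linear ramp, or the fixed override.

    Defaults give 2 y at marriage age 15 rising to 3.25 y at 20.
    """
    m = _check_age(m)
    if params.ibi_override is not None:
        return float(params.ibi_override)
    ibi = params.ibi_intercept + (m - params.reference_age) * params.ibi_slope
    if ibi <= 0:
        raise ParameterError(
            f"inter-birth interval is non-positive ({ibi:.3f} y) at M={m}"
        )
    return ibi


def age_first_pregnancy(m: float, params: ModelParameters) -> float:
    """Age at first pregnancy: marriage age plus the first-birth lag (1 y)."""
    return _check_age(m) + params.first_birth_lag


def total_fertility(m: float, params: ModelParameters) -> float:
    """Offspring born between first pregnancy and reproductive cessation.

    TF = (k1 - AFP) / IBI, floored at zero and left continuous (not rounded).
    """
    m = _check_age(m)
    tf = (params.reproductive_end_age - age_first_pregnancy(m, params)) / (
        inter_birth_interval(m, params)
    )
    return max(0.0, tf)


def lbw_risk(m: float, params: ModelParameters) -> float:
    """Probability of a low-birth-weight (< 3 kg) offspring; 0.9 at 15 y,
    falling 0.1 per year, clipped to [0, 1]."""
    m = _check_age(m)
    return _clip01(params.lbw_intercept - (m - params.reference_age) * params.lbw_slope)


def postnatal_factor(m: float, params: ModelParameters) -> float:
    """Post-natal survival deficit k2 - 0.065 (M - 15), floored at 0."""
    m = _check_age(m)
    return max(
        0.0,
        params.postnatal_intercept
        - (m - params.reference_age) * params.postnatal_slope,
    )


def child_mortality_rate(m: float, params: ModelParameters) -> float:
    """Fraction of births dying before age 5.

    Composite of birth-weight and post-natal pathways:
    MR = LBW(M) x (k2 - 0.065 k3) x mortality_multiplier, clipped to [0, 1],
    with k3 = M - reference_age.
    """
    m = _check_age(m)
    raw = lbw_risk(m, params) * postnatal_factor(m, params)
    return _clip01(raw * params.mortality_multiplier)


def stunting_rate(m: float, params: ModelParameters) -> float:
    """Stunting prevalence: LBW scaled by post-natal catch-up (0.75), times
    the scenario stunting multiplier, clipped to [0, 1]."""
    m = _check_age(m)
    return _clip01(
        lbw_risk(m, params)
        * params.stunting_catchup_factor
        * params.stunting_multiplier
    )


def paternity_uncertainty(m: float, params: ModelParameters) -> float:
    """Fraction of offspring not sired by the husband.

    Ramp: 0 at 15 y rising 0.05/y (0.25 at 20 y); a fixed override models
    household monitoring or education scenarios.
    """
    m = _check_age(m)
    if params.pu_override is not None:
        return _clip01(float(params.pu_override))
    return _clip01((m - params.reference_age) * params.pu_slope)


def maternal_mortality_risk(m: float, params: ModelParameters) -> float:
    """Per-career maternal mortality risk, cubic in marriage age.

    MMR = k4 - k5 M + k6 M^3, clipped to [0, 1]; exactly 0 when the
    maternal-mortality extension is disabled (the basic model).
    """
    m = _check_age(m)
    if not params.maternal_mortality_enabled:
        return 0.0
    return _clip01(params.mm_k4 - params.mm_k5 * m + params.mm_k6 * m**3)


def maternal_lrf(m: float, params: ModelParameters) -> float:
    """Maternal lifetime reproductive fitness: TF x (1 - MR) x (1 - MMR)."""
    m = _check_age(m)
    return (
        total_fertility(m, params)
        * (1.0 - child_mortality_rate(m, params))
        * (1.0 - maternal_mortality_risk(m, params))
    )


def paternal_lrf(m: float, params: ModelParameters) -> float:
    """Paternal fitness: maternal LRF discounted by paternity uncertainty.

    The maternal value already carries the (1 - MMR) survival term; widowed
    fathers are assumed not to remarry, so no paternal-side correction.
    """
    m = _check_age(m)
    return maternal_lrf(m, params) * (1.0 - paternity_uncertainty(m, params))


def evaluate(m: float, params: ModelParameters | None = None) -> FitnessOutcome:
    """Evaluate every model quantity at one marriage age.

    Each field equals its single-operation counterpart exactly (the record is
    built from those functions, not re-derived).
    """
    if params is None:
        params = ModelParameters()
    m = _check_age(m)
    return FitnessOutcome(
        marriage_age=m,
        afp=age_first_pregnancy(m, params),
        ibi=inter_birth_interval(m, params),
        total_fertility=total_fertility(m, params),
        lbw_risk=lbw_risk(m, params),
        postnatal_factor=postnatal_factor(m, params),
        child_mortality_rate=child_mortality_rate(m, params),
        stunting_rate=stunting_rate(m, params),
        paternity_uncertainty=paternity_uncertainty(m, params),
        maternal_mortality_risk=maternal_mortality_risk(m, params),
        maternal_lrf=maternal_lrf(m, params),
        paternal_lrf=paternal_lrf(m, params),
    )
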