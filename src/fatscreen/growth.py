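"""BMI and BMI-for-age z-scores from an LMS growth reference.

The LMS parameterisation summarises a growth reference at each age and sex
by a Box-Cox power ``L``, a median ``M`` and a coefficient of variation
``S``.  A measurement ``X`` maps to a z-score via

    z = ((X / M)**L - 1) / (L * S)            (L != 0)
    z = ln(X / M) / S                         (L -> 0 limit)

For |z| > 3 the WHO convention replaces the raw z-score with a linear
extrapolation anchored at the +/-3 SD and +/-2 SD reference values
("restricted tails"), which keeps extreme BMIs on a stable scale.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    AgeOutOfRangeError,
    InvalidMeasurementError,
    InvalidParameterError,
    ReferenceIncompleteError,
)

__all__ = [
    "LMSReference",
    "bmi",
    "lms_zscore",
    "lms_value",
    "bmi_for_age_z",
    "classify_bmi_status",
    "OBESE",
    "OVERWEIGHT_NOT_OBESE",
    "NEITHER",
]

# switch to the logarithmic limit of the LMS formula below this |L|
_L_EPS = 1e-7

OBESE = "obese"
OVERWEIGHT_NOT_OBESE = "overweight_not_obese"
NEITHER = "neither"

_SEXES = ("male", "female")

SEX_ALIASES = {
    "m": "male", "male": "male", "boy": "male", "boys": "male", "1": "male",
    "f": "female", "female": "female", "girl": "female", "girls": "female",
    "2": "female",
}


def normalize_sex(value) -> str:
    """Map common sex encodings ({M,F}, {male,female}, {1,2}) to canonical labels."""
    key = str(value).strip().lower()
    if key not in SEX_ALIASES:
        raise InvalidParameterError(f"unrecognised sex encoding: {value!r}")
    return SEX_ALIASES[key]


def bmi(weight_kg: float, height_m: float) -> float:
    """Body mass index: weight divided by height squared, kg/m^2."""
    if not weight_kg > 0:
        raise InvalidMeasurementError(f"weight must be positive, got {weight_kg}")
    if not height_m > 0:
        raise InvalidMeasurementError(f"height must be positive, got {height_m}")
    return weight_kg / (height_m * height_m)


def lms_zscore(value: float, L: float, M: float, S: float) -> float:
    """Raw LMS z-score of ``value`` against parameters (L, M, S).

    Uses the logarithmic limit when |L| < 1e-7.  No tail restriction is
    applied here; see :func:`bmi_for_age_z` for the WHO convention.
    """
    if not value > 0:
        raise InvalidParameterError(f"value must be positive, got {value}")
    if not M > 0:
        raise InvalidParameterError(f"M must be positive, got {M}")
    if not S > 0:
        raise InvalidParameterError(f"S must be positive, got {S}")
    if abs(L) < _L_EPS:
        return math.log(value / M) / S
    return ((value / M) ** L - 1.0) / (L * S)


def lms_value(z: float, L: float, M: float, S: float) -> float:
    """Inverse of :func:`lms_zscore`: the measurement at z-score ``z``."""
    if not M > 0:
        raise InvalidParameterError(f"M must be positive, got {M}")
    if not S > 0:
        raise InvalidParameterError(f"S must be positive, got {S}")
    if abs(L) < _L_EPS:
        return M * math.exp(S * z)
    base = 1.0 + L * S * z
    if base <= 0:
        raise InvalidParameterError(
            f"z={z} outside the domain of the LMS inverse for L={L}, S={S}"
        )
    return M * base ** (1.0 / L)


@dataclass
class LMSReference:
    """Sex-stratified grid of LMS parameters on an integer month scale.

    Parameters
    ----------
    table
        DataFrame with columns ``sex`` (male/female), ``age_months``
        (strictly increasing integers within sex), ``L``, ``M``, ``S``.
    """

    table: pd.DataFrame
    _by_sex: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        required = {"sex", "age_months", "L", "M", "S"}
        missing = required - set(self.table.columns)
        if missing:
            raise ReferenceIncompleteError(f"reference lacks columns {sorted(missing)}")
        tab = self.table.copy()
        tab["sex"] = tab["sex"].map(normalize_sex)
        if set(tab["sex"].unique()) != set(_SEXES):
            raise ReferenceIncompleteError(
                "reference must contain exactly the strata male and female"
            )
        if (tab["M"] <= 0).any() or (tab["S"] <= 0).any():
            raise InvalidParameterError("reference requires M > 0 and S > 0")
        self._by_sex = {}
        for sex, grp in tab.groupby("sex"):
            grp = grp.sort_values("age_months")
            ages = grp["age_months"].to_numpy(dtype=float)
            if len(ages) < 2 or np.any(np.diff(ages) <= 0):
                raise ReferenceIncompleteError(
                    f"age grid for {sex} must be strictly increasing with >= 2 rows"
                )
            self._by_sex[sex] = (
                ages,
                grp["L"].to_numpy(dtype=float),
                grp["M"].to_numpy(dtype=float),
                grp["S"].to_numpy(dtype=float),
            )
        self.table = tab.reset_index(drop=True)

    @classmethod
    def from_file(cls, path) -> "LMSReference":
        """Read a WHO-layout reference (sex, age_months, L, M, S) from CSV/TSV.

        The delimiter is auto-detected between comma and tab from the header
        line.
        """
        with open(path, "rt", encoding="utf-8") as fh:
            head = fh.readline()
            sep = "\t" if head.count("\t") >= head.count(",") else ","
            fh.seek(0)
            tab = pd.read_csv(fh, sep=sep)
        return cls(tab)

    def to_file(self, path) -> None:
        self.table.to_csv(path, index=False)

    def age_span(self, sex: str) -> tuple[float, float]:
        ages = self._by_sex[normalize_sex(sex)][0]
        return float(ages[0]), float(ages[-1])

    def interpolate(self, sex: str, age_months: float) -> tuple[float, float, float]:
        """L, M, S linearly interpolated to an exact age in months."""
        sex = normalize_sex(sex)
        if sex not in self._by_sex:
            raise ReferenceIncompleteError(f"no reference stratum for sex {sex}")
        ages, L, M, S = self._by_sex[sex]
        if not (ages[0] <= age_months <= ages[-1]):
            raise AgeOutOfRangeError(
                f"age {age_months} months outside reference span "
                f"[{ages[0]:.0f}, {ages[-1]:.0f}]"
            )
        return (
            float(np.interp(age_months, ages, L)),
            float(np.interp(age_months, ages, M)),
            float(np.interp(age_months, ages, S)),
        )

    def with_sd_columns(self) -> pd.DataFrame:
        """Reference table augmented with the BMI values at z = +/-2, +/-3."""
        tab = self.table.copy()
        for name, z in (("SD3neg", -3), ("SD2neg", -2), ("SD2pos", 2), ("SD3pos", 3)):
            tab[name] = [
                lms_value(z, r.L, r.M, r.S) for r in tab.itertuples()
            ]
        return tab


def _restricted_z(value: float, L: float, M: float, S: float) -> float:
    # WHO 2007 convention: beyond |z| = 3 the scale is linearised between the
    # 2 SD and 3 SD reference values so extreme BMIs stay comparable.
    z = lms_zscore(value, L, M, S)
    if z > 3:
        sd3 = lms_value(3, L, M, S)
        sd2 = lms_value(2, L, M, S)
        return 3.0 + (value - sd3) / (sd3 - sd2)
    if z < -3:
        sd3n = lms_value(-3, L, M, S)
        sd2n = lms_value(-2, L, M, S)
        return -3.0 + (value - sd3n) / (sd2n - sd3n)
    return z


def _restricted_value(z: float, L: float, M: float, S: float) -> float:
    # inverse of _restricted_z, used when synthesising cohorts from target z
    if z > 3:
        sd3 = lms_value(3, L, M, S)
        sd2 = lms_value(2, L, M, S)
        return sd3 + (z - 3.0) * (sd3 - sd2)
    if z < -3:
        sd3n = lms_value(-3, L, M, S)
        sd2n = lms_value(-2, L, M, S)
        return sd3n + (z + 3.0) * (sd2n - sd3n)
    return lms_value(z, L, M, S)


def bmi_for_age_z(
    sex: str,
    age_months: float,
    bmi_value: float,
    reference: LMSReference,
) -> float:
    """BMI-for-age z-score with the WHO restricted-tail adjustment.

    L, M and S are linearly interpolated to the exact age in months before
    the LMS formula is applied.
    """
    L, M, S = reference.interpolate(sex, age_months)
    return _restricted_z(bmi_value, L, M, S)


def bmi_from_z(
    sex: str,
    age_months: float,
    z: float,
    reference: LMSReference,
) -> float:
    """BMI at z-score ``z``; exact inverse of :func:`bmi_for_age_z`."""
    L, M, S = reference.interpolate(sex, age_months)
    return _restricted_value(z, L, M, S)


def classify_bmi_status(z: float) -> str:
    """WHO school-age classification: obese (z > 2), overweight-not-obese
    (1 < z <= 2), neither (z <= 1).  Inequalities are strict."""
    if not math.isfinite(z):
        raise InvalidParameterError(f"z-score must be finite, got {z}")
    if z > 2.0:
        return OBESE
    if z > 1.0:
        return OVERWEIGHT_NOT_OBESE
    return NEITHER
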