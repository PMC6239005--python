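"""Deuterium-dilution body composition.

A weighed oral dose of deuterium oxide (0.5 g per kg body weight)
equilibrates with body water; the rise in saliva deuterium enrichment at
isotopic plateau (sampled 3 h and 4 h post-dose) gives the dilution space

    N (kg) = dose (mg) / delta-enrichment (mg/kg)

which overestimates total body water because deuterium also exchanges with
non-aqueous hydrogen; dividing by 1.041 corrects for that.  Fat-free mass
follows from the age- and sex-specific hydration of fat-free mass, and fat
mass is the remainder of body weight.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import pandas as pd

from .errors import (
    ConfigurationError,
    IncompleteRecordError,
    InconsistentEnrichmentError,
    InvalidMeasurementError,
    InvalidParameterError,
)
from .growth import normalize_sex

__all__ = [
    "DILUTION_SPACE_RATIO",
    "DOSE_G_PER_KG",
    "FAT_PCT_THRESHOLDS",
    "HydrationTable",
    "BodyComposition",
    "compute_dose",
    "plateau_enrichment",
    "total_body_water",
    "body_composition",
    "classify_fat_status",
    "EXCESSIVE",
    "NOT_EXCESSIVE",
]

#: deuterium dilution space / total body water; corrects non-aqueous exchange
DILUTION_SPACE_RATIO = 1.041

#: dosing rule, g deuterium oxide per kg body weight
DOSE_G_PER_KG = 0.5

#: excessive-fatness thresholds, % of body weight (strict >)
FAT_PCT_THRESHOLDS = {"male": 25.0, "female": 30.0}

EXCESSIVE = "excessive"
NOT_EXCESSIVE = "not_excessive"


@dataclass
class HydrationTable:
    """Hydration-of-fat-free-mass coefficients by sex and age band (years).

    Bands are half-open ``[age_min_yr, age_max_yr)`` and must tile the
    supported range without overlap for each sex.  Coefficients are the
    water fraction of fat-free mass, ~0.76-0.78 in school-age children.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sex", "age_min_yr", "age_max_yr", "coefficient"}
        missing = required - set(self.table.columns)
        if missing:
            raise ConfigurationError(f"hydration table lacks columns {sorted(missing)}")
        tab = self.table.copy()
        tab["sex"] = tab["sex"].map(normalize_sex)
        coeff = tab["coefficient"]
        if not ((coeff > 0.60) & (coeff < 0.85)).all():
            raise ConfigurationError(
                "hydration coefficients must lie in (0.60, 0.85)"
            )
        for sex, grp in tab.groupby("sex"):
            grp = grp.sort_values("age_min_yr")
            lo, hi = grp["age_min_yr"].to_numpy(), grp["age_max_yr"].to_numpy()
            if (lo >= hi).any() or (lo[1:] < hi[:-1]).any():
                raise ConfigurationError(f"hydration bands for {sex} overlap or invert")
        self.table = tab.reset_index(drop=True)

    @classmethod
    def default(cls) -> "HydrationTable":
        """Packaged Lohman-type constants for 8-12-year-olds."""
        src = importlib.resources.files("fatscreen.data") / "hydration_coefficients.csv"
        with importlib.resources.as_file(src) as path:
            return cls(pd.read_csv(path))

    @classmethod
    def from_file(cls, path) -> "HydrationTable":
        with open(path, "rt", encoding="utf-8") as fh:
            head = fh.readline()
            sep = "\t" if head.count("\t") >= head.count(",") else ","
            fh.seek(0)
            return cls(pd.read_csv(fh, sep=sep))

    def coefficient(self, sex: str, age_years: float) -> float:
        sex = normalize_sex(sex)
        tab = self.table
        hit = tab[
            (tab["sex"] == sex)
            & (tab["age_min_yr"] <= age_years)
            & (age_years < tab["age_max_yr"])
        ]
        if hit.empty:
            raise ConfigurationError(
                f"no hydration coefficient for sex={sex}, age={age_years} years"
            )
        return float(hit["coefficient"].iloc[0])


@dataclass(frozen=True)
class BodyComposition:
    """Body-composition summary for one child (all masses in kg)."""

    tbw: float
    ffm: float
    fm: float
    fat_pct: float
    fmi: float
    ffmi: float


def compute_dose(weight_kg: float) -> float:
    """Deuterium oxide dose in g (0.5 g/kg), at the 0.001 g weighing precision."""
    if not weight_kg > 0:
        raise InvalidMeasurementError(f"weight must be positive, got {weight_kg}")
    return round(DOSE_G_PER_KG * weight_kg, 3)


def plateau_enrichment(pre_dose: float, post_3h: float, post_4h: float) -> float:
    """Baseline-corrected plateau enrichment, mg/kg.

    The plateau value is the mean of the 3 h and 4 h samples; the pre-dose
    enrichment is subtracted as baseline.
    """
    for name, v in (("pre_dose", pre_dose), ("post_3h", post_3h), ("post_4h", post_4h)):
        if v is None or pd.isna(v):
            raise IncompleteRecordError(f"missing enrichment sample {name}")
        if v < 0:
            raise InvalidMeasurementError(f"enrichment {name} must be >= 0, got {v}")
    delta = 0.5 * (post_3h + post_4h) - pre_dose
    if delta < 0:
        raise InconsistentEnrichmentError(
            f"post-dose mean {0.5 * (post_3h + post_4h)} below baseline {pre_dose}"
        )
    return delta


def total_body_water(dose_g: float, delta_enrichment: float) -> float:
    """Total body water in kg from dose (g) and plateau enrichment (mg/kg)."""
    if not dose_g > 0:
        raise InvalidMeasurementError(f"dose must be positive, got {dose_g}")
    if not delta_enrichment > 0:
        raise InconsistentEnrichmentError(
            f"plateau enrichment must be positive, got {delta_enrichment}"
        )
    dilution_space = (dose_g * 1000.0) / delta_enrichment
    return dilution_space / DILUTION_SPACE_RATIO


def body_composition(
    tbw_kg: float,
    weight_kg: float,
    height_m: float,
    sex: str,
    age_years: float,
    hydration: HydrationTable,
) -> BodyComposition:
    """Fat-free mass, fat mass and the derived indices from total body water.

    A negative fat mass is returned as computed (it is unphysiological and
    will be caught by quality control), never silently clipped.
    """
    if not tbw_kg > 0:
        raise InvalidMeasurementError(f"total body water must be positive, got {tbw_kg}")
    coeff = hydration.coefficient(sex, age_years)
    ffm = tbw_kg / coeff
    fm = weight_kg - ffm
    fat_pct = 100.0 * fm / weight_kg
    h2 = height_m * height_m
    return BodyComposition(
        tbw=tbw_kg,
        ffm=ffm,
        fm=fm,
        fat_pct=fat_pct,
        fmi=fm / h2,
        ffmi=ffm / h2,
    )


def classify_fat_status(fat_pct: float, sex: str) -> str:
    """Excessive fatness: > 25 % body fat in boys, > 30 % in girls (strict)."""
    if fat_pct is None or pd.isna(fat_pct):
        raise InvalidParameterError("fat percentage must be finite")
    sex = normalize_sex(sex)
    return EXCESSIVE if fat_pct > FAT_PCT_THRESHOLDS[sex] else NOT_EXCESSIVE
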