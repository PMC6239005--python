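"""Synthetic multicentre cohorts for exercising the full pipeline.

The generator emulates an eight-centre cohort of 8-11-year-olds: per-centre
BMI-for-age z-score distributions (locations echoing the spread observed
across urban African study sites), heights from a simple linear growth
model, body-fat percentage linear in BMI-z with a sex-specific intercept
(girls fatter at the same z), and saliva enrichments synthesised by
inverting the dilution equation from the true total body water, with
multiplicative measurement noise applied on the enrichment scale where the
spectrometer operates.

Clean cohorts are generated conditional on passing the quality-control
screens: after assembly the generator previews the QC cascade (with a
small safety margin) and redraws the noise components of any record that
would be flagged, keeping its sex, age and BMI-z.  A "clean" record is
therefore clean by construction, so downstream QC failures occur if and
only if they are injected — which is what makes the injected-failure
ledger an exact oracle for the QC cascade.  The price is a mild
truncation of joint noise tails, documented as a non-feature for realism.

A ground-truth ledger accompanies every cohort so that tests can compare
pipeline output against what the generator actually drew.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .growth import LMSReference, bmi_from_z
from .isotope import (
    DILUTION_SPACE_RATIO,
    FAT_PCT_THRESHOLDS,
    HydrationTable,
    compute_dose,
)
from .qc import QCThresholds, qc_enrichment_range, qc_fat_outlier

__all__ = [
    "GeneratorConfig",
    "GroundTruthLedger",
    "generate_lms_fixture",
    "generate_cohort",
    "inject_qc_failures",
]

#: centre name -> (sample size, BMI-z location); seven centres ~150 and one
#: larger centre ~350, with locations spanning lean to heavy populations
DEFAULT_CENTRES = {
    "Ghana": (150, -0.70),
    "Kenya": (150, -0.82),
    "Mauritius": (150, 0.68),
    "Morocco": (150, -0.27),
    "Namibia": (150, 0.19),
    "Senegal": (150, -1.32),
    "Tunisia": (150, 0.10),
    "United Republic of Tanzania": (350, 0.02),
}

INJECTABLE_CRITERIA = ("plateau", "enrichment_range", "fat_mismatch")

# QC preview used when conditioning clean cohorts: the pipeline thresholds
# tightened by a margin so that injection-induced shifts in the cohort
# regressions cannot push a conditioned-clean record over the real cut
_PREVIEW_THRESHOLDS = QCThresholds(
    hydration_ratio_low=0.32,
    hydration_ratio_high=0.78,
    fat_pct_low=4.0,
    fat_pct_high=58.0,
    max_abs_residual=2.7,
)
_MAX_CONDITIONING_ROUNDS = 50


@dataclass
class GeneratorConfig:
    """All tunable parameters of the synthetic-cohort generator.

    Defaults are calibrated so the pipeline lands in the regime of a large
    urban African school-age cohort: fat-excess prevalence near 0.3 and an
    AUC of BMI-z for fat-excess near 0.85.
    """

    centres: dict = field(default_factory=lambda: dict(DEFAULT_CENTRES))
    female_fraction: float = 0.535
    age_min_months: int = 96
    age_max_months: int = 143
    bmi_z_sd: float = 1.30
    bmi_z_truncation: float = 3.0            # SD units around the centre mean
    fat_intercept_male: float = 22.0         # % fat at z = 0
    fat_intercept_female: float = 26.4
    fat_slope: float = 4.2                   # % fat per SD of BMI-z
    fat_residual_sd: float = 6.0
    fat_residual_truncation: float = 2.5     # SD units
    fat_min: float = 4.0                     # redraw outside this range
    fat_max: float = 58.0
    height_base_male_m: float = 1.28         # height at 96 months
    height_base_female_m: float = 1.27
    height_slope_male: float = 0.0046        # m per month
    height_slope_female: float = 0.0050
    height_noise_sd_m: float = 0.04
    baseline_enrichment_mean: float = 150.0  # mg/kg, natural deuterium abundance
    baseline_enrichment_sd: float = 3.0
    enrichment_noise_sd: float = 0.005       # relative, per post-dose sample
    condition_on_qc: bool = True             # redraw records the QC preview flags

    def __post_init__(self) -> None:
        for name, (n, _mu) in self.centres.items():
            if n <= 0:
                raise ConfigurationError(f"centre {name!r} has non-positive size {n}")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ConfigurationError("female_fraction must lie in [0, 1]")
        for name in ("bmi_z_sd", "fat_residual_sd", "enrichment_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")

    @classmethod
    def from_file(cls, path) -> "GeneratorConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            raw = json.load(fh)
        if "centres" in raw:
            raw["centres"] = {k: tuple(v) for k, v in raw["centres"].items()}
        return cls(**raw)

    def to_file(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)


@dataclass
class GroundTruthLedger:
    """Per-record generator truth plus injected-failure bookkeeping."""

    frame: pd.DataFrame

    @property
    def injected_ids(self) -> list:
        mask = self.frame["injected_criterion"] != ""
        return sorted(self.frame.loc[mask, "id"])

    def injected_ids_for(self, criterion: str) -> list:
        mask = self.frame["injected_criterion"] == criterion
        return sorted(self.frame.loc[mask, "id"])

    @property
    def true_sensitivity(self) -> float:
        """Sensitivity of BMI-z > +2 for fat-excess under the generating model."""
        pos = self.frame["true_fat_excess"]
        if not pos.any():
            return float("nan")
        return float(self.frame.loc[pos, "true_bmi_obese"].mean())

    @property
    def true_specificity(self) -> float:
        neg = ~self.frame["true_fat_excess"]
        if not neg.any():
            return float("nan")
        return float((~self.frame.loc[neg, "true_bmi_obese"]).mean())

    def to_file(self, path) -> None:
        self.frame.to_csv(path, index=False)


def generate_lms_fixture(
    age_min_months: int = 96,
    age_max_months: int = 144,
    step_months: int = 1,
) -> LMSReference:
    """Deterministic LMS reference with smooth, WHO-shaped parameter curves.

    Median BMI rises slowly with age, the distribution is right-skewed
    (L < 0) and the coefficient of variation grows through late childhood.
    """
    if age_max_months <= age_min_months or step_months <= 0:
        raise ConfigurationError("invalid fixture age grid")
    ages = np.arange(age_min_months, age_max_months + 1, step_months)
    span = max(age_max_months - age_min_months, 1)
    frac = (ages - age_min_months) / span
    rows = []
    for sex, m0, growth, l0, s0 in (
        ("male", 15.7, 0.080, -1.4, 0.110),
        ("female", 15.5, 0.088, -1.5, 0.115),
    ):
        for age, f in zip(ages, frac):
            rows.append(
                {
                    "sex": sex,
                    "age_months": int(age),
                    "L": l0 - 0.3 * f,
                    "M": m0 * float(np.exp(growth * f)),
                    "S": s0 + 0.025 * f,
                }
            )
    return LMSReference(pd.DataFrame(rows))


def _truncated_normal(rng, sd, size, trunc):
    """Mean-zero normal draws rejected outside +/- trunc * sd."""
    out = rng.normal(0.0, sd, size)
    if sd > 0:
        bad = np.abs(out) > trunc * sd
        while bad.any():
            out[bad] = rng.normal(0.0, sd, int(bad.sum()))
            bad = np.abs(out) > trunc * sd
    return out


class _RecordSynthesiser:
    """Builds one record's measurements from its (sex, age, z) skeleton."""

    def __init__(self, config, reference, hydration, rng):
        self.cfg = config
        self.ref = reference
        self.hyd = hydration
        self.rng = rng

    def draw(self, sex: str, age_m: int, z: float) -> dict:
        cfg, rng = self.cfg, self.rng
        bmi_val = bmi_from_z(sex, age_m, z, self.ref)
        if sex == "male":
            height = cfg.height_base_male_m + cfg.height_slope_male * (age_m - 96)
            fat_mu = cfg.fat_intercept_male + cfg.fat_slope * z
        else:
            height = cfg.height_base_female_m + cfg.height_slope_female * (age_m - 96)
            fat_mu = cfg.fat_intercept_female + cfg.fat_slope * z
        height += float(_truncated_normal(rng, cfg.height_noise_sd_m, 1, 2.5)[0])
        weight = bmi_val * height * height

        fat = fat_mu + float(
            _truncated_normal(rng, cfg.fat_residual_sd, 1, cfg.fat_residual_truncation)[0]
        )
        tries = 0
        while not (cfg.fat_min <= fat <= cfg.fat_max):
            fat = fat_mu + float(
                _truncated_normal(
                    rng, cfg.fat_residual_sd, 1, cfg.fat_residual_truncation
                )[0]
            )
            tries += 1
            if tries > 1000:
                raise ConfigurationError(
                    f"fat model infeasible (mean {fat_mu:.1f}% never lands in "
                    f"[{cfg.fat_min}, {cfg.fat_max}])"
                )

        coeff = self.hyd.coefficient(sex, age_m // 12)
        ffm = (1.0 - fat / 100.0) * weight
        tbw = ffm * coeff
        dose = compute_dose(weight)
        delta = (dose * 1000.0) / (DILUTION_SPACE_RATIO * tbw)
        noise = _truncated_normal(rng, cfg.enrichment_noise_sd, 2, 2.5)
        pre = cfg.baseline_enrichment_mean + float(
            _truncated_normal(rng, cfg.baseline_enrichment_sd, 1, 2.5)[0]
        )
        return {
            "sex": sex,
            "age_months": age_m,
            "z": z,
            "bmi": bmi_val,
            "height_m": height,
            "weight_kg": weight,
            "fat": fat,
            "tbw": tbw,
            "dose_g": dose,
            "enr_pre": pre,
            "enr_3h": pre + delta * (1.0 + float(noise[0])),
            "enr_4h": pre + delta * (1.0 + float(noise[1])),
        }


def _measured_preview(cohort: pd.DataFrame, ledger: pd.DataFrame) -> pd.DataFrame:
    """Quantities the QC screens will see, recomputed from the enrichments."""
    delta = 0.5 * (cohort["enr_3h"] + cohort["enr_4h"]) - cohort["enr_pre"]
    tbw = (cohort["dose_g"] * 1000.0) / delta / DILUTION_SPACE_RATIO
    coeff = ledger["hydration_coeff"].to_numpy()
    ffm = tbw / coeff
    fat = 100.0 * (cohort["weight_kg"] - ffm) / cohort["weight_kg"]
    return pd.DataFrame(
        {
            "tbw": tbw,
            "weight_kg": cohort["weight_kg"],
            "height_m": cohort["height_cm"] / 100.0,
            "fat_pct": fat,
            "bmi_z": ledger["true_bmi_z"],
        },
        index=cohort.index,
    )


def generate_cohort(
    config: GeneratorConfig,
    seed: int,
    reference: LMSReference | None = None,
    hydration: HydrationTable | None = None,
) -> tuple[pd.DataFrame, GroundTruthLedger]:
    """Draw a full cohort and its ground-truth ledger.

    Identical ``(config, seed)`` produce identical output.  The returned
    cohort frame uses the on-disk interchange layout (height in cm, raw
    enrichments); the ledger carries the generating truth per record.
    With ``condition_on_qc`` (the default), noise components of records
    the QC preview would flag are redrawn until the whole cohort passes.
    """
    rng = np.random.default_rng(seed)
    reference = reference or generate_lms_fixture()
    hydration = hydration or HydrationTable.default()
    synth = _RecordSynthesiser(config, reference, hydration, rng)

    skeletons = []  # (id, centre, sex, age_months, z)
    counter = 0
    for centre, (n, z_mu) in config.centres.items():
        sexes = np.where(rng.random(n) < config.female_fraction, "female", "male")
        ages = rng.integers(config.age_min_months, config.age_max_months + 1, n)
        zs = z_mu + _truncated_normal(rng, config.bmi_z_sd, n, config.bmi_z_truncation)
        for i in range(n):
            counter += 1
            skeletons.append(
                (f"{centre[:3].upper()}-{counter:05d}", centre,
                 sexes[i], int(ages[i]), float(zs[i]))
            )

    cohort_rows, ledger_rows = [], []
    for rid, centre, sex, age_m, z in skeletons:
        rec = synth.draw(sex, age_m, z)
        cohort_rows.append(_cohort_row(rid, centre, rec))
        ledger_rows.append(_ledger_row(rid, centre, rec, hydration))
    cohort = pd.DataFrame(cohort_rows)
    ledger = pd.DataFrame(ledger_rows)

    if config.condition_on_qc:
        # records flagged by the preview get their noise redrawn; a record
        # still flagged after a few attempts is structurally unscreenable
        # (extreme BMI-z) and is redrawn wholesale, z included
        attempts = pd.Series(0, index=cohort.index)
        for _ in range(_MAX_CONDITIONING_ROUNDS):
            preview = _measured_preview(cohort, ledger)
            c2 = qc_enrichment_range(preview, _PREVIEW_THRESHOLDS)
            c3 = qc_fat_outlier(preview, _PREVIEW_THRESHOLDS)
            flagged = ~(c2.all(axis=1) & c3.all(axis=1))
            if not flagged.any():
                break
            for idx in cohort.index[flagged]:
                rid, centre = cohort.at[idx, "id"], cohort.at[idx, "centre"]
                sex = cohort.at[idx, "sex"]
                age_m = int(cohort.at[idx, "age_months"])
                attempts.at[idx] += 1
                if attempts.at[idx] <= 3:
                    z = float(ledger.at[idx, "true_bmi_z"])
                else:
                    z_mu = config.centres[centre][1]
                    z = z_mu + float(
                        _truncated_normal(
                            rng, config.bmi_z_sd, 1, config.bmi_z_truncation
                        )[0]
                    )
                rec = synth.draw(sex, age_m, z)
                cohort.loc[idx] = pd.Series(_cohort_row(rid, centre, rec))
                ledger.loc[idx] = pd.Series(_ledger_row(rid, centre, rec, hydration))
        else:
            raise ConfigurationError(
                "QC conditioning did not converge; the configured noise model "
                "is incompatible with the quality-control screens"
            )

    return cohort, GroundTruthLedger(ledger)


def _cohort_row(rid: str, centre: str, rec: dict) -> dict:
    return {
        "id": rid,
        "centre": centre,
        "sex": rec["sex"],
        "age_months": rec["age_months"],
        "weight_kg": rec["weight_kg"],
        "height_cm": rec["height_m"] * 100.0,
        "dose_g": rec["dose_g"],
        "enr_pre": rec["enr_pre"],
        "enr_3h": rec["enr_3h"],
        "enr_4h": rec["enr_4h"],
    }


def _ledger_row(rid: str, centre: str, rec: dict, hydration: HydrationTable) -> dict:
    return {
        "id": rid,
        "centre": centre,
        "sex": rec["sex"],
        "age_months": rec["age_months"],
        "true_bmi_z": rec["z"],
        "true_bmi": rec["bmi"],
        "true_fat_pct": rec["fat"],
        "true_tbw": rec["tbw"],
        "hydration_coeff": hydration.coefficient(rec["sex"], rec["age_months"] // 12),
        "true_fat_excess": rec["fat"] > FAT_PCT_THRESHOLDS[rec["sex"]],
        "true_bmi_obese": rec["z"] > 2.0,
        "injected_criterion": "",
    }


def inject_qc_failures(
    cohort: pd.DataFrame,
    ledger: GroundTruthLedger,
    rates: dict,
    seed: int,
    hydration: HydrationTable | None = None,
) -> tuple[pd.DataFrame, GroundTruthLedger]:
    """Corrupt a random subset of records in criterion-specific ways.

    ``rates`` maps criterion name to either a global rate or a
    ``{centre: rate}`` mapping.  Criteria:

    - ``plateau``: the 3 h sample is shifted 10 % off the 4 h sample, so
      each post-dose sample deviates ~3.5-5 % from their mean even against
      worst-case measurement noise (> 2 % rule);
    - ``enrichment_range``: both post-dose enrichments are compressed
      toward baseline, implying a total body water far above the
      physiological hydration fraction;
    - ``fat_mismatch``: enrichments are rewritten so the measured fat
      percentage lands 27 points away from the value the cohort-wide
      fat-on-BMI-z fit predicts for the child (upward for lean children,
      downward for fat ones), a displacement no plausible residual masks.

    Every injection is recorded in the ledger; a record receives at most
    one injection.
    """
    for key in rates:
        if key not in INJECTABLE_CRITERIA:
            raise ConfigurationError(
                f"unknown QC criterion {key!r}; expected one of {INJECTABLE_CRITERIA}"
            )
    rng = np.random.default_rng(seed)
    hydration = hydration or HydrationTable.default()
    cohort = cohort.copy()
    frame = ledger.frame.copy().set_index("id")

    def rate_for(criterion: str, centre: str) -> float:
        spec = rates.get(criterion, 0.0)
        if isinstance(spec, dict):
            return float(spec.get(centre, 0.0))
        return float(spec)

    # anchor fat_mismatch targets at the cohort's own fat-on-z prediction so
    # the displacement survives whatever residual the record already carries
    fat_fit = np.polyfit(frame["true_bmi_z"], frame["true_fat_pct"], 1)

    for criterion in INJECTABLE_CRITERIA:
        if criterion not in rates:
            continue
        for pos in cohort.index:
            row = cohort.loc[pos]
            if frame.loc[row["id"], "injected_criterion"] != "":
                continue
            if rng.random() >= rate_for(criterion, row["centre"]):
                continue
            pre = row["enr_pre"]
            if criterion == "plateau":
                cohort.loc[pos, "enr_3h"] = pre + (row["enr_3h"] - pre) * 1.10
            elif criterion == "enrichment_range":
                for col in ("enr_3h", "enr_4h"):
                    cohort.loc[pos, col] = pre + (row[col] - pre) * 0.45
            else:  # fat_mismatch
                pred = float(np.polyval(fat_fit, frame.loc[row["id"], "true_bmi_z"]))
                target = pred + 27.0 if pred <= 28.0 else pred - 27.0
                weight = row["weight_kg"]
                coeff = hydration.coefficient(row["sex"], row["age_months"] // 12)
                tbw_new = (1.0 - target / 100.0) * weight * coeff
                delta_new = (row["dose_g"] * 1000.0) / (DILUTION_SPACE_RATIO * tbw_new)
                cohort.loc[pos, "enr_3h"] = pre + delta_new
                cohort.loc[pos, "enr_4h"] = pre + delta_new
            frame.loc[row["id"], "injected_criterion"] = criterion

    return cohort, GroundTruthLedger(frame.reset_index())
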