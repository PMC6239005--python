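"""Reading and writing the package's delimited interchange formats."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import IncompleteRecordError
from .growth import SEX_ALIASES

COHORT_REQUIRED = ("id", "centre", "sex", "age_months", "weight_kg", "height_cm")
COHORT_OPTIONAL = ("dose_g", "enr_pre", "enr_3h", "enr_4h")


def _read_delimited(path) -> pd.DataFrame:
    with open(path, "rt", encoding="utf-8") as fh:
        head = fh.readline()
        sep = "\t" if head.count("\t") >= head.count(",") else ","
        fh.seek(0)
        return pd.read_csv(fh, sep=sep)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort file and normalise it for analysis.

    Heights are accepted in cm and converted to m (column ``height_m``);
    sex encodings {M,F}/{male,female}/{1,2} are normalised; records whose
    sex cannot be interpreted keep a missing sex and are excluded later
    with an explicit reason rather than dropped here.
    """
    frame = _read_delimited(path)
    missing = set(COHORT_REQUIRED) - set(frame.columns)
    if missing:
        raise IncompleteRecordError(
            f"cohort file {path} lacks required columns {sorted(missing)}"
        )
    return normalize_cohort(frame)


def normalize_cohort(frame: pd.DataFrame) -> pd.DataFrame:
    """Apply the ingest normalisations to an in-memory cohort frame."""
    frame = frame.copy()
    frame["sex"] = (
        frame["sex"].astype(str).str.strip().str.lower().map(SEX_ALIASES)
    )
    frame["height_m"] = frame["height_cm"] / 100.0
    for col in COHORT_OPTIONAL:
        if col not in frame.columns:
            frame[col] = np.nan
    return frame


def write_cohort(frame: pd.DataFrame, path) -> None:
    cols = [c for c in (*COHORT_REQUIRED, *COHORT_OPTIONAL) if c in frame.columns]
    frame[cols].to_csv(path, index=False)
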