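"""Column schema of the cohort table and biomarker panel metadata.

The pipeline operates on a pandas DataFrame with one row per participant.
Baseline columns:

==================  =========================================================
``participant_id``  opaque string identifier
``age``             years at baseline
``sex``             0 = male, 1 = female
``apoe_e4``         0/1 APOE-e4 carrier flag
``education``       years of schooling (used as covariate for cognition)
``csf_ab4240``      CSF Abeta42/40 ratio (unitless, decreases with pathology)
``csf_mptau181``    CSF mid-region p-tau181, pg/ml
``plasma_ptau181``  plasma p-tau181, pg/ml
``plasma_ptau217``  plasma p-tau217, pg/ml (arbitrary assay units)
``plasma_ptau231``  plasma p-tau231, pg/ml
``plasma_gfap``     plasma GFAP, pg/ml
``plasma_nfl``      plasma NfL, pg/ml
``plasma_ab4240``   plasma Abeta42/40 ratio (unitless, decreases)
``centiloids``      amyloid-PET Centiloids (may be missing, may be negative)
==================  =========================================================

Follow-up columns (separate table, joined on ``participant_id``) carry
visit-2 Centiloids, visit dates and the four cognitive subtests at both
visits; see :mod:`preclad.synthetic` for the generator that emits them.

Missing values are empty CSV fields / NaN.  An external CSV with different
column names is adapted through a plain-text key->value mapping file
(``load_cohort``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

ID = "participant_id"
AGE = "age"
SEX = "sex"
APOE = "apoe_e4"
EDUCATION = "education"
CENTILOIDS = "centiloids"

CSF_AB4240 = "csf_ab4240"
CSF_MPTAU181 = "csf_mptau181"


@dataclass(frozen=True)
class BiomarkerInfo:
    """Transformation and orientation metadata for one biomarker column.

    ``log10`` marks concentrations that are log10-transformed before any
    modelling (all except the two Abeta42/40 ratios).  ``direction`` is +1
    for markers that rise with amyloid pathology and -1 for the ratios,
    which fall.
    """

    column: str
    log10: bool
    direction: int
    label: str


PLASMA_PANEL: tuple[BiomarkerInfo, ...] = (
    BiomarkerInfo("plasma_ptau181", True, +1, "p-tau181"),
    BiomarkerInfo("plasma_ptau217", True, +1, "p-tau217"),
    BiomarkerInfo("plasma_ptau231", True, +1, "p-tau231"),
    BiomarkerInfo("plasma_gfap", True, +1, "GFAP"),
    BiomarkerInfo("plasma_nfl", True, +1, "NfL"),
    BiomarkerInfo("plasma_ab4240", False, -1, "Abeta42/40"),
)

CSF_PANEL: tuple[BiomarkerInfo, ...] = (
    BiomarkerInfo(CSF_AB4240, False, -1, "CSF Abeta42/40"),
    BiomarkerInfo(CSF_MPTAU181, True, +1, "CSF M-p-tau181"),
)

PLASMA_COLUMNS = tuple(b.column for b in PLASMA_PANEL)
BIOMARKER_COLUMNS = PLASMA_COLUMNS + tuple(b.column for b in CSF_PANEL)
RATIO_COLUMNS = tuple(b.column for b in PLASMA_PANEL + CSF_PANEL if not b.log10)

BASELINE_REQUIRED = (
    ID, AGE, SEX, APOE, CSF_AB4240, CSF_MPTAU181,
) + PLASMA_COLUMNS

# follow-up table
CL_V2 = "centiloids_v2"
PET_DATE_V1 = "pet_date_v1"
PET_DATE_V2 = "pet_date_v2"
COG_DATE_V1 = "cog_date_v1"
COG_DATE_V2 = "cog_date_v2"

SUBTESTS = ("fcsrt", "lm_delayed", "coding", "fluency")
SUBTEST_LABELS = {
    "fcsrt": "FCSRT immediate total recall",
    "lm_delayed": "Logical Memory delayed recall",
    "coding": "Coding",
    "fluency": "Semantic fluency (animals/1 min)",
}


def subtest_col(name: str, visit: int) -> str:
    return f"{name}_v{visit}"


def biomarker_info(column: str) -> BiomarkerInfo:
    for info in PLASMA_PANEL + CSF_PANEL:
        if info.column == column:
            return info
    raise KeyError(f"unknown biomarker column: {column!r}")


def load_cohort(path: str | Path, mapping: str | Path | None = None) -> pd.DataFrame:
    """Read a cohort CSV, optionally renaming columns via a mapping file.

    The mapping file is plain-text key: value YAML where keys are the
    canonical column names above and values are the names used in the CSV.
    Sex accepts 0/1 or the strings M/F (and male/female, case-insensitive).
    """
    df = pd.read_csv(path)
    if mapping is not None:
        with open(mapping) as fh:
            m = yaml.safe_load(fh) or {}
        df = df.rename(columns={v: k for k, v in m.items()})
    if SEX in df.columns and df[SEX].dtype == object:
        df[SEX] = (
            df[SEX].astype(str).str.strip().str.lower()
            .map({"m": 0, "male": 0, "f": 1, "female": 1})
        )
    return df


def validate_schema(df: pd.DataFrame, require_centiloids: bool = False,
                    require_apoe: bool = False) -> list[str]:
    """Check required columns, value ranges and positivity.

    Returns the list of all violations found (empty when the table is
    usable).  Violations are data, not exceptions: callers decide whether
    to abort.
    """
    problems: list[str] = []
    for col in BASELINE_REQUIRED:
        if col not in df.columns:
            if col == APOE and not require_apoe:
                continue
            problems.append(f"missing required column: {col}")
    if require_centiloids and CENTILOIDS not in df.columns:
        problems.append(f"missing required column: {CENTILOIDS}")
    if problems:
        return problems

    if df[ID].duplicated().any():
        dupes = df.loc[df[ID].duplicated(), ID].tolist()
        problems.append(f"duplicate participant ids: {dupes[:5]}")
    age = pd.to_numeric(df[AGE], errors="coerce")
    bad = df.index[(age <= 0) | age.isna()]
    for i in bad:
        problems.append(f"row {i}: age must be a positive number")
    for col in RATIO_COLUMNS:
        if col not in df.columns:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.notna() & ~((vals > 0) & (vals < 1))]
        for i in bad:
            problems.append(f"row {i}: {col} must lie in (0, 1)")
    for col in BIOMARKER_COLUMNS:
        if col in RATIO_COLUMNS or col not in df.columns:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.notna() & (vals <= 0)]
        for i in bad:
            problems.append(f"row {i}: {col} must be strictly positive")
    for col in (SEX, APOE):
        if col in df.columns:
            vals = df[col].dropna()
            if not np.isin(vals.unique(), [0, 1]).all():
                problems.append(f"{col} must be coded 0/1")
    return problems
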