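"""Biomarker transformation, group classification and reference z-scoring.

Order of operations for the trajectory z-scores is fixed as
log10-transform -> age/sex residualization -> standardization against the
amyloid-normal reference stratum (CSF Abeta42/40 > 0.1); the order of the
last two steps can be swapped via ``residualize_before_zscore`` because the
source description is ambiguous on that point.

Augmented columns are namespaced with double-underscore suffixes:
``<col>__t`` (transformed scale), ``<col>__resid`` (age/sex residual),
``<col>__z`` (reference z-score), plus ``at_group``, ``csf_pet_group`` and
``centiloid_stage`` labels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import config as cfg
from . import schema

AT_LABELS = ("A-T-", "A+T-", "A+T+", "A-T+")
CSF_PET_LABELS = ("negative", "low_burden", "positive", "unclassified_discordant")
STAGE_LABELS = ("<12", "12-30", ">=30")


def log_transform_panel(df: pd.DataFrame,
                        columns: tuple[str, ...] = schema.BIOMARKER_COLUMNS,
                        ) -> tuple[pd.DataFrame, dict[str, str]]:
    """log10-transform concentration biomarkers; pass ratios through.

    None of the concentration markers are normally distributed on the raw
    scale, so every biomarker except the two Abeta42/40 ratios is replaced
    by its base-10 logarithm.  Returns the transformed copy and a
    per-column record of what was applied.

    Raises ``ValueError`` naming the first offending row/column if a
    concentration is zero or negative (log10 undefined).
    """
    out = df.copy()
    meta: dict[str, str] = {}
    for col in columns:
        if col not in out.columns:
            continue
        info = schema.biomarker_info(col)
        vals = pd.to_numeric(out[col], errors="coerce")
        if info.log10:
            bad = out.index[vals.notna() & (vals <= 0)]
            if len(bad):
                i = bad[0]
                raise ValueError(
                    f"non-positive value in column {col!r} at row {i} "
                    f"(id={out.loc[i, schema.ID] if schema.ID in out else i}): "
                    "log10 transform undefined")
            out[col] = np.log10(vals)
            meta[col] = "log10"
        else:
            meta[col] = "identity"
    return out, meta


def classify_at(csf_ab4240, csf_mptau181):
    """Four-way AT label from the two CSF cutoffs (strict inequalities).

    A+ iff CSF Abeta42/40 < 0.071, T+ iff CSF M-p-tau181 > 24 pg/ml.
    Accepts scalars or array-likes; missing values raise.
    """
    ab = np.asarray(csf_ab4240, dtype=float)
    pt = np.asarray(csf_mptau181, dtype=float)
    if np.isnan(ab).any() or np.isnan(pt).any():
        raise ValueError("AT classification requires both CSF values present")
    a = ab < cfg.CSF_AB4240_POSITIVITY
    t = pt > cfg.CSF_MPTAU181_POSITIVITY
    labels = np.where(a, np.where(t, "A+T+", "A+T-"), np.where(t, "A-T+", "A-T-"))
    return labels.item() if labels.ndim == 0 else labels


def classify_csf_pet(csf_ab4240, centiloids):
    """Three-group CSF/PET amyloid status plus an explicit discordant cell.

    negative: CSF >= 0.071 and CL < 30; low_burden: CSF < 0.071 and CL < 30;
    positive: CSF < 0.071 and CL >= 30.  The remaining cell (CSF normal but
    CL >= 30) is not defined by the three-group system and is labelled
    ``unclassified_discordant`` rather than silently binned.  Missing
    Centiloids yield a missing group.
    """
    ab = np.asarray(csf_ab4240, dtype=float)
    cl = np.asarray(centiloids, dtype=float)
    if np.isnan(ab).any():
        raise ValueError("CSF/PET classification requires the CSF ratio")
    a = ab < cfg.CSF_AB4240_POSITIVITY
    high = cl >= cfg.CL_ESTABLISHED
    labels = np.where(
        a, np.where(high, "positive", "low_burden"),
        np.where(high, "unclassified_discordant", "negative"))
    labels = np.where(np.isnan(cl), None, labels)
    return labels.item() if labels.ndim == 0 else labels


def centiloid_stage(centiloids):
    """Stage by the early (12 CL) and established (30 CL) cutoffs."""
    cl = np.asarray(centiloids, dtype=float)
    labels = np.where(cl < cfg.CL_EARLY, "<12",
                      np.where(cl < cfg.CL_ESTABLISHED, "12-30", ">=30"))
    labels = np.where(np.isnan(cl), None, labels)
    return labels.item() if labels.ndim == 0 else labels


def residualize(values, age, sex) -> np.ndarray:
    """OLS residuals of ``values`` on intercept + age + sex.

    NaNs propagate: rows with any missing input get NaN residuals and do
    not influence the fit.  Raises on a collinear design (e.g. single sex
    with constant age).
    """
    v = np.asarray(values, dtype=float)
    a = np.asarray(age, dtype=float)
    s = np.asarray(sex, dtype=float)
    if not (v.shape == a.shape == s.shape):
        raise ValueError("values, age and sex must have equal length")
    ok = np.isfinite(v) & np.isfinite(a) & np.isfinite(s)
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete cases to residualize")
    X = np.column_stack([np.ones(ok.sum()), a[ok], s[ok]])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("collinear age/sex design: residualization undefined")
    beta, *_ = np.linalg.lstsq(X, v[ok], rcond=None)
    out = np.full(v.shape, np.nan)
    out[ok] = v[ok] - X @ beta
    return out


def zscore_to_reference(values, reference_mask) -> np.ndarray:
    """Standardize all values by the mean/SD of the reference subset.

    Sample SD (n-1 denominator).  Raises if the reference subset has
    fewer than two finite members or zero spread.
    """
    v = np.asarray(values, dtype=float)
    m = np.asarray(reference_mask, dtype=bool)
    if v.shape != m.shape:
        raise ValueError("values and reference_mask must have equal length")
    ref = v[m & np.isfinite(v)]
    if ref.size < 2:
        raise ValueError("reference group needs >= 2 finite members")
    sd = ref.std(ddof=1)
    if sd <= 0:
        raise ValueError("reference group has zero spread")
    return (v - ref.mean()) / sd


def preprocess_cohort(df: pd.DataFrame,
                      run_config: cfg.RunConfig | None = None) -> pd.DataFrame:
    """Full preprocessing pass: transform, label, residualize, z-score.

    Returns a copy of ``df`` with namespaced analysis columns appended.
    Raw columns are preserved unchanged.
    """
    rc = run_config or cfg.RunConfig()
    out = df.copy()
    transformed, meta = log_transform_panel(df)
    for col, how in meta.items():
        out[f"{col}__t"] = transformed[col]

    out["at_group"] = classify_at(df[schema.CSF_AB4240], df[schema.CSF_MPTAU181])
    if schema.CENTILOIDS in df.columns:
        out["csf_pet_group"] = classify_csf_pet(
            df[schema.CSF_AB4240], df[schema.CENTILOIDS])
        out["centiloid_stage"] = centiloid_stage(df[schema.CENTILOIDS])

    ref_mask = (df[schema.CSF_AB4240] > rc.reference_ab4240).to_numpy()
    age = df[schema.AGE].to_numpy(float)
    sex = df[schema.SEX].to_numpy(float)
    for info in schema.PLASMA_PANEL:
        t = out[f"{info.column}__t"].to_numpy(float)
        resid = residualize(t, age, sex)
        out[f"{info.column}__resid"] = resid
        if rc.residualize_before_zscore:
            out[f"{info.column}__z"] = zscore_to_reference(resid, ref_mask)
        else:
            z = zscore_to_reference(t, ref_mask)
            out[f"{info.column}__z"] = residualize(z, age, sex)
    out.attrs["transforms"] = meta
    out.attrs["reference_n"] = int(ref_mask.sum())
    return out
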