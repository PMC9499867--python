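"""PACC composite, annualized change and baseline-biomarker change regressions.

The cognitive composite averages z-scores of four subtests (FCSRT immediate
total recall, Logical Memory delayed recall, Coding, Semantic fluency),
standardized against the biomarker-negative (A-T-) subgroup at baseline;
visit-2 composites reuse the baseline reference statistics.  MMSE is not
part of the composite (insensitive in preclinical cohorts).  Annualized
change is (visit2 - visit1) / years between visits (365.25-day years).
Change regressions adjust for age and sex (plus education for cognition)
and optionally include a biomarker-by-amyloid-status interaction or a
restriction to participants below 30 Centiloids at baseline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import config as cfg
from . import schema
from .discrimination import fdr_adjust


def compute_pacc(subtests: pd.DataFrame, reference_mask,
                 baseline_stats: dict[str, tuple[float, float]] | None = None,
                 ) -> tuple[np.ndarray, dict[str, tuple[float, float]]]:
    """Composite = mean of the four subtest z-scores.

    ``subtests`` has one column per subtest (any visit).  Reference mean/SD
    per subtest come from the baseline A-T- subgroup (``reference_mask``),
    or from ``baseline_stats`` for visit-2 scores so both visits share the
    baseline scale.  Returns the composite and the stats used.
    """
    missing = [c for c in schema.SUBTESTS if c not in subtests.columns]
    if missing:
        raise ValueError(f"missing subtest columns: {missing}")
    if baseline_stats is None:
        m = np.asarray(reference_mask, dtype=bool)
        baseline_stats = {}
        for name in schema.SUBTESTS:
            vals = subtests[name].to_numpy(float)[m]
            vals = vals[np.isfinite(vals)]
            if vals.size < 2:
                raise ValueError(f"reference group too small for {name!r}")
            sd = vals.std(ddof=1)
            if sd <= 0:
                raise ValueError(f"zero reference spread in subtest {name!r}")
            baseline_stats[name] = (float(vals.mean()), float(sd))
    z = np.column_stack([
        (subtests[name].to_numpy(float) - baseline_stats[name][0])
        / baseline_stats[name][1]
        for name in schema.SUBTESTS])
    return z.mean(axis=1), baseline_stats


def annualized_change(v1, v2, t1, t2) -> np.ndarray:
    """(v2 - v1) / years between t1 and t2, with 365.25-day years.

    ``t1``/``t2`` may be dates (anything ``pd.to_datetime`` accepts) or
    numeric times in years.  Non-positive intervals raise.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    t1a, t2a = np.asarray(t1), np.asarray(t2)
    if np.issubdtype(t1a.dtype, np.number) and np.issubdtype(t2a.dtype, np.number):
        dt = t2a.astype(float) - t1a.astype(float)
    else:
        d1 = pd.to_datetime(pd.Series(np.atleast_1d(t1)))
        d2 = pd.to_datetime(pd.Series(np.atleast_1d(t2)))
        dt = (d2 - d1).dt.days.to_numpy(float) / 365.25
    dt = np.asarray(dt, dtype=float)
    valid = np.isfinite(dt)
    if np.any(dt[valid] <= 0):
        raise ValueError("visit 2 must postdate visit 1")
    out = (v2 - v1) / dt
    return out if out.ndim else float(out)


def change_regression(change, biomarker, age, sex, abeta_status=None,
                      education=None, include_interaction: bool = False,
                      subset_mask=None) -> pd.DataFrame:
    """OLS of annualized change on a baseline biomarker with covariates.

    Covariates: age + sex (+ education when given, as for cognitive
    outcomes).  ``include_interaction`` adds amyloid status and its product
    with the biomarker.  ``subset_mask`` restricts the fit (e.g. baseline
    < 30 Centiloids sensitivity analysis).  Returns a tidy coefficient
    table (term, coef, se, t, p).
    """
    y = np.asarray(change, dtype=float)
    cols = {"biomarker": np.asarray(biomarker, dtype=float),
            "age": np.asarray(age, dtype=float),
            "sex": np.asarray(sex, dtype=float)}
    if education is not None:
        cols["education"] = np.asarray(education, dtype=float)
    if include_interaction:
        if abeta_status is None:
            raise ValueError("interaction model needs abeta_status")
        st = np.asarray(abeta_status, dtype=float)
        cols["abeta_pos"] = st
        cols["biomarker_x_abeta"] = cols["biomarker"] * st
    X = np.column_stack(list(cols.values()))
    keep = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    if subset_mask is not None:
        keep &= np.asarray(subset_mask, dtype=bool)
    if keep.sum() == 0:
        raise ValueError("empty subset after masking")
    if keep.sum() < X.shape[1] + 3:
        raise ValueError("too few complete cases for the regression")
    Xc = sm.add_constant(X[keep], has_constant="add")
    res = sm.OLS(y[keep], Xc).fit()
    terms = ["intercept"] + list(cols)
    return pd.DataFrame({"term": terms, "coef": res.params, "se": res.bse,
                         "t": res.tvalues, "p": res.pvalues,
                         "n": int(keep.sum())})


def change_report(baseline: pd.DataFrame, followup: pd.DataFrame,
                  run_config: cfg.RunConfig | None = None) -> pd.DataFrame:
    """Change regressions of both outcomes on every plasma biomarker.

    For each biomarker (log10-transformed baseline value): the adjusted
    association with annualized PACC change (age + sex + education) and
    with annualized Centiloid change (age + sex); each also refit with the
    amyloid-status interaction, the Centiloid outcome additionally within
    the <30-Centiloid subset.  BH-FDR is applied to the biomarker (and
    interaction) p-values within each outcome block.
    """
    rc = run_config or cfg.RunConfig()
    df = baseline.merge(followup, on=schema.ID, how="inner", validate="1:1")
    if len(df) == 0:
        raise ValueError("no overlapping participant ids")
    at = df["at_group"] if "at_group" in df else None
    if at is None:
        from .preprocess import classify_at
        at = pd.Series(classify_at(df[schema.CSF_AB4240], df[schema.CSF_MPTAU181]))
    ref_mask = (at == "A-T-").to_numpy()
    abeta_pos = (df[schema.CSF_AB4240].to_numpy(float)
                 < rc.csf_ab4240_positivity).astype(float)
    age = df[schema.AGE].to_numpy(float)
    sex = df[schema.SEX].to_numpy(float)
    edu = df[schema.EDUCATION].to_numpy(float) if schema.EDUCATION in df else None

    # PACC at both visits on the baseline reference scale
    v1 = df[[schema.subtest_col(s, 1) for s in schema.SUBTESTS]]
    v1 = v1.set_axis(list(schema.SUBTESTS), axis=1)
    v2 = df[[schema.subtest_col(s, 2) for s in schema.SUBTESTS]]
    v2 = v2.set_axis(list(schema.SUBTESTS), axis=1)
    has_cog = v1.notna().all(axis=1).to_numpy() & v2.notna().all(axis=1).to_numpy()
    outcomes: dict[str, tuple[np.ndarray, np.ndarray | None]] = {}
    if has_cog.sum() >= 10:
        pacc1, stats1 = compute_pacc(v1[has_cog], ref_mask[has_cog])
        pacc2, _ = compute_pacc(v2[has_cog], None, baseline_stats=stats1)
        d_pacc = np.full(len(df), np.nan)
        d_pacc[has_cog] = annualized_change(
            pacc1, pacc2,
            df.loc[has_cog, schema.COG_DATE_V1], df.loc[has_cog, schema.COG_DATE_V2])
        outcomes["pacc"] = (d_pacc, edu)
    cl1 = df[schema.CENTILOIDS].to_numpy(float) if schema.CENTILOIDS in df else None
    if cl1 is not None and schema.CL_V2 in df:
        cl2 = df[schema.CL_V2].to_numpy(float)
        has_pet = np.isfinite(cl1) & np.isfinite(cl2)
        d_cl = np.full(len(df), np.nan)
        if has_pet.sum() >= 10:
            d_cl[has_pet] = annualized_change(
                cl1[has_pet], cl2[has_pet],
                df.loc[has_pet, schema.PET_DATE_V1], df.loc[has_pet, schema.PET_DATE_V2])
            outcomes["centiloids"] = (d_cl, None)

    rows = []
    for outcome, (chg, extra_edu) in outcomes.items():
        for info in schema.PLASMA_PANEL:
            raw = df[info.column].to_numpy(float)
            bm = np.log10(raw) if info.log10 else raw
            variants = [("main", False, None),
                        ("interaction", True, None),
                        ("abeta_positive", False, abeta_pos == 1),
                        ("abeta_negative", False, abeta_pos == 0)]
            if outcome == "centiloids":
                variants.append(("cl_below_30", False,
                                 cl1 < rc.cl_established))
            for variant, inter, mask in variants:
                tab = change_regression(chg, bm, age, sex,
                                        abeta_status=abeta_pos,
                                        education=extra_edu,
                                        include_interaction=inter,
                                        subset_mask=mask)
                tab = tab.assign(outcome=outcome, biomarker=info.column,
                                 variant=variant)
                rows.append(tab)
    out = pd.concat(rows, ignore_index=True)
    out["p_fdr"] = np.nan
    for outcome in out["outcome"].unique():
        for term, variant in (("biomarker", "main"),
                              ("biomarker_x_abeta", "interaction")):
            m = ((out["outcome"] == outcome) & (out["term"] == term)
                 & (out["variant"] == variant))
            if m.any():
                out.loc[m, "p_fdr"] = fdr_adjust(out.loc[m, "p"].to_numpy())
    return out
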