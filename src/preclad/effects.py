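"""Group-difference stage: Cohen's d on age/sex residuals, and ANCOVA with
Tukey-corrected pairwise comparisons across biomarker-defined groups."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import preprocess, schema
from .discrimination import fdr_adjust


@dataclass
class EffectSizeResult:
    """Standardized mean difference between two groups.

    ``d`` is oriented so that positive means the second (more pathologic)
    group moved in the pathological direction; ``d_raw`` keeps the plain
    (mean_b - mean_a)/pooled-SD sign.
    """

    biomarker: str
    group_a: str
    group_b: str
    d: float
    ci_low: float
    ci_high: float
    n_a: int
    n_b: int
    p_value: float
    d_raw: float


def cohens_d(group_a, group_b, direction: int = 1,
             biomarker: str = "", group_a_name: str = "a",
             group_b_name: str = "b") -> EffectSizeResult:
    """Cohen's d with pooled SD and a normal-approximation 95% CI.

    d = (mean_b - mean_a) / s_p with
    s_p^2 = ((n_a-1)s_a^2 + (n_b-1)s_b^2) / (n_a+n_b-2).
    The CI uses se(d) = sqrt((n_a+n_b)/(n_a n_b) + d^2/(2(n_a+n_b))); the
    p-value comes from the pooled-variance two-sample t-test.  ``direction``
    (+1/-1) orients the reported ``d`` so that positive = change in the
    pathological direction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs >= 2 values")
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 <= 0:
        raise ValueError("zero pooled standard deviation")
    d_raw = (b.mean() - a.mean()) / np.sqrt(sp2)
    se = np.sqrt((na + nb) / (na * nb) + d_raw ** 2 / (2 * (na + nb)))
    _, p = stats.ttest_ind(b, a, equal_var=True)
    d = direction * d_raw
    lo, hi = d - 1.96 * se, d + 1.96 * se
    return EffectSizeResult(biomarker, group_a_name, group_b_name,
                            float(d), float(lo), float(hi), na, nb,
                            float(p), float(d_raw))


def ancova_pairwise(values, groups, age, sex,
                    include_pairwise: bool = True) -> dict:
    """One-way ANCOVA (group factor adjusting for age and sex) with Tukey
    post-hoc pairwise comparisons of the adjusted group means.

    Returns a dict with the omnibus F statistic and p-value for the group
    factor, and a DataFrame of pairwise contrasts: difference of adjusted
    means, unadjusted p and Tukey studentized-range-adjusted p.
    ``include_pairwise=False`` skips the post-hoc stage (the studentized-
    range tail evaluation dominates runtime in simulation studies).
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    a = np.asarray(age, dtype=float)
    s = np.asarray(sex, dtype=float)
    ok = np.isfinite(v) & np.isfinite(a) & np.isfinite(s) & (g != None)  # noqa: E711
    v, g, a, s = v[ok], g[ok], a[ok], s[ok]
    levels, gidx = np.unique(g, return_inverse=True)
    k = levels.size
    if k < 2:
        raise ValueError("need >= 2 groups")
    for j, lev in enumerate(levels):
        if (gidx == j).sum() < 2:
            raise ValueError(f"group {lev!r} has fewer than 2 members")

    # full model: intercept + k-1 group dummies + age + sex
    dummies = (gidx[:, None] == np.arange(1, k)).astype(float)
    X_full = np.column_stack([np.ones(v.size), dummies, a, s])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        for j, lev in enumerate(levels):
            sub = X_full[gidx == j]
            if np.linalg.matrix_rank(sub[:, [0, k, k + 1]]) < 2:
                raise ValueError(f"group {lev!r} collinear with covariates")
        raise ValueError("ANCOVA design matrix is rank deficient")
    full = sm.OLS(v, X_full).fit()
    reduced = sm.OLS(v, np.column_stack([np.ones(v.size), a, s])).fit()
    df_num = k - 1
    df_den = full.df_resid
    F = ((reduced.ssr - full.ssr) / df_num) / (full.ssr / df_den)
    p_omnibus = stats.f.sf(F, df_num, df_den)

    # pairwise Tukey on adjusted means (evaluated at covariate means,
    # i.e. differences of the group-dummy coefficients)
    covb = full.cov_params()
    coefs = np.concatenate([[0.0], full.params[1:k]])  # group effects vs level 0
    rows = []
    if not include_pairwise:
        return {"f_statistic": float(F), "p_omnibus": float(p_omnibus),
                "df": (df_num, float(df_den)), "pairwise": pd.DataFrame(rows)}
    for i in range(k):
        for j in range(i + 1, k):
            c = np.zeros(X_full.shape[1])
            if i > 0:
                c[i] -= 1.0
            c[j] += 1.0
            diff = coefs[j] - coefs[i]
            se = float(np.sqrt(c @ covb @ c))
            t = diff / se
            p_unadj = 2 * stats.t.sf(abs(t), df_den)
            q = abs(t) * np.sqrt(2.0)
            p_tukey = float(stats.studentized_range.sf(q, k, df_den))
            rows.append({"group_a": levels[i], "group_b": levels[j],
                         "diff_adjusted": float(diff), "se": se,
                         "p_unadjusted": float(p_unadj),
                         "p_tukey": min(1.0, p_tukey)})
    return {"f_statistic": float(F), "p_omnibus": float(p_omnibus),
            "df": (df_num, float(df_den)), "pairwise": pd.DataFrame(rows)}


#: reference (least-pathologic) level of each grouping system
_REFERENCE_LEVEL = {"at": "A-T-", "csf_pet": "negative"}
_GROUP_ORDER = {
    "at": ("A+T-", "A+T+", "A-T+"),
    "csf_pet": ("low_burden", "positive"),
}


def effect_size_profile(pre: pd.DataFrame, grouping: str = "at",
                        biomarkers: tuple[str, ...] = schema.PLASMA_COLUMNS,
                        ) -> pd.DataFrame:
    """Cohen's d of every biomarker for each group vs the reference group.

    ``grouping`` is ``"at"`` (reference A-T-) or ``"csf_pet"`` (reference
    CSF/PET-negative; the discordant cell is never compared).  Residual
    columns from :func:`preclad.preprocess.preprocess_cohort` are the
    dependent variable.  Returns a tidy frame with BH-FDR adjusted p.
    """
    if grouping not in _REFERENCE_LEVEL:
        raise ValueError("grouping must be 'at' or 'csf_pet'")
    col = "at_group" if grouping == "at" else "csf_pet_group"
    labels = pre[col].to_numpy(dtype=object)
    ref_level = _REFERENCE_LEVEL[grouping]
    ref_mask = labels == ref_level
    if ref_mask.sum() == 0:
        raise ValueError(f"empty reference group {ref_level!r}")
    rows = []
    for bm in biomarkers:
        info = schema.biomarker_info(bm)
        resid = pre[f"{bm}__resid"].to_numpy(float)
        for level in _GROUP_ORDER[grouping]:
            mask = labels == level
            if mask.sum() < 2:
                continue
            res = cohens_d(resid[ref_mask], resid[mask],
                           direction=info.direction, biomarker=bm,
                           group_a_name=ref_level, group_b_name=level)
            rows.append({"biomarker": bm, "reference": ref_level,
                         "group": level, "d": res.d, "d_raw": res.d_raw,
                         "ci_low": res.ci_low, "ci_high": res.ci_high,
                         "n_reference": res.n_a, "n_group": res.n_b,
                         "p": res.p_value})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_fdr"] = fdr_adjust(out["p"].to_numpy())
    return out


def effects_report(pre: pd.DataFrame, grouping: str = "at") -> dict:
    """ANCOVA omnibus/Tukey plus the Cohen's d profile for one grouping."""
    col = "at_group" if grouping == "at" else "csf_pet_group"
    labels = pre[col].to_numpy(dtype=object)
    wanted = [_REFERENCE_LEVEL[grouping]] + list(_GROUP_ORDER[grouping])
    # groups too small to model are dropped, not fatal (tiny cohorts)
    sizes = pd.Series(labels).value_counts()
    usable = [g for g in wanted if sizes.get(g, 0) >= 2]
    if len(usable) < len(wanted):
        warnings.warn(f"dropping groups with <2 members: "
                      f"{sorted(set(wanted) - set(usable))}")
    keep = np.isin(labels, usable)
    age = pre[schema.AGE].to_numpy(float)
    sex = pre[schema.SEX].to_numpy(float)
    ancova_rows = []
    for bm in schema.PLASMA_COLUMNS:
        res = ancova_pairwise(pre[f"{bm}__t"].to_numpy(float)[keep],
                              labels[keep], age[keep], sex[keep])
        pw = res["pairwise"].assign(biomarker=bm)
        ancova_rows.append(pw.assign(p_omnibus=res["p_omnibus"],
                                     f_statistic=res["f_statistic"]))
    return {"effect_sizes": effect_size_profile(pre, grouping),
            "ancova": pd.concat(ancova_rows, ignore_index=True)}
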