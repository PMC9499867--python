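"""ROC stage: AUCs with DeLong inference, model comparison against a base
risk-factor model, operating points, age stratification and FDR correction.

AUC is the Mann-Whitney statistic with tied pairs counted one half; its
variance and the covariance between two correlated AUCs come from DeLong's
placement values (structural components).  Combined models are in-sample
maximum-likelihood logistic regressions (apparent AUC, no cross-validation);
a Firth-type penalized fit is substituted, and flagged, when the likelihood
is separated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from . import config as cfg
from . import schema

log = logging.getLogger(__name__)


@dataclass
class RocResult:
    model: str
    auc: float
    auc_var: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int


@dataclass
class OperatingPoint:
    cutoff: float
    sensitivity: float
    specificity: float
    criterion: str
    attained: bool = True


@dataclass
class DeLongResult:
    delta_auc: float
    z: float
    p: float
    degenerate: bool = False


def _check_labels(labels) -> np.ndarray:
    y = np.asarray(labels)
    if not np.isin(y, [0, 1]).all():
        raise ValueError("labels must be 0/1")
    y = y.astype(int)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    return y


def _placements(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values: V10 per positive, V01 per negative.

    V10_i = fraction of negatives scored below positive i (ties half);
    V01_j = fraction of positives scored above negative j (ties half).
    """
    pos = scores[y == 1]
    neg = scores[y == 0]
    sn = np.sort(neg)
    left = np.searchsorted(sn, pos, side="left")
    right = np.searchsorted(sn, pos, side="right")
    v10 = (left + 0.5 * (right - left)) / neg.size
    sp = np.sort(pos)
    left = np.searchsorted(sp, neg, side="left")
    right = np.searchsorted(sp, neg, side="right")
    v01 = ((sp.size - right) + 0.5 * (right - left)) / pos.size
    return v10, v01


def roc_auc(scores, labels, model: str = "model") -> RocResult:
    """AUC with DeLong variance and a logit-scale Wald 95% CI."""
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=float)
    v10, v01 = _placements(s, y)
    auc = float(v10.mean())
    m, n = v10.size, v01.size
    var = (v10.var(ddof=1) / m if m > 1 else 0.0) \
        + (v01.var(ddof=1) / n if n > 1 else 0.0)
    if var > 0 and 0 < auc < 1:
        se_logit = np.sqrt(var) / (auc * (1 - auc))
        l = np.log(auc / (1 - auc))
        lo = expit(l - 1.96 * se_logit)
        hi = expit(l + 1.96 * se_logit)
    else:
        lo = hi = auc
    return RocResult(model, auc, float(var), float(lo), float(hi), m, n)


def delong_test(scores_1, scores_2, labels) -> DeLongResult:
    """Two-sided DeLong test for two correlated AUCs on the same subjects.

    Rank-equivalent score vectors have identical placements, hence zero
    variance of the difference; that degenerate case returns p = 1 with a
    flag rather than a 0/0.
    """
    y = _check_labels(labels)
    s1 = np.asarray(scores_1, dtype=float)
    s2 = np.asarray(scores_2, dtype=float)
    if s1.shape != s2.shape or s1.shape != y.shape:
        raise ValueError("scores_1, scores_2 and labels must be aligned")
    v10_1, v01_1 = _placements(s1, y)
    v10_2, v01_2 = _placements(s2, y)
    m, n = v10_1.size, v01_1.size
    d_auc = float(v10_2.mean() - v10_1.mean())
    var = 0.0
    if m > 1:
        c10 = np.cov(np.vstack([v10_1, v10_2]), ddof=1)
        var += (c10[0, 0] + c10[1, 1] - 2 * c10[0, 1]) / m
    if n > 1:
        c01 = np.cov(np.vstack([v01_1, v01_2]), ddof=1)
        var += (c01[0, 0] + c01[1, 1] - 2 * c01[0, 1]) / n
    if var <= 1e-16:
        return DeLongResult(d_auc, 0.0, 1.0, degenerate=True)
    z = d_auc / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return DeLongResult(d_auc, float(z), float(p))


def operating_points(scores, labels,
                     fixed_sensitivity: float = cfg.FIXED_SENSITIVITY,
                     ) -> tuple[OperatingPoint, OperatingPoint]:
    """Youden-index and fixed-sensitivity operating points.

    Candidate cutoffs are the observed scores (positive call: score >=
    cutoff).  The Youden point maximizes sensitivity + specificity - 1,
    breaking ties toward higher specificity; the fixed-sensitivity point is
    the largest cutoff whose sensitivity still reaches the target (the
    attained maximum, flagged, when the target is unattainable).
    """
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=float)
    cuts = np.unique(s)  # ascending
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    # counts of scores >= cutoff, per class
    sp = np.sort(s[y == 1])
    sn = np.sort(s[y == 0])
    sens = (n_pos - np.searchsorted(sp, cuts, side="left")) / n_pos
    spec = np.searchsorted(sn, cuts, side="left") / n_neg
    j = sens + spec - 1.0
    # ties (to rounding tolerance) break toward higher specificity
    candidates = np.flatnonzero(j >= j.max() - 1e-10)
    best = candidates[np.argmax(spec[candidates])]
    youden = OperatingPoint(float(cuts[best]), float(sens[best]),
                            float(spec[best]), "youden")
    attainable = sens >= fixed_sensitivity
    if attainable.any():
        i = np.flatnonzero(attainable).max()
        fixed = OperatingPoint(float(cuts[i]), float(sens[i]), float(spec[i]),
                               f"fixed_sensitivity_{fixed_sensitivity:g}")
    else:  # cannot happen with cutoff = min score (sens = 1), kept defensively
        i = int(np.argmax(sens))
        warnings.warn("target sensitivity unattainable; reporting the maximum")
        fixed = OperatingPoint(float(cuts[i]), float(sens[i]), float(spec[i]),
                               f"fixed_sensitivity_{fixed_sensitivity:g}",
                               attained=False)
    return youden, fixed


def _firth_logit(y: np.ndarray, X: np.ndarray,
                 max_iter: int = 200, tol: float = 1e-10) -> np.ndarray:
    """Firth-type penalized logistic regression (Jeffreys-prior score
    correction); finite estimates exist even under complete separation."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        p = expit(X @ beta)
        w = np.clip(p * (1 - p), 1e-12, None)
        XW = X * w[:, None]
        F = X.T @ XW
        Finv = np.linalg.pinv(F)
        h = np.einsum("ij,jk,ik->i", XW, Finv, X)
        U = X.T @ (y - p + h * (0.5 - p))
        step = Finv @ U
        # step-halving for stability
        while np.max(np.abs(step)) > 5.0:
            step *= 0.5
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def fit_risk_model(outcome, predictors) -> tuple[np.ndarray, dict]:
    """Logistic-regression scores (in-sample predicted probabilities).

    Returns ``(scores, info)`` where ``info`` holds the coefficients and a
    ``separation`` flag; on separation or non-convergence the scores come
    from the Firth-type penalized fit instead.
    """
    y = _check_labels(outcome)
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if y.size <= X.shape[1] + 1:
        raise ValueError("need n > number of predictors + 1")
    Xc = sm.add_constant(X, has_constant="add")
    separated = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        params = np.asarray(res.params)
        converged = bool(res.mle_retvals.get("converged", True))
        if not converged or not np.all(np.isfinite(params)) \
                or np.max(np.abs(params[1:] * Xc[:, 1:].std(axis=0))) > 30:
            separated = True
    except (PerfectSeparationError, np.linalg.LinAlgError):
        separated = True
    if separated:
        log.warning("separation detected: falling back to penalized fit")
        params = _firth_logit(y.astype(float), Xc)
    scores = expit(Xc @ params)
    return scores, {"params": params, "separation": separated}


def fdr_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj


_OUTCOMES = {
    "csf": "CSF Abeta42/40 < 0.071",
    "cl12": "Centiloids >= 12",
    "cl30": "Centiloids >= 30",
}


def _outcome_vector(df: pd.DataFrame, outcome_def: str,
                    rc: cfg.RunConfig) -> np.ndarray:
    if outcome_def == "csf":
        return (df[schema.CSF_AB4240].to_numpy(float)
                < rc.csf_ab4240_positivity).astype(float)
    cl = df[schema.CENTILOIDS].to_numpy(float)
    thr = rc.cl_early if outcome_def == "cl12" else rc.cl_established
    out = (cl >= thr).astype(float)
    out[~np.isfinite(cl)] = np.nan
    return out


def model_comparison_table(df: pd.DataFrame, outcome_def: str = "csf",
                           age_cutoff: float | None = None,
                           run_config: cfg.RunConfig | None = None,
                           ) -> pd.DataFrame:
    """ROC comparison table for one amyloid outcome definition.

    Rows per stratum: the base risk-factor model (age + sex + APOE-e4),
    each biomarker alone (oriented so higher = more pathologic), and each
    biomarker combined with the base model, with DeLong p versus the base
    model and BH-FDR adjusted p.  With ``age_cutoff`` the table is computed
    for all participants and for the <=cutoff / >cutoff strata; a stratum
    whose outcome is single-class is skipped with a warning.

    Complete-case per stratum: rows missing the outcome, a predictor or the
    biomarker are dropped for the affected models.
    """
    if outcome_def not in _OUTCOMES:
        raise ValueError(f"outcome_def must be one of {sorted(_OUTCOMES)}")
    rc = run_config or cfg.RunConfig()
    age = df[schema.AGE].to_numpy(float)
    strata: list[tuple[str, np.ndarray]] = [("all", np.ones(len(df), bool))]
    if age_cutoff is not None:
        strata += [(f"age<={age_cutoff:g}", age <= age_cutoff),
                   (f"age>{age_cutoff:g}", age > age_cutoff)]

    y_all = _outcome_vector(df, outcome_def, rc)
    sex = df[schema.SEX].to_numpy(float)
    apoe = df[schema.APOE].to_numpy(float)
    rows = []
    for stratum, smask in strata:
        mask = smask & np.isfinite(y_all) & np.isfinite(age) \
            & np.isfinite(sex) & np.isfinite(apoe)
        y = y_all[mask]
        if y.size == 0 or y.min() == y.max():
            warnings.warn(f"stratum {stratum!r} has a single outcome class; skipped")
            continue
        base_X = np.column_stack([age[mask], sex[mask], apoe[mask]])
        base_scores, base_info = fit_risk_model(y, base_X)
        base_roc = roc_auc(base_scores, y, "base")
        rows.append({"stratum": stratum, "model": "base_risk_factors",
                     "auc": base_roc.auc, "ci_low": base_roc.ci_low,
                     "ci_high": base_roc.ci_high, "n_pos": base_roc.n_pos,
                     "n_neg": base_roc.n_neg, "p_vs_base": np.nan,
                     "separation": base_info["separation"],
                     "youden_sens": np.nan, "youden_spec": np.nan,
                     "fixed_sens_spec": np.nan})
        for info in schema.PLASMA_PANEL:
            t = df[f"{info.column}__t"] if f"{info.column}__t" in df \
                else df[info.column]
            t = t.to_numpy(float)
            bmask = mask & np.isfinite(t)
            yb = y_all[bmask]
            if yb.min() == yb.max():
                warnings.warn(f"{info.column} in stratum {stratum!r}: "
                              "single class after complete cases; skipped")
                continue
            base_Xb = np.column_stack([age[bmask], sex[bmask], apoe[bmask]])
            base_scores_b, _ = fit_risk_model(yb, base_Xb)
            for kind in ("alone", "combined"):
                if kind == "alone":
                    scores = info.direction * t[bmask]
                    sep = False
                else:
                    scores, fit_info = fit_risk_model(
                        yb, np.column_stack([base_Xb, t[bmask]]))
                    sep = fit_info["separation"]
                rr = roc_auc(scores, yb, info.column)
                dl = delong_test(base_scores_b, scores, yb)
                yj, fx = operating_points(scores, yb, rc.fixed_sensitivity)
                rows.append({"stratum": stratum,
                             "model": f"{info.column}_{kind}",
                             "auc": rr.auc, "ci_low": rr.ci_low,
                             "ci_high": rr.ci_high, "n_pos": rr.n_pos,
                             "n_neg": rr.n_neg, "p_vs_base": dl.p,
                             "separation": sep,
                             "youden_sens": yj.sensitivity,
                             "youden_spec": yj.specificity,
                             "fixed_sens_spec": fx.specificity})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_fdr"] = np.nan
        for stratum in out["stratum"].unique():
            m = (out["stratum"] == stratum) & out["p_vs_base"].notna()
            if m.any():
                out.loc[m, "p_fdr"] = fdr_adjust(out.loc[m, "p_vs_base"].to_numpy())
    out.attrs["outcome"] = _OUTCOMES[outcome_def]
    out.attrs["note"] = ("combined models are in-sample logistic regressions; "
                         "apparent AUC without cross-validation")
    return out


def render_table(table: pd.DataFrame) -> str:
    """Plain-text rendering of a model-comparison table."""
    lines = [f"Outcome: {table.attrs.get('outcome', '?')}",
             table.attrs.get("note", ""), ""]
    for stratum, sub in table.groupby("stratum", sort=False):
        lines.append(f"-- stratum: {stratum}")
        for _, r in sub.iterrows():
            ci = f"({r.ci_low:.3f}-{r.ci_high:.3f})"
            p = "" if pd.isna(r.p_vs_base) else \
                f"  p={r.p_vs_base:.4g}  p_fdr={r.p_fdr:.4g}"
            flag = "  [penalized]" if r.separation else ""
            lines.append(f"   {r.model:<28s} AUC {r.auc:.3f} {ci}{p}{flag}")
        lines.append("")
    return "\n".join(lines)
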