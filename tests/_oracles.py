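"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately written the slow, obvious way (per-point
loops, explicit least squares, exhaustive pair counting) and shares no code
with the package internals it checks.
"""

import numpy as np


def rlowess_oracle(x, y, span, iterations=5):
    """Per-point tricube/bisquare weighted-least-squares robust smoother."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    d = np.abs(x[:, None] - x[None, :])
    dmax = np.sort(d, axis=1)[:, span - 1]
    rw = np.ones(n)
    fit = np.empty(n)
    for it in range(iterations + 1):
        for i in range(n):
            if dmax[i] > 0:
                u = d[i] / dmax[i]
                tw = np.where(u < 1, (1 - u ** 3) ** 3, 0.0)
            else:
                tw = (d[i] == 0).astype(float)
            w = tw * rw
            dx = x - x[i]
            A = np.column_stack([np.ones(n), dx]) * np.sqrt(w)[:, None]
            b = y * np.sqrt(w)
            gram = A.T @ A
            if np.linalg.cond(gram) < 1e10:
                coef = np.linalg.solve(gram, A.T @ b)
                fit[i] = coef[0]
            elif w.sum() > 0:
                fit[i] = np.average(y, weights=w)
            else:
                fit[i] = 0.0
        if it == iterations:
            break
        r = y - fit
        s = 6.0 * np.median(np.abs(r))
        if s <= 1e-9 * np.max(np.abs(y)) or s <= 0:
            break
        rr = r / s
        rw = np.where(np.abs(rr) < 1, (1 - rr ** 2) ** 2, 0.0)
    return fit


def auc_bruteforce(scores, labels):
    """AUC by exhaustive positive-negative pair counting, ties half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def delong_variance_oracle(s1, s2, labels):
    """Variance of AUC1 - AUC2 via explicit placement values."""
    s1 = np.asarray(s1, float)
    s2 = np.asarray(s2, float)
    y = np.asarray(labels, int)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    m, n = len(pos), len(neg)

    def placements(s):
        v10 = np.array([np.mean([1.0 if s[i] > s[j] else 0.5 if s[i] == s[j]
                                 else 0.0 for j in neg]) for i in pos])
        v01 = np.array([np.mean([1.0 if s[i] > s[j] else 0.5 if s[i] == s[j]
                                 else 0.0 for i in pos]) for j in neg])
        return v10, v01

    v10_1, v01_1 = placements(s1)
    v10_2, v01_2 = placements(s2)
    d10 = v10_1 - v10_2
    d01 = v01_1 - v01_2
    return d10.var(ddof=1) / m + d01.var(ddof=1) / n


def youden_bruteforce(scores, labels):
    """Best (J, cutoff, sens, spec) over all observed cutoffs; ties toward
    higher specificity."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    best = None
    for c in np.unique(scores):
        pred = scores >= c
        sens = np.mean(pred[labels == 1])
        spec = np.mean(~pred[labels == 0])
        j = sens + spec - 1
        if best is None or j > best[0] + 1e-12 or \
                (abs(j - best[0]) <= 1e-12 and spec > best[3]):
            best = (j, c, sens, spec)
    return best


def bh_stepup_oracle(p):
    """Benjamini-Hochberg adjusted p by the textbook step-up recursion."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        adj[i] = val
        prev = val
    return adj


def ols_normal_equations(X, y):
    """Least-squares coefficients via explicit normal equations."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    return np.linalg.solve(X.T @ X, X.T @ y)
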