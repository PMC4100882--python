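"""Statistical layer: constrained fits, AIC, ANCOVA, ANOVA/Tukey, correlation.

Cavity volume is modeled over deposited energy with linear (``y = b1 x``)
or quadratic (``y = b1 x + b2 x^2``) least-squares fits constrained
through the origin — zero deposited energy produces no cavity, and the
constraint removes one degree of freedom.  Candidate fits are compared by
the Akaike information criterion in its least-squares form

    AIC = n ln(RSS / n) + 2 k

where k counts the regression coefficients plus the noise variance.
Slopes are compared across groups by the ANCOVA homogeneity-of-slopes
F-test, group means by one-way ANOVA with Tukey's HSD (studentized-range)
multiple comparison, and repeated shots by Pearson correlation.

These routines are computed from the normal equations and sum-of-squares
decompositions directly; scipy supplies only the reference distributions
(F, t, studentized range).

A note on R²: for through-origin fits it is computed against the
grand-mean baseline, ``1 - RSS / sum((y - ybar)^2)``.  Conventions for
through-origin R² differ between packages (some use an uncorrected
baseline); with this convention R² can be negative when the constrained
fit does worse than the mean.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["RegressionResult", "fit_through_origin", "aic_select",
           "ancova_slopes", "anova_tukey", "reproducibility_correlation"]

#: default significance level
ALPHA = 0.05


@dataclass(frozen=True)
class RegressionResult:
    """A least-squares fit through the origin.

    ``aic`` is the plain least-squares AIC; ``aicc`` carries the
    small-sample correction ``2k(k+1)/(n-k-1)`` (infinite when the
    correction's denominator is not positive).
    """

    model: str  # "linear_origin" | "quadratic_origin"
    coefficients: tuple
    rss: float
    r_squared: float
    aic: float
    aicc: float
    n: int

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        y = self.coefficients[0] * x
        if self.model == "quadratic_origin":
            y = y + self.coefficients[1] * x**2
        return y


def fit_through_origin(x, y, degree: int = 1) -> RegressionResult:
    """Least-squares fit of y on {x} (degree 1) or {x, x²} (degree 2),
    with no intercept.

    R² is computed against the mean-of-y baseline and can be negative;
    AIC uses ``n ln(RSS/n) + 2k`` with ``k = degree + 1``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    n = x.size
    if n < degree + 1:
        raise ValueError(f"need at least {degree + 1} points for degree {degree}")
    if np.all(x == 0):
        raise ValueError("x must not be all zero")
    X = np.column_stack([x**p for p in range(1, degree + 1)])
    # normal equations; rcond check guards a singular design
    coef, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < degree:
        raise ValueError("singular design matrix")
    resid = y - X @ coef
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    k = degree + 1  # coefficients + error variance
    with np.errstate(divide="ignore"):
        aic = n * np.log(max(rss, 1e-300) / n) + 2 * k
    aicc = aic + 2 * k * (k + 1) / (n - k - 1) if n - k - 1 > 0 else np.inf
    model = "linear_origin" if degree == 1 else "quadratic_origin"
    return RegressionResult(model, tuple(float(c) for c in coef),
                            rss, r2, float(aic), float(aicc), n)


def aic_select(fit_linear: RegressionResult,
               fit_quadratic: RegressionResult,
               criterion: str = "aicc") -> dict:
    """Choose between the linear and quadratic through-origin fits by AIC.

    By default the small-sample corrected AICc is compared: with only a
    handful of shots per bullet the uncorrected AIC over-selects the
    quadratic (its penalty of 2 per parameter is too weak for n ≲ 40·k),
    and AICc is the standard correction in that regime.  Pass
    ``criterion="aic"`` for the uncorrected comparison.

    Returns the preferred model name and Δ = crit(quadratic) −
    crit(linear); at a tie the linear model (fewer parameters) wins.
    """
    if fit_linear.n != fit_quadratic.n:
        raise ValueError("fits must be on identical data (n differs)")
    if criterion not in ("aic", "aicc"):
        raise ValueError("criterion must be 'aic' or 'aicc'")
    a_lin = getattr(fit_linear, criterion)
    a_quad = getattr(fit_quadratic, criterion)
    delta = a_quad - a_lin
    preferred = "quadratic_origin" if delta < 0 else "linear_origin"
    return {"preferred": preferred, "criterion": criterion,
            "delta_aic": float(delta),
            "aic_linear": fit_linear.aic, "aic_quadratic": fit_quadratic.aic,
            "aicc_linear": fit_linear.aicc, "aicc_quadratic": fit_quadratic.aicc}


def ancova_slopes(groups) -> tuple[float, float]:
    """ANCOVA homogeneity-of-slopes test across groups of (x, y) data.

    Fits the pooled linear model with per-group intercepts and a common
    slope (reduced) against per-group intercepts and slopes (full) and
    F-tests the slope-by-group interaction:

        F = [(RSS_r - RSS_f) / (g - 1)] / [RSS_f / (N - 2g)]

    Returns ``(F, p)``.
    """
    data = [(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
            for x, y in groups]
    g = len(data)
    if g < 2:
        raise ValueError("need at least two groups")
    for x, y in data:
        if x.size < 3 or x.size != y.size:
            raise ValueError("each group needs n >= 3 paired values")
        if np.ptp(x) == 0:
            raise ValueError("a group has constant x: slope undefined")
    N = sum(x.size for x, _ in data)
    # full model: each group fit separately
    rss_f = 0.0
    for x, y in data:
        X = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        rss_f += float(r @ r)
    # reduced model: common slope, per-group intercepts
    xall = np.concatenate([x for x, _ in data])
    yall = np.concatenate([y for _, y in data])
    Xr = np.zeros((N, g + 1))
    pos = 0
    for i, (x, _) in enumerate(data):
        Xr[pos:pos + x.size, i] = 1.0
        pos += x.size
    Xr[:, g] = xall
    coef, *_ = np.linalg.lstsq(Xr, yall, rcond=None)
    r = yall - Xr @ coef
    rss_r = float(r @ r)
    df1, df2 = g - 1, N - 2 * g
    if df2 <= 0:
        raise ValueError("not enough data for the interaction test")
    F = ((rss_r - rss_f) / df1) / (rss_f / df2) if rss_f > 0 else np.inf
    p = float(sps.f.sf(F, df1, df2))
    return float(F), p


def anova_tukey(groups) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA with Tukey's HSD multiple comparison.

    Returns the ANOVA ``(F, p)`` and a pairwise table with the mean
    difference, the studentized-range adjusted p and the unadjusted
    two-sample p (pooled variance) for every group pair.
    """
    data = [np.asarray(v, dtype=float) for v in groups]
    k = len(data)
    if k < 2:
        raise ValueError("need at least two groups")
    if any(v.size < 2 for v in data):
        raise ValueError("each group needs n >= 2")
    N = sum(v.size for v in data)
    grand = np.concatenate(data).mean()
    ssb = sum(v.size * (v.mean() - grand) ** 2 for v in data)
    ssw = sum(float(((v - v.mean()) ** 2).sum()) for v in data)
    dfb, dfw = k - 1, N - k
    msw = ssw / dfw
    if msw == 0:
        F = np.inf if ssb > 0 else 0.0
    else:
        F = (ssb / dfb) / msw
    p = float(sps.f.sf(F, dfb, dfw)) if np.isfinite(F) else 0.0
    if F == 0.0:
        p = 1.0

    rows = []
    for i, j in itertools.combinations(range(k), 2):
        a, b = data[i], data[j]
        diff = b.mean() - a.mean()
        se_q = np.sqrt(msw / 2.0 * (1.0 / a.size + 1.0 / b.size)) if msw > 0 else 0.0
        if se_q > 0:
            q = abs(diff) / se_q
            p_adj = float(sps.studentized_range.sf(q, k, dfw))
        else:
            p_adj = 1.0 if diff == 0 else 0.0
        se_t = np.sqrt(msw * (1.0 / a.size + 1.0 / b.size)) if msw > 0 else 0.0
        if se_t > 0:
            t = abs(diff) / se_t
            p_raw = float(2 * sps.t.sf(t, dfw))
        else:
            p_raw = 1.0 if diff == 0 else 0.0
        rows.append({"group_a": i, "group_b": j, "mean_diff": float(diff),
                     "p_adj": p_adj, "p_unadj": p_raw})
    return float(F), p, pd.DataFrame(rows)


def reproducibility_correlation(first_shots, second_shots,
                                groups=None) -> dict:
    """Pearson correlation between paired first- and second-shot values.

    With ``groups`` (one label per pair) a per-group correlation is also
    reported, mirroring per-bullet reproducibility summaries.
    """
    a = np.asarray(first_shots, dtype=float)
    b = np.asarray(second_shots, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired lists must be 1D and of equal length")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in one of the lists")
    out = {"pearson_r": float(sps.pearsonr(a, b).statistic), "n": int(a.size)}
    if groups is not None:
        groups = np.asarray(groups)
        per = {}
        for gname in pd.unique(groups):
            sel = groups == gname
            if sel.sum() >= 3 and np.ptp(a[sel]) > 0 and np.ptp(b[sel]) > 0:
                per[str(gname)] = float(sps.pearsonr(a[sel], b[sel]).statistic)
            else:
                per[str(gname)] = float("nan")
        out["per_group_r"] = per
    return out
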