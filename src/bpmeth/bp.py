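"""Per-subject blood-pressure summarization from repeated, irregular readings.

The exposure fed to the probe-wise association stage is not a raw average:
visit schedules are irregular and population BP follows a non-linear
gestational trend (mid-pregnancy dip, rise to term), so naive per-subject
means are confounded by *when* a woman happened to be measured. The pipeline
therefore

1. derives the four indicators — SBP, DBP, MAP = SBP/3 + 2*DBP/3 and
   PP = SBP - DBP — from each reading,
2. estimates the smooth population trend by a penalized (GCV-smoothed)
   spline and detrends each reading (subtract trend, add back the grand
   mean, staying on the mmHg scale),
3. fits, within each time window (early <= 27 weeks, late > 27, whole), an
   intercept-only mixed model with a subject random intercept and
   continuous-time AR(1) residual correlation rho^|dt|, by profiled REML,
4. reports each subject's shrunken estimate bp_hat = intercept + BLUP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import minimize

WEEK_DOMAIN = (8.0, 42.0)
EARLY_LATE_BOUNDARY = 27.0
INDICATORS = ("sbp", "dbp", "map", "pp")

#: plausibility bounds applied before any modelling
SBP_MAX, DBP_MAX = 260.0, 200.0


# ---------------------------------------------------------------------------
# Indicators
# ---------------------------------------------------------------------------

def compute_indicators(sbp, dbp):
    """Mean arterial pressure and pulse pressure from SBP/DBP (mmHg).

    MAP = SBP/3 + 2*DBP/3 approximates the time-averaged arterial pressure
    over a cardiac cycle; PP = SBP - DBP is the pulsatile component.
    """
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    if np.any(sbp <= dbp):
        raise ValueError("systolic pressure must exceed diastolic pressure")
    return sbp / 3.0 + 2.0 * dbp / 3.0, sbp - dbp


def add_indicators(records: pd.DataFrame) -> pd.DataFrame:
    """Append map/pp columns to a long BP table (subject_id, week, sbp, dbp)."""
    out = records.copy()
    out["map"], out["pp"] = compute_indicators(out["sbp"], out["dbp"])
    return out


def apply_plausibility_filter(records: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop readings outside plausibility bounds; returns (kept, n_dropped)."""
    ok = (
        (records["week"] > 0) & (records["week"] <= 43)
        & (records["sbp"] > records["dbp"]) & (records["dbp"] > 0)
        & (records["sbp"] <= SBP_MAX) & (records["dbp"] <= DBP_MAX)
    )
    return records.loc[ok].copy(), int((~ok).sum())


def assign_window(week) -> np.ndarray:
    """'early' for week <= 27 (inclusive boundary), else 'late'."""
    week = np.asarray(week, dtype=float)
    if np.any(week <= 0):
        raise ValueError("gestational week must be positive")
    return np.where(week <= EARLY_LATE_BOUNDARY, "early", "late")


# ---------------------------------------------------------------------------
# Trend estimation and detrending
# ---------------------------------------------------------------------------

@dataclass
class TrendModel:
    """Smooth population trajectory of one indicator over gestational weeks."""

    spline: object
    grand_mean: float
    domain: tuple[float, float]

    def __call__(self, week) -> np.ndarray:
        week = np.asarray(week, dtype=float)
        lo, hi = self.domain
        w = np.clip(week, lo, hi)
        val = self.spline(w)
        # linear extension beyond the fitted range
        eps = 1e-4
        dlo = (self.spline(lo + eps) - self.spline(lo)) / eps
        dhi = (self.spline(hi) - self.spline(hi - eps)) / eps
        val = np.where(week < lo, self.spline(lo) + (week - lo) * dlo, val)
        val = np.where(week > hi, self.spline(hi) + (week - hi) * dhi, val)
        return val


def _penalized_spline(x: np.ndarray, y: np.ndarray, n_knots: int = 8,
                      degree: int = 3) -> BSpline:
    """Cubic P-spline: fixed interior knots at quantiles, second-difference
    coefficient penalty, smoothing parameter chosen by GCV on a log grid."""
    interior = np.quantile(x, np.linspace(0, 1, n_knots + 2)[1:-1])
    interior = np.unique(interior)
    lo, hi = float(x.min()), float(x.max())
    t = np.concatenate([[lo] * (degree + 1),
                        interior[(interior > lo) & (interior < hi)],
                        [hi] * (degree + 1)])
    B = BSpline.design_matrix(np.clip(x, lo, hi), t, degree).toarray()
    k = B.shape[1]
    D = np.diff(np.eye(k), n=2, axis=0)
    P = D.T @ D
    BtB = B.T @ B
    Bty = B.T @ y
    n = len(y)
    best = (np.inf, None)
    for lam in np.logspace(-3, 7, 31):
        A = BtB + lam * P
        coef = np.linalg.solve(A, Bty)
        edf = np.trace(np.linalg.solve(A, BtB))
        rss = np.sum((y - B @ coef) ** 2)
        gcv = n * rss / (n - edf) ** 2
        if gcv < best[0]:
            best = (gcv, coef)
    return BSpline(t, best[1], degree, extrapolate=False)


def estimate_trend(records: pd.DataFrame, indicator: str) -> TrendModel:
    """GCV-smoothed spline of pooled indicator values on gestational week."""
    if indicator not in INDICATORS:
        raise ValueError(f"unknown indicator {indicator!r}")
    df = records.dropna(subset=[indicator, "week"])
    weeks = df["week"].to_numpy(dtype=float)
    values = df[indicator].to_numpy(dtype=float)
    if len(weeks) < 50:
        raise ValueError("trend estimation needs >= 50 pooled observations")
    span = weeks.max() - weeks.min()
    if span < 20:
        raise ValueError(f"observations span only {span:.1f} weeks (< 20)")

    spline = _penalized_spline(weeks, values, n_knots=8)

    lo = max(WEEK_DOMAIN[0], float(weeks.min()))
    hi = min(WEEK_DOMAIN[1], float(weeks.max()))
    grid = np.linspace(max(lo, 8.0), min(hi, 41.0), 500)
    grand_mean = float(np.trapezoid(spline(grid), grid) / (grid[-1] - grid[0]))
    return TrendModel(spline=spline, grand_mean=grand_mean, domain=(lo, hi))


def detrend(records: pd.DataFrame, trend: TrendModel, indicator: str
            ) -> pd.DataFrame:
    """value' = value - trend(week) + grand_mean (stays on the mmHg scale)."""
    weeks = records["week"].to_numpy(dtype=float)
    lo, hi = trend.domain
    if np.any((weeks < lo) | (weeks > hi)):
        warnings.warn("weeks outside the fitted trend domain; "
                      "linear extension used", stacklevel=2)
    out = records.copy()
    out[indicator] = (records[indicator].to_numpy(dtype=float)
                      - trend(weeks) + trend.grand_mean)
    return out


# ---------------------------------------------------------------------------
# Two-stage mixed model (random intercept + continuous-time AR(1))
# ---------------------------------------------------------------------------

@dataclass
class TwoStageFit:
    summaries: pd.DataFrame        # subject_id, bp_hat, n_obs
    mu: float                      # GLS fixed intercept
    sigma_b: float
    sigma_e: float
    rho: float
    converged: bool
    reml: float


def _group_arrays(values: pd.Series, weeks: pd.Series, subjects: pd.Series):
    order = np.lexsort((weeks.to_numpy(), subjects.to_numpy()))
    sid = subjects.to_numpy()[order]
    y = values.to_numpy(dtype=float)[order]
    t = weeks.to_numpy(dtype=float)[order]
    uniq, starts = np.unique(sid, return_index=True)
    bounds = np.append(starts, len(sid))
    groups = [(uniq[i], y[bounds[i]:bounds[i + 1]], t[bounds[i]:bounds[i + 1]])
              for i in range(len(uniq))]
    return groups


def _batch_groups(groups):
    """Stack subjects with equal visit counts for batched linear algebra."""
    by_size: dict[int, list] = {}
    for g in groups:
        by_size.setdefault(len(g[1]), []).append(g)
    batches = []
    for m, gs in sorted(by_size.items()):
        Y = np.stack([g[1] for g in gs])                       # (s, m)
        T = np.stack([g[2] for g in gs])
        D = np.abs(T[:, :, None] - T[:, None, :])              # (s, m, m)
        batches.append((Y, D))
    return batches


def _reml_neg_loglik(theta, batches):
    """-2 * REML log-likelihood, profiled over the GLS intercept."""
    sb2, se2 = np.exp(theta[0]), np.exp(theta[1])
    rho = 1.0 / (1.0 + np.exp(-theta[2]))  # (0, 1)
    logdet = xtvx = xtvy = ytvy = 0.0
    for Y, D in batches:
        s, m = Y.shape
        V = sb2 + se2 * rho ** D
        try:
            chol = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e12
        logdet += 2.0 * np.log(np.diagonal(chol, axis1=1, axis2=2)).sum()
        rhs = np.empty((s, m, 2))
        rhs[:, :, 0] = 1.0
        rhs[:, :, 1] = Y
        sol = np.linalg.solve(chol, rhs)
        xtvx += np.einsum("smi,smi->", sol[:, :, :1], sol[:, :, :1])
        xtvy += np.einsum("sm,sm->", sol[:, :, 0], sol[:, :, 1])
        ytvy += np.einsum("sm,sm->", sol[:, :, 1], sol[:, :, 1])
    if xtvx <= 0:
        return 1e12
    mu = xtvy / xtvx
    rss = ytvy - 2 * mu * xtvy + mu ** 2 * xtvx
    return logdet + np.log(xtvx) + rss


def fit_two_stage(records: pd.DataFrame, indicator: str,
                  max_iter: int = 400) -> TwoStageFit:
    """Shrunken per-subject BP estimates bp_hat = mu + BLUP(b_i).

    Variance components (sigma_b^2, sigma_e^2, rho) by REML (Nelder-Mead on
    log/logit-transformed parameters) with the intercept profiled out in
    closed form by GLS.
    """
    df = records.dropna(subset=[indicator, "week"])
    if df["subject_id"].nunique() < 2:
        raise ValueError("two-stage model needs >= 2 subjects")
    groups = _group_arrays(df[indicator], df["week"], df["subject_id"])
    y_all = df[indicator].to_numpy(dtype=float)

    # degenerate: no within-subject variability at all
    within_var = max((np.var(y) for _, y, _ in groups if len(y) > 1),
                     default=0.0)
    total_var = float(np.var(y_all))
    if total_var < 1e-12:
        v = float(y_all[0])
        summ = pd.DataFrame({"subject_id": [g[0] for g in groups],
                             "bp_hat": v,
                             "n_obs": [len(g[1]) for g in groups]})
        return TwoStageFit(summ, v, 0.0, 0.0, 0.0, True, 0.0)
    if within_var < 1e-12:
        # each subject's readings are constant: no shrinkage is defensible,
        # bp_hat is exactly the subject's value (sigma_e -> 0 limit)
        summ = pd.DataFrame({"subject_id": [g[0] for g in groups],
                             "bp_hat": [float(np.mean(g[1])) for g in groups],
                             "n_obs": [len(g[1]) for g in groups]})
        mu = float(np.mean([np.mean(g[1]) for g in groups]))
        return TwoStageFit(summ, mu, float(np.sqrt(total_var)), 0.0, 0.0,
                           True, 0.0)

    # moment-based start: within-subject variance for sigma_e^2, excess
    # between-subject variance of the means for sigma_b^2
    within = np.mean([np.var(y, ddof=1) for _, y, _ in groups if len(y) > 1])
    means = np.array([np.mean(y) for _, y, _ in groups])
    mbar = np.mean([len(y) for _, y, _ in groups])
    between = max(np.var(means, ddof=1) - within / mbar, 0.05 * total_var)
    starts = [np.array([np.log(between), np.log(max(within, 1e-3)), 0.0]),
              np.array([np.log(total_var / 2), np.log(total_var / 2), -1.0])]
    batches = _batch_groups(groups)
    res = None
    for x0 in starts:
        cand = minimize(_reml_neg_loglik, x0, args=(batches,),
                        method="Nelder-Mead",
                        options={"maxiter": max_iter, "xatol": 1e-8,
                                 "fatol": 1e-10})
        if res is None or cand.fun < res.fun:
            res = cand
    if res.fun >= 1e12:
        raise RuntimeError(
            f"REML optimization failed; last objective {res.fun:.6g}")
    sb2, se2 = np.exp(res.x[0]), np.exp(res.x[1])
    rho = 1.0 / (1.0 + np.exp(-res.x[2]))

    # GLS intercept and BLUPs at the REML estimates
    xtvx = xtvy = 0.0
    per_subject = []
    for sid, y, t in groups:
        n_i = len(y)
        corr = rho ** np.abs(t[:, None] - t[None, :]) if n_i > 1 else np.ones((1, 1))
        v = sb2 + se2 * corr
        vi1 = np.linalg.solve(v, np.ones(n_i))
        viy = np.linalg.solve(v, y)
        xtvx += vi1.sum()
        xtvy += viy.sum()
        per_subject.append((sid, y, vi1, viy))
    mu = xtvy / xtvx
    rows = []
    for sid, y, vi1, viy in per_subject:
        blup = sb2 * (viy.sum() - mu * vi1.sum())
        rows.append((sid, mu + blup, len(y)))
    summ = pd.DataFrame(rows, columns=["subject_id", "bp_hat", "n_obs"])
    return TwoStageFit(summ, float(mu), float(np.sqrt(sb2)),
                       float(np.sqrt(se2)), float(rho),
                       bool(res.success), float(res.fun))


# ---------------------------------------------------------------------------
# End-to-end BP summarization
# ---------------------------------------------------------------------------

def summarize_bp(records: pd.DataFrame, indicator: str, window: str = "whole"
                 ) -> pd.DataFrame:
    """Plausibility-filter, derive the indicator, detrend, restrict to the
    window, and fit the two-stage model. Returns a BPSummary table
    (subject_id, window, indicator, bp_hat, n_obs)."""
    if window not in ("early", "late", "whole"):
        raise ValueError(f"unknown window {window!r}")
    kept, _ = apply_plausibility_filter(records)
    kept = add_indicators(kept)
    trend = estimate_trend(kept, indicator)
    det = detrend(kept, trend, indicator)
    if window != "whole":
        det = det.loc[assign_window(det["week"]) == window]
    fit = fit_two_stage(det, indicator)
    out = fit.summaries.copy()
    out.insert(1, "window", window)
    out.insert(2, "indicator", indicator)
    return out
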