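"""Probe-wise robust association of M-values with the shrunken BP estimate.

For each CpG j the model is

    M_ij = alpha_0j + alpha_BPj * BPhat_i + alpha_Zj' Z_i + eps_ij

fitted by Huber M-estimation (tuning constant 1.345, MAD residual scale,
IRLS to relative tolerance 1e-8). ``alpha_BPj`` is the M-scale effect per
mmHg; for interpretability it is also reported on the beta scale per
10 mmHg via the intercept method (difference of back-transformed fitted
values at the covariate means). P-values use a t reference with residual
degrees of freedom; multiplicity is handled by Benjamini-Hochberg across
all tested probes. A BACON-style empirical-null mixture estimates the
bias/inflation of the test statistics.

The IRLS is vectorized across probes (shared design matrix, per-probe
weights), which is what makes the replicate-level simulations tractable;
it is checked against statsmodels' RLM in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import qr
from statsmodels.stats.multitest import multipletests

from .qc import beta_to_m, m_to_beta

log = logging.getLogger(__name__)

HUBER_C = 1.345
IRLS_TOL = 1e-8
IRLS_MAX_ITER = 100


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

def build_design(bp_hat: pd.Series, covariates: pd.DataFrame | None = None
                 ) -> tuple[np.ndarray, list[str]]:
    """[intercept, bp_hat, encoded covariates]; categoricals dummy-coded."""
    cols = [pd.Series(1.0, index=bp_hat.index, name="intercept"),
            bp_hat.astype(float).rename("bp_hat")]
    if covariates is not None:
        cov = covariates.loc[bp_hat.index]
        enc = pd.get_dummies(cov, drop_first=True, dtype=float)
        for name in enc.columns:
            cols.append(enc[name])
    X = pd.concat(cols, axis=1)
    arr = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        _, r, piv = qr(arr, mode="economic", pivoting=True)
        d = np.abs(np.diag(r))
        bad = sorted(X.columns[piv[i]] for i in range(len(d))
                     if d[i] < d[0] * 1e-10)
        raise ValueError(f"design matrix is rank deficient; collinear "
                         f"columns: {bad}")
    return arr, list(X.columns)


# ---------------------------------------------------------------------------
# Vectorized Huber IRLS
# ---------------------------------------------------------------------------

def huber_fit(Y: np.ndarray, X: np.ndarray,
              c: float = HUBER_C, tol: float = IRLS_TOL,
              max_iter: int = IRLS_MAX_ITER):
    """Huber regression of every row of ``Y`` (p x n, NaN = missing) on the
    shared design ``X`` (n x k).

    Returns (coef (p x k), se (p x k), n_used (p,)). Probes with fewer than
    k + 10 complete cases come back all-NaN.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, k = X.shape
    mask = ~np.isnan(Y)
    n_used = mask.sum(axis=1)
    ok = n_used >= k + 10
    Y0 = np.where(mask, Y, 0.0)

    def wls(W):
        A = np.einsum("ni,pn,nj->pij", X, W, X, optimize=True)
        b = np.einsum("ni,pn->pi", X, W * Y0, optimize=True)
        return np.linalg.solve(A, b[:, :, None])[:, :, 0]

    W = mask.astype(float)
    W[~ok] = 0.0
    W[~ok, :k + 10] = 1.0          # keep the solve non-singular; discarded
    coef = wls(W)
    scale = np.ones(Y.shape[0])
    for _ in range(max_iter):
        r = Y0 - coef @ X.T
        r_nan = np.where(mask, r, np.nan)
        with np.errstate(all="ignore"):
            scale = np.nanmedian(np.abs(r_nan), axis=1) / 0.6745
        tiny = scale < 1e-12
        scale = np.where(tiny, 1.0, scale)
        u = np.abs(r) / scale[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            wh = np.minimum(1.0, c / u)
        wh[u == 0] = 1.0
        wh[tiny] = 1.0             # exact fit: plain least squares step
        Wn = wh * mask
        Wn[~ok] = W[~ok]
        new = wls(Wn)
        delta = np.max(np.abs(new - coef) / np.maximum(np.abs(coef), 1e-10),
                       axis=1)
        coef = new
        if np.all(delta < tol):
            break

    # Huber sandwich standard errors with the small-sample correction factor
    r = np.where(mask, Y0 - coef @ X.T, np.nan)
    with np.errstate(all="ignore"):
        scale = np.nanmedian(np.abs(r), axis=1) / 0.6745
    scale = np.maximum(scale, 1e-12)
    u = r / scale[:, None]
    psi = np.clip(u, -c, c)
    dpsi = (np.abs(u) <= c).astype(float)
    dpsi[~mask] = np.nan
    psi[~mask] = np.nan
    with np.errstate(all="ignore"):
        m1 = np.nanmean(dpsi, axis=1)
        v1 = np.nanvar(dpsi, axis=1)
        sum_psi2 = np.nansum(psi ** 2, axis=1)
    kappa = 1.0 + (k / n_used.clip(min=1)) * v1 / np.maximum(m1, 1e-12) ** 2
    var_f = (kappa ** 2 * scale ** 2 * sum_psi2
             / np.maximum(n_used - k, 1) / np.maximum(m1, 1e-12) ** 2)
    G = np.einsum("ni,pn,nj->pij", X, mask.astype(float), X, optimize=True)
    G[~ok] = np.eye(k)
    Ginv = np.linalg.inv(G)
    se = np.sqrt(var_f[:, None] * np.einsum("pii->pi", Ginv))
    coef = np.where(ok[:, None], coef, np.nan)
    se = np.where(ok[:, None], se, np.nan)
    return coef, se, n_used


def fit_probe(m_values: np.ndarray, bp_hat: pd.Series,
              covariates: pd.DataFrame | None = None):
    """Single-probe convenience wrapper: returns (effect_m, se_m, p)."""
    X, _ = build_design(bp_hat, covariates)
    coef, se, n_used = huber_fit(np.asarray(m_values, dtype=float)[None, :], X)
    eff, s = coef[0, 1], se[0, 1]
    df = max(int(n_used[0]) - X.shape[1], 1)
    p = 2.0 * stats.t.sf(abs(eff / s), df)
    return float(eff), float(s), float(p)


# ---------------------------------------------------------------------------
# Effect-size rescaling (intercept method)
# ---------------------------------------------------------------------------

def effect_to_beta_scale(alpha0_m, effect_m, delta_mmhg: float = 10.0):
    """Beta-scale change for a ``delta_mmhg`` increase in BP:
    s(alpha0 + effect*delta) - s(alpha0), with s the M-to-beta transform."""
    alpha0_m = np.asarray(alpha0_m, dtype=float)
    effect_m = np.asarray(effect_m, dtype=float)
    return m_to_beta(alpha0_m + effect_m * delta_mmhg) - m_to_beta(alpha0_m)


# ---------------------------------------------------------------------------
# Whole-array run
# ---------------------------------------------------------------------------

def run_ewas(matrix: pd.DataFrame, bp_hat: pd.Series,
             covariates: pd.DataFrame | None = None,
             values_are_m: bool = False) -> pd.DataFrame:
    """Probe-wise robust EWAS over a beta matrix (probes x samples).

    ``bp_hat`` is the per-subject shrunken BP estimate indexed by sample id;
    covariates (optional) are indexed the same way. Returns a table with
    effect_m (per mmHg), se_m, p, fdr, effect_beta_per10 and n_used.
    """
    missing = [s for s in matrix.columns if s not in bp_hat.index]
    extra = [s for s in bp_hat.index if s not in matrix.columns]
    if missing or extra:
        raise ValueError("sample mismatch between methylation matrix and BP "
                         f"summaries; only in matrix: {missing[:5]}, only in "
                         f"BP: {extra[:5]}")
    bp_hat = bp_hat.loc[list(matrix.columns)]
    if covariates is not None:
        absent = [s for s in matrix.columns if s not in covariates.index]
        if absent:
            raise ValueError(f"samples without covariates: {absent[:5]}")
        covariates = covariates.loc[list(matrix.columns)]
    if matrix.shape[0] == 0:
        return pd.DataFrame(columns=["probe_id", "effect_m", "se_m", "p",
                                     "fdr", "effect_beta_per10", "n_used"])

    X, names = build_design(bp_hat, covariates)
    vals = matrix.to_numpy(dtype=float)
    M = vals if values_are_m else np.where(np.isnan(vals), np.nan,
                                           beta_to_m(vals))
    coef, se, n_used = huber_fit(M, X)
    eff, s = coef[:, 1], se[:, 1]
    dof = np.maximum(n_used - X.shape[1], 1)
    with np.errstate(all="ignore"):
        tstat = eff / s
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)

    # intercept method: reference point = fitted value at the regressor means
    xbar = X.mean(axis=0)
    alpha0 = coef @ xbar
    eff_beta10 = effect_to_beta_scale(alpha0, eff, 10.0)

    out = pd.DataFrame({
        "probe_id": matrix.index, "effect_m": eff, "se_m": s, "p": p,
        "effect_beta_per10": eff_beta10, "n_used": n_used,
    })
    tested = out["p"].notna()
    out["fdr"] = np.nan
    if tested.any():
        out.loc[tested, "fdr"] = multipletests(out.loc[tested, "p"],
                                               method="fdr_bh")[1]
    return out[["probe_id", "effect_m", "se_m", "p", "fdr",
                "effect_beta_per10", "n_used"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Empirical-null inflation / bias
# ---------------------------------------------------------------------------

@dataclass
class InflationReport:
    bif: float          # sd of the empirical null component
    bias: float         # mean of the empirical null component
    prop_null: float    # mixture weight of the null
    converged: bool
    warning: str | None = None


def estimate_inflation(z: np.ndarray | None = None,
                       p_values: np.ndarray | None = None,
                       effects: np.ndarray | None = None,
                       max_iter: int = 1000, tol: float = 1e-9
                       ) -> InflationReport:
    """Empirical-null bias/inflation by a 3-component Gaussian-mixture EM.

    The z-scores are modeled as null N(bias, bif^2) plus two tail
    components (means constrained at least 1 sd away from the null on
    either side). Feed either z-scores directly, or two-sided p-values with
    signed effects (reconstructed as sign * qnorm(1 - p/2)).
    """
    if z is None:
        if p_values is None or effects is None:
            raise ValueError("provide z, or p_values together with effects")
        pv = np.clip(np.asarray(p_values, dtype=float), 1e-300, 1.0)
        z = np.sign(effects) * stats.norm.isf(pv / 2.0)
    z = np.asarray(z, dtype=float)
    z = z[np.isfinite(z)]
    if z.size < 500:
        raise ValueError("inflation estimation needs >= 500 test statistics")
    if np.var(z) < 1e-12:
        return InflationReport(bif=0.0, bias=float(z.mean()), prop_null=1.0,
                               converged=False,
                               warning="degenerate: zero-variance statistics")

    mu0, s0 = float(np.median(z)), float(stats.median_abs_deviation(
        z, scale="normal"))
    s0 = max(s0, 0.05)
    pi = np.array([0.90, 0.05, 0.05])
    mu = np.array([mu0, mu0 - 3 * s0, mu0 + 3 * s0])
    sd = np.array([s0, 2 * s0, 2 * s0])
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        dens = np.stack([pi[c] * stats.norm.pdf(z, mu[c], sd[c])
                         for c in range(3)])
        tot = dens.sum(axis=0)
        tot = np.maximum(tot, 1e-300)
        resp = dens / tot
        ll = float(np.log(tot).sum())
        nk = resp.sum(axis=1)
        pi = nk / z.size
        for c in range(3):
            if nk[c] < 1e-8:
                continue
            mu[c] = float(resp[c] @ z / nk[c])
            sd[c] = float(np.sqrt(resp[c] @ (z - mu[c]) ** 2 / nk[c]))
        sd = np.maximum(sd, 0.05)
        # identifiability: tail components model genuine signal, so their
        # means stay well outside the null and their spread is at least the
        # null's — otherwise they absorb the null's shoulders
        mu[1] = min(mu[1], mu[0] - 2 * sd[0])
        mu[2] = max(mu[2], mu[0] + 2 * sd[0])
        sd[1] = max(sd[1], sd[0])
        sd[2] = max(sd[2], sd[0])
        if abs(ll - ll_old) < tol * (1 + abs(ll)):
            converged = True
            break
        ll_old = ll
    warning = None if converged else "EM did not converge"
    if warning:
        log.warning(warning)
    return InflationReport(bif=float(sd[0]), bias=float(mu[0]),
                           prop_null=float(pi[0]), converged=converged,
                           warning=warning)


# ---------------------------------------------------------------------------
# Candidate look-up / replication
# ---------------------------------------------------------------------------

def replicate_candidates(ewas: pd.DataFrame, candidates: pd.DataFrame,
                         alpha: float = 0.05) -> pd.DataFrame:
    """Look up candidate CpGs from prior studies.

    ``candidates`` needs columns probe_id and expected_direction (+1/-1 or
    '+'/'-'). A candidate is *replicated* when the effect sign matches and
    the uncorrected p-value is below ``alpha``; a significant hit with the
    opposite sign is flagged separately; candidates absent from the tested
    set are 'untested'.
    """
    dir_map = {"+": 1, "-": -1, "1": 1, "-1": -1, 1: 1, -1: -1, "+1": 1}
    tested = ewas.set_index("probe_id")
    rows = []
    for _, cand in candidates.iterrows():
        pid = cand["probe_id"]
        expected = dir_map[cand["expected_direction"]]
        if pid not in tested.index or not np.isfinite(tested.at[pid, "p"]):
            rows.append((pid, expected, np.nan, np.nan, "untested"))
            continue
        eff, p = tested.at[pid, "effect_m"], tested.at[pid, "p"]
        if p < alpha and np.sign(eff) == expected:
            status = "replicated"
        elif p < alpha:
            status = "significant_diverging_direction"
        else:
            status = "not_replicated"
        rows.append((pid, expected, float(eff), float(p), status))
    return pd.DataFrame(rows, columns=["probe_id", "expected_direction",
                                       "effect_m", "p", "status"])
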