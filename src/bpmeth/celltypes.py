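"""Reference-based placental cell-type deconvolution and BP association.

Bulk placental methylation is a mixture of six reference cell types
(Syncytiotrophoblast, Stromal, Endothelial, Trophoblast, Hofbauer, nRBC).
Per-sample proportions are recovered by constrained projection: minimize
||beta_bulk - R'w||^2 subject to w >= 0 and sum(w) = 1, solved as a
non-negative least-squares problem with a heavily weighted sum-to-one row
(deterministic, no tuning). Association with BP is tested on ilr
coordinates (a multivariate likelihood-ratio F test), and on the single
log(Stromal/SCT) ratio by ordinary least squares.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import nnls

from .compositional import CELL_TYPES, clr, ilr, stromal_sct_log_ratio, zero_replace
from .ewas import build_design

log = logging.getLogger(__name__)

MIN_DECONV_PROBES = 20
_SUM_WEIGHT = 1000.0


def select_discriminating_probes(refs: pd.DataFrame, n_per_type: int
                                 ) -> list[str]:
    """Per cell type, the ``n_per_type`` probes with the largest
    |beta_type - mean(beta_others)| margin; union, deduplicated."""
    if n_per_type <= 0:
        raise ValueError("n_per_type must be positive")
    vals = refs.to_numpy(dtype=float)
    n_types, n_probes = vals.shape
    if n_probes < 6 * n_per_type:
        log.warning("reference panel has only %d probes; using all", n_probes)
        return list(refs.columns)
    picked: list[str] = []
    for k in range(n_types):
        others = np.delete(vals, k, axis=0).mean(axis=0)
        margin = np.abs(vals[k] - others)
        top = np.argsort(-margin, kind="stable")[:n_per_type]
        picked.extend(refs.columns[i] for i in top)
    return sorted(set(picked), key=picked.index)


def _deconvolve_one(b: np.ndarray, R: np.ndarray) -> np.ndarray:
    A = np.vstack([R, _SUM_WEIGHT * np.ones((1, R.shape[1]))])
    y = np.append(b, _SUM_WEIGHT)
    w, _ = nnls(A, y)
    s = w.sum()
    if s <= 0:
        raise RuntimeError("deconvolution produced an all-zero solution")
    return w / s


def deconvolve(bulk: pd.DataFrame, refs: pd.DataFrame,
               probe_set: list[str] | None = None) -> pd.DataFrame:
    """Estimate compositions for every sample of a beta matrix
    (probes x samples). Missing bulk values are dropped pairwise; fewer
    than 20 usable probes for a sample is an error."""
    if probe_set is None:
        probe_set = [p for p in refs.columns if p in bulk.index]
    probes = [p for p in probe_set if p in bulk.index and p in refs.columns]
    if len(probes) < MIN_DECONV_PROBES:
        raise ValueError(f"only {len(probes)} usable probes "
                         f"(need >= {MIN_DECONV_PROBES})")
    R = refs[probes].to_numpy(dtype=float).T        # probes x 6
    B = bulk.loc[probes].to_numpy(dtype=float)      # probes x samples
    out = np.empty((B.shape[1], len(CELL_TYPES)))
    for j in range(B.shape[1]):
        b = B[:, j]
        keep = ~np.isnan(b)
        if keep.sum() < MIN_DECONV_PROBES:
            raise ValueError(f"sample {bulk.columns[j]!r} has only "
                             f"{int(keep.sum())} non-missing probes")
        out[j] = _deconvolve_one(b[keep], R[keep])
    return pd.DataFrame(out, index=bulk.columns, columns=list(CELL_TYPES))


# ---------------------------------------------------------------------------
# Association tests
# ---------------------------------------------------------------------------

def test_global_association(compositions: pd.DataFrame, bp_hat: pd.Series,
                            covariates: pd.DataFrame | None = None) -> float:
    """Global test of BP against the whole composition.

    Compositions are mapped to 5 ilr coordinates and regressed jointly on
    BP plus covariates; the test is a likelihood-ratio comparison against
    the no-BP model via Wilks' lambda with Rao's F approximation (exact for
    a single-column hypothesis). Returns the p-value.
    """
    comp = zero_replace(compositions.to_numpy(dtype=float))
    Y = ilr(comp)
    X_full, _ = _design_or_none(bp_hat, covariates, with_bp=True)
    X_red, _ = _design_or_none(bp_hat, covariates, with_bp=False)
    if X_full is None:
        return 1.0   # BP constant: zero hypothesis variance, nothing to test
    n, k_full = X_full.shape
    pv = Y.shape[1]
    if n <= k_full + pv + 1:
        raise ValueError("too few samples for the multivariate test")
    E_full = _resid_crossprod(Y, X_full)
    E_red = _resid_crossprod(Y, X_red)
    lam = np.linalg.det(E_full) / np.linalg.det(E_red)
    nu_e = n - k_full
    fstat = (nu_e - pv + 1) / pv * (1.0 - lam) / lam
    return float(stats.f.sf(fstat, pv, nu_e - pv + 1))


def _design_or_none(bp_hat, covariates, with_bp):
    if with_bp:
        if np.std(np.asarray(bp_hat, dtype=float)) < 1e-12:
            return None, None
        return build_design(bp_hat, covariates)
    cols = [pd.Series(1.0, index=bp_hat.index, name="intercept")]
    if covariates is not None:
        enc = pd.get_dummies(covariates.loc[bp_hat.index], drop_first=True,
                             dtype=float)
        cols.extend(enc[c] for c in enc.columns)
    X = pd.concat(cols, axis=1)
    return X.to_numpy(dtype=float), list(X.columns)


def _resid_crossprod(Y, X):
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    R = Y - X @ beta
    return R.T @ R


def fit_ratio_model(compositions: pd.DataFrame, bp_hat: pd.Series,
                    covariates: pd.DataFrame | None = None):
    """OLS of log(Stromal/SCT) on BP (+ covariates).

    Returns (effect per mmHg, (ci_lo, ci_hi), p) with Wald 95% intervals.
    """
    comp = zero_replace(compositions.to_numpy(dtype=float))
    y = stromal_sct_log_ratio(comp)
    X, names = build_design(bp_hat, covariates)
    fit = sm.OLS(y, X).fit()
    j = names.index("bp_hat")
    ci = fit.conf_int()[j]
    return float(fit.params[j]), (float(ci[0]), float(ci[1])), float(fit.pvalues[j])


def per_celltype_association(compositions: pd.DataFrame, bp_hat: pd.Series,
                             covariates: pd.DataFrame | None = None
                             ) -> pd.DataFrame:
    """Linear model of each proportion on BP, one cell type at a time.

    Proportions are not independent outcomes (they sum to one); these
    per-type fits are descriptive companions to the global ilr test.
    """
    X, names = build_design(bp_hat, covariates)
    j = names.index("bp_hat")
    rows = []
    for ct in CELL_TYPES:
        fit = sm.OLS(compositions[ct].to_numpy(dtype=float), X).fit()
        ci = fit.conf_int()[j]
        rows.append((ct, float(fit.params[j]), float(ci[0]), float(ci[1]),
                     float(fit.pvalues[j])))
    return pd.DataFrame(rows, columns=["cell_type", "effect", "ci_lo",
                                       "ci_hi", "p"])


def compositional_pca(compositions: pd.DataFrame) -> dict:
    """PCA of centered-log-ratio compositions (SVD of the centered clr)."""
    Z = clr(zero_replace(compositions.to_numpy(dtype=float)))
    Zc = Z - Z.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(Zc, full_matrices=False)
    evr = s ** 2 / np.sum(s ** 2) if s.sum() > 0 else s
    ncomp = min(5, vt.shape[0])
    return {
        "loadings": pd.DataFrame(vt[:ncomp].T, index=list(CELL_TYPES),
                                 columns=[f"PC{i+1}" for i in range(ncomp)]),
        "scores": pd.DataFrame(u[:, :ncomp] * s[:ncomp],
                               index=compositions.index,
                               columns=[f"PC{i+1}" for i in range(ncomp)]),
        "explained_variance_ratio": evr[:ncomp],
    }
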