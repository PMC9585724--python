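"""Direct vs cell-composition-mediated effects of BP on methylation.

For each probe the BP -> methylation association is decomposed with two
linear models sharing the confounders Z:

* mediator model:  mediator ~ BP + Z      (coefficients a)
* outcome model:   M ~ BP + mediator + Z  (direct effect c', coefficients b)
* marginal model:  M ~ BP + Z             (total effect c)

For least-squares fits c - c' = a'b exactly, so total = direct + indirect
holds to numerical precision, and component-wise indirect effects a_k b_k
sum to the indirect effect. The mediator is either the full composition
(as 5 ilr coordinates, the first being the Stromal/SCT contrast) or the
single log(Stromal/SCT) ratio. Uncertainty comes from a seeded
nonparametric bootstrap over subjects with percentile 95% intervals;
significance = interval excluding zero. Probe-level calls are aggregated
per DMR into All / Some / No classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compositional import ilr, stromal_sct_log_ratio, zero_replace
from .ewas import build_design

log = logging.getLogger(__name__)

#: re-exported: multiplicative zero replacement (log-ratio domain requirement)
from .compositional import zero_replace, ilr, ilr_inverse  # noqa: F401,E402


@dataclass
class MediationResult:
    probe_id: str
    total: float
    direct: float
    indirect: float
    component_indirect: np.ndarray
    ci95_direct: tuple[float, float]
    ci95_indirect: tuple[float, float]
    n_boot: int
    seed: int


def _point_estimates(X_red: np.ndarray, Mmed: np.ndarray, Y: np.ndarray):
    """(total, direct, indirect, components) for every column of Y."""
    X_out = np.column_stack([X_red[:, :2], Mmed, X_red[:, 2:]])
    q = Mmed.shape[1]
    a = np.linalg.lstsq(X_red, Mmed, rcond=None)[0][1]          # (q,)
    bo = np.linalg.lstsq(X_out, Y, rcond=None)[0]               # (k, p)
    direct = bo[1]
    b = bo[2:2 + q]                                             # (q, p)
    total = np.linalg.lstsq(X_red, Y, rcond=None)[0][1]
    indirect = total - direct
    comps = a[:, None] * b                                      # (q, p)
    return total, direct, indirect, comps


def _mediate(bp_hat: pd.Series, mediator: np.ndarray, m_values: np.ndarray,
             covariates: pd.DataFrame | None, probe_ids: list[str],
             n_boot: int, seed: int) -> list[MediationResult]:
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200 for stable percentile CIs")
    X_red, _ = build_design(bp_hat, covariates)
    Mmed = np.atleast_2d(np.asarray(mediator, dtype=float))
    if Mmed.shape[0] != X_red.shape[0]:
        Mmed = Mmed.T
    Y = np.asarray(m_values, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X_red.shape[0]
    if Y.shape[0] != n:
        raise ValueError("m_values not aligned with samples")

    total, direct, indirect, comps = _point_estimates(X_red, Mmed, Y)

    rng = np.random.default_rng(seed)
    k_out = X_red.shape[1] + Mmed.shape[1]
    boot_direct = np.empty((n_boot, Y.shape[1]))
    boot_indirect = np.empty((n_boot, Y.shape[1]))
    for bi in range(n_boot):
        for attempt in range(10):
            idx = rng.integers(0, n, size=n)
            Xb = X_red[idx]
            Xob = np.column_stack([Xb[:, :2], Mmed[idx], Xb[:, 2:]])
            if np.linalg.matrix_rank(Xob) == k_out:
                break
            log.info("rank-deficient bootstrap resample redrawn "
                     "(attempt %d)", attempt + 1)
        else:
            raise RuntimeError("could not draw a full-rank bootstrap "
                               "resample in 10 tries")
        tb, db, ib, _ = _point_estimates(Xb, Mmed[idx], Y[idx])
        boot_direct[bi] = db
        boot_indirect[bi] = ib

    lo_d, hi_d = np.percentile(boot_direct, [2.5, 97.5], axis=0)
    lo_i, hi_i = np.percentile(boot_indirect, [2.5, 97.5], axis=0)
    return [
        MediationResult(
            probe_id=probe_ids[j], total=float(total[j]),
            direct=float(direct[j]), indirect=float(indirect[j]),
            component_indirect=comps[:, j].copy(),
            ci95_direct=(float(lo_d[j]), float(hi_d[j])),
            ci95_indirect=(float(lo_i[j]), float(hi_i[j])),
            n_boot=n_boot, seed=seed)
        for j in range(Y.shape[1])
    ]


def compositional_mediation(bp_hat: pd.Series, compositions: pd.DataFrame,
                            m_values: np.ndarray,
                            covariates: pd.DataFrame | None = None,
                            n_boot: int = 1000, seed: int = 0,
                            probe_ids: list[str] | None = None
                            ) -> list[MediationResult]:
    """Mediation through the full composition as 5 ilr coordinates.

    ``m_values`` may be one probe (n,) or a matrix (n x p); the mediator
    model is shared across probes, the outcome regressions are vectorized.
    """
    comp = zero_replace(compositions.to_numpy(dtype=float))
    coords = ilr(comp)
    Y = np.asarray(m_values, dtype=float)
    p = 1 if Y.ndim == 1 else Y.shape[1]
    ids = probe_ids if probe_ids is not None else [f"probe{j}" for j in range(p)]
    return _mediate(bp_hat, coords, Y, covariates, ids, n_boot, seed)


def ratio_mediation(bp_hat: pd.Series, compositions: pd.DataFrame | None,
                    m_values: np.ndarray,
                    covariates: pd.DataFrame | None = None,
                    n_boot: int = 1000, seed: int = 0,
                    log_ratio: np.ndarray | None = None,
                    probe_ids: list[str] | None = None
                    ) -> list[MediationResult]:
    """Single-mediator analysis via log(Stromal/SCT) (product of
    coefficients; indirect = a * b). Pass ``compositions`` or a
    pre-computed ``log_ratio``."""
    if log_ratio is None:
        if compositions is None:
            raise ValueError("need compositions or log_ratio")
        comp = zero_replace(compositions.to_numpy(dtype=float))
        log_ratio = stromal_sct_log_ratio(comp)
    lr = np.asarray(log_ratio, dtype=float)[:, None]
    Y = np.asarray(m_values, dtype=float)
    p = 1 if Y.ndim == 1 else Y.shape[1]
    ids = probe_ids if probe_ids is not None else [f"probe{j}" for j in range(p)]
    return _mediate(bp_hat, lr, Y, covariates, ids, n_boot, seed)


def results_table(results: list[MediationResult]) -> pd.DataFrame:
    """Flatten MediationResults into a tidy per-probe table."""
    rows = []
    for r in results:
        rows.append({
            "probe_id": r.probe_id, "total": r.total, "direct": r.direct,
            "indirect": r.indirect,
            "ci_direct_lo": r.ci95_direct[0], "ci_direct_hi": r.ci95_direct[1],
            "ci_indirect_lo": r.ci95_indirect[0],
            "ci_indirect_hi": r.ci95_indirect[1],
            "n_boot": r.n_boot, "seed": r.seed,
        })
    return pd.DataFrame(rows)


def aggregate_dmr(mediation_results: pd.DataFrame,
                  dmr_membership: dict[str, list[str]]) -> pd.DataFrame:
    """Classify each DMR by its member probes' significance pattern.

    For direct and indirect effects separately: 'All' if every member
    probe's CI excludes zero, 'No' if none does, 'Some' otherwise. DMRs
    with probes missing from the mediation table are flagged incomplete.
    """
    med = mediation_results.set_index("probe_id")
    rows = []
    for dmr_id, probes in dmr_membership.items():
        present = [p for p in probes if p in med.index]
        incomplete = len(present) < len(probes)
        if not present:
            rows.append((dmr_id, "incomplete", "incomplete", True))
            continue
        sub = med.loc[present]
        sig_d = ((sub["ci_direct_lo"] > 0) | (sub["ci_direct_hi"] < 0))
        sig_i = ((sub["ci_indirect_lo"] > 0) | (sub["ci_indirect_hi"] < 0))

        def classify(sig):
            if sig.all():
                return "All"
            if not sig.any():
                return "No"
            return "Some"

        rows.append((dmr_id, classify(sig_d), classify(sig_i), incomplete))
    return pd.DataFrame(rows, columns=["dmr_id", "direct_class",
                                       "indirect_class", "incomplete"])
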