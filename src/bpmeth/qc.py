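"""Methylation-matrix hygiene: scale transforms, outlier masking, probe filters.

Inputs are assumed already normalized (e.g. BMIQ); this module starts where
the statistical analysis starts. Beta-values are the methylated fraction in
[0, 1]; regressions run on M-values, M = log2(beta / (1 - beta)), whose
variance is more homoscedastic across the beta range.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

BETA_CLIP = 1e-6


def beta_to_m(beta):
    """M = log2(beta / (1 - beta)); beta clipped to [1e-6, 1 - 1e-6] first."""
    beta = np.clip(np.asarray(beta, dtype=float), BETA_CLIP, 1.0 - BETA_CLIP)
    return np.log2(beta / (1.0 - beta))


def m_to_beta(m):
    """Inverse transform beta = 2^M / (1 + 2^M)."""
    m = np.asarray(m, dtype=float)
    p = np.exp2(m)
    return p / (1.0 + p)


def mask_outliers(matrix: pd.DataFrame, k_iqr: float = 3.0,
                  min_obs: int = 10) -> tuple[pd.DataFrame, float]:
    """Set extreme values missing, probe by probe.

    Within each probe row, values above Q3 + k*IQR or below Q1 - k*IQR are
    set to NaN (quartiles by linear / type-7 interpolation, the numpy
    default). Rows with fewer than ``min_obs`` non-missing values are left
    untouched. Returns the masked matrix and the global fraction removed.
    """
    x = matrix.to_numpy(dtype=float)
    n_obs = np.sum(~np.isnan(x), axis=1)
    rows = n_obs >= min_obs
    q1 = np.full(x.shape[0], -np.inf)
    q3 = np.full(x.shape[0], np.inf)
    if rows.any():
        q1[rows] = np.nanquantile(x[rows], 0.25, axis=1)
        q3[rows] = np.nanquantile(x[rows], 0.75, axis=1)
    iqr = q3 - q1
    lo = (q1 - k_iqr * iqr)[:, None]
    hi = (q3 + k_iqr * iqr)[:, None]
    with np.errstate(invalid="ignore"):
        bad = (x < lo) | (x > hi)
    n_values = np.sum(~np.isnan(x))
    out = x.copy()
    out[bad] = np.nan
    frac = float(bad.sum() / n_values) if n_values else 0.0
    log.info("outlier masking removed %d values (%.4f%%)", bad.sum(),
             100 * frac)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns), frac


def filter_probes(matrix: pd.DataFrame, annotation: pd.DataFrame,
                  blocklists: list[set[str]] | None = None,
                  drop_sex_chroms: bool = True) -> tuple[pd.DataFrame, int]:
    """Remove blocklisted probes (SNP-adjacent, cross-reactive) and,
    optionally, probes on chrX/chrY. Returns (filtered matrix, n retained).
    Blocklist entries absent from the matrix are ignored with a logged count.
    """
    probes = pd.Index(matrix.index)
    drop: set[str] = set()
    n_unknown = 0
    for bl in blocklists or []:
        bl = set(bl)
        n_unknown += len(bl - set(probes))
        drop |= bl & set(probes)
    if n_unknown:
        log.info("%d blocklisted probes not present in the matrix", n_unknown)
    if drop_sex_chroms:
        ann = annotation.set_index("probe_id")["chrom"]
        sex = {"chrX", "chrY", "X", "Y"}
        on_sex = {p for p in probes if str(ann.get(p)) in sex}
        drop |= on_sex
    keep = probes.difference(drop, sort=False)
    if keep.empty:
        log.warning("probe filtering removed every probe")
    out = matrix.loc[keep]
    return out, len(out)


def read_blocklist(path) -> set[str]:
    """One probe id per line; blank lines and '#' comments ignored."""
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out
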