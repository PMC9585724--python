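"""Differentially methylated region detection from probe-level p-values.

Single-CpG tests rarely survive epigenome-wide correction; coordinated
signal across neighboring probes is the more sensitive target. This module
implements a comb-p style caller:

1. estimate the correlation of probe z-scores as a function of genomic
   distance (binned, up to a maximum lag);
2. smooth each probe's p-value by a Stouffer-Liptak combination over its
   neighbors, with the covariance implied by the distance-correlation
   function;
3. seed regions at probes with smoothed p below a stringent threshold,
   extend through consecutive probes while the inter-probe gap stays small
   and the smoothed p stays nominally significant;
4. score each candidate region by Stouffer-Liptak over the *raw* member
   p-values, correct for the genome searched with a Sidak width correction,
   then Benjamini-Hochberg across candidate regions.

The Sidak step (exponent = total tested width / region width) is applied
before BH because candidate regions are selected by the seeding step;
ranking raw region p-values directly would ignore that selection.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

P_FLOOR, P_CEIL = 1e-300, 1.0 - 1e-16


def _z_from_p(p: np.ndarray) -> np.ndarray:
    return stats.norm.isf(np.clip(p, P_FLOOR, P_CEIL))


# ---------------------------------------------------------------------------
# Distance-binned correlation of test statistics
# ---------------------------------------------------------------------------

def estimate_p_correlation(p_values: np.ndarray, chrom: np.ndarray,
                           pos: np.ndarray, max_lag_bp: int = 1000,
                           bin_width_bp: int = 50, min_pairs: int = 200
                           ) -> pd.DataFrame:
    """Pearson correlation of probe z-scores by inter-probe distance.

    Probe pairs on the same chromosome at distance <= ``max_lag_bp`` are
    binned by distance (bins of ``bin_width_bp``); bins with fewer than
    ``min_pairs`` pairs are merged with the following bin(s). Correlations
    are clipped below at zero. Returns columns lo, hi, corr, n_pairs.
    """
    z = _z_from_p(np.asarray(p_values, dtype=float))
    chrom = np.asarray(chrom)
    pos = np.asarray(pos, dtype=float)

    d_all, zi_all, zj_all = [], [], []
    for c in pd.unique(chrom):
        sel = chrom == c
        order = np.argsort(pos[sel], kind="mergesort")
        pc, zc = pos[sel][order], z[sel][order]
        j = 0
        for i in range(len(pc)):
            lo = pc[i] - max_lag_bp
            while pc[j] < lo:
                j += 1
            if j < i:
                d_all.append(pc[i] - pc[j:i])
                zi_all.append(np.full(i - j, zc[i]))
                zj_all.append(zc[j:i])
    if not d_all:
        log.warning("no probe pairs within %d bp; assuming zero correlation",
                    max_lag_bp)
        return pd.DataFrame({"lo": [0], "hi": [max_lag_bp], "corr": [0.0],
                             "n_pairs": [0]})
    d = np.concatenate(d_all)
    zi = np.concatenate(zi_all)
    zj = np.concatenate(zj_all)

    edges = np.arange(0, max_lag_bp + bin_width_bp, bin_width_bp)
    which = np.clip(np.searchsorted(edges, d, side="right") - 1, 0,
                    len(edges) - 2)
    rows = []
    buf_i, buf_j = [], []
    lo_edge = edges[0]
    for b in range(len(edges) - 1):
        sel = which == b
        buf_i.append(zi[sel])
        buf_j.append(zj[sel])
        n = sum(len(a) for a in buf_i)
        if n >= min_pairs:
            a = np.concatenate(buf_i)
            bb = np.concatenate(buf_j)
            r = float(np.corrcoef(a, bb)[0, 1]) if n > 1 else 0.0
            rows.append((lo_edge, edges[b + 1], max(r, 0.0), n))
            buf_i, buf_j = [], []
            lo_edge = edges[b + 1]
    if buf_i and sum(len(a) for a in buf_i):
        a = np.concatenate(buf_i)
        bb = np.concatenate(buf_j)
        n = len(a)
        if rows and n < min_pairs:
            # fold the sparse tail into the last emitted bin's estimate
            rows[-1] = (rows[-1][0], edges[-1], rows[-1][2], rows[-1][3] + n)
        else:
            r = float(np.corrcoef(a, bb)[0, 1]) if n > 1 else 0.0
            rows.append((lo_edge, edges[-1], max(r, 0.0) if np.isfinite(r)
                         else 0.0, n))
    if not rows:
        log.warning("too few probe pairs for correlation estimation; "
                    "flat zero-correlation fallback")
        rows = [(0, max_lag_bp, 0.0, int(len(d)))]
    return pd.DataFrame(rows, columns=["lo", "hi", "corr", "n_pairs"])


def correlation_lookup(corr_table: pd.DataFrame, max_lag_bp: int = 1000):
    """Step function distance -> correlation (0 beyond the last bin)."""
    lo = corr_table["lo"].to_numpy(dtype=float)
    cr = corr_table["corr"].to_numpy(dtype=float)
    hi_last = float(corr_table["hi"].iloc[-1])

    def f(dist):
        dist = np.asarray(dist, dtype=float)
        idx = np.clip(np.searchsorted(lo, dist, side="right") - 1, 0,
                      len(lo) - 1)
        out = cr[idx]
        return np.where(dist >= hi_last, 0.0, out)

    return f


# ---------------------------------------------------------------------------
# Stouffer-Liptak combination
# ---------------------------------------------------------------------------

def nearest_psd(sigma: np.ndarray) -> np.ndarray:
    """Eigenvalue-clipped nearest positive semi-definite repair."""
    w, v = np.linalg.eigh(sigma)
    if w.min() >= -1e-10:
        return sigma
    log.info("correlation matrix repaired to nearest PSD "
             "(min eigenvalue %.3g)", w.min())
    w = np.clip(w, 0.0, None)
    out = (v * w) @ v.T
    d = np.sqrt(np.clip(np.diag(out), 1e-12, None))
    return out / np.outer(d, d)


def stouffer_liptak(p_vector: np.ndarray,
                    correlation_matrix: np.ndarray | None = None) -> float:
    """Combine p-values with dependence: z_c = sum(z) / sqrt(1' Sigma 1)."""
    p = np.atleast_1d(np.asarray(p_vector, dtype=float))
    z = _z_from_p(p)
    if correlation_matrix is None:
        denom = float(len(p))
    else:
        sigma = nearest_psd(np.asarray(correlation_matrix, dtype=float))
        denom = float(sigma.sum())
    zc = z.sum() / np.sqrt(max(denom, 1e-12))
    return float(np.clip(stats.norm.sf(zc), P_FLOOR, 1.0))


def _sigma_from_positions(pos: np.ndarray, corr_fn) -> np.ndarray:
    d = np.abs(pos[:, None] - pos[None, :])
    sigma = corr_fn(d)
    np.fill_diagonal(sigma, 1.0)
    return sigma


# ---------------------------------------------------------------------------
# Smoothing and region calling
# ---------------------------------------------------------------------------

def _smooth_p(p: np.ndarray, pos: np.ndarray, corr_fn, half_window: float
              ) -> np.ndarray:
    """Per-probe Stouffer-Liptak over neighbors within +/- half_window."""
    z = _z_from_p(p)
    lo = np.searchsorted(pos, pos - half_window, side="left")
    hi = np.searchsorted(pos, pos + half_window, side="right")
    csum = np.concatenate([[0.0], np.cumsum(z)])
    out = np.empty_like(p)
    for i in range(len(p)):
        a, b = lo[i], hi[i]
        if b - a == 1:
            out[i] = p[i]
            continue
        w = pos[a:b]
        sigma_sum = _sigma_from_positions(w, corr_fn).sum()
        zc = (csum[b] - csum[a]) / np.sqrt(max(sigma_sum, 1e-12))
        out[i] = stats.norm.sf(zc)
    return np.clip(out, P_FLOOR, 1.0)


def call_regions(ewas: pd.DataFrame, annotation: pd.DataFrame,
                 corr_table: pd.DataFrame | None = None,
                 seed_p: float = 1e-3, max_gap: int = 500,
                 min_probes: int = 3, extend_p: float = 0.05,
                 max_lag_bp: int = 1000, bin_width_bp: int = 50,
                 smooth_window_bp: int = 300,
                 significance: str | None = "fdr", alpha: float = 0.05
                 ) -> pd.DataFrame:
    """Call DMRs from an EWAS table and probe annotation.

    ``smooth_window_bp`` is the total width of the p-value smoothing window
    (the comb-p bin-size convention); ``max_lag_bp`` bounds the
    distance-correlation estimation. ``significance`` selects the final
    filter: 'fdr' (BH over Sidak-corrected region p-values, default),
    'sidak', or None to return every candidate region with its statistics.
    """
    df = ewas.merge(annotation[["probe_id", "chrom", "pos"]], on="probe_id")
    df = df.dropna(subset=["p"]).sort_values(["chrom", "pos"],
                                             kind="mergesort")
    if df.empty:
        return _empty_regions()
    if corr_table is None:
        corr_table = estimate_p_correlation(df["p"].to_numpy(),
                                            df["chrom"].to_numpy(),
                                            df["pos"].to_numpy(),
                                            max_lag_bp, bin_width_bp)
    corr_fn = correlation_lookup(corr_table, max_lag_bp)

    total_bp = int(df.groupby("chrom")["pos"]
                     .agg(lambda s: s.max() - s.min() + 1).sum())

    regions = []
    for chrom, sub in df.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy(dtype=float)
        p = sub["p"].to_numpy(dtype=float)
        sp = _smooth_p(p, pos, corr_fn, half_window=smooth_window_bp / 2)
        extend = sp < extend_p
        seed = sp < seed_p
        if not seed.any():
            continue
        # maximal runs of consecutive extendable probes with gaps <= max_gap
        gap_ok = np.concatenate([[False], np.diff(pos) <= max_gap])
        run_start = extend & ~(np.concatenate([[False], extend[:-1]]) & gap_ok)
        run_id = np.where(extend, np.cumsum(run_start), -1)
        for rid in np.unique(run_id[seed]):
            idx = np.where(run_id == rid)[0]
            if len(idx) < min_probes:
                continue
            rpos = pos[idx]
            sigma = _sigma_from_positions(rpos, corr_fn)
            p_region = stouffer_liptak(p[idx], sigma)
            eff = sub["effect_beta_per10"].to_numpy()[idx] / 10.0
            regions.append({
                "chrom": chrom, "start": int(rpos.min()),
                "end": int(rpos.max()), "n_probes": len(idx),
                "probe_ids": ",".join(sub["probe_id"].to_numpy()[idx]),
                "p_region": p_region,
                "mean_effect_beta": float(np.nanmean(eff)),
            })
    if not regions:
        return _empty_regions()
    out = pd.DataFrame(regions)
    width = (out["end"] - out["start"] + 1).clip(lower=1)
    exponent = np.maximum(total_bp / width, 1.0)
    out["p_sidak"] = np.clip(-np.expm1(exponent * np.log1p(-out["p_region"])),
                             out["p_region"], 1.0)
    order = out["p_sidak"].rank(method="first").astype(int)
    m = len(out)
    # step-up BH on the Sidak-corrected region p-values
    srt = out["p_sidak"].sort_values()
    adj = np.minimum.accumulate((srt.to_numpy() * m
                                 / np.arange(1, m + 1))[::-1])[::-1]
    out["fdr"] = pd.Series(np.clip(adj, 0, 1), index=srt.index)
    del order
    if significance == "fdr":
        out = out[out["fdr"] < alpha]
    elif significance == "sidak":
        out = out[out["p_sidak"] < alpha]
    elif significance is not None:
        raise ValueError(f"unknown significance filter {significance!r}")
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def _empty_regions() -> pd.DataFrame:
    return pd.DataFrame(columns=["chrom", "start", "end", "n_probes",
                                 "probe_ids", "p_region", "mean_effect_beta",
                                 "p_sidak", "fdr"])


# ---------------------------------------------------------------------------
# Annotation and enrichment
# ---------------------------------------------------------------------------

def annotate_regions(dmrs: pd.DataFrame, gene_table: pd.DataFrame,
                     max_distance: int = 10_000) -> pd.DataFrame:
    """Label each region with an overlapping gene (ties broken by distance
    to the TSS, then lexicographically), else the nearest gene within
    ``max_distance`` bp, else 'intergenic'."""
    genes = gene_table.copy()
    if "strand" not in genes.columns:
        genes["strand"] = "+"
    genes["tss"] = np.where(genes["strand"] == "-", genes["end"],
                            genes["start"])
    labels = []
    for _, r in dmrs.iterrows():
        g = genes[genes["chrom"] == r["chrom"]]
        if g.empty:
            labels.append("intergenic")
            continue
        overlap = g[(g["start"] <= r["end"]) & (g["end"] >= r["start"])]
        if not overlap.empty:
            tss_d = np.abs(overlap["tss"]
                           - np.clip(overlap["tss"], r["start"], r["end"]))
            cand = overlap.assign(_d=tss_d).sort_values(["_d", "name"])
            labels.append(cand["name"].iloc[0])
            continue
        dist = np.maximum(g["start"] - r["end"], r["start"] - g["end"])
        near = g.assign(_d=dist).query("_d <= @max_distance")
        if near.empty:
            labels.append("intergenic")
        else:
            labels.append(near.sort_values(["_d", "name"])["name"].iloc[0])
    out = dmrs.copy()
    out["gene_label"] = labels
    return out


def location_enrichment(dmr_probes: set[str], all_probes: list[str],
                        annotation: pd.DataFrame) -> pd.DataFrame:
    """Fisher exact enrichment of DMR membership per location class
    (e.g. TSS-region / gene body / other), BH-corrected across classes."""
    ann = annotation.set_index("probe_id")
    cls = ann.reindex(all_probes)["location_class"]
    in_dmr = pd.Index(all_probes).isin(dmr_probes)
    rows = []
    for c in sorted(cls.dropna().unique()):
        members = (cls == c).to_numpy()
        a = int(np.sum(in_dmr & members))
        b = int(np.sum(in_dmr & ~members))
        c2 = int(np.sum(~in_dmr & members))
        d = int(np.sum(~in_dmr & ~members))
        if a + c2 == 0:
            continue
        orr, p = stats.fisher_exact([[a, b], [c2, d]])
        rows.append((c, a, float(orr), float(p)))
    if not rows:
        return pd.DataFrame(columns=["location_class", "n_dmr_probes",
                                     "odds_ratio", "p", "fdr"])
    out = pd.DataFrame(rows, columns=["location_class", "n_dmr_probes",
                                      "odds_ratio", "p"])
    from statsmodels.stats.multitest import multipletests
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def to_bed(dmrs: pd.DataFrame) -> pd.DataFrame:
    """Convert 1-based inclusive regions to 0-based half-open BED records."""
    return pd.DataFrame({
        "chrom": dmrs["chrom"],
        "start": dmrs["start"].astype(int) - 1,
        "end": dmrs["end"].astype(int),
        "name": [f"dmr_{i}" for i in range(len(dmrs))],
        "score": np.minimum(1000, -10 * np.log10(
            np.clip(dmrs["p_region"].astype(float), 1e-100, 1.0))).astype(int),
    })
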