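"""Reproducible evaluation suite: parameter recovery on synthetic cohorts.

Every function here regenerates its inputs from scratch under a caller
seed, runs the corresponding pipeline stage(s), and returns the measured
quantities. The problem sizes are chosen so the whole suite runs in a few
minutes on one CPU; docs/methods.md discusses what these checks do and do
not establish.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import bp as bp_mod
from . import celltypes, dmr as dmr_mod, ewas as ewas_mod, mediation, qc, synthetic


def _spawn(seed: int, k: int) -> list[int]:
    return [int(x) for x in np.random.default_rng(seed).integers(0, 2**31,
                                                                 size=k)]


# ---------------------------------------------------------------------------
# 1. MAP worked example
# ---------------------------------------------------------------------------

def map_worked_example() -> dict:
    """MAP at representative whole-pregnancy medians (SBP 115, DBP 64.9)."""
    m, pp = bp_mod.compute_indicators(115.0, 64.9)
    return {"map_mmhg": float(np.round(m, 1)), "pp_mmhg": float(np.round(pp, 1))}


# ---------------------------------------------------------------------------
# 2. Deconvolution recovery
# ---------------------------------------------------------------------------

def deconvolution_recovery(seed: int, n_mixtures: int = 100,
                           noise_sd: float = 0.02) -> dict:
    """RMSE of recovered vs true compositions for noisy synthetic mixtures."""
    s = _spawn(seed, 3)
    refs = synthetic.generate_reference_profiles(600, 50, s[0])
    rng = np.random.default_rng(s[1])
    z = np.log(synthetic.DEFAULT_COMPOSITION)[None, :] \
        + rng.normal(0, 0.25, (n_mixtures, 6))
    w = np.exp(z)
    w /= w.sum(axis=1, keepdims=True)
    bulk = np.clip(w @ refs.to_numpy(), 1e-6, 1 - 1e-6)
    m = np.log2(bulk / (1 - bulk)) + rng.normal(0, noise_sd, bulk.shape)
    beta = pd.DataFrame((np.exp2(m) / (1 + np.exp2(m))).T,
                        index=refs.columns,
                        columns=[f"s{i}" for i in range(n_mixtures)])
    probes = celltypes.select_discriminating_probes(refs, 50)
    est = celltypes.deconvolve(beta, refs, probes)
    rmse = np.sqrt(((est.to_numpy() - w) ** 2).mean(axis=0))
    return {"max_component_rmse": float(rmse.max()),
            "mean_component_rmse": float(rmse.mean()),
            "n": n_mixtures}


# ---------------------------------------------------------------------------
# 3. EWAS type-I calibration and inflation
# ---------------------------------------------------------------------------

def ewas_null_calibration(seed: int, n_subjects: int = 300,
                          n_probes: int = 2000) -> dict:
    """Fraction of null probes with p < 0.05, and the empirical-null BIF,
    on a cohort with no planted effects and no composition-BP coupling."""
    cohort = synthetic.generate_cohort(
        n_subjects=n_subjects, n_probes=n_probes, n_dmr_blocks=0,
        gamma_comp=0.0, seed=seed)
    summ = bp_mod.summarize_bp(cohort.bp_records, "sbp", "whole")
    bp_hat = summ.set_index("subject_id")["bp_hat"]
    res = ewas_mod.run_ewas(cohort.beta, bp_hat)
    rate = float((res["p"] < 0.05).mean())
    infl = ewas_mod.estimate_inflation(p_values=res["p"].to_numpy(),
                                       effects=res["effect_m"].to_numpy())
    return {"type1_rate_p05": rate, "bif": float(infl.bif),
            "bias": float(infl.bias), "n": n_probes}


# ---------------------------------------------------------------------------
# 4. DMR recovery and family-wise null calibration
# ---------------------------------------------------------------------------

def _dmr_one_recovery(seed: int) -> bool:
    cohort = synthetic.generate_cohort(
        n_subjects=600, n_probes=1000, n_dmr_blocks=1, block_size=8,
        effect_m_per_mmhg=0.0289,     # ~0.05 on the beta scale per 10 mmHg
        gamma_comp=0.0, seed=seed)
    summ = bp_mod.summarize_bp(cohort.bp_records, "sbp", "whole")
    bp_hat = summ.set_index("subject_id")["bp_hat"]
    res = ewas_mod.run_ewas(cohort.beta, bp_hat)
    regs = dmr_mod.call_regions(res, cohort.annotation, significance="fdr")
    blk = cohort.truth.dmr_blocks[0]
    hit = regs[(regs["chrom"] == blk.chrom) & (regs["start"] <= blk.end)
               & (regs["end"] >= blk.start)]
    if len(hit) != 1 or len(regs) != 1:
        return False
    ann = cohort.annotation[cohort.annotation["chrom"] == blk.chrom] \
        .sort_values("pos").reset_index(drop=True)
    idx = {p: i for i, p in enumerate(ann["pos"])}
    r = hit.iloc[0]
    return (abs(idx[r["start"]] - idx[blk.start]) <= 1
            and abs(idx[r["end"]] - idx[blk.end]) <= 1)


def dmr_recovery(seed: int, n_reps: int = 50) -> dict:
    """Fraction of replicates where the planted 8-probe region is called as
    exactly one DMR with boundaries within one probe of truth."""
    seeds = _spawn(seed, n_reps)
    hits = sum(_dmr_one_recovery(s) for s in seeds)
    return {"detection_rate": hits / n_reps, "n": n_reps}


def dmr_null_calibration(seed: int, n_reps: int = 200,
                         n_probes: int = 5000) -> dict:
    """Family-wise rate of the region caller under the global null
    (independent uniform probe p-values on an array-like probe layout)."""
    probe_ids = [f"cg{i:08d}" for i in range(n_probes)]
    s = _spawn(seed, 2)
    ann = synthetic.generate_probe_annotation(probe_ids, s[0])
    rng = np.random.default_rng(s[1])
    fam = 0
    for _ in range(n_reps):
        ew = pd.DataFrame({"probe_id": probe_ids,
                           "p": rng.uniform(size=n_probes),
                           "effect_beta_per10": 0.0})
        regs = dmr_mod.call_regions(ew, ann, significance="fdr")
        fam += int(len(regs) > 0)
    return {"familywise_rate": fam / n_reps, "n": n_reps}


# ---------------------------------------------------------------------------
# 5. Stouffer-Liptak oracle
# ---------------------------------------------------------------------------

def stouffer_oracle() -> dict:
    """Worked combination examples with known closed-form answers."""
    p_ind = dmr_mod.stouffer_liptak([0.05, 0.05, 0.05], np.eye(3))
    p_dep = dmr_mod.stouffer_liptak([0.05, 0.05, 0.05], np.ones((3, 3)))
    return {"combined_p_independent": float(p_ind),
            "combined_p_perfect_corr": float(p_dep)}


# ---------------------------------------------------------------------------
# 6. Mediation algebra, recovery, null coverage
# ---------------------------------------------------------------------------

def mediation_recovery(seed: int, n_reps: int = 50,
                       n_subjects: int = 600, n_boot: int = 300) -> dict:
    """Planted direct 0.008 / indirect 0.004 (M per mmHg): identity error,
    fraction of replicates recovering both within 30% relative error, and
    CI coverage of zero under a null indirect path."""
    seeds = _spawn(seed, 2 * n_reps)
    ok = 0
    ident = 0.0
    for s in seeds[:n_reps]:
        d = synthetic.generate_mediation_cohort(
            n_subjects, direct=0.008, a_path=-0.02, b_path=-0.2, seed=s)
        bp_hat = pd.Series(d["bp"], index=[f"S{i}" for i in range(n_subjects)])
        r = mediation.compositional_mediation(
            bp_hat, d["compositions"], d["m_values"], n_boot=n_boot, seed=s)[0]
        ident = max(ident, abs(r.total - r.direct - r.indirect),
                    abs(r.component_indirect.sum() - r.indirect))
        ok += (abs(r.direct - d["true_direct"]) / abs(d["true_direct"]) < 0.3
               and abs(r.indirect - d["true_indirect"])
               / abs(d["true_indirect"]) < 0.3)
    cover = 0
    for s in seeds[n_reps:]:
        d = synthetic.generate_mediation_cohort(
            n_subjects, direct=0.008, a_path=-0.02, b_path=0.0, seed=s)
        bp_hat = pd.Series(d["bp"], index=[f"S{i}" for i in range(n_subjects)])
        r = mediation.ratio_mediation(
            bp_hat, d["compositions"], d["m_values"], n_boot=n_boot, seed=s)[0]
        cover += (r.ci95_indirect[0] <= 0.0 <= r.ci95_indirect[1])
    return {"recovery_rate": ok / n_reps,
            "max_identity_error": float(ident),
            "null_indirect_ci_coverage": cover / n_reps,
            "n": n_reps}


# ---------------------------------------------------------------------------
# 7. Two-stage BP recovery
# ---------------------------------------------------------------------------

def bp_two_stage_recovery(seed: int, n_subjects: int = 600) -> dict:
    """Correlation of the shrunken estimates with the latent subject
    offsets at the study noise conditions, plus the exactness of the
    noise-free balanced case."""
    records, offsets = synthetic.generate_bp_records(
        n_subjects, (5, 13), sigma_subject=6.0, sigma_resid=8.0, rho=0.5,
        seed=seed)
    records = bp_mod.add_indicators(records)
    trend = bp_mod.estimate_trend(records, "sbp")
    det = bp_mod.detrend(records, trend, "sbp")
    fit = bp_mod.fit_two_stage(det, "sbp")
    est = fit.summaries.set_index("subject_id")["bp_hat"]
    corr = float(np.corrcoef(est.loc[offsets.index], offsets)[0, 1])

    # noise-free balanced design: estimates must equal subject means exactly
    weeks = np.array([10.0, 20.0, 30.0, 40.0])
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(20):
        b = rng.normal(0, 6)
        for w in weeks:
            rows.append((f"B{i}", w, 110.0 + b))
    flat = pd.DataFrame(rows, columns=["subject_id", "week", "sbp"])
    f2 = bp_mod.fit_two_stage(flat, "sbp")
    merged = f2.summaries.set_index("subject_id")["bp_hat"]
    truth = flat.groupby("subject_id")["sbp"].mean()
    exact_err = float(np.abs(merged - truth).max())
    return {"corr_bp_hat_truth": corr, "noise_free_max_error": exact_err,
            "n": n_subjects}


# ---------------------------------------------------------------------------
# 8. Transforms
# ---------------------------------------------------------------------------

def transform_checks() -> dict:
    """Beta/M round trip and the intercept-method closed forms."""
    rng = np.random.default_rng(0)
    beta = rng.uniform(1e-5, 1 - 1e-5, 10_000)
    rt = float(np.abs(qc.m_to_beta(qc.beta_to_m(beta))
                      - np.clip(beta, 1e-6, 1 - 1e-6)).max())
    e1 = float(ewas_mod.effect_to_beta_scale(0.0, 0.1, 10.0))   # s(1)-s(0)
    e2 = float(ewas_mod.effect_to_beta_scale(2.0, 0.1, 10.0))   # s(3)-s(2)
    return {"roundtrip_max_error": rt,
            "intercept_method_alpha0_0": e1,
            "intercept_method_alpha0_2": e2}
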