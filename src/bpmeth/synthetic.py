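"""Synthetic pregnancy cohorts with known ground truth.

The real study data (repeated maternal blood-pressure readings linked to
450K-style placental methylation) are access-restricted, so this module
generates cohorts that reproduce the statistical structure the analysis
assumes, with every generative parameter recorded in a :class:`TruthLedger`:

* sparse, irregular BP visits around a smooth non-linear population trend
  (mid-pregnancy dip, rise to term) with subject random intercepts and
  continuous-time AR(1) within-subject noise;
* six placental reference cell-type methylation profiles
  (Syncytiotrophoblast, Stromal, Endothelial, Trophoblast, Hofbauer, nRBC)
  with planted discriminating probes;
* cell compositions on the 6-part simplex, logistic-normal around the
  typical term-placenta mixture (SCT ~63%), whose stromal/SCT log-ratio
  shifts linearly with the subject's latent BP (the mediated path);
* bulk beta-values as cell-type mixtures plus *direct* BP effects planted
  on contiguous probe blocks (the regions a DMR caller should recover).

Direct effects are applied on the M-value (log2-logit) scale so the planted
per-mmHg effect is exactly the coefficient a probe-wise M-value regression
estimates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .compositional import CELL_TYPES, ilr, ilr_inverse

#: Typical term-placenta composition, order as CELL_TYPES
#: (SCT, Stromal, Endothelial, Trophoblast, Hofbauer, nRBC).
DEFAULT_COMPOSITION = np.array([0.63, 0.10, 0.09, 0.10, 0.02, 0.02])

_WEEK_LO, _WEEK_HI = 8.0, 41.0


# ---------------------------------------------------------------------------
# Population BP trends
# ---------------------------------------------------------------------------

def _cubic_trend(anchor: float, scale: float) -> Callable[[np.ndarray], np.ndarray]:
    # antiderivative of (t - 22)(t + 10): decreasing before week 22, rising after
    def F(t):
        t = np.asarray(t, dtype=float)
        return t ** 3 / 3.0 - 6.0 * t ** 2 - 220.0 * t

    offset = anchor - scale * F(22.0)

    def trend(week):
        return scale * F(week) + offset

    return trend


def default_trends() -> dict[str, Callable]:
    """Smooth population trends: minimum near week 22, ~5 mmHg amplitude."""
    return {
        "sbp": _cubic_trend(anchor=112.0, scale=7e-4),
        "dbp": _cubic_trend(anchor=63.0, scale=4e-4),
    }


# ---------------------------------------------------------------------------
# Truth ledger
# ---------------------------------------------------------------------------

@dataclass
class DMRBlock:
    chrom: str
    start: int
    end: int
    probe_ids: tuple[str, ...]


@dataclass
class TruthLedger:
    """Everything the generator decided, for downstream parameter recovery."""

    subject_true_bp: pd.Series            # latent per-subject BP offset (mmHg)
    trend_fn: Mapping[str, Callable]      # population trend per raw indicator
    gamma_comp: float                     # d log(Stromal/SCT) / d mmHg
    direct_effects: dict[str, float]      # probe -> M-value effect per mmHg
    dmr_blocks: list[DMRBlock]
    isolated_probes: frozenset[str] = frozenset()
    seed: int = 0

    def validate(self, annotation: pd.DataFrame | None = None) -> None:
        block_probes: set[str] = set()
        for blk in self.dmr_blocks:
            dup = block_probes & set(blk.probe_ids)
            if dup:
                raise ValueError(f"probes in more than one dmr_block: {sorted(dup)}")
            block_probes |= set(blk.probe_ids)
        stray = set(self.direct_effects) - block_probes - set(self.isolated_probes)
        if stray:
            raise ValueError(f"direct-effect probes neither in a block nor "
                             f"flagged isolated: {sorted(stray)}")
        if annotation is not None:
            ann = annotation.set_index("probe_id")
            for blk in self.dmr_blocks:
                if len(blk.probe_ids) < 3:
                    raise ValueError("dmr_block with fewer than 3 probes")
                pos = ann.loc[list(blk.probe_ids), "pos"].to_numpy()
                if np.any(np.diff(np.sort(pos)) > 500):
                    raise ValueError("dmr_block with inter-probe gap > 500 bp")

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "gamma_comp": self.gamma_comp,
            "subject_true_bp": self.subject_true_bp.round(6).to_dict(),
            "direct_effects": self.direct_effects,
            "isolated_probes": sorted(self.isolated_probes),
            "dmr_blocks": [
                {"chrom": b.chrom, "start": b.start, "end": b.end,
                 "probe_ids": list(b.probe_ids)}
                for b in self.dmr_blocks
            ],
        }
        return json.dumps(payload, indent=1)


# ---------------------------------------------------------------------------
# Reference cell-type profiles
# ---------------------------------------------------------------------------

def generate_reference_profiles(n_probes: int, n_discriminating_per_type: int,
                                seed: int,
                                probe_ids: Sequence[str] | None = None,
                                exclude_discriminating: Iterable[str] = (),
                                ) -> pd.DataFrame:
    """Mean beta per probe for the six reference cell types (6 x n_probes).

    Each type receives ``n_discriminating_per_type`` probes at which its beta
    differs from every other type's by at least 0.4 (the margin a
    deconvolution feature selector should find); all remaining probes share a
    common baseline across types. The planted sets are stored in
    ``df.attrs["discriminating"]``.
    """
    needed = 6 * n_discriminating_per_type
    if n_probes < needed:
        raise ValueError(
            f"n_probes={n_probes} cannot host {n_discriminating_per_type} "
            f"discriminating probes for each of 6 cell types (need >= {needed})")
    rng = np.random.default_rng(seed)
    if probe_ids is None:
        probe_ids = [f"cg{i:08d}" for i in range(n_probes)]
    elif len(probe_ids) != n_probes:
        raise ValueError("probe_ids length must equal n_probes")
    probe_ids = list(probe_ids)

    # bimodal baseline typical of methylation arrays
    low = rng.uniform(0.05, 0.30, size=n_probes)
    high = rng.uniform(0.70, 0.95, size=n_probes)
    baseline = np.where(rng.random(n_probes) < 0.5, low, high)
    betas = np.tile(baseline, (6, 1))

    excl = set(exclude_discriminating)
    eligible = np.array([i for i, p in enumerate(probe_ids) if p not in excl])
    if len(eligible) < needed:
        raise ValueError("too few probes eligible for discrimination after "
                         "exclusions")
    order = rng.permutation(eligible)
    disc: dict[str, list[str]] = {}
    pos = 0
    for k, cell in enumerate(CELL_TYPES):
        picks = order[pos:pos + n_discriminating_per_type]
        pos += n_discriminating_per_type
        base = rng.uniform(0.05, 0.30, size=picks.size)
        delta = rng.uniform(0.45, 0.65, size=picks.size)
        up = rng.random(picks.size) < 0.5
        others = np.where(up, base, base + delta)
        own = np.where(up, base + delta, base)
        betas[:, picks] = others
        betas[k, picks] = own
        disc[cell] = [probe_ids[i] for i in picks]

    df = pd.DataFrame(betas, index=list(CELL_TYPES), columns=probe_ids)
    df.attrs["discriminating"] = disc
    return df


# ---------------------------------------------------------------------------
# Probe genomic annotation
# ---------------------------------------------------------------------------

def generate_probe_annotation(probe_ids: Sequence[str], seed: int,
                              chroms: Sequence[str] = ("chr1", "chr2"),
                              cluster_gap: tuple[int, int] = (30, 200),
                              between_gap: tuple[int, int] = (2_000, 50_000),
                              ) -> pd.DataFrame:
    """Assign 1-based positions mimicking array design: CpG-dense clusters
    (gaps 30-200 bp) separated by kilobase-scale deserts, split over
    ``chroms``. Returns columns probe_id, chrom, pos."""
    rng = np.random.default_rng(seed)
    n = len(probe_ids)
    per_chrom = np.array_split(np.arange(n), len(chroms))
    rows = []
    for chrom, idx in zip(chroms, per_chrom):
        pos = 10_000
        i = 0
        while i < len(idx):
            size = int(rng.integers(1, 15))  # cluster of 1..14 probes
            for _ in range(min(size, len(idx) - i)):
                rows.append((probe_ids[idx[i]], chrom, pos))
                pos += int(rng.integers(*cluster_gap))
                i += 1
            pos += int(rng.integers(*between_gap))
    return pd.DataFrame(rows, columns=["probe_id", "chrom", "pos"])


# ---------------------------------------------------------------------------
# Repeated BP measurements
# ---------------------------------------------------------------------------

def generate_bp_records(n_subjects: int,
                        visits_per_subject: tuple[int, int] = (5, 13),
                        sigma_subject: float = 6.0,
                        sigma_resid: float = 8.0,
                        rho: float = 0.5,
                        seed: int = 0,
                        trends: Mapping[str, Callable] | None = None,
                        dbp_scale: float = 0.6,
                        ) -> tuple[pd.DataFrame, pd.Series]:
    """Sparse irregular SBP/DBP readings.

    SBP_i(t) = mu_S(t) + b_i + e_i(t) with b_i ~ N(0, sigma_subject^2) and
    corr(e(t), e(t')) = rho^|t-t'| (continuous-time AR(1), per-week lag);
    DBP shares b_i and the residual scale, both multiplied by ``dbp_scale``.

    Returns the long-format records and the latent subject offsets b_i.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must be in [0, 1)")
    vmin, vmax = visits_per_subject
    if vmin < 1 or vmax < vmin:
        raise ValueError("invalid visits_per_subject range")
    trends = default_trends() if trends is None else trends
    rng = np.random.default_rng(seed)
    subjects = [f"S{i:04d}" for i in range(n_subjects)]
    b = rng.normal(0.0, sigma_subject, size=n_subjects)

    rows = []
    for i, sid in enumerate(subjects):
        n_i = int(rng.integers(vmin, vmax + 1))
        weeks = np.sort(rng.uniform(_WEEK_LO, _WEEK_HI, size=n_i))
        if sigma_resid > 0:
            corr = rho ** np.abs(weeks[:, None] - weeks[None, :])
            chol = np.linalg.cholesky(corr + 1e-10 * np.eye(n_i))
            e_s = sigma_resid * (chol @ rng.standard_normal(n_i))
            e_d = dbp_scale * sigma_resid * (chol @ rng.standard_normal(n_i))
        else:
            e_s = e_d = np.zeros(n_i)
        sbp = trends["sbp"](weeks) + b[i] + e_s
        dbp = trends["dbp"](weeks) + dbp_scale * b[i] + e_d
        for w, s_v, d_v in zip(weeks, sbp, dbp):
            rows.append((sid, float(w), float(s_v), float(d_v)))
    records = pd.DataFrame(rows, columns=["subject_id", "week", "sbp", "dbp"])
    return records, pd.Series(b, index=subjects, name="true_bp_offset")


# ---------------------------------------------------------------------------
# Truth construction
# ---------------------------------------------------------------------------

def make_truth(annotation: pd.DataFrame,
               subject_true_bp: pd.Series,
               seed: int,
               n_dmr_blocks: int = 2,
               block_size: int = 8,
               effect_m_per_mmhg: float = 0.025,
               gamma_comp: float = -0.02,
               exclude_probes: Iterable[str] = (),
               n_isolated: int = 0,
               trends: Mapping[str, Callable] | None = None,
               ) -> TruthLedger:
    """Plant direct effects on contiguous probe blocks satisfying the DMR
    caller's own criteria (>= 3 probes, consecutive gaps <= 500 bp)."""
    rng = np.random.default_rng(seed)
    exclude = set(exclude_probes)
    ann = annotation.sort_values(["chrom", "pos"], kind="mergesort")

    # candidate runs: contiguous probes with gaps <= 500 bp. Preference goes
    # to *whole* clusters of exactly block_size probes (bounded by > 500 bp
    # gaps on both sides), so a planted region's true boundaries coincide
    # with gaps the region caller itself respects.
    whole_exact, whole_larger, partial = [], [], []
    for _, sub in ann.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        pid = sub["probe_id"].to_numpy()
        excl = np.isin(pid, list(exclude)) if exclude else np.zeros(len(pid),
                                                                    bool)
        breaks = np.where(np.diff(pos) > 500)[0]
        for run in np.split(np.arange(len(pos)), breaks + 1):
            chrom = sub["chrom"].iloc[0]
            if not excl[run].any():
                if len(run) == block_size:
                    whole_exact.append((chrom, pos[run], pid[run]))
                elif len(run) > block_size:
                    whole_larger.append((chrom, pos[run], pid[run]))
                continue
            # split the run into homogeneous excluded / eligible stretches
            for piece in np.split(run, np.where(np.diff(excl[run]))[0] + 1):
                if len(piece) >= block_size and not excl[piece].any():
                    partial.append((chrom, pos[piece], pid[piece]))
    candidates, picks = [], []
    for tier in (whole_exact, whole_larger, partial):
        if tier:
            take = min(n_dmr_blocks - len(picks), len(tier))
            chosen = rng.choice(len(tier), size=take, replace=False)
            picks.extend(len(candidates) + c for c in chosen)
            candidates.extend(tier)
        if len(picks) == n_dmr_blocks:
            break
    if len(picks) < n_dmr_blocks:
        raise ValueError("annotation has too few dense probe clusters to "
                         f"plant {n_dmr_blocks} blocks of {block_size}")

    direct: dict[str, float] = {}
    blocks: list[DMRBlock] = []
    for c in picks:
        chrom, pos, ids = candidates[c]
        ids = ids[:block_size]
        pos = pos[:block_size]
        for p in ids:
            direct[p] = effect_m_per_mmhg
        blocks.append(DMRBlock(chrom, int(pos.min()), int(pos.max()),
                               tuple(ids)))

    isolated: set[str] = set()
    if n_isolated:
        used = set(direct) | exclude
        singles = [p for p in ann["probe_id"] if p not in used]
        for p in rng.choice(singles, size=n_isolated, replace=False):
            direct[str(p)] = effect_m_per_mmhg
            isolated.add(str(p))

    truth = TruthLedger(subject_true_bp=subject_true_bp,
                        trend_fn=default_trends() if trends is None else trends,
                        gamma_comp=gamma_comp, direct_effects=direct,
                        dmr_blocks=blocks,
                        isolated_probes=frozenset(isolated), seed=seed)
    truth.validate(annotation)
    return truth


# ---------------------------------------------------------------------------
# Bulk methylome
# ---------------------------------------------------------------------------

def _softmax_rows(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def generate_compositions(bp: np.ndarray, gamma_comp: float, seed: int,
                          comp_sd: float = 0.25,
                          center: np.ndarray = DEFAULT_COMPOSITION,
                          ) -> pd.DataFrame:
    """Logistic-normal compositions whose Stromal/SCT log-ratio shifts by
    ``gamma_comp`` per mmHg of latent BP (an exactly linear mediator path)."""
    rng = np.random.default_rng(seed)
    bp = np.asarray(bp, dtype=float)
    n = bp.size
    i_s = CELL_TYPES.index("Stromal")
    i_t = CELL_TYPES.index("Syncytiotrophoblast")
    z = np.log(center)[None, :] + rng.normal(0.0, comp_sd, size=(n, 6))
    z[:, i_s] += 0.5 * gamma_comp * bp
    z[:, i_t] -= 0.5 * gamma_comp * bp
    w = _softmax_rows(z)
    return pd.DataFrame(w, columns=list(CELL_TYPES))


def generate_methylome(refs: pd.DataFrame, bp_truth: TruthLedger,
                       noise_sd: float = 0.2, seed: int = 0,
                       comp_sd: float = 0.25,
                       center: np.ndarray = DEFAULT_COMPOSITION,
                       compositions: pd.DataFrame | None = None,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bulk beta matrix (probes x samples) and per-sample compositions.

    bulk_j = sum_k w_k beta_kj, then an M-scale shift of
    direct_effects[j] * BP_i plus N(0, noise_sd) M-scale noise, back to the
    beta scale, clipped to [1e-6, 1 - 1e-6].
    """
    rng = np.random.default_rng(seed)
    bp = bp_truth.subject_true_bp
    subjects = list(bp.index)
    if compositions is None:
        compositions = generate_compositions(bp.to_numpy(),
                                             bp_truth.gamma_comp,
                                             seed=rng.integers(2**31),
                                             comp_sd=comp_sd, center=center)
    compositions = compositions.copy()
    compositions.index = subjects
    w = compositions.to_numpy()
    if np.any(np.abs(w.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("composition rows do not sum to 1 within 1e-9")

    bulk = w @ refs.to_numpy()                        # n x p
    probe_ids = list(refs.columns)
    d = np.array([bp_truth.direct_effects.get(p, 0.0) for p in probe_ids])
    if noise_sd == 0.0 and not np.any(d):
        beta = bulk
    else:
        bulk = np.clip(bulk, 1e-6, 1 - 1e-6)
        m = np.log2(bulk / (1.0 - bulk))
        m = m + bp.to_numpy()[:, None] * d[None, :]
        if noise_sd > 0:
            m = m + rng.normal(0.0, noise_sd, size=m.shape)
        pw = np.exp2(m)
        beta = np.clip(pw / (1.0 + pw), 1e-6, 1 - 1e-6)
    beta_df = pd.DataFrame(beta.T, index=probe_ids, columns=subjects)
    return beta_df, compositions


# ---------------------------------------------------------------------------
# Covariate sheet
# ---------------------------------------------------------------------------

def generate_covariates(subjects: Sequence[str], seed: int) -> pd.DataFrame:
    """Plausible cohort covariates (no effect on methylation is planted)."""
    rng = np.random.default_rng(seed)
    n = len(subjects)
    return pd.DataFrame({
        "subject_id": list(subjects),
        "center": rng.choice(["Nancy", "Poitiers"], size=n, p=[0.57, 0.43]),
        "maternal_age": np.round(rng.normal(29.0, 4.5, size=n), 1),
        "child_sex": rng.choice(["F", "M"], size=n),
        "parity": rng.choice([0, 1], size=n, p=[0.45, 0.55]),
        "smoking": rng.choice(["never", "former", "current"], size=n,
                              p=[0.58, 0.10, 0.32]),
        "gestational_duration": np.round(
            np.clip(rng.normal(39.7, 1.4, size=n), 30.0, 42.0), 1),
        "preeclampsia": (rng.random(n) < 0.025).astype(int),
    })


# ---------------------------------------------------------------------------
# One-call cohort
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    bp_records: pd.DataFrame
    covariates: pd.DataFrame
    beta: pd.DataFrame            # probes x samples
    annotation: pd.DataFrame
    refs: pd.DataFrame            # 6 x probes
    compositions: pd.DataFrame    # samples x 6
    truth: TruthLedger


def generate_cohort(n_subjects: int = 300, n_probes: int = 2000,
                    n_discriminating_per_type: int = 50,
                    n_dmr_blocks: int = 2, block_size: int = 8,
                    effect_m_per_mmhg: float = 0.025,
                    gamma_comp: float = -0.02,
                    sigma_subject: float = 6.0, sigma_resid: float = 8.0,
                    rho: float = 0.5, noise_sd: float = 0.2,
                    comp_sd: float = 0.25, seed: int = 0) -> Cohort:
    """Generate a full synthetic cohort under the study's default conditions."""
    rng = np.random.default_rng(seed)
    s = [int(x) for x in rng.integers(0, 2**31, size=6)]
    probe_ids = [f"cg{i:08d}" for i in range(n_probes)]
    annotation = generate_probe_annotation(probe_ids, s[1])
    records, offsets = generate_bp_records(
        n_subjects, (5, 13), sigma_subject, sigma_resid, rho, s[2])
    truth = make_truth(annotation, offsets, s[3], n_dmr_blocks=n_dmr_blocks,
                       block_size=block_size,
                       effect_m_per_mmhg=effect_m_per_mmhg,
                       gamma_comp=gamma_comp)
    # deconvolution marker probes stay clear of the planted effect regions
    refs = generate_reference_profiles(
        n_probes, n_discriminating_per_type, s[0], probe_ids=probe_ids,
        exclude_discriminating=set(truth.direct_effects))
    beta, comp = generate_methylome(refs, truth, noise_sd=noise_sd, seed=s[4],
                                    comp_sd=comp_sd)
    covariates = generate_covariates(list(offsets.index), s[5])
    return Cohort(records, covariates, beta, annotation, refs, comp, truth)


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write the cohort as plain TSV/JSON files and return the paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "bp_records": out / "bp_records.tsv",
        "covariates": out / "covariates.tsv",
        "beta": out / "beta_matrix.tsv",
        "annotation": out / "probe_annotation.tsv",
        "refs": out / "reference_profiles.tsv",
        "compositions": out / "true_compositions.tsv",
        "truth": out / "truth.json",
    }
    cohort.bp_records.to_csv(paths["bp_records"], sep="\t", index=False)
    cohort.covariates.to_csv(paths["covariates"], sep="\t", index=False)
    cohort.beta.to_csv(paths["beta"], sep="\t", index_label="probe_id")
    cohort.annotation.to_csv(paths["annotation"], sep="\t", index=False)
    cohort.refs.to_csv(paths["refs"], sep="\t", index_label="cell_type")
    cohort.compositions.to_csv(paths["compositions"], sep="\t",
                               index_label="subject_id")
    paths["truth"].write_text(cohort.truth.to_json())
    return paths


# ---------------------------------------------------------------------------
# Mediation fixture with closed-form truth
# ---------------------------------------------------------------------------

def generate_mediation_cohort(n_subjects: int, direct: float, a_path: float,
                              b_path: float, seed: int,
                              bp_sd: float = 6.0, mediator_sd: float = 0.25,
                              noise_m: float = 0.2, alpha0: float = 0.0,
                              ) -> dict:
    """Single-probe cohort where the mediation decomposition is known exactly.

    Only the first ilr coordinate (the Stromal/SCT contrast) responds to BP:
    coord1 = a_path * BP + noise, and the M-value outcome is
    M = alpha0 + direct * BP + b_path * coord1 + noise. The true indirect
    effect is therefore a_path * b_path, on the M scale per mmHg.
    """
    rng = np.random.default_rng(seed)
    bp = rng.normal(0.0, bp_sd, size=n_subjects)
    base = ilr(DEFAULT_COMPOSITION[None, :])[0]
    coords = base[None, :] + rng.normal(0.0, mediator_sd, size=(n_subjects, 5))
    coords[:, 0] += a_path * bp
    comp = ilr_inverse(coords)
    m = alpha0 + direct * bp + b_path * coords[:, 0] \
        + rng.normal(0.0, noise_m, size=n_subjects)
    return {
        "bp": bp,
        "compositions": pd.DataFrame(comp, columns=list(CELL_TYPES)),
        "ilr_coords": coords,
        "m_values": m,
        "true_direct": direct,
        "true_indirect": a_path * b_path,
    }
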