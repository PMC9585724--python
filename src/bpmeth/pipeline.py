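"""End-to-end orchestration: config, stage ordering, logging, file glue.

Stages run in a fixed order (bp -> qc -> deconvolve -> ewas -> dmr ->
mediation), each writing a plain TSV into the run directory; a summary
JSON records probe/sample counts surviving every filter plus a hash of the
configuration, and seeded stages are bit-reproducible for a given config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import bp as bp_mod
from . import celltypes, dmr as dmr_mod, ewas as ewas_mod, mediation, qc, synthetic
from .compositional import ilr, zero_replace

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    indicator: str = "map"                 # sbp | dbp | map | pp
    window: str = "whole"                  # early | late | whole
    covariates: list[str] = field(default_factory=lambda: [
        "center", "maternal_age", "child_sex", "parity", "smoking"])
    exclude_pe: bool = False
    adjust_gestational_age: bool = False
    adjust_celltypes: bool = False
    mask_outliers: bool = True
    drop_sex_chroms: bool = True
    blocklists: list[str] = field(default_factory=list)
    dmr_seed_p: float = 1e-3
    dmr_max_gap: int = 500
    dmr_min_probes: int = 3
    dmr_max_lag_bp: int = 1000
    dmr_smooth_window_bp: int = 300
    dmr_extend_p: float = 0.05
    dmr_significance: str = "fdr"
    mediator: str = "stromal-sct-ratio"    # composition | stromal-sct-ratio
    n_boot: int = 1000
    n_deconv_probes_per_type: int = 50
    seed: int = 0
    # synthetic-cohort knobs (used by `simulate` / self-contained runs)
    n_subjects: int = 300
    n_probes: int = 5000

    def validate(self) -> None:
        if self.indicator not in bp_mod.INDICATORS:
            raise ValueError(f"unknown indicator {self.indicator!r}")
        if self.window not in ("early", "late", "whole"):
            raise ValueError(f"unknown window {self.window!r}")
        if self.mediator not in ("composition", "stromal-sct-ratio"):
            raise ValueError(f"unknown mediator {self.mediator!r}")
        if self.adjust_celltypes and self.mediator == "composition":
            raise ValueError(
                "adjust_celltypes cannot be combined with mediation on the "
                "full composition: the mediator cannot also be a covariate")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _covariate_frame(cfg: PipelineConfig, covariates: pd.DataFrame
                     ) -> pd.DataFrame | None:
    cols = list(cfg.covariates)
    if cfg.adjust_gestational_age and "gestational_duration" not in cols:
        cols.append("gestational_duration")
    cols = [c for c in cols if c in covariates.columns]
    return covariates[cols] if cols else None


def run_all(config: PipelineConfig, outdir: str | Path,
            cohort: synthetic.Cohort | None = None) -> dict:
    """Run every stage on a cohort (simulated under ``config.seed`` when not
    supplied). Returns the summary dict, also written to summary.json."""
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_hash": config.hash(), "config": asdict(config),
                     "stages": {}}

    if cohort is None:
        cohort = synthetic.generate_cohort(
            n_subjects=config.n_subjects, n_probes=config.n_probes,
            seed=config.seed)
        synthetic.write_cohort(cohort, out / "inputs")

    try:
        # --- stage 1: blood pressure ---------------------------------------
        summaries = bp_mod.summarize_bp(cohort.bp_records, config.indicator,
                                        config.window)
        bp_hat = summaries.set_index("subject_id")["bp_hat"]
        summaries.to_csv(out / "bp_summaries.tsv", sep="\t", index=False)
        summary["stages"]["bp"] = {"n_subjects": int(len(bp_hat))}

        # --- stage 2: methylation QC ---------------------------------------
        beta = cohort.beta
        n0 = len(beta)
        frac_masked = 0.0
        if config.mask_outliers:
            beta, frac_masked = qc.mask_outliers(beta)
        blocklists = [qc.read_blocklist(p) for p in config.blocklists]
        beta, n_kept = qc.filter_probes(beta, cohort.annotation, blocklists,
                                        drop_sex_chroms=config.drop_sex_chroms)
        summary["stages"]["qc"] = {
            "probes_in": n0, "probes_retained": n_kept,
            "fraction_outliers_masked": round(frac_masked, 6)}

        # --- stage 3: deconvolution ----------------------------------------
        probe_set = celltypes.select_discriminating_probes(
            cohort.refs, config.n_deconv_probes_per_type)
        comps = celltypes.deconvolve(cohort.beta, cohort.refs, probe_set)
        comps.to_csv(out / "cell_compositions.tsv", sep="\t",
                     index_label="sample_id")
        summary["stages"]["deconvolution"] = {
            "n_probes_used": len(probe_set), "n_samples": len(comps)}

        # --- stage 4: EWAS --------------------------------------------------
        covs = cohort.covariates.set_index("subject_id")
        samples = [s for s in beta.columns if s in bp_hat.index]
        if config.exclude_pe and "preeclampsia" in covs.columns:
            pe = set(covs.index[covs["preeclampsia"] == 1])
            samples = [s for s in samples if s not in pe]
        Z = _covariate_frame(config, covs)
        if config.adjust_celltypes:
            coords = pd.DataFrame(
                ilr(zero_replace(comps.to_numpy())), index=comps.index,
                columns=[f"ilr{i+1}" for i in range(5)])
            Z = coords if Z is None else pd.concat([Z, coords], axis=1)
        ew = ewas_mod.run_ewas(beta[samples], bp_hat.loc[samples],
                               None if Z is None else Z.loc[samples])
        ew.to_csv(out / "ewas_results.tsv", sep="\t", index=False)
        infl = ewas_mod.estimate_inflation(
            p_values=ew["p"].dropna().to_numpy(),
            effects=ew.loc[ew["p"].notna(), "effect_m"].to_numpy()) \
            if ew["p"].notna().sum() >= 500 else None
        summary["stages"]["ewas"] = {
            "n_probes_tested": int(ew["p"].notna().sum()),
            "n_samples": len(samples),
            "n_fdr_significant": int((ew["fdr"] < 0.05).sum()),
            "inflation_bif": None if infl is None else round(infl.bif, 4),
            "inflation_bias": None if infl is None else round(infl.bias, 4)}

        # --- stage 5: DMR ----------------------------------------------------
        regions = dmr_mod.call_regions(
            ew, cohort.annotation, seed_p=config.dmr_seed_p,
            max_gap=config.dmr_max_gap, min_probes=config.dmr_min_probes,
            max_lag_bp=config.dmr_max_lag_bp,
            smooth_window_bp=config.dmr_smooth_window_bp,
            extend_p=config.dmr_extend_p,
            significance=config.dmr_significance)
        regions.to_csv(out / "dmrs.tsv", sep="\t", index=False)
        dmr_mod.to_bed(regions).to_csv(out / "dmrs.bed", sep="\t",
                                       index=False, header=False)
        summary["stages"]["dmr"] = {"n_regions": int(len(regions))}

        # --- stage 6: mediation ----------------------------------------------
        med_summary = {"n_dmrs": int(len(regions))}
        if len(regions):
            probes = sorted({p for ids in regions["probe_ids"]
                             for p in ids.split(",")})
            M = qc.beta_to_m(cohort.beta.loc[probes, samples].to_numpy()).T
            kwargs = dict(covariates=None if Z is None else Z.loc[samples],
                          n_boot=config.n_boot, seed=config.seed,
                          probe_ids=probes)
            if config.mediator == "composition":
                res = mediation.compositional_mediation(
                    bp_hat.loc[samples], comps.loc[samples], M, **kwargs)
            else:
                res = mediation.ratio_mediation(
                    bp_hat.loc[samples], comps.loc[samples], M, **kwargs)
            med_df = mediation.results_table(res)
            med_df.to_csv(out / "mediation.tsv", sep="\t", index=False)
            membership = {f"dmr_{i}": row["probe_ids"].split(",")
                          for i, row in regions.iterrows()}
            classes = mediation.aggregate_dmr(med_df, membership)
            classes.to_csv(out / "dmr_mediation_classes.tsv", sep="\t",
                           index=False)
            med_summary["classes"] = classes["indirect_class"].value_counts() \
                                            .to_dict()
        summary["stages"]["mediation"] = med_summary
    except Exception as exc:
        summary["failed_stage"] = _current_stage(summary)
        summary["error"] = str(exc)
        (out / "summary.json").write_text(json.dumps(summary, indent=1))
        raise RuntimeError(
            f"pipeline failed at stage {summary['failed_stage']!r}: {exc}"
        ) from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary


def _current_stage(summary: dict) -> str:
    order = ["bp", "qc", "deconvolution", "ewas", "dmr", "mediation"]
    done = set(summary["stages"])
    for s in order:
        if s not in done:
            return s
    return "finalize"
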