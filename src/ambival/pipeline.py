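"""Reproducible simulate -> fit -> GLM -> group pipeline with manifest and report.

All randomness flows from one root seed, split per stage and per subject; a
run's configuration is copied beside its outputs and every written file is
checksummed into the manifest, so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import choice, cohort, design, evaluation, glm, group

log = logging.getLogger("ambival.pipeline")

_MOD_COLS = evaluation._MOD_COLS


@dataclass
class PipelineConfig:
    """Fully serialisable configuration of one pipeline run."""

    seed: int = 0
    n_subjects: int = 12
    out_dir: str = "ambival_run"
    cohort: cohort.CohortConfig = field(default_factory=cohort.CohortConfig)
    n_starts: int = 10
    glm_variants: tuple = ("glm1", "glm2", "glm3", "glm4", "glm5")
    excluded_runs: dict = field(default_factory=dict)  # subject_id -> [run indices]
    write_events: bool = True

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["glm_variants"] = list(d["glm_variants"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["cohort"] = cohort.CohortConfig(**d.get("cohort", {}))
        d["glm_variants"] = tuple(d.get("glm_variants", cls.glm_variants))
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest = {"stages": [], "warnings": [], "completed": False}
    t_start = time.time()

    def finish_stage(name: str, outputs: list[Path]):
        manifest["stages"].append(
            {
                "stage": name,
                "outputs": {str(p.relative_to(out)): _checksum(p) for p in outputs},
                "elapsed_s": round(time.time() - t_start, 2),
            }
        )
        log.info("stage %s done (%d outputs)", name, len(outputs))

    try:
        # ---- design ------------------------------------------------------
        d = design.generate_design()
        schedules = {}
        subjects = cohort.sample_population(config.n_subjects, config.cohort,
                                            seed=config.seed)
        outputs = []
        for i, sub in enumerate(subjects):
            order = 1 if i % 2 == 0 else 2
            schedules[sub.subject_id] = design.schedule_blocks(
                d, order=order, rng_seed=config.seed + 17 * (i + 1)
            )
            if config.write_events:
                subj_dir = out / sub.subject_id
                outputs += [Path(p) for p in design.write_events(
                    schedules[sub.subject_id], subj_dir)]
        finish_stage("design", outputs)

        # ---- cohort ------------------------------------------------------
        clin_path = out / "clinical.csv"
        cohort.write_clinical(subjects, clin_path)
        truth_path = out / "ground_truth.json"
        cohort.write_ground_truth(subjects, truth_path)
        choice_tables = {}
        outputs = [clin_path, truth_path]
        for i, sub in enumerate(subjects):
            ch = cohort.simulate_choices(
                sub, schedules[sub.subject_id], seed=config.seed + 1000 + i,
                lapse_rate=config.cohort.lapse_rate,
                rt_logmean=config.cohort.rt_logmean, rt_logsd=config.cohort.rt_logsd,
            )
            choice_tables[sub.subject_id] = ch
            p = out / sub.subject_id / "choices.tsv"
            p.parent.mkdir(exist_ok=True)
            cohort.write_choices(ch, p)
            outputs.append(p)
        finish_stage("cohort", outputs)

        # ---- fit ---------------------------------------------------------
        fit_config = choice.FitConfig(n_starts=config.n_starts, seed=config.seed)
        catch_ids = set(design.identify_catch_trials(d)["trial_id"])
        param_rows, attitude_rows = [], []
        per_day_svs = {}
        for sub in subjects:
            ch = choice_tables[sub.subject_id]
            merged = ch.merge(d, on="trial_id")
            qc = choice.catch_trial_quality(merged, catch_ids)
            fits = {}
            for dom in ("gain", "loss"):
                res = evaluation._fit_domain(merged, dom, fit_config)
                fits[dom] = res
                row = {"subject": sub.subject_id, **res.params.as_dict(),
                       "qc_pass": qc.passed}
                param_rows.append(row)
            att = choice.transform_attitudes(fits["gain"].params, fits["loss"].params)
            attitude_rows.append(
                {"subject": sub.subject_id, "qc_pass": qc.passed, **att.as_dict()}
            )
            per_day_svs[sub.subject_id] = evaluation._per_day_svs(
                merged, schedules[sub.subject_id], fit_config
            )
        params_path = out / "params.csv"
        choice.write_params_csv(param_rows, params_path)
        att_path = out / "attitudes.csv"
        pd.DataFrame(attitude_rows).to_csv(att_path, index=False)
        finish_stage("fit", [params_path, att_path])

        # ---- glm ---------------------------------------------------------
        beta_rows = []
        for i, sub in enumerate(subjects):
            sch = schedules[sub.subject_id]
            svs_true = cohort.true_subjective_values(sub, d)
            rts = choice_tables[sub.subject_id].set_index("trial_id")["response_time"]
            series = cohort.simulate_roi_timeseries(
                sub, sch, svs_true, seed=config.seed + 5000 + i, response_times=rts
            )
            excluded = set(config.excluded_runs.get(sub.subject_id, []))
            if excluded:
                manifest["warnings"].append(
                    f"{sub.subject_id}: runs {sorted(excluded)} excluded by config"
                )
            svs_fit = per_day_svs[sub.subject_id]
            merged = choice_tables[sub.subject_id].merge(d, on="trial_id")
            bins = None
            for variant in config.glm_variants:
                if variant == "glm5":
                    trials = merged[["trial_id", "domain", "uncertainty"]].copy()
                    sv_arr = svs_fit.reindex(trials["trial_id"]).to_numpy()
                    z = glm.z_normalize_per_block(sv_arr, np.zeros(len(sv_arr)))
                    bins_ser = glm.assign_sv_bins(trials, z)
                    bins = pd.Series(bins_ser.to_numpy(),
                                     index=trials["trial_id"].to_numpy())
                run_ids, Xs = glm.subject_designs(
                    sch, glm.GlmSpec(variant), svs_per_trial=svs_fit, bins=bins,
                    response_times=rts, exclude_runs=excluded,
                )
                kept = [s for s in series if s.run_id in run_ids]
                res = glm.fit_glm(kept, Xs)
                for w in res.dropped_columns:
                    if not w.startswith(("motion", "intercept")):
                        manifest["warnings"].append(
                            f"{sub.subject_id}/{variant}: dropped all-zero column {w}"
                        )
                beta_rows.append(res.beta_table(sub.subject_id, variant))
        beta_path = out / "betas.csv"
        pd.concat(beta_rows, ignore_index=True).to_csv(beta_path, index=False)
        finish_stage("glm", [beta_path])

        # ---- group -------------------------------------------------------
        outputs = _group_stage(out, config, manifest["warnings"])
        finish_stage("group", outputs)
        manifest["completed"] = True
    except Exception as exc:  # noqa: BLE001 - manifest records partial completion
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        log.exception("pipeline halted")
        _write_manifest(out, manifest)
        raise
    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def _group_stage(out: Path, config: PipelineConfig, warnings_list: list) -> list[Path]:
    clin = pd.read_csv(out / "clinical.csv")
    att = pd.read_csv(out / "attitudes.csv")
    betas = pd.read_csv(out / "betas.csv")
    params = pd.read_csv(out / "params.csv")
    data = att.merge(clin, on="subject")
    data = data[data["qc_pass"]]
    results = []
    for attitude in ("risk_gain", "risk_loss", "amb_gain", "amb_loss"):
        results.append(
            group.correlate_with_symptoms(
                data[attitude], data["caps_total"], "caps",
                analysis=f"{attitude}~caps_total",
            )
        )
        results.append(
            group.correlate_with_symptoms(
                data[attitude], data["pcl5"], "pcl5", analysis=f"{attitude}~pcl5"
            )
        )
    # covariate-adjusted symptom effects on attitudes
    bic = (params.groupby("subject")["bic"].mean().rename("bic").reset_index())
    adj = data.merge(bic, on="subject")
    for attitude in ("risk_gain", "amb_loss"):
        try:
            results.append(
                group.covariate_adjusted_effect(
                    adj, attitude, analysis=f"{attitude}~caps_total|covariates"
                )
            )
        except ValueError as exc:
            warnings_list.append(f"covariate model for {attitude} skipped: {exc}")
    # value/saliency group tests from GLM 3/4 modulator betas
    if {"glm3", "glm4"}.issubset(set(config.glm_variants)):
        vs = _value_saliency_frame(betas).merge(clin[["subject", "group"]], on="subject")
        try:
            results += group.value_saliency_group_tests(
                vs["value"], vs["saliency"], vs["group"]
            )
        except ValueError as exc:
            warnings_list.append(f"value/saliency group tests skipped: {exc}")
    res_path = out / "group_results.csv"
    group.results_frame(results).to_csv(res_path, index=False)
    outputs = [res_path]
    # clinical PCA
    measures = clin[["caps_total", "bdi", "stai_trait", "des", "ces", "ctq"]]
    if len(measures.dropna()) >= measures.shape[1]:
        pca = group.pca_clinical(measures)
        pca_path = out / "pca_loadings.csv"
        pca.loadings.assign(variance_explained_pc=np.nan).to_csv(pca_path)
        pd.DataFrame({"component": pca.loadings.columns,
                      "variance_explained": pca.variance_explained}).to_csv(
            out / "pca_variance.csv", index=False)
        outputs += [pca_path, out / "pca_variance.csv"]
    return outputs


def _value_saliency_frame(betas: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for subject, g in betas.groupby("subject"):
        row = {"subject": subject}
        for variant, key in (("glm3", "value"), ("glm4", "saliency")):
            sel = g[(g["glm"] == variant) & g["predictor"].isin(_MOD_COLS[variant])]
            if len(sel):
                row[key] = sel["beta"].mean()
        rows.append(row)
    return pd.DataFrame(rows)


def make_report(run_dir) -> dict:
    """Summary tables and figures from a completed run directory.

    Writes a symptom-vs-attitude scatter, grouped value/saliency bar plot,
    and the 6-bin mean-activity profile (monotonic under value coding,
    U-shaped under saliency coding); numeric panel data are also written as
    CSV.  Incomplete runs yield a partial report with warnings.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run = Path(run_dir)
    manifest_path = run / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {run}: not a pipeline run directory")
    manifest = json.loads(manifest_path.read_text())
    report: dict = {"warnings": []}
    if not manifest.get("completed"):
        report["warnings"].append("run incomplete; report covers available outputs only")

    fig_dir = run / "report"
    fig_dir.mkdir(exist_ok=True)

    clin = pd.read_csv(run / "clinical.csv") if (run / "clinical.csv").exists() else None
    att_path = run / "attitudes.csv"
    if clin is not None and att_path.exists():
        att = pd.read_csv(att_path).merge(clin, on="subject")
        fig, axes = plt.subplots(1, 4, figsize=(14, 3.2), sharey=True)
        for ax, a in zip(axes, ("risk_gain", "amb_gain", "risk_loss", "amb_loss")):
            ax.scatter(att["caps_total"], att[a], s=14)
            ax.set_xlabel("CAPS total")
            ax.set_title(a)
        axes[0].set_ylabel("attitude (neg = averse)")
        fig.tight_layout()
        fig.savefig(fig_dir / "attitudes_vs_caps.png", dpi=110)
        plt.close(fig)
    else:
        report["warnings"].append("attitudes or clinical table missing")

    beta_path = run / "betas.csv"
    if beta_path.exists() and clin is not None:
        betas = pd.read_csv(beta_path)
        vs = _value_saliency_frame(betas).merge(clin[["subject", "group"]], on="subject")
        if {"value", "saliency"}.issubset(vs.columns):
            summary = vs.groupby("group")[["value", "saliency"]].agg(["mean", "sem"])
            summary.to_csv(fig_dir / "value_saliency_by_group.csv")
            report["value_saliency"] = summary
            fig, ax = plt.subplots(figsize=(5, 3.5))
            m = summary.xs("mean", axis=1, level=1)
            e = summary.xs("sem", axis=1, level=1)
            m.plot.bar(yerr=e, ax=ax, rot=0)
            ax.set_ylabel("beta (PSC / z-SV)")
            fig.tight_layout()
            fig.savefig(fig_dir / "value_saliency_by_group.png", dpi=110)
            plt.close(fig)
        profile = bin_profile(betas, clin)
        if profile is not None:
            profile.to_csv(fig_dir / "bin_profile.csv", index=False)
            report["bin_profile"] = profile
            fig, ax = plt.subplots(figsize=(5, 3.5))
            for grp, g in profile.groupby("group"):
                ax.errorbar(g["bin"], g["mean"], yerr=g["sem"], marker="o", label=grp)
            ax.set_xlabel("subjective-value bin (1 = worst loss, 6 = best gain)")
            ax.set_ylabel("mean bin beta")
            ax.legend()
            fig.tight_layout()
            fig.savefig(fig_dir / "bin_profile.png", dpi=110)
            plt.close(fig)
    else:
        report["warnings"].append("beta table missing; neural panels skipped")
    return report


def bin_profile(betas: pd.DataFrame, clin: pd.DataFrame) -> pd.DataFrame | None:
    """Mean GLM-5 ambiguous-trial bin beta per group (bins 1-6 ascending SV)."""
    g5 = betas[betas["glm"] == "glm5"]
    if len(g5) == 0:
        return None
    g5 = g5[g5["predictor"].str.startswith("bin_ambiguous_")].copy()
    g5["bin"] = g5["predictor"].str.rsplit("_", n=1).str[-1].astype(int)
    g5 = g5.merge(clin[["subject", "group"]], on="subject")
    out = (
        g5.groupby(["group", "bin"])["beta"]
        .agg(["mean", "sem", "count"])
        .reset_index()
    )
    return out
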