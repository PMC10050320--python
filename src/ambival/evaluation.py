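"""End-to-end evaluation studies on synthetic cohorts with known ground truth.

Each function here runs one self-contained study — design bookkeeping,
parameter recovery, closed-loop GLM recovery, the value/saliency encoding
dissociation, best-subset selection, and statistical calibration — and
returns plain dictionaries of summary numbers.  They are used both by the
test suite and by the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import choice, cohort, design, glm, group

_MOD_COLS = {
    "glm3": ["ambiguous_xsv", "risky_xsv"],
    "glm4": ["ambiguous_xsaliency", "risky_xsaliency"],
}


def design_counts() -> dict:
    """Exact bookkeeping of the trial factorial and GLM-5 predictor set."""
    d = design.generate_design()
    return {
        "n_trials": int(len(d)),
        "n_gain_trials": int((d["domain"] == "gain").sum()),
        "n_loss_trials": int((d["domain"] == "loss").sum()),
        "n_catch_trials": int(len(design.identify_catch_trials(d))),
        "n_glm5_bin_predictors": len(glm._condition_names("glm5")),
    }


def _fit_domain(merged: pd.DataFrame, domain: str, fit_config: choice.FitConfig):
    sel = merged[(merged["domain"] == domain) & merged["chose_lottery"].notna()]
    sel = sel.astype({"chose_lottery": bool})
    return choice.RiskAmbiguityChoiceModel(sel).fit(fit_config)


def parameter_recovery_study(
    n_subjects: int = 50,
    seed: int = 0,
    n_starts: int = 20,
    config: cohort.CohortConfig | None = None,
) -> dict:
    """Simulate choices on the 120-trial per-domain design and refit.

    Reports rank correlations between true and recovered alpha and beta
    (pooled over gain and loss fits) and the median recovered/true gamma
    ratio.
    """
    d = design.generate_design()
    sch = design.schedule_blocks(d, order=1, rng_seed=seed)
    subjects = cohort.sample_population(n_subjects, config, seed=seed)
    fit_config = choice.FitConfig(n_starts=n_starts, seed=seed)
    true_a, fit_a, true_b, fit_b, ratio_g = [], [], [], [], []
    for i, sub in enumerate(subjects):
        choices = cohort.simulate_choices(sub, sch, seed=seed + 1000 + i)
        merged = choices.merge(d, on="trial_id")
        for dom in ("gain", "loss"):
            res = _fit_domain(merged, dom, fit_config)
            tp = sub.params[dom]
            true_a.append(tp.alpha)
            fit_a.append(res.alpha)
            true_b.append(tp.beta)
            fit_b.append(res.beta)
            ratio_g.append(res.gamma / tp.gamma)
    return {
        "alpha_spearman": float(spearmanr(true_a, fit_a).statistic),
        "beta_spearman": float(spearmanr(true_b, fit_b).statistic),
        "gamma_median_ratio": float(np.median(ratio_g)),
        "n_fits": len(true_a),
    }


def closed_loop_glm_study(seed: int = 0, amplitude: float = 0.37) -> dict:
    """Noiseless forward-then-inverse ROI test of value vs. saliency coding.

    Simulates a pure value-mode and a pure saliency-mode ROI with zero noise
    and fits both GLM 3 (signed SV) and GLM 4 (|SV|).  Reports the relative
    error of the on-mode modulator beta against the generative amplitude and
    the off-mode/on-mode beta ratio.
    """
    d = design.generate_design()
    sch = design.schedule_blocks(d, order=1, rng_seed=seed)
    sub = cohort.sample_population(2, seed=seed)[0]
    svs = cohort.true_subjective_values(sub, d)
    out = {}
    for mode, on_variant, off_variant in (
        ("value", "glm3", "glm4"),
        ("saliency", "glm4", "glm3"),
    ):
        enc = cohort.EncodingSpec(mode=mode, amplitude=amplitude, noise_sd=0.0,
                                  drift=0.0, motion_coupling=0.0,
                                  normalization="per_block")
        series = cohort.simulate_roi_timeseries(sub, sch, svs, encoding=enc, seed=seed)
        betas = {}
        for variant in (on_variant, off_variant):
            _, Xs = glm.subject_designs(sch, glm.GlmSpec(variant), svs_per_trial=svs)
            res = glm.fit_glm(series, Xs)
            betas[variant] = float(np.mean([res.params[c] for c in _MOD_COLS[variant]]))
        out[f"{mode}_mode_rel_error"] = abs(betas[on_variant] - amplitude) / amplitude
        out[f"{mode}_mode_off_on_ratio"] = abs(betas[off_variant]) / abs(betas[on_variant])
    return out


def _per_day_svs(merged: pd.DataFrame, sch: design.BlockSchedule,
                 fit_config: choice.FitConfig) -> pd.Series:
    """Trial-wise SVs from per-day, per-domain refits (the GLM convention)."""
    all_trials = sch.all_trials()
    svs = {}
    for session in (1, 2):
        day_ids = set(all_trials.loc[all_trials["session"] == session, "trial_id"])
        day = merged[merged["trial_id"].isin(day_ids)]
        for dom in ("gain", "loss"):
            sel = day[day["domain"] == dom]
            if sel["chose_lottery"].notna().sum() == 0:
                continue
            res = _fit_domain(day, dom, fit_config)
            dd = sel.set_index("trial_id")
            svs.update(
                dict(zip(dd.index, res.subjective_values(dd.reset_index())))
            )
    return pd.Series(svs)


def subject_encoding_betas(
    sub: cohort.SyntheticSubject,
    sch: design.BlockSchedule,
    d: pd.DataFrame,
    seed: int,
    fit_config: choice.FitConfig,
    lapse_rate: float = 0.02,
) -> dict:
    """One subject through the full chain: choices -> per-day fits -> GLM 3/4.

    The ROI forward model uses the subject's *generative* SVs; the estimating
    GLMs use SVs from the refitted behavioural model, as in a real analysis.
    Returns the mean modulator beta per variant.
    """
    choices = cohort.simulate_choices(sub, sch, seed=seed, lapse_rate=lapse_rate)
    merged = choices.merge(d, on="trial_id")
    svs_true = cohort.true_subjective_values(sub, d)
    rts = choices.set_index("trial_id")["response_time"]
    series = cohort.simulate_roi_timeseries(sub, sch, svs_true, seed=seed + 1,
                                            response_times=rts)
    svs_fit = _per_day_svs(merged, sch, fit_config)
    betas = {}
    for variant in ("glm3", "glm4"):
        _, Xs = glm.subject_designs(sch, glm.GlmSpec(variant), svs_per_trial=svs_fit,
                                    response_times=rts)
        res = glm.fit_glm(series, Xs)
        betas[variant] = float(np.mean([res.params[c] for c in _MOD_COLS[variant]]))
    return betas


def encoding_dissociation_study(
    n_replicates: int = 20,
    n_subjects: int = 48,
    n_ptsd: int = 19,
    seed: int = 0,
    n_starts: int = 8,
    q: float = 0.05,
) -> dict:
    """Replicate the group-level value/saliency dissociation on seeded cohorts.

    Each replicate simulates a cohort with value-coding controls and
    saliency-coding ptsd subjects, runs the full per-subject chain, then the
    four one-sample group tests with BH-FDR.  A replicate succeeds when the
    control value beta and the ptsd saliency beta are both significantly
    positive after FDR.
    """
    d = design.generate_design()
    cfg = cohort.CohortConfig(n_ptsd=n_ptsd)
    fit_config = choice.FitConfig(n_starts=n_starts, seed=seed)
    successes = 0
    for rep in range(n_replicates):
        rep_seed = seed + 10_000 * (rep + 1)
        subjects = cohort.sample_population(n_subjects, cfg, seed=rep_seed)
        rows = []
        for i, sub in enumerate(subjects):
            order = 1 if i % 2 == 0 else 2
            sch = design.schedule_blocks(d, order=order, rng_seed=rep_seed + i)
            betas = subject_encoding_betas(sub, sch, d, seed=rep_seed + 100 * i,
                                           fit_config=fit_config)
            rows.append({"group": sub.profile.group, "value": betas["glm3"],
                         "saliency": betas["glm4"]})
        df = pd.DataFrame(rows)
        results = group.value_saliency_group_tests(
            df["value"], df["saliency"], df["group"], q=q
        )
        by_name = {r.analysis: r for r in results}
        ok = (
            by_name["value_control_vs_0"].statistic > 0
            and by_name["value_control_vs_0"].p_fdr < q
            and by_name["saliency_ptsd_vs_0"].statistic > 0
            and by_name["saliency_ptsd_vs_0"].p_fdr < q
        )
        successes += ok
    return {
        "replicate_success_rate": successes / n_replicates,
        "n_replicates": n_replicates,
        "n_subjects": n_subjects,
    }


def subset_selection_study(
    n_replicates: int = 100,
    n_subjects: int = 200,
    seed: int = 0,
    noise_sd: float = 0.25,
) -> dict:
    """Recover the driving symptom factor by exhaustive best-subset regression.

    Synthetic ROI activity is a linear function of the emotional-numbing
    factor alone (standardised, plus Gaussian noise); the 7 candidates are
    the five CAPS symptom factors, age, and intelligence — a deliberately
    collinear set, since all symptom factors share a latent severity.
    Reports how often the single-predictor numbing model attains the lowest
    BIC.

    The default cohort size (200) sits where BIC subset selection is
    consistent: the probability that some spurious candidate explains more
    than ~ln(n)/n of residual variance — the point at which BIC admits it —
    is about ``6 * P(chi2_1 > ln n)``, i.e. ~27% at n = 48 but <15% by
    n = 200, independent of the noise scale.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for rep in range(n_replicates):
        subjects = cohort.sample_population(n_subjects, seed=seed + 500 + rep)
        clin = cohort.clinical_frame(subjects)
        X = pd.DataFrame(
            {
                "re_experiencing": clin["caps_re_experiencing"],
                "avoidance": clin["caps_avoidance"],
                "emotional_numbing": clin["caps_emotional_numbing"],
                "dysphoric_arousal": clin["caps_dysphoric_arousal"],
                "anxious_arousal": clin["caps_anxious_arousal"],
                "age": clin["age"],
                "kbit": clin["kbit"],
            }
        )
        numb = X["emotional_numbing"]
        y = -(numb - numb.mean()) / numb.std(ddof=1) + rng.normal(0, noise_sd, len(numb))
        sel = group.exhaustive_subset_selection(y.to_numpy(), X)
        hits += sel.best_set == ("emotional_numbing",)
    return {
        "numbing_selection_rate": hits / n_replicates,
        "n_replicates": n_replicates,
    }


def type_one_error_study(
    n_replicates: int = 1000,
    n_control: int = 29,
    n_ptsd: int = 19,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Monte-Carlo calibration of the group tests under the null.

    Betas for both groups are mean-zero Gaussian; reports the raw per-test
    rejection rate of the four one-sample t tests (nominal 0.05).
    """
    rng = np.random.default_rng(seed)
    groups = np.array(["control"] * n_control + ["ptsd"] * n_ptsd)
    n_tests = 0
    n_reject = 0
    for _ in range(n_replicates):
        value = rng.standard_normal(n_control + n_ptsd)
        sal = rng.standard_normal(n_control + n_ptsd)
        results = group.value_saliency_group_tests(value, sal, groups, q=alpha)
        raw = [r.p_raw for r in results if r.analysis.endswith("_vs_0")]
        n_tests += len(raw)
        n_reject += int(np.sum(np.asarray(raw) < alpha))
    return {
        "type_one_error_rate": n_reject / n_tests,
        "n_tests": n_tests,
    }
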