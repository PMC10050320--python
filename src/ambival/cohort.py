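"""Ground-truth synthetic cohort: behaviour, symptoms, and ROI time series.

Every downstream stage of the pipeline (choice-model fitting, first-level
GLMs, group inference) is exercised against data generated here with known
parameters.  The generator emulates a combat-veteran cohort with a wide range
of posttrauma symptom severity:

* **Behaviour** — per-subject (alpha, beta, gamma) per gain/loss domain drawn
  from log-normal/normal priors, with configurable couplings from a latent
  severity factor to risk attitude in gains and ambiguity attitude in losses
  (more severe symptoms -> more averse).
* **Symptoms** — one latent severity factor drives the five CAPS symptom
  factors, PCL-5, BDI, STAI, and DES with strong loadings; combat exposure
  (CES) and childhood trauma (CTQ) load weakly and carry their own latents,
  so a clinical PCA yields a dominant severity component plus distinct
  exposure/trauma components.  CAPS total is the sum of the five factor
  scores; group membership (ptsd/control) is a configurable CAPS cutoff.
* **Neural data** — ROI series at TR = 1 s on a percent-signal-change scale
  in which the valuation signal follows either a monotonic *value* code
  (amplitude x z-normalised signed SV) or a U-shaped *saliency* code
  (amplitude x z-normalised |SV|), built from the same box-car/HRF design
  machinery as the estimating GLMs, plus white noise, slow cosine drift and
  motion-coupled nuisance series.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import glm as _glm
from .choice import SubjectParams, choice_probability, subjective_value
from .design import RESPONSE_WINDOW, SURE_AMOUNT, BlockSchedule

#: per-factor (mean, sd, max) loosely matching published cohort descriptives
_CAPS_FACTORS = {
    "re_experiencing": (8.6, 10.3, 40),
    "avoidance": (4.6, 5.6, 16),
    "emotional_numbing": (7.9, 9.7, 40),
    "dysphoric_arousal": (7.3, 7.3, 24),
    "anxious_arousal": (4.4, 4.3, 16),
}
_SEVERITY_LOADING = 0.85


@dataclass
class ClinicalProfile:
    """Symptom and covariate scores for one synthetic subject."""

    caps_factors: dict
    caps_total: float
    pcl5: float
    bdi: float
    stai_state: float
    stai_trait: float
    des: float
    ces: float
    ctq: float
    age: float
    income_band: int
    education_band: int
    kbit: float
    group: str  # "ptsd" | "control"

    def as_row(self) -> dict:
        row = {f"caps_{k}": v for k, v in self.caps_factors.items()}
        row.update(
            caps_total=self.caps_total, pcl5=self.pcl5, bdi=self.bdi,
            stai_state=self.stai_state, stai_trait=self.stai_trait, des=self.des,
            ces=self.ces, ctq=self.ctq, age=self.age, income_band=self.income_band,
            education_band=self.education_band, kbit=self.kbit, group=self.group,
        )
        return row


@dataclass
class EncodingSpec:
    """Generative neural encoding of subjective value for one subject's ROI."""

    mode: str = "value"          # value | saliency | mixed
    amplitude: float = 0.1       # PSC units per unit z-normalised SV
    mix_weight: float = 0.0      # saliency share in mixed mode
    condition_amplitude: float = 0.2  # PSC units of the condition box-car
    noise_sd: float = 1.0        # PSC units per TR
    drift: float = 0.5           # low-frequency drift amplitude (PSC)
    motion_coupling: float = 0.1  # leakage of nuisance series into the signal
    #: 'global' z-scores signed SV across the whole session (the brain keeps a
    #: common value scale across blocks); 'per_block' reuses the estimating
    #: GLM's per-block normalisation, making the generative and estimating
    #: designs identical (exact noiseless recovery)
    normalization: str = "global"

    def __post_init__(self):
        if self.mode not in ("value", "saliency", "mixed"):
            raise ValueError(f"unknown encoding mode {self.mode!r}")
        if self.normalization not in ("global", "per_block"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not 0.0 <= self.mix_weight <= 1.0:
            raise ValueError("mix_weight must lie in [0, 1]")


@dataclass
class CohortConfig:
    """Generative study conditions for a synthetic cohort.

    Defaults are chosen to resemble the published cohort: a CAPS cutoff of 40
    splits roughly 40% of subjects into the ptsd group; severity couples
    negatively to risk attitude in gains and ambiguity attitude in losses;
    controls carry a value code and ptsd subjects a saliency code in the ROI.
    """

    caps_cutoff: float = 40.0
    #: fix the ptsd-group size exactly (labels by CAPS-total rank); None = use the cutoff
    n_ptsd: int | None = None
    # behavioural priors (log-normal for alpha/gamma, normal for beta)
    alpha_gain_logmean: float = float(np.log(0.75))
    alpha_loss_logmean: float = float(np.log(0.95))
    alpha_logsd: float = 0.30
    beta_gain_mean: float = 0.35
    beta_loss_mean: float = 0.25
    beta_sd: float = 0.50
    # median gamma of 1.0 keeps catch-trial (dominated-option) error rates in
    # the 10-20% range seen in real cohorts; much lower values would fail most
    # subjects on the >50% inferior-choice exclusion rule
    gamma_logmean: float = float(np.log(1.0))
    gamma_logsd: float = 0.50
    # severity -> behaviour couplings (per SD of latent severity)
    coupling_alpha_gain: float = -0.12   # on log alpha: aversion grows with severity
    coupling_beta_loss: float = -0.20    # on beta_loss: amb_loss attitude drops
    # choice simulation
    lapse_rate: float = 0.02
    rt_logmean: float = float(np.log(1.2))
    rt_logsd: float = 0.35
    # neural encoding
    encoding_by_group: bool = True
    base_amplitude: float = 0.1
    amplitude_logsd: float = 0.50
    condition_amplitude: float = 0.2
    noise_sd: float = 1.0
    drift: float = 0.5
    motion_coupling: float = 0.1

    def __post_init__(self):
        if not 0.0 <= self.lapse_rate < 1.0:
            raise ValueError("lapse_rate must lie in [0, 1)")
        for name in ("alpha_logsd", "beta_sd", "gamma_logsd", "noise_sd",
                     "base_amplitude", "amplitude_logsd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SyntheticSubject:
    """Everything generative about one subject (the recovery-test ground truth)."""

    subject_id: str
    severity: float
    params: dict  # domain -> SubjectParams (true generative values)
    profile: ClinicalProfile
    encoding: EncodingSpec


def _truncate(x, lo, hi):
    return float(np.clip(x, lo, hi))


def _clinical_profile(rng: np.random.Generator, s: float, cfg: CohortConfig) -> ClinicalProfile:
    lam = _SEVERITY_LOADING

    def loaded(mean, sd, lo, hi, loading=lam):
        z = loading * s + np.sqrt(max(0.0, 1 - loading**2)) * rng.standard_normal()
        return _truncate(round(mean + sd * z), lo, hi)

    factors = {
        k: loaded(m * 0.75, sd, 0, mx) for k, (m, sd, mx) in _CAPS_FACTORS.items()
    }
    caps_total = float(sum(factors.values()))
    l_exposure = rng.standard_normal()   # latent combat-exposure factor
    l_trauma = rng.standard_normal()     # latent childhood-trauma factor
    ces = _truncate(round(15.8 + 9.4 * (0.30 * s + 0.85 * l_exposure
                                        + 0.44 * rng.standard_normal())), 0, 41)
    ctq = _truncate(round(36.3 + 11.4 * (0.25 * s + 0.85 * l_trauma
                                         + 0.46 * rng.standard_normal())), 25, 125)
    return ClinicalProfile(
        caps_factors=factors,
        caps_total=caps_total,
        pcl5=loaded(23.6, 21.9, 0, 80),
        bdi=loaded(14.0, 14.8, 0, 63),
        stai_state=loaded(39.0, 13.3, 20, 80),
        stai_trait=loaded(38.0, 15.5, 20, 80),
        des=loaded(28.4, 32.5, 0, 100),
        ces=ces,
        ctq=ctq,
        age=_truncate(round(37.3 + 9.0 * rng.standard_normal()), 23, 75),
        income_band=int(rng.integers(1, 6)),
        education_band=int(rng.integers(1, 6)),
        kbit=_truncate(round(109.0 + 12.5 * rng.standard_normal()), 55, 145),
        group="ptsd" if caps_total >= cfg.caps_cutoff else "control",
    )


def _behavioural_params(rng: np.random.Generator, s: float, cfg: CohortConfig) -> dict:
    from .choice import ALPHA_BOUNDS, BETA_BOUNDS, GAMMA_BOUNDS

    def alpha(logmean, coupling):
        return _truncate(
            np.exp(logmean + coupling * s + cfg.alpha_logsd * rng.standard_normal()),
            *ALPHA_BOUNDS,
        )

    def beta(mean, coupling):
        return _truncate(mean + coupling * s + cfg.beta_sd * rng.standard_normal(),
                         *BETA_BOUNDS)

    def gamma():
        return _truncate(
            np.exp(cfg.gamma_logmean + cfg.gamma_logsd * rng.standard_normal()),
            GAMMA_BOUNDS[0] + 1e-3, GAMMA_BOUNDS[1],
        )

    return {
        "gain": SubjectParams("gain", alpha(cfg.alpha_gain_logmean, cfg.coupling_alpha_gain),
                              beta(cfg.beta_gain_mean, 0.0), gamma()),
        "loss": SubjectParams("loss", alpha(cfg.alpha_loss_logmean, 0.0),
                              beta(cfg.beta_loss_mean, cfg.coupling_beta_loss), gamma()),
    }


def sample_population(
    n_subjects: int, config: CohortConfig | None = None, seed: int = 0
) -> list[SyntheticSubject]:
    """Draw a fully seeded synthetic cohort with ground-truth parameters."""
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    cfg = config or CohortConfig()
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n_subjects):
        s = rng.standard_normal()
        profile = _clinical_profile(rng, s, cfg)
        params = _behavioural_params(rng, s, cfg)
        amp = cfg.base_amplitude * np.exp(cfg.amplitude_logsd * rng.standard_normal())
        encoding = EncodingSpec(
            mode="value", amplitude=float(amp), mix_weight=0.0,
            condition_amplitude=cfg.condition_amplitude, noise_sd=cfg.noise_sd,
            drift=cfg.drift, motion_coupling=cfg.motion_coupling,
        )
        subjects.append(
            SyntheticSubject(
                subject_id=f"sub-{i + 1:03d}", severity=float(s),
                params=params, profile=profile, encoding=encoding,
            )
        )
    if cfg.n_ptsd is not None:
        if not 0 <= cfg.n_ptsd <= n_subjects:
            raise ValueError("n_ptsd must lie in [0, n_subjects]")
        order = np.argsort([-sub.profile.caps_total for sub in subjects], kind="stable")
        for rank, j in enumerate(order):
            subjects[j].profile.group = "ptsd" if rank < cfg.n_ptsd else "control"
    for sub in subjects:
        if cfg.encoding_by_group and sub.profile.group == "ptsd":
            sub.encoding.mode = "saliency"
    return subjects


def clinical_frame(subjects: list[SyntheticSubject]) -> pd.DataFrame:
    rows = []
    for sub in subjects:
        row = {"subject": sub.subject_id}
        row.update(sub.profile.as_row())
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_choices(
    subject: SyntheticSubject,
    schedule: BlockSchedule,
    seed: int,
    lapse_rate: float = 0.02,
    rt_logmean: float = float(np.log(1.2)),
    rt_logsd: float = 0.35,
) -> pd.DataFrame:
    """Bernoulli choices and truncated log-normal response times per trial.

    Returns a DataFrame aligned to the schedule's presentation order with
    columns ``trial_id, chose_lottery, response_time``; lapses (no button
    press within the 3.5-s window) leave both fields missing.
    """
    rng = np.random.default_rng(seed)
    trials = schedule.all_trials()
    rows = []
    for _, t in trials.iterrows():
        p = subject.params[t["domain"]]
        sv_l = subjective_value(t["P"], t["A"], t["V"], p.alpha, p.beta, t["domain"])
        sv_c = subjective_value(1.0, 0.0, SURE_AMOUNT, p.alpha, p.beta, t["domain"])
        prob = choice_probability(sv_l, sv_c, p.gamma)
        if rng.random() < lapse_rate:
            rows.append((int(t["trial_id"]), pd.NA, np.nan))
            continue
        chose = bool(rng.random() < prob)
        rt = min(float(rng.lognormal(rt_logmean, rt_logsd)), RESPONSE_WINDOW - 0.05)
        rows.append((int(t["trial_id"]), chose, rt))
    return pd.DataFrame(rows, columns=["trial_id", "chose_lottery", "response_time"])


def true_subjective_values(subject: SyntheticSubject, design: pd.DataFrame) -> pd.Series:
    """Signed lottery SV per trial_id at the subject's generative parameters."""
    svs = np.empty(len(design))
    for domain in ("gain", "loss"):
        m = (design["domain"] == domain).to_numpy()
        p = subject.params[domain]
        svs[m] = subjective_value(
            design.loc[m, "P"], design.loc[m, "A"], design.loc[m, "V"],
            p.alpha, p.beta, domain,
        )
    return pd.Series(svs, index=design["trial_id"].to_numpy())


def _drift_series(rng: np.random.Generator, n: int, amplitude: float) -> np.ndarray:
    """Slow drift as a random-phase sum of three low-frequency cosines, zero mean."""
    if amplitude == 0:
        return np.zeros(n)
    t = np.arange(n)
    out = np.zeros(n)
    for k in range(1, 4):
        phase = rng.uniform(0, 2 * np.pi)
        out += np.cos(2 * np.pi * k * t / (2.0 * n) + phase) / k
    out -= out.mean()
    return amplitude * out


def simulate_roi_timeseries(
    subject: SyntheticSubject,
    schedule: BlockSchedule,
    svs_per_trial: pd.Series,
    encoding: EncodingSpec | None = None,
    seed: int = 0,
    response_times: pd.Series | None = None,
) -> list[_glm.RoiTimeSeries]:
    """Forward-simulate one ROI's runs on the percent-signal-change scale.

    The valuation signal is built from the *same* design machinery the
    estimating GLMs use: condition box-cars and z-normalised (signed or
    unsigned) SV modulators convolved with the canonical HRF.  Value mode
    scales the signed-SV modulator by ``amplitude``; saliency mode the |SV|
    modulator; mixed mode blends them by ``mix_weight``.  Gaussian noise,
    slow cosine drift and motion-coupled nuisance series are added on top.
    """
    enc = encoding or subject.encoding
    rng = np.random.default_rng(seed)
    svs_per_trial = pd.Series(svs_per_trial)
    missing = set(schedule.all_trials()["trial_id"]) - set(svs_per_trial.index)
    if missing:
        raise ValueError(f"missing SVs for scheduled trials (e.g. {sorted(missing)[:5]})")

    if enc.mode == "value":
        w_value, w_sal = 1.0, 0.0
    elif enc.mode == "saliency":
        w_value, w_sal = 0.0, 1.0
    else:
        w_value, w_sal = 1.0 - enc.mix_weight, enc.mix_weight

    spec_v = _glm.GlmSpec("glm3")
    spec_s = _glm.GlmSpec("glm4")
    kernel = _glm._hrf_kernel(spec_v)
    if enc.normalization == "global":
        all_sv = svs_per_trial.loc[schedule.all_trials()["trial_id"]]
        z_all = (all_sv - all_sv.mean()) / all_sv.std(ddof=1)
    out = []
    for b in schedule.blocks:
        n = b.n_trs
        onsets = b.trials["onset"].to_numpy(float)
        durs = np.full(len(b.trials), spec_v.epoch_duration)
        cond = _glm._convolved_column(onsets, durs, np.ones(len(b.trials)), n, kernel)
        if enc.normalization == "per_block":
            Xv = _glm.build_design_matrix(b, spec_v, svs_per_trial=svs_per_trial,
                                          response_times=response_times)
            Xs = _glm.build_design_matrix(b, spec_s, svs_per_trial=svs_per_trial,
                                          response_times=response_times)
            mod_v = Xv[["ambiguous_xsv", "risky_xsv"]].sum(axis=1).to_numpy()
            mod_s = Xs[["ambiguous_xsaliency", "risky_xsaliency"]].sum(axis=1).to_numpy()
        else:
            zb = z_all.loc[b.trials["trial_id"]].to_numpy(float)
            mod_v = _glm._convolved_column(onsets, durs, zb, n, kernel)
            mod_s = _glm._convolved_column(onsets, durs, np.abs(zb), n, kernel)
        nuisance = np.cumsum(rng.normal(0.0, 0.02, size=(n, 6)), axis=0)
        signal = (
            enc.condition_amplitude * cond
            + enc.amplitude * (w_value * mod_v + w_sal * mod_s)
            + _drift_series(rng, n, enc.drift)
            + enc.motion_coupling * nuisance.sum(axis=1)
            + rng.normal(0.0, enc.noise_sd, size=n)
        )
        out.append(_glm.RoiTimeSeries(run_id=b.index, values=signal, nuisance=nuisance))
    return out


# ---------------------------------------------------------------------------
# writers

def write_choices(choices: pd.DataFrame, path) -> None:
    choices.to_csv(path, sep="\t", index=False)


def write_clinical(subjects: list[SyntheticSubject], path) -> None:
    clinical_frame(subjects).to_csv(path, index=False)


def write_roi_timeseries(series: list[_glm.RoiTimeSeries], path) -> None:
    """One TSV per subject: value column plus nuisance columns per run."""
    parts = []
    for s in series:
        df = pd.DataFrame({"run": s.run_id, "t": np.arange(len(s.values)),
                           "value": s.values})
        for i in range(6):
            df[f"motion_{i + 1}"] = s.nuisance[:, i]
        parts.append(df)
    pd.concat(parts, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_roi_timeseries(path) -> list[_glm.RoiTimeSeries]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for run, g in df.groupby("run"):
        g = g.sort_values("t")
        nuis = g[[f"motion_{i + 1}" for i in range(6)]].to_numpy()
        out.append(_glm.RoiTimeSeries(run_id=int(run), values=g["value"].to_numpy(),
                                      nuisance=nuis))
    return out


def write_ground_truth(subjects: list[SyntheticSubject], path) -> None:
    payload = []
    for s in subjects:
        payload.append(
            {
                "subject": s.subject_id,
                "severity": s.severity,
                "params": {d: p.as_dict() for d, p in s.params.items()},
                "profile": s.profile.as_row(),
                "encoding": asdict(s.encoding),
            }
        )
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
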