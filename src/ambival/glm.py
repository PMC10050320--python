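"""First-level ROI GLMs: design-matrix construction and least-squares estimation.

Five GLM variants probe how an ROI's activity relates to the decision task:

* ``glm1`` — four binary condition predictors (ambiguous/risky x gain/loss).
* ``glm2`` — glm1 plus four parametric modulators carrying the trial-wise
  signed subjective value (positive for gains, negative for losses),
  z-normalised within each scanning block.
* ``glm3`` — gains and losses combined: two condition predictors (ambiguous,
  risky) with signed-SV modulators; tests monotonic *value* coding.
* ``glm4`` — as glm3 but with unsigned |SV| modulators; tests U-shaped
  *saliency* coding.
* ``glm5`` — twelve binary predictors, one per subjective-value bin
  (2 uncertainty domains x 2 gain/loss domains x 3 equal-count bins).

Condition predictors are 6-s box-cars at option onset convolved with a
canonical double-gamma HRF; parametric modulators multiply the normalised
value into the box-car *before* convolution.  A 1-TR response regressor at
the button press and 6 motion-like nuisance series complete each model.
Runs are concatenated with run-wise intercepts and estimated by OLS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .design import DISPLAY_DURATION, Block, BlockSchedule

GLM_VARIANTS = ("glm1", "glm2", "glm3", "glm4", "glm5")

#: microtime resolution (s) for box-car construction; onsets fall on this grid
MICRO_DT = 0.5
HRF_LENGTH = 32.0  # s


def double_gamma_hrf(
    t,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_disp: float = 1.0,
    undershoot_disp: float = 1.0,
    ratio: float = 6.0,
):
    """Canonical double-gamma haemodynamic response, peak-normalised.

    Difference of two gamma densities: the positive lobe peaks near
    ``peak_delay`` (~5-6 s with the defaults) and the undershoot near
    ``undershoot_delay`` (16 s), with peak:undershoot amplitude ``ratio``
    (6:1).  Normalised so the maximum over [0, 32] s equals 1.
    """
    for name, v in (
        ("peak_delay", peak_delay),
        ("undershoot_delay", undershoot_delay),
        ("peak_disp", peak_disp),
        ("undershoot_disp", undershoot_disp),
        ("ratio", ratio),
    ):
        if v <= 0:
            raise ValueError(f"HRF parameter {name} must be positive, got {v}")
    t = np.asarray(t, dtype=float)
    h = gamma_dist.pdf(t, peak_delay / peak_disp, scale=peak_disp) - gamma_dist.pdf(
        t, undershoot_delay / undershoot_disp, scale=undershoot_disp
    ) / ratio
    grid = np.arange(0.0, HRF_LENGTH, 0.1)
    peak = np.max(
        gamma_dist.pdf(grid, peak_delay / peak_disp, scale=peak_disp)
        - gamma_dist.pdf(grid, undershoot_delay / undershoot_disp, scale=undershoot_disp) / ratio
    )
    out = h / peak
    return out if out.ndim else float(out)


def percent_signal_change(values: np.ndarray) -> np.ndarray:
    """Convert one run's raw series to percent signal change: 100*(x-mean)/mean."""
    x = np.asarray(values, dtype=float)
    m = x.mean()
    if m == 0:
        raise ValueError("run mean is zero; percent signal change undefined")
    return 100.0 * (x - m) / m


def z_normalize_per_block(values, block_labels) -> np.ndarray:
    """Z-score values within each block (sample SD, ddof=1).

    Zero-variance blocks map to zeros with a warning, so a constant-SV block
    contributes a null modulator rather than NaNs.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(block_labels)
    out = np.empty_like(values)
    for b in np.unique(labels):
        m = labels == b
        sd = values[m].std(ddof=1) if m.sum() > 1 else 0.0
        if sd == 0:
            warnings.warn(f"block {b!r}: zero-variance modulator, normalised to zeros",
                          stacklevel=2)
            out[m] = 0.0
        else:
            out[m] = (values[m] - values[m].mean()) / sd
    return out


def assign_sv_bins(trials: pd.DataFrame, svs) -> pd.Series:
    """Assign each trial a subjective-value bin label 1-6 per uncertainty domain.

    Within each uncertainty domain (risk, ambiguity) separately: loss trials
    are ranked by signed SV ascending and split into 3 equal-count bins
    (labels 1-3); gain trials likewise into labels 4-6.  Ties are broken by
    ``trial_id``; any remainder goes to the lower bins.
    """
    svs = np.asarray(svs, dtype=float)
    if len(svs) != len(trials):
        raise ValueError("svs and trials length mismatch")
    unc_arr = trials["uncertainty"].to_numpy()
    dom_arr = trials["domain"].to_numpy()
    tid_arr = trials["trial_id"].to_numpy()
    out = np.zeros(len(trials), dtype=int)
    for unc in np.unique(unc_arr):
        for domain, base in (("loss", 0), ("gain", 3)):
            pos_idx = np.flatnonzero((unc_arr == unc) & (dom_arr == domain))
            if len(pos_idx) == 0:
                continue
            order = pos_idx[np.lexsort((tid_arr[pos_idx], svs[pos_idx]))]
            n = len(order)
            sizes = [n // 3 + (1 if r < n % 3 else 0) for r in range(3)]
            pos = 0
            for k, s in enumerate(sizes):
                out[order[pos : pos + s]] = base + k + 1
                pos += s
    return pd.Series(out, index=trials.index)


@dataclass
class GlmSpec:
    """Configuration of one first-level GLM variant."""

    variant: str
    epoch_duration: float = DISPLAY_DURATION  # s (6 TR)
    response_duration: float = 1.0            # s (1 TR at button press)
    hrf_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.variant not in GLM_VARIANTS:
            raise ValueError(f"unknown GLM variant {self.variant!r}")


def _hrf_kernel(spec: GlmSpec) -> np.ndarray:
    t = np.arange(0.0, HRF_LENGTH, MICRO_DT)
    return np.asarray(double_gamma_hrf(t, **spec.hrf_params))


def _convolved_column(onsets, durations, weights, n_trs, kernel) -> np.ndarray:
    """Weighted box-car on the microtime grid, convolved and sampled at TR=1 s."""
    n_grid = int(round(n_trs / MICRO_DT))
    g = np.zeros(n_grid)
    for on, du, w in zip(onsets, durations, weights):
        i0 = int(round(on / MICRO_DT))
        i1 = min(int(round((on + du) / MICRO_DT)), n_grid)
        g[i0:i1] += w
    conv = np.convolve(g, kernel)[:n_grid]
    step = int(round(1.0 / MICRO_DT))
    return conv[::step][:n_trs]


def _condition_names(variant: str) -> list[str]:
    if variant in ("glm1", "glm2"):
        return ["ambiguous_gain", "risky_gain", "ambiguous_loss", "risky_loss"]
    if variant in ("glm3", "glm4"):
        return ["ambiguous", "risky"]
    return [f"bin_{u}_{k}" for u in ("ambiguous", "risky") for k in range(1, 7)]


def _trial_condition(variant: str, unc: str, domain: str) -> str:
    label = {"risk": "risky", "ambiguity": "ambiguous"}[unc]
    if variant in ("glm1", "glm2"):
        return f"{label}_{domain}"
    return label


def build_design_matrix(
    block: Block,
    spec: GlmSpec,
    svs_per_trial: dict | pd.Series | None = None,
    bins: pd.Series | None = None,
    response_times: pd.Series | None = None,
) -> pd.DataFrame:
    """Design matrix (TR x predictors) for one run.

    ``svs_per_trial`` maps ``trial_id`` to the subject's signed lottery SV and
    is required for glm2-glm5 (glm5 via ``bins``, a ``trial_id``-indexed bin
    label series).  Modulators are z-normalised within the run (scanning
    block), multiplied into the box-car, then convolved.  ``response_times``
    (trial_id -> RT in s, NaN = missed) place the 1-TR response regressor;
    without them the regressor sits at the end of the response window.
    """
    variant = spec.variant
    t = block.trials
    n_trs = block.n_trs
    kernel = _hrf_kernel(spec)
    cols: dict[str, np.ndarray] = {}

    needs_sv = variant in ("glm2", "glm3", "glm4")
    if needs_sv or (variant == "glm5" and bins is None):
        if svs_per_trial is None and variant != "glm5":
            raise ValueError(f"{variant} requires svs_per_trial")
    sv = None
    if svs_per_trial is not None:
        mapped = pd.Series(svs_per_trial).reindex(t["trial_id"])
        if mapped.isna().any():
            missing = t["trial_id"][mapped.isna().to_numpy()].tolist()
            raise ValueError(f"missing SVs for scheduled trials {missing[:5]}")
        sv = mapped.to_numpy(float)

    cond_of_trial = np.array(
        [_trial_condition(variant, u, d) for u, d in zip(t["uncertainty"], t["domain"])]
    )
    onsets = t["onset"].to_numpy(float)
    durs = np.full(len(t), spec.epoch_duration)

    if variant == "glm5":
        if bins is None:
            raise ValueError("glm5 requires precomputed bin labels")
        blabels = pd.Series(bins).reindex(t["trial_id"])
        if blabels.isna().any():
            raise ValueError("missing bin labels for scheduled trials")
        for name in _condition_names("glm5"):
            ulabel, k = name.split("_")[1], int(name.split("_")[2])
            m = (cond_of_trial == ulabel) & (blabels.to_numpy() == k)
            cols[name] = _condition_column(onsets, durs, m, n_trs, kernel)
    else:
        for name in _condition_names(variant):
            m = cond_of_trial == name
            cols[name] = _condition_column(onsets, durs, m, n_trs, kernel)

    if needs_sv:
        # each modulator is z-normalised over its own condition's trials within
        # the scanning block (the parametric-modulation convention), so the
        # masked weights are exactly zero-mean and unit-sd per condition
        mod_values = np.abs(sv) if variant == "glm4" else sv
        suffix = "xsaliency" if variant == "glm4" else "xsv"
        for name in _condition_names(variant):
            m = cond_of_trial == name
            w = np.zeros(len(t))
            if m.sum() > 1:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    w[m] = z_normalize_per_block(mod_values[m], np.zeros(int(m.sum())))
            cols[f"{name}_{suffix}"] = _convolved_column(onsets, durs, w, n_trs, kernel)

    # 1-TR response regressor at the button press
    if response_times is not None:
        rt = pd.Series(response_times).reindex(t["trial_id"]).to_numpy(float)
    else:
        rt = np.full(len(t), np.nan)
    press = onsets + spec.epoch_duration + np.where(np.isnan(rt), np.nan, rt)
    resp_on = press[~np.isnan(press)]
    if response_times is None:  # nominal presses at end of display epoch
        resp_on = onsets + spec.epoch_duration
    cols["response"] = _convolved_column(
        resp_on, np.full(len(resp_on), spec.response_duration), np.ones(len(resp_on)),
        n_trs, kernel,
    )
    return pd.DataFrame(cols)


def _condition_column(onsets, durs, mask, n_trs, kernel):
    return _convolved_column(onsets[mask], durs[mask], np.ones(int(mask.sum())), n_trs, kernel)


@dataclass
class RoiTimeSeries:
    """One run of ROI activity in percent-signal-change units at TR = 1 s."""

    run_id: int
    values: np.ndarray
    nuisance: np.ndarray  # (n_trs, 6) motion-like series
    tr: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.nuisance = np.asarray(self.nuisance, dtype=float)
        if self.nuisance.shape != (len(self.values), 6):
            raise ValueError("nuisance must be (n_trs, 6) aligned to values")


class RoiGlm:
    """OLS estimation of one GLM variant on concatenated runs of ROI data.

    Runs are concatenated with run-wise intercepts; motion-like nuisance
    series enter unconvolved.  All-zero predictor columns (conditions absent
    from the supplied runs) are dropped and reported.  Rank deficiency among
    the remaining columns raises with the offending columns named.
    """

    def __init__(
        self,
        series: list[RoiTimeSeries],
        designs: list[pd.DataFrame],
        include_nuisance: bool = True,
    ):
        if len(series) != len(designs):
            raise ValueError("series/design count mismatch")
        for s, X in zip(series, designs):
            if len(s.values) != len(X):
                raise ValueError(
                    f"run {s.run_id}: series length {len(s.values)} != design rows {len(X)}"
                )
        self.series = series
        self.designs = designs
        self.include_nuisance = include_nuisance

    def _assemble(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        names = list(self.designs[0].columns)
        blocks = []
        y = []
        n_runs = len(self.series)
        for r, (s, X) in enumerate(zip(self.series, self.designs)):
            parts = [X.to_numpy(float)]
            if self.include_nuisance:
                parts.append(s.nuisance)
            run_icpt = np.zeros((len(X), n_runs))
            run_icpt[:, r] = 1.0
            parts.append(run_icpt)
            blocks.append(np.hstack(parts))
            y.append(s.values)
        full_names = list(names)
        if self.include_nuisance:
            full_names += [f"motion_{i}" for i in range(1, 7)]
        full_names += [f"intercept_run{r + 1}" for r in range(n_runs)]
        return np.vstack(blocks), np.concatenate(y), full_names

    def fit(self) -> "RoiGlmResults":
        X, y, names = self._assemble()
        keep = ~np.all(X == 0, axis=0)
        dropped = [n for n, k in zip(names, keep) if not k]
        Xk = X[:, keep]
        kept_names = [n for n, k in zip(names, keep) if k]
        rank = np.linalg.matrix_rank(Xk)
        if rank < Xk.shape[1]:
            offending = _collinear_columns(Xk, kept_names)
            raise np.linalg.LinAlgError(
                f"design matrix rank deficient; offending columns: {offending}"
            )
        beta, _, _, _ = np.linalg.lstsq(Xk, y, rcond=None)
        resid = y - Xk @ beta
        return RoiGlmResults(
            params=pd.Series(beta, index=kept_names),
            dropped_columns=dropped,
            resid=resid,
            nobs=len(y),
            condition_number=float(np.linalg.cond(Xk)),
        )


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Greedy identification of columns that do not increase the rank."""
    bad, cols = [], []
    r = 0
    for j in range(X.shape[1]):
        trial = cols + [j]
        if np.linalg.matrix_rank(X[:, trial]) > r:
            cols = trial
            r += 1
        else:
            bad.append(names[j])
    return bad


@dataclass
class RoiGlmResults:
    """OLS betas (percent-signal-change units; per unit z-SV for modulators)."""

    params: pd.Series
    dropped_columns: list[str]
    resid: np.ndarray
    nobs: int
    condition_number: float

    def beta_table(self, subject: str, variant: str) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": subject,
                "glm": variant,
                "predictor": self.params.index,
                "beta": self.params.to_numpy(),
            }
        )

    def summary(self) -> str:
        lines = [
            "ROI GLM (OLS, concatenated runs)",
            "=" * 40,
            f"observations:     {self.nobs}",
            f"condition number: {self.condition_number:.1f}",
        ]
        if self.dropped_columns:
            lines.append(f"dropped (all-zero): {', '.join(self.dropped_columns)}")
        lines.append("-" * 40)
        for name, b in self.params.items():
            lines.append(f"{name:24s} {b:10.5f}")
        return "\n".join(lines)


def fit_glm(series: list[RoiTimeSeries], designs: list[pd.DataFrame]) -> RoiGlmResults:
    """Functional wrapper over :class:`RoiGlm`."""
    return RoiGlm(series, designs).fit()


def subject_designs(
    schedule: BlockSchedule,
    spec: GlmSpec,
    svs_per_trial=None,
    bins=None,
    response_times=None,
    exclude_runs: set[int] | frozenset[int] = frozenset(),
) -> tuple[list[int], list[pd.DataFrame]]:
    """Design matrices for every (non-excluded) run of a schedule.

    ``exclude_runs`` mirrors motion-based run exclusion; in synthetic data it
    is driven by configuration, not motion estimation.
    """
    run_ids, designs = [], []
    for b in schedule.blocks:
        if b.index in exclude_runs:
            continue
        run_ids.append(b.index)
        designs.append(
            build_design_matrix(b, spec, svs_per_trial=svs_per_trial, bins=bins,
                                response_times=response_times)
        )
    return run_ids, designs
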