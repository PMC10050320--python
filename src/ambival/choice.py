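"""Subjective-value choice model for risky and ambiguous monetary lotteries.

The model has two stages.  Valuation assigns each option a subjective value

    SV = [P - beta * (A / 2)] * V ** alpha

where ``P`` is the outcome probability (0.25/0.50/0.75 for risky lotteries,
0.50 for ambiguous ones, 1 for the certain option), ``A`` the ambiguity level
(fraction of the probability display occluded; 0 for risky lotteries), and
``V`` the unsigned dollar magnitude.  ``alpha`` captures utility curvature
(risk attitude) and ``beta`` linear discounting of probability by ambiguity.
The choice stage is a softmax over the lottery/certain SV difference with
noise parameter ``gamma``.

Sign convention
---------------
Loss-domain subjective values are represented internally as *negative*
numbers (gains positive), and the lottery-choice probability is the logistic
``1 / (1 + exp(-gamma * (SV_L - SV_C)))`` with ``gamma >= 0``, so that
higher-valued options are always chosen more often.  Under this convention
the attitude transforms are: risky gains ``alpha - 1``, risky losses
``1 - alpha``, ambiguous gains ``-beta``, ambiguous losses ``beta``
(negative = averse, positive = seeking).

Fitting is per subject and per domain (gains and losses separately) by
maximum likelihood with a seeded Latin-hypercube multistart over bounded
parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit
from scipy.stats import qmc

from .design import RESPONSE_WINDOW, SURE_AMOUNT

ALPHA_BOUNDS: tuple[float, float] = (0.0894, 4.34)  # symmetric in log space around 1
BETA_BOUNDS: tuple[float, float] = (-4.0, 4.0)
GAMMA_BOUNDS: tuple[float, float] = (0.0, 20.0)

_N_PARAMS = 3  # (alpha, beta, gamma) per subject x domain


def subjective_value(P, A, V, alpha, beta, domain):
    """Signed subjective value of an option.

    Gains return ``[P - beta*A/2] * V**alpha``; losses return its negative.
    The certain option corresponds to ``P=1, A=0, V=5``.  Accepts scalars or
    arrays (broadcast).
    """
    P = np.asarray(P, dtype=float)
    A = np.asarray(A, dtype=float)
    V = np.asarray(V, dtype=float)
    if np.any(V < 0):
        raise ValueError("magnitude V must be non-negative (unsigned)")
    if np.any((P < 0) | (P > 1)):
        raise ValueError("probability P must lie in [0, 1]")
    if np.any((A < 0) | (A >= 1)):
        raise ValueError("ambiguity level A must lie in [0, 1)")
    if domain not in ("gain", "loss"):
        raise ValueError(f"domain must be 'gain' or 'loss', got {domain!r}")
    sv = (P - beta * (A / 2.0)) * V**alpha
    out = sv if domain == "gain" else -sv
    return out if out.ndim else float(out)


def choice_probability(sv_lottery, sv_sure, gamma):
    """Probability of choosing the lottery under softmax noise ``gamma >= 0``.

    Numerically stable logistic of ``gamma * (sv_lottery - sv_sure)``; equals
    0.5 whenever the two signed SVs coincide or ``gamma == 0``.
    """
    if np.any(np.asarray(gamma) < 0):
        raise ValueError("gamma must be non-negative")
    out = expit(gamma * (np.asarray(sv_lottery, float) - np.asarray(sv_sure, float)))
    return out if out.ndim else float(out)


def _nll_arrays(theta, P, A, V, sign, chose):
    """Negative log-likelihood from pre-extracted trial arrays (hot path)."""
    alpha, beta, gamma = theta
    sv_l = sign * (P - beta * (A / 2.0)) * V**alpha
    sv_c = sign * SURE_AMOUNT**alpha
    p = expit(gamma * (sv_l - sv_c))
    eps = np.finfo(float).eps
    p = np.clip(p, eps, 1.0 - eps)
    return -np.sum(np.where(chose, np.log(p), np.log1p(-p)))


def _nll_and_grad_t(t, P, A, V, sign, chose):
    """NLL and its gradient in the transformed space (log alpha, beta, log gamma).

    With u = gamma * (sv_l - sv_c) and p = expit(u), dNLL/du_i = p_i - c_i;
    the chain rule through sv gives the three partials in closed form.
    """
    alpha, beta, gamma = np.exp(t[0]), t[1], np.exp(t[2])
    Va = V**alpha
    bracket = P - beta * (A / 2.0)
    sv_l = sign * bracket * Va
    sv_c = sign * SURE_AMOUNT**alpha
    delta = sv_l - sv_c
    u = gamma * delta
    p = expit(u)
    eps = np.finfo(float).eps
    pc = np.clip(p, eps, 1.0 - eps)
    nll = -np.sum(np.where(chose, np.log(pc), np.log1p(-pc)))
    r = p - chose  # dNLL/du per trial
    ddelta_dalpha = sign * (bracket * Va * np.log(V) - SURE_AMOUNT**alpha * np.log(SURE_AMOUNT))
    ddelta_dbeta = -sign * (A / 2.0) * Va
    g_logalpha = gamma * alpha * np.sum(r * ddelta_dalpha)
    g_beta = gamma * np.sum(r * ddelta_dbeta)
    g_loggamma = np.sum(r * u)
    return float(nll), np.array([g_logalpha, g_beta, g_loggamma])


def negative_log_likelihood(alpha, beta, gamma, choices: pd.DataFrame) -> float:
    """NLL of observed choices from one domain under (alpha, beta, gamma).

    ``choices`` needs columns ``P, A, V, domain, chose_lottery``; missed
    responses must be excluded beforehand.  Probabilities are clamped away
    from 0/1 by a machine-epsilon guard.
    """
    if len(choices) == 0:
        raise ValueError("empty choice list")
    domains = choices["domain"].unique()
    if len(domains) != 1:
        raise ValueError("choices must come from a single domain")
    sign = 1.0 if domains[0] == "gain" else -1.0
    return float(
        _nll_arrays(
            (alpha, beta, gamma),
            choices["P"].to_numpy(float),
            choices["A"].to_numpy(float),
            choices["V"].to_numpy(float),
            sign,
            choices["chose_lottery"].to_numpy(bool),
        )
    )


@dataclass
class SubjectParams:
    """Fitted (or generative) parameters for one subject x domain."""

    domain: str
    alpha: float
    beta: float
    gamma: float
    nll: float | None = None
    bic: float | None = None
    n_trials: int | None = None
    low_identifiability: bool = False

    def as_dict(self) -> dict:
        return {
            "domain": self.domain,
            "alpha": self.alpha,
            "beta": self.beta,
            "gamma": self.gamma,
            "nll": self.nll,
            "bic": self.bic,
            "n_trials": self.n_trials,
        }


@dataclass
class AttitudeSet:
    """The four uncertainty attitudes; negative = averse, positive = seeking."""

    risk_gain: float
    risk_loss: float
    amb_gain: float
    amb_loss: float

    def as_dict(self) -> dict:
        return {
            "risk_gain": self.risk_gain,
            "risk_loss": self.risk_loss,
            "amb_gain": self.amb_gain,
            "amb_loss": self.amb_loss,
        }


def transform_attitudes(gain_params: SubjectParams, loss_params: SubjectParams) -> AttitudeSet:
    """Map fitted (alpha, beta) per domain onto signed attitudes.

    Risky gains: alpha - 1; risky losses: 1 - alpha; ambiguous gains: -beta;
    ambiguous losses: beta.
    """
    return AttitudeSet(
        risk_gain=gain_params.alpha - 1.0,
        risk_loss=1.0 - loss_params.alpha,
        amb_gain=-gain_params.beta,
        amb_loss=loss_params.beta,
    )


@dataclass
class FitConfig:
    """Multistart optimiser settings for per-subject fits."""

    n_starts: int = 20
    seed: int = 0
    alpha_bounds: tuple[float, float] = ALPHA_BOUNDS
    beta_bounds: tuple[float, float] = BETA_BOUNDS
    gamma_bounds: tuple[float, float] = GAMMA_BOUNDS
    gamma_floor: float = 1e-3  # below this the fit is flagged low-identifiability


class RiskAmbiguityChoiceModel:
    """Per-subject, per-domain maximum-likelihood model of lottery choices.

    Parameters
    ----------
    choices : DataFrame
        One row per non-missed trial of a single domain with columns
        ``P, A, V, domain, chose_lottery``.
    """

    def __init__(self, choices: pd.DataFrame):
        if len(choices) == 0:
            raise ValueError("empty choice list")
        domains = choices["domain"].unique()
        if len(domains) != 1:
            raise ValueError("fit one domain at a time")
        self.domain = str(domains[0])
        self.choices = choices.reset_index(drop=True)
        self._P = choices["P"].to_numpy(float)
        self._A = choices["A"].to_numpy(float)
        self._V = choices["V"].to_numpy(float)
        self._sign = 1.0 if self.domain == "gain" else -1.0
        self._chose = choices["chose_lottery"].to_numpy(bool)

    @classmethod
    def from_dataframe(
        cls, choices: pd.DataFrame, design: pd.DataFrame, domain: str
    ) -> "RiskAmbiguityChoiceModel":
        """Join a ``(trial_id, chose_lottery[, response_time])`` table with the design."""
        merged = choices.merge(design, on="trial_id", how="left", validate="1:1")
        merged = merged[merged["domain"] == domain]
        merged = merged[merged["chose_lottery"].notna()]
        merged = merged.astype({"chose_lottery": bool})
        return cls(merged)

    def loglike(self, alpha: float, beta: float, gamma: float) -> float:
        return -self.nll((alpha, beta, gamma))

    def nll(self, theta) -> float:
        return float(_nll_arrays(theta, self._P, self._A, self._V, self._sign, self._chose))

    def fit(self, config: FitConfig | None = None) -> "ChoiceModelResults":
        """Bounded multistart maximum likelihood; deterministic under the seed.

        Starts are a seeded Latin hypercube over the bounded (alpha, beta,
        gamma) cube; the best converged NLL wins, ties broken by the
        lexicographically smallest parameter vector.
        """
        config = config or FitConfig()
        # optimise in (log alpha, beta, log gamma): log-scale curvature and
        # noise keep the objective well conditioned across their bounds
        gamma_lo = max(config.gamma_bounds[0], 1e-4)
        tbounds = [
            (np.log(config.alpha_bounds[0]), np.log(config.alpha_bounds[1])),
            config.beta_bounds,
            (np.log(gamma_lo), np.log(config.gamma_bounds[1])),
        ]
        lo = np.array([b[0] for b in tbounds])
        hi = np.array([b[1] for b in tbounds])
        sampler = qmc.LatinHypercube(d=_N_PARAMS, seed=config.seed)
        starts = lo + sampler.random(config.n_starts) * (hi - lo)

        def tnll(t):
            return _nll_and_grad_t(t, self._P, self._A, self._V, self._sign, self._chose)

        best: optimize.OptimizeResult | None = None
        n_converged = 0
        for x0 in starts:
            res = optimize.minimize(tnll, x0, method="L-BFGS-B", jac=True, bounds=tbounds)
            if not res.success:
                continue
            n_converged += 1
            if (
                best is None
                or res.fun < best.fun - 1e-10
                or (abs(res.fun - best.fun) <= 1e-10 and tuple(res.x) < tuple(best.x))
            ):
                best = res
        if best is None:
            raise RuntimeError(
                f"optimizer failed to converge on all {config.n_starts} starts "
                f"({self.domain} domain, n={len(self.choices)})"
            )
        alpha, beta, gamma = np.exp(best.x[0]), best.x[1], np.exp(best.x[2])
        if gamma <= gamma_lo * (1 + 1e-9) and config.gamma_bounds[0] == 0.0:
            gamma = gamma  # numeric floor stands in for the gamma = 0 boundary
        n = len(self.choices)
        nll = float(best.fun)
        bic = 2.0 * nll + _N_PARAMS * np.log(n)
        params = SubjectParams(
            domain=self.domain,
            alpha=float(alpha),
            beta=float(beta),
            gamma=float(gamma),
            nll=nll,
            bic=float(bic),
            n_trials=n,
            low_identifiability=bool(gamma < config.gamma_floor),
        )
        return ChoiceModelResults(self, params, n_converged=n_converged, config=config)


@dataclass
class ChoiceModelResults:
    """Result of a per-domain maximum-likelihood fit."""

    model: RiskAmbiguityChoiceModel
    params: SubjectParams
    n_converged: int = 0
    config: FitConfig = field(default_factory=FitConfig)

    @property
    def alpha(self) -> float:
        return self.params.alpha

    @property
    def beta(self) -> float:
        return self.params.beta

    @property
    def gamma(self) -> float:
        return self.params.gamma

    @property
    def nll(self) -> float:
        return self.params.nll

    @property
    def bic(self) -> float:
        return self.params.bic

    def predict(self, design: pd.DataFrame | None = None) -> np.ndarray:
        """Lottery-choice probabilities at the fitted parameters."""
        d = design if design is not None else self.model.choices
        sv_l = subjective_value(d["P"], d["A"], d["V"], self.alpha, self.beta, self.model.domain)
        sv_c = subjective_value(1.0, 0.0, SURE_AMOUNT, self.alpha, self.beta, self.model.domain)
        return np.asarray(choice_probability(sv_l, sv_c, self.gamma))

    def subjective_values(self, design: pd.DataFrame) -> np.ndarray:
        """Signed trial-wise lottery SVs at the fitted parameters."""
        return np.asarray(
            subjective_value(
                design["P"], design["A"], design["V"], self.alpha, self.beta, self.model.domain
            )
        )

    def summary(self) -> str:
        p = self.params
        lines = [
            "Risk & Ambiguity Choice Model (maximum likelihood)",
            "=" * 50,
            f"domain:           {p.domain}",
            f"n trials:         {p.n_trials}",
            f"alpha (curvature) {p.alpha:10.4f}",
            f"beta  (ambiguity) {p.beta:10.4f}",
            f"gamma (noise)     {p.gamma:10.4f}",
            f"NLL               {p.nll:10.4f}",
            f"BIC               {p.bic:10.4f}",
            f"starts converged: {self.n_converged}/{self.config.n_starts}",
        ]
        if p.low_identifiability:
            lines.append("warning: gamma near 0 — alpha/beta weakly identified")
        return "\n".join(lines)


def fit_subject_domain(choices: pd.DataFrame, config: FitConfig | None = None) -> SubjectParams:
    """Functional wrapper: fit one subject x domain, return the parameter record."""
    res = RiskAmbiguityChoiceModel(choices).fit(config)
    if res.params.low_identifiability:
        warnings.warn("gamma near 0: alpha/beta weakly identified", stacklevel=2)
    return res.params


@dataclass
class CatchQuality:
    """Catch-trial quality control: fail iff inferior-choice fraction > 0.5."""

    passed: bool
    inferior_fraction: float
    n_catch: int


def catch_trial_quality(choices: pd.DataFrame, catch_ids) -> CatchQuality:
    """Apply the catch-trial exclusion rule.

    On catch trials (lottery magnitude equal to the sure $5) one option weakly
    dominates: in gains the sure $5 dominates any $5 lottery with P < 1, so
    choosing the lottery is inferior; in losses a chance of losing $5 weakly
    dominates the sure $5 loss, so choosing the sure option is inferior.
    A subject fails when strictly more than half of the responded catch trials
    are inferior choices.

    ``choices`` needs columns ``trial_id, domain, chose_lottery``.
    """
    catch_ids = set(np.asarray(list(catch_ids)).tolist())
    sub = choices[choices["trial_id"].isin(catch_ids)]
    sub = sub[sub["chose_lottery"].notna()]
    if len(sub) == 0:
        return CatchQuality(passed=True, inferior_fraction=0.0, n_catch=0)
    chose = sub["chose_lottery"].astype(bool)
    inferior = np.where(sub["domain"].to_numpy() == "gain", chose, ~chose)
    frac = float(np.mean(inferior))
    return CatchQuality(passed=frac <= 0.5, inferior_fraction=frac, n_catch=int(len(sub)))


def validate_response_times(choices: pd.DataFrame) -> None:
    rt = choices.get("response_time")
    if rt is not None and np.any(rt.dropna() > RESPONSE_WINDOW):
        raise ValueError(f"response times must be <= {RESPONSE_WINDOW} s")


def write_params_csv(rows: list[dict], path) -> None:
    """Per-subject parameter CSV (subject, domain, alpha, beta, gamma, nll, bic, qc_pass)."""
    pd.DataFrame(rows).to_csv(path, index=False)
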