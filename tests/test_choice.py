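"""Subjective value, softmax choice, likelihood, fitting, and quality control."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ambival import choice, cohort, design


class TestSubjectiveValue:
    def test_linear_no_ambiguity(self):
        assert choice.subjective_value(0.5, 0, 5, alpha=1, beta=0.7, domain="gain") == 2.5

    def test_sure_amount_sign_convention(self):
        assert choice.subjective_value(1, 0, 5, 1, 0, "gain") == 5
        assert choice.subjective_value(1, 0, 5, 1, 0, "loss") == -5

    def test_hand_evaluated_ambiguous(self):
        # [0.5 - 1*0.74/2] * 10^0.8 = 0.13 * 10^0.8
        got = choice.subjective_value(0.5, 0.74, 10, alpha=0.8, beta=1.0, domain="gain")
        assert got == pytest.approx(0.13 * 10**0.8, abs=1e-12)
        assert got == pytest.approx(0.820, abs=5e-4)

    @pytest.mark.parametrize(
        "kwargs", [dict(P=1.2), dict(P=-0.1), dict(V=-3), dict(A=1.0)]
    )
    def test_input_validation(self, kwargs):
        args = dict(P=0.5, A=0.0, V=10, alpha=1.0, beta=0.0, domain="gain")
        args.update(kwargs)
        with pytest.raises(ValueError):
            choice.subjective_value(**args)

    @given(
        v=st.floats(1.0, 120.0),
        dv=st.floats(0.1, 10.0),
        alpha=st.floats(0.2, 2.0),
        beta=st.floats(-2.0, 2.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_magnitude(self, v, dv, alpha, beta):
        lo = choice.subjective_value(0.5, 0.24, v, alpha, beta, "gain")
        hi = choice.subjective_value(0.5, 0.24, v + dv, alpha, beta, "gain")
        assert hi > lo or (0.5 - beta * 0.12) == 0
        # losses: more money at stake -> more negative
        lo_l = choice.subjective_value(0.5, 0.24, v, alpha, beta, "loss")
        hi_l = choice.subjective_value(0.5, 0.24, v + dv, alpha, beta, "loss")
        assert (hi_l < lo_l) == (hi > lo)

    def test_decreasing_in_ambiguity_when_beta_positive(self):
        svs = [choice.subjective_value(0.5, a, 20, 0.8, 0.6, "gain")
               for a in (0.24, 0.5, 0.74)]
        assert svs[0] > svs[1] > svs[2]


class TestChoiceProbability:
    def test_indifference(self):
        assert choice.choice_probability(1.3, 1.3, gamma=2.0) == 0.5

    def test_zero_gamma_pure_noise(self):
        assert choice.choice_probability(100.0, -100.0, gamma=0.0) == 0.5

    def test_closed_form(self):
        assert choice.choice_probability(math.log(3), 0.0, 1.0) == pytest.approx(0.75)

    def test_extreme_arguments_stable(self):
        assert choice.choice_probability(1e6, 0, 20.0) == pytest.approx(1.0)
        assert choice.choice_probability(-1e6, 0, 20.0) == pytest.approx(0.0)

    @given(
        d1=st.floats(-30, 30), d2=st.floats(-30, 30), gamma=st.floats(0.01, 5.0)
    )
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_sv_difference(self, d1, d2, gamma):
        p1 = choice.choice_probability(d1, 0.0, gamma)
        p2 = choice.choice_probability(d2, 0.0, gamma)
        if d1 < d2:
            assert p1 < p2 or p1 == pytest.approx(p2)  # equality only at saturation
        elif d1 == d2:
            assert p1 == p2


def _choices_frame(P, A, V, domain, chose):
    return pd.DataFrame(
        {"P": P, "A": A, "V": V, "domain": domain, "chose_lottery": chose}
    )


class TestNegativeLogLikelihood:
    def test_single_even_trial(self):
        # alpha=1, beta=0: lottery 0.5*10=5 equals sure 5 -> p=0.5 -> ln 2
        df = _choices_frame([0.5], [0.0], [10.0], "gain", [True])
        nll = choice.negative_log_likelihood(1.0, 0.0, 2.0, df)
        assert nll == pytest.approx(math.log(2), abs=1e-12)

    def test_consistent_choices_high_gamma_limit(self):
        df = _choices_frame(
            [0.75, 0.25], [0.0, 0.0], [120.0, 5.0], "gain", [True, False]
        )
        assert choice.negative_log_likelihood(1.0, 0.0, 19.0, df) < 1e-8

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        df = _choices_frame(
            rng.choice([0.25, 0.5, 0.75], 10),
            rng.choice([0.0, 0.24, 0.5, 0.74], 10),
            rng.choice([6.0, 19.0, 52.0, 120.0], 10),
            "loss",
            rng.random(10) < 0.5,
        )
        alpha, beta, gamma = 0.9, 0.4, 0.8
        expected = 0.0
        for _, r in df.iterrows():  # hand-summed, scalar math only
            sv_l = -((r.P - beta * r.A / 2) * r.V**alpha)
            sv_c = -(5.0**alpha)
            p = 1.0 / (1.0 + math.exp(-gamma * (sv_l - sv_c)))
            expected += -math.log(p if r.chose_lottery else 1 - p)
        got = choice.negative_log_likelihood(alpha, beta, gamma, df)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            choice.negative_log_likelihood(1, 0, 1, _choices_frame([], [], [], [], []))


def _simulate_domain(full_design, params, seed, domain="gain"):
    d = full_design[full_design["domain"] == domain].reset_index(drop=True)
    rng = np.random.default_rng(seed)
    sv_l = choice.subjective_value(d["P"], d["A"], d["V"], params.alpha, params.beta, domain)
    sv_c = choice.subjective_value(1, 0, 5, params.alpha, params.beta, domain)
    p = choice.choice_probability(sv_l, sv_c, params.gamma)
    return d.assign(chose_lottery=rng.random(len(d)) < p)


class TestFitting:
    def test_recovery_beats_grid_oracle(self, full_design):
        """The multistart optimum is at least as good as a coarse grid search."""
        true = choice.SubjectParams("gain", alpha=0.7, beta=0.5, gamma=2.0)
        df = _simulate_domain(full_design, true, seed=21)
        res = choice.RiskAmbiguityChoiceModel(df).fit(choice.FitConfig(seed=0))
        grid_best = min(
            choice.negative_log_likelihood(a, b, g, df)
            for a in np.arange(0.3, 1.5, 0.05)
            for b in np.arange(-0.5, 1.51, 0.1)
            for g in (0.25, 0.5, 1.0, 2.0, 4.0)
        )
        assert res.nll <= grid_best + 1e-6
        assert res.alpha == pytest.approx(true.alpha, abs=0.15)
        assert res.beta == pytest.approx(true.beta, abs=0.35)

    def test_bic_definition(self, full_design):
        true = choice.SubjectParams("loss", alpha=0.9, beta=0.3, gamma=1.0)
        df = _simulate_domain(full_design, true, seed=3, domain="loss")
        res = choice.RiskAmbiguityChoiceModel(df).fit(choice.FitConfig(seed=0))
        assert res.bic == pytest.approx(2 * res.nll + 3 * math.log(len(df)))

    def test_refit_deterministic(self, full_design):
        true = choice.SubjectParams("gain", alpha=0.8, beta=0.2, gamma=1.5)
        df = _simulate_domain(full_design, true, seed=8)
        cfg = choice.FitConfig(seed=5)
        r1 = choice.RiskAmbiguityChoiceModel(df).fit(cfg)
        r2 = choice.RiskAmbiguityChoiceModel(df).fit(cfg)
        assert (r1.alpha, r1.beta, r1.gamma, r1.nll) == (r2.alpha, r2.beta, r2.gamma, r2.nll)

    def test_symmetric_choices_flagged_low_identifiability(self, full_design):
        """Each trial answered both ways: gamma = 0 is the exact optimum."""
        d = full_design[full_design["domain"] == "gain"].reset_index(drop=True)
        df = pd.concat([d.assign(chose_lottery=True), d.assign(chose_lottery=False)],
                       ignore_index=True)
        res = choice.RiskAmbiguityChoiceModel(df).fit(choice.FitConfig(seed=0))
        assert res.params.gamma < 0.01
        assert res.params.low_identifiability
        assert res.nll == pytest.approx(240 * math.log(2), rel=1e-6)

    def test_boundary_data_returns_bound(self, full_design):
        """An extreme generative alpha lands on the fit bound without error."""
        true = choice.SubjectParams("gain", alpha=choice.ALPHA_BOUNDS[1], beta=0.0,
                                    gamma=5.0)
        df = _simulate_domain(full_design, true, seed=2)
        res = choice.RiskAmbiguityChoiceModel(df).fit(choice.FitConfig(seed=0))
        assert res.alpha >= 0.9 * choice.ALPHA_BOUNDS[1]

    def test_mixed_domains_rejected(self, full_design):
        df = full_design.assign(chose_lottery=True)
        with pytest.raises(ValueError, match="domain"):
            choice.RiskAmbiguityChoiceModel(df)

    def test_summary_mentions_parameters(self, full_design):
        true = choice.SubjectParams("gain", alpha=0.8, beta=0.2, gamma=1.5)
        df = _simulate_domain(full_design, true, seed=8)
        text = choice.RiskAmbiguityChoiceModel(df).fit(choice.FitConfig(seed=0)).summary()
        for token in ("alpha", "beta", "gamma", "BIC", "gain"):
            assert token in text


class TestAttitudes:
    def test_neutrality(self):
        g = choice.SubjectParams("gain", 1.0, 0.0, 1.0)
        l = choice.SubjectParams("loss", 1.0, 0.0, 1.0)
        att = choice.transform_attitudes(g, l)
        assert att.as_dict() == {
            "risk_gain": 0.0, "risk_loss": 0.0, "amb_gain": 0.0, "amb_loss": 0.0,
        }

    def test_transform_directions(self):
        g = choice.SubjectParams("gain", 0.8, 0.4, 1.0)
        l = choice.SubjectParams("loss", 1.1, -0.3, 1.0)
        att = choice.transform_attitudes(g, l)
        assert att.risk_gain == pytest.approx(-0.2)   # alpha - 1: averse
        assert att.risk_loss == pytest.approx(-0.1)   # 1 - alpha
        assert att.amb_gain == pytest.approx(-0.4)    # -beta
        assert att.amb_loss == pytest.approx(-0.3)    # beta: averse


class TestCatchQuality:
    def _catch_frame(self, n_inferior, n_total=12):
        # 6 gain catch trials (inferior = chose lottery), 6 loss (inferior = chose sure)
        rows = []
        for i in range(n_total):
            domain = "gain" if i < n_total // 2 else "loss"
            inferior = i < n_inferior
            chose = inferior if domain == "gain" else not inferior
            rows.append({"trial_id": i, "domain": domain, "chose_lottery": chose})
        return pd.DataFrame(rows)

    @pytest.mark.parametrize(
        "n_inferior, expect_pass", [(0, True), (6, True), (7, False), (12, False)]
    )
    def test_strict_majority_rule(self, n_inferior, expect_pass):
        q = choice.catch_trial_quality(self._catch_frame(n_inferior), range(12))
        assert q.passed is expect_pass
        assert q.inferior_fraction == pytest.approx(n_inferior / 12)

    def test_simulated_sensible_agent_passes(self, full_design, schedule, one_subject):
        ch = cohort.simulate_choices(one_subject, schedule, seed=0)
        merged = ch.merge(full_design, on="trial_id")
        catch = design.identify_catch_trials(full_design)["trial_id"]
        assert choice.catch_trial_quality(merged, catch).passed
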