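"""Mixed-model recipes: standardization, R^2, Holm, recovery, coverage,
power, and cross-checks against lme4 as an independent backend."""

import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest

from vrintercept.config import SelfReportTruth
from vrintercept.models import (ModelError, effect_label, fit_appraisal_model,
                                fit_condition_model,
                                fit_error_dependency_model, fit_lmm,
                                fit_logistic_mm, fit_outcome_model,
                                holm_adjust, holm_followups, r_squared,
                                reproduce_reported_models, simulate_power,
                                standardized_betas)
from vrintercept.synthdata import generate_selfreports


def _check_fit_invariants(fit):
    assert 0.0 <= fit.r2_marginal <= fit.r2_conditional <= 1.0
    for term in fit.params.index:
        assert fit.conf_int.loc[term, "lower"] <= fit.params[term] \
            <= fit.conf_int.loc[term, "upper"]


class TestStandardization:
    def test_identity_case(self):
        params = pd.Series({"x": 0.5})
        design = pd.DataFrame({"x": np.repeat([0.0, 1.0, 2.0], 20)})  # sd != 1
        design["x"] = (design["x"] - design["x"].mean()) / design["x"].std(ddof=1)
        y = np.random.default_rng(0).normal(0, 1, 60)
        y = (y - y.mean()) / y.std(ddof=1)
        out = standardized_betas(params, design, y)
        assert out["x"] == pytest.approx(0.5, rel=1e-9)
        assert effect_label(out["x"]) == "moderate"

    def test_sd_rescaling_boundary_moderate(self):
        rng = np.random.default_rng(1)
        design = pd.DataFrame({"x": rng.normal(0, 2, 500)})
        design["x"] *= 2 / design["x"].std(ddof=1)
        y = rng.normal(0, 5, 500)
        y *= 5 / y.std(ddof=1)
        out = standardized_betas(pd.Series({"x": 0.5}), design, y)
        # 0.5 * 2 / 5 = 0.2 exactly: the boundary is assigned upward
        assert out["x"] == pytest.approx(0.2, rel=1e-9)
        assert effect_label(out["x"]) == "moderate"

    def test_label_bands(self):
        assert effect_label(0.19) == "weak"
        assert effect_label(-0.35) == "moderate"
        assert effect_label(0.51) == "strong"

    def test_zero_variance_outcome_rejected(self):
        with pytest.raises(ModelError, match="zero variance"):
            standardized_betas(pd.Series({"x": 1.0}),
                               pd.DataFrame({"x": [0.0, 1.0]}),
                               np.array([2.0, 2.0]))


class TestRSquared:
    def test_no_fixed_effects(self):
        m, c = r_squared(0.0, 1.0, 1.0)
        assert m == 0.0 and c == pytest.approx(0.5)

    def test_deterministic_limit(self):
        m, c = r_squared(1.0, 0.0, 0.0)
        assert m == 1.0 and c == 1.0

    def test_bounds_on_real_fits(self, probe_design):
        d = generate_selfreports(probe_design, SelfReportTruth(),
                                 np.random.default_rng(2))
        for fit in (fit_condition_model(d, "pof"), fit_appraisal_model(d)):
            _check_fit_invariants(fit)


class TestHolm:
    def test_two_p_closed_form(self):
        np.testing.assert_allclose(holm_adjust([0.01, 0.04]), [0.02, 0.04])

    def test_single_contrast_unchanged(self):
        np.testing.assert_allclose(holm_adjust([0.03]), [0.03])

    def test_three_equal_ps(self):
        np.testing.assert_allclose(holm_adjust([0.05, 0.05, 0.05]), [0.15] * 3)

    def test_adjustment_monotone_and_never_smaller(self):
        rng = np.random.default_rng(0)
        p = rng.random(10)
        adj = holm_adjust(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_followup_contrasts(self, probe_design):
        d = generate_selfreports(probe_design, SelfReportTruth(),
                                 np.random.default_rng(3))
        out = holm_followups(
            d, "cof",
            [("pressure @ low feedback", "feedback == 0", "pressure", ""),
             ("pressure @ high feedback", "feedback == 1", "pressure", "")])
        assert len(out) == 2
        assert (out["p_holm"] >= out["p_raw"] - 1e-12).all()
        # the generator's truth has the pressure effect only under high feedback
        assert out.set_index("contrast").loc["pressure @ high feedback", "p_holm"] \
            < 0.05


class TestConditionAndAppraisalModels:
    def test_single_dataset_recovery(self, probe_design):
        d = generate_selfreports(probe_design, SelfReportTruth(),
                                 np.random.default_rng(4))
        fit = fit_condition_model(d, "pof")
        ci = fit.conf_int.loc["feedback"]
        se = (ci["upper"] - ci["lower"]) / (2 * 1.96)
        assert abs(fit.params["feedback"] - 0.46) < 3 * se
        _check_fit_invariants(fit)

    def test_type_one_error_near_nominal(self):
        # null truth: rejection rate of the feedback test ~ alpha
        truth = SelfReportTruth(beta_feedback_on_pof=0.0,
                                beta_pressure_on_pof=0.0,
                                beta_interaction_on_pof=0.0)
        rows = [{"participant": p, "pressure": pr, "feedback": fe}
                for p in range(20) for (pr, fe) in
                [(0, 0), (0, 1), (1, 0), (1, 1)] for _ in range(2)]
        design = pd.DataFrame(rows)
        reps, hits = 200, 0
        for r in range(reps):
            d = generate_selfreports(design, truth, np.random.default_rng(r))
            hits += fit_condition_model(d, "pof").pvalues["feedback"] < 0.05
        rate = hits / reps
        assert abs(rate - 0.05) < 2.5 * np.sqrt(0.05 * 0.95 / reps) + 0.02

    def test_degenerate_appraisal_inputs_rejected(self, probe_design):
        d = probe_design.copy()
        d["pof"], d["cof"] = 3.0, 3.0
        d["anxiety"] = np.random.default_rng(0).normal(3, 1, len(d))
        with pytest.raises(ModelError, match="zero variance"):
            fit_appraisal_model(d)

    def test_too_few_participants_rejected(self):
        d = pd.DataFrame({"participant": [0] * 8, "pressure": [0, 1] * 4,
                          "feedback": [0, 0, 1, 1] * 2,
                          "pof": np.arange(8.0)})
        with pytest.raises(ModelError, match="participants"):
            fit_condition_model(d, "pof")


class TestOutcomeModels:
    def test_null_anxiety_coupling_coverage(self, probe_design):
        # outcome independent of anxiety: the anxiety CI should cover zero
        # at roughly the nominal rate
        truth = SelfReportTruth()
        covered = 0
        reps = 60
        for r in range(reps):
            rng = np.random.default_rng(500 + r)
            d = generate_selfreports(probe_design, truth, rng)
            u = rng.normal(0, 2.0, 43)
            d["bounce_fix_pitch"] = -21.0 + u[d["participant"]] \
                + rng.normal(0, 1.0, len(d))
            fit = fit_outcome_model(d, "bounce_fix_pitch")
            ci = fit.conf_int.loc["anxiety"]
            covered += ci["lower"] <= 0.0 <= ci["upper"]
        assert covered >= int(0.87 * reps)

    def test_constant_outcome_rejected(self, probe_design):
        d = generate_selfreports(probe_design, SelfReportTruth(),
                                 np.random.default_rng(6))
        d["peak_swing_velocity"] = 4.0
        with pytest.raises(ModelError, match="zero variance"):
            fit_outcome_model(d, "peak_swing_velocity")

    def test_all_intercepted_is_separation_error(self, probe_design):
        d = generate_selfreports(probe_design, SelfReportTruth(),
                                 np.random.default_rng(7))
        d["intercepted"] = 1
        with pytest.raises(ModelError, match="constant"):
            fit_outcome_model(d, "intercepted")

    def test_error_dependency_null_coverage(self, probe_design):
        rng = np.random.default_rng(8)
        covered = 0
        reps = 25
        for _ in range(reps):
            n = 30
            rows = []
            for p in range(n):
                m = 40
                rows.append(pd.DataFrame({
                    "participant": p,
                    "prior_errors": rng.integers(0, 5, m),
                    "carried_anxiety": rng.normal(3, 1, m),
                }))
            d = pd.concat(rows, ignore_index=True)
            u = rng.normal(0, 0.7, n)
            eta = 0.6 + u[d["participant"]]
            d["intercepted"] = rng.binomial(1, 1 / (1 + np.exp(-eta)))
            fit = fit_error_dependency_model(d)
            ci = fit.conf_int.loc["prior_errors"]
            covered += ci["lower"] <= 0.0 <= ci["upper"]
        assert covered >= reps - 4


class TestAgainstLme4:
    """Cross-check both backends against lme4 on one small fixture."""

    @pytest.fixture(scope="class")
    def fixture_df(self):
        rng = np.random.default_rng(42)
        n, m = 24, 12
        pid = np.repeat(np.arange(n), m)
        x1 = rng.normal(0, 1, n * m)
        x2 = np.tile(np.repeat([0.0, 1.0], m // 2), n)
        u = rng.normal(0, 0.8, n)[pid]
        y = 1.0 + 0.4 * x2 + 0.3 * x1 + u + rng.normal(0, 0.9, n * m)
        eta = -0.2 + 0.5 * x2 + 0.25 * x1 + u
        yb = rng.binomial(1, 1 / (1 + np.exp(-eta)))
        return pd.DataFrame({"participant": pid, "x1": x1, "x2": x2,
                             "y": y, "yb": yb})

    def test_lmm_and_glmm_match_lme4(self, fixture_df, tmp_path):
        csv = tmp_path / "fix.csv"
        fixture_df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            f1 <- lmer(y ~ x1 + x2 + (1|participant), data=d, REML=TRUE)
            f2 <- glmer(yb ~ x1 + x2 + (1|participant), data=d, family=binomial)
            cat(fixef(f1), "\\n")
            cat(as.data.frame(VarCorr(f1))$vcov, "\\n")
            cat(fixef(f2), "\\n")
            cat(as.data.frame(VarCorr(f2))$vcov[1], "\\n")
        """))
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        lines = [np.fromstring(l, sep=" ") for l in out.stdout.strip().splitlines()]
        r_fe_lin, r_vc_lin, r_fe_log, r_vu_log = lines

        ours_lin = fit_lmm("y ~ x1 + x2", fixture_df)
        np.testing.assert_allclose(ours_lin.params.to_numpy(), r_fe_lin,
                                   rtol=1e-4, atol=1e-5)
        np.testing.assert_allclose([ours_lin.var_random, ours_lin.var_resid],
                                   r_vc_lin, rtol=1e-3)

        ours_log = fit_logistic_mm("yb ~ x1 + x2", fixture_df)
        np.testing.assert_allclose(ours_log.params.to_numpy(), r_fe_log,
                                   rtol=0.02, atol=0.01)
        np.testing.assert_allclose(ours_log.var_random, r_vu_log,
                                   rtol=0.05, atol=0.02)


class TestReproductionSuite:
    def test_full_suite_on_synthetic_study(self, probe_design):
        rng = np.random.default_rng(9)
        d = generate_selfreports(probe_design, SelfReportTruth(), rng)
        u = rng.normal(0, 1.5, 43)
        d["bounce_fix_pitch"] = -21 + u[d.participant] + rng.normal(0, 1, len(d))
        d["bounce_fix_duration"] = np.clip(
            0.5 + 0.1 * u[d.participant] + rng.normal(0, 0.1, len(d)), 0.1, None)
        d["peak_swing_velocity"] = 4 + 0.3 * u[d.participant] \
            + rng.normal(0, 0.3, len(d))
        eta = 0.8 + 0.5 * u[d.participant]
        d["intercepted"] = rng.binomial(1, 1 / (1 + np.exp(-eta)))
        fits = reproduce_reported_models(d)
        expected = {"condition_pof", "condition_cof", "condition_anxiety",
                    "appraisal_anxiety", "outcome_bounce_fix_pitch",
                    "outcome_bounce_fix_duration",
                    "outcome_peak_swing_velocity", "outcome_intercepted"}
        assert expected <= set(fits)
        for fit in fits.values():
            _check_fit_invariants(fit)


class TestPower:
    def test_null_effect_power_near_alpha(self):
        out = simulate_power(0.0, 43, reps=100, seed=11)
        p = out["power"].iloc[0]
        assert abs(p - 0.05) <= 2 * np.sqrt(0.05 * 0.95 / 100) + 0.01

    def test_power_monotone_in_effect_and_n(self):
        lo = simulate_power(0.08, 12, obs_per_participant=8, reps=80, seed=12)
        hi_n = simulate_power(0.08, 43, obs_per_participant=8, reps=80, seed=13)
        hi_eff = simulate_power(0.3, 12, obs_per_participant=8, reps=80, seed=14)
        assert hi_n["power"].iloc[0] >= lo["power"].iloc[0] - 0.1
        assert hi_eff["power"].iloc[0] >= lo["power"].iloc[0] - 0.1

    def test_reproducible_under_seed(self):
        a = simulate_power(0.1, 20, obs_per_participant=8, reps=60, seed=3)
        b = simulate_power(0.1, 20, obs_per_participant=8, reps=60, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_reps_rejected(self):
        with pytest.raises(ModelError, match="reps"):
            simulate_power(0.2, 10, reps=10)
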