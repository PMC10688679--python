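"""Odds-ratio estimation: aggregation, PQL fits, sensitivity terms, GLS route."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from mdisw import (
    CorrelationModel,
    FitError,
    GenerativeParams,
    ModelSpec,
    aggregate_cluster_periods,
    fit_per_standard,
    fit_primary,
    fit_sensitivity,
    gls_wald,
    simulate_trial,
)
from mdisw.inference import _fallback_ladder
from mdisw.power_calc import binary_sigma2


class TestAggregation:
    def test_design_A_aggregates_to_240_cells(self, design_A_schedules):
        rec = simulate_trial(design_A_schedules, GenerativeParams(m=25), seed=0)
        agg = aggregate_cluster_periods(rec)
        assert len(agg) == 240
        assert (agg["n"] == 25).all()

    def test_totals_preserved(self, design_B_schedules):
        rec = simulate_trial(design_B_schedules, GenerativeParams(m=7), seed=1)
        agg = aggregate_cluster_periods(rec)
        assert agg["n_compliant"].sum() == rec["compliant"].sum()
        assert agg["n"].sum() == len(rec)

    def test_empty_input_gives_empty_table(self):
        agg = aggregate_cluster_periods(pd.DataFrame(columns=["facility_id"]))
        assert agg.empty


class TestFitPrimary:
    def test_recovers_simulated_odds_ratio(self, design_B_schedules):
        params = GenerativeParams(mu=0.2, theta=np.log(2), sigma_u=0.3, sigma_w=0.2)
        rec = simulate_trial(design_B_schedules, params, seed=42)
        fit = fit_primary(rec)
        assert fit.converged
        assert fit.fallback_applied is None
        assert abs(fit.theta_hat - np.log(2)) < 3 * fit.se
        lo, hi = fit.ci95
        assert np.isclose(lo, np.exp(fit.theta_hat - 1.96 * fit.se))
        assert np.isclose(hi, np.exp(fit.theta_hat + 1.96 * fit.se))
        assert set(fit.variance_components) == {"facility", "facility_month"}

    def test_flat_data_gives_unit_odds_ratio(self, design_B_schedules):
        """Cells whose compliance depends on month alone (identical counts in
        control and intervention cells of the same month) yield OR ~ 1."""
        from mdisw import event_table

        ev = event_table(design_B_schedules)
        agg = ev.copy()
        agg["n"] = 20
        agg["n_compliant"] = 8 + (agg["month"] % 3)  # month-driven trend only
        fit = fit_primary(agg)
        assert fit.converged
        assert abs(fit.theta_hat) < 0.05
        assert 0.9 < fit.or_hat < 1.1

    def test_single_exposure_state_rejected(self, design_B_schedules):
        rec = simulate_trial(design_B_schedules, GenerativeParams(m=3), seed=0)
        with pytest.raises(FitError):
            fit_primary(rec[rec["exposure"] == 0])

    def test_accepts_client_level_and_aggregated(self, design_B_schedules):
        rec = simulate_trial(design_B_schedules, GenerativeParams(theta=0.4), seed=7)
        f1 = fit_primary(rec)
        f2 = fit_primary(aggregate_cluster_periods(rec))
        assert np.isclose(f1.theta_hat, f2.theta_hat)
        assert np.isclose(f1.se, f2.se)


class TestFitSensitivity:
    def test_reference_spec_matches_fit_primary(self, design_B_schedules):
        rec = simulate_trial(design_B_schedules, GenerativeParams(theta=0.5), seed=3)
        f1 = fit_primary(rec)
        f2 = fit_sensitivity(rec, ModelSpec())
        assert f1.theta_hat == f2.theta_hat

    def test_common_effect_yields_null_interaction(self, design_B_schedules):
        """When the audit benefit is common to all standards, the
        intervention x standard Wald tests are non-significant in at least
        90% of replicates."""
        spec = ModelSpec(
            fixed_terms=("intervention", "month", "standard", "intervention_x_standard"),
            random_terms=("facility", "facility_month"),
        )
        params = GenerativeParams(mu=0.0, theta=np.log(2), sigma_u=0.3, sigma_w=0.2)
        n_sig = 0
        n_rep = 40
        for s in range(n_rep):
            rec = simulate_trial(design_B_schedules, params, seed=5000 + s)
            fit = fit_sensitivity(rec, spec)
            assert fit.converged
            inter = [
                abs(v) / fit.fixed_effect_ses[k]
                for k, v in fit.fixed_effects.items()
                if k.startswith("intervention:")
            ]
            # Bonferroni Wald screen over the five interaction contrasts
            n_sig += any(z > 2.576 for z in inter)
        assert n_sig <= 0.1 * n_rep + 2

    def test_facility_standard_random_term_estimable_on_design_A(
        self, design_A_schedules
    ):
        params = GenerativeParams(
            mu=0.0, theta=np.log(2.8), sigma_u=0.3, sigma_w=0.2, sigma_fs=0.2
        )
        rec = simulate_trial(design_A_schedules, params, seed=11)
        spec = ModelSpec(
            fixed_terms=("intervention", "month", "standard"),
            random_terms=("facility", "facility_month", "facility_standard"),
        )
        fit = fit_sensitivity(rec, spec)
        assert fit.converged
        assert fit.variance_components.get("facility_standard", 0) > 0

    def test_fallback_ladder_order(self):
        spec = ModelSpec(
            fixed_terms=("intervention", "month", "standard"),
            random_terms=("facility", "facility_month", "facility_standard"),
        )
        ladder = _fallback_ladder(spec)
        assert ladder[0][1] is None
        assert "facility x month" in ladder[1][1]
        # final rung mirrors dropping month fixed effect and facility intercept
        final_spec, note = ladder[2]
        assert "month" not in final_spec.fixed_terms
        assert "facility" not in final_spec.random_terms
        assert "facility_standard" in final_spec.random_terms
        assert "month fixed effect" in note

    def test_lag_term_estimates_attenuation(self, design_B_schedules):
        params = GenerativeParams(
            mu=0.0, theta=1.2, lag_coef=-0.15, sigma_u=0.2, sigma_w=0.1
        )
        rec = simulate_trial(design_B_schedules, params, seed=21)
        spec = ModelSpec(
            fixed_terms=("intervention", "month", "standard", "lag"),
            random_terms=("facility", "facility_month"),
        )
        fit = fit_sensitivity(rec, spec)
        assert fit.converged
        assert fit.fixed_effects["lag"] < 0

    def test_unknown_terms_rejected(self):
        with pytest.raises(FitError):
            ModelSpec(fixed_terms=("intervention", "weekday"))
        with pytest.raises(FitError):
            ModelSpec(fixed_terms=("month",))


class TestPerStandard:
    def test_warns_and_fits(self, design_B_schedules):
        params = GenerativeParams(mu=0.0, theta=np.log(2), sigma_u=0.2, sigma_w=0.1)
        rec = simulate_trial(design_B_schedules, params, seed=8)
        with pytest.warns(UserWarning, match="caution"):
            fit = fit_per_standard(rec, "Sa")
        assert np.isfinite(fit.theta_hat)


class TestAgreementWithIndependentFitters:
    def test_matches_lme4_glmer(self, design_B_schedules, tmp_path):
        """The PQL estimate agrees with lme4's Laplace fit of the same model
        on the same aggregated data (independent implementation)."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        params = GenerativeParams(mu=0.2, theta=np.log(2), sigma_u=0.3, sigma_w=0.2)
        rec = simulate_trial(design_B_schedules, params, seed=42)
        agg = aggregate_cluster_periods(rec)
        fit = fit_primary(agg)
        csv = tmp_path / "agg.csv"
        agg.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            textwrap.dedent(
                f"""
                suppressMessages(library(lme4))
                agg <- read.csv("{csv}")
                agg$month <- factor(agg$month)
                agg$standard <- factor(agg$standard)
                agg$fm <- interaction(agg$facility_id, agg$month)
                m <- glmer(cbind(n_compliant, n - n_compliant) ~ exposure + month +
                           standard + (1 | facility_id) + (1 | fm),
                           data = agg, family = binomial)
                s <- summary(m)
                cat(fixef(m)["exposure"], s$coefficients["exposure", "Std. Error"], "\\n")
                """
            )
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        theta_r, se_r = map(float, out.stdout.split()[-2:])
        assert abs(fit.theta_hat - theta_r) < 0.05
        assert abs(fit.se - se_r) / se_r < 0.1

    def test_agrees_with_gaussian_gls_route(self, design_B_schedules):
        """With large cluster-periods and a small effect, the GLMM log-odds
        estimate, converted through the logistic density at p = 1/2, tracks
        the aggregated Gaussian GLS estimate within 10% relative error."""
        params = GenerativeParams(
            mu=0.0, theta=0.3, sigma_u=0.05, sigma_w=0.05, m=200
        )
        rec = simulate_trial(design_B_schedules, params, seed=13)
        glmm = fit_primary(rec)
        gls = gls_wald(rec, binary_sigma2(0.5, 0.57), CorrelationModel(0.01, 1.0))
        # d p / d logit = p (1 - p) ~ 1/4 at p ~ 0.5
        assert abs(glmm.theta_hat * 0.25 - gls["theta_hat"]) < 0.1 * abs(
            gls["theta_hat"]
        )
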