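"""Mixed-model machinery: marginal likelihood, AICc, LRT, contrasts,
residual diagnostics."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from rankwatch import glmm
from rankwatch.errors import DomainError, SeparationError


def toy_table(rng, n, groups=("A", "B"), activity=True):
    acts = ["calm", "moderate", "frenetic"] if activity else ["calm"]
    return pd.DataFrame(
        {
            "individual_id": rng.choice(list(groups), size=n),
            "outcome": rng.integers(0, 2, size=n),
            "elo_z": rng.normal(size=n),
            "crowd_size_value": rng.choice([5.0, 15.0, 25.0], size=n),
            "crowd_activity": rng.choice(acts, size=n),
        }
    )


def simulated_table(rng, n_groups=10, n_per=80, beta0=-0.5, b_elo=0.8, sigma=0.7):
    rows = []
    for g in range(n_groups):
        b = rng.normal(0, sigma)
        z = rng.normal(size=n_per)
        act = rng.choice(["calm", "moderate", "frenetic"], size=n_per)
        eta = beta0 + b_elo * z + 0.4 * (act == "frenetic") + b
        y = (rng.random(n_per) < expit(eta)).astype(int)
        for j in range(n_per):
            rows.append((f"G{g}", y[j], z[j], 15.0, act[j]))
    return pd.DataFrame(
        rows, columns=["individual_id", "outcome", "elo_z", "crowd_size_value", "crowd_activity"]
    )


def trapezoid_loglik(table, spec, beta, sigma):
    """Brute-force marginal log-likelihood: 501-node trapezoid over +/-10 sigma."""
    X, _ = glmm.design_matrix(table, spec)
    y = table["outcome"].to_numpy(float)
    total = 0.0
    for gid in sorted(table["individual_id"].unique()):
        m = (table["individual_id"] == gid).to_numpy()
        b = np.linspace(-10 * sigma, 10 * sigma, 501)
        eta = (X[m] @ beta)[:, None] + b[None, :]
        lik = np.prod(np.where(y[m][:, None] == 1, expit(eta), 1 - expit(eta)), axis=0)
        dens = np.exp(-0.5 * (b / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
        total += np.log(np.trapezoid(lik * dens, b))
    return total


class TestDesignMatrix:
    def test_reference_coding(self):
        table = pd.DataFrame(
            {
                "individual_id": ["A"] * 3,
                "outcome": [0, 1, 0],
                "elo_z": [0.0, 1.0, -1.0],
                "crowd_size_value": [5.0, 15.0, 25.0],
                "crowd_activity": ["calm", "moderate", "frenetic"],
            }
        )
        X, names = glmm.design_matrix(table, glmm.ModelSpec(("crowd_activity",)))
        assert names == ["Intercept", "crowd_activity[moderate]", "crowd_activity[frenetic]"]
        assert X[0].tolist() == [1.0, 0.0, 0.0]  # calm row: reference level
        assert X[1].tolist() == [1.0, 1.0, 0.0]
        assert X[2].tolist() == [1.0, 0.0, 1.0]

    def test_terms_canonically_ordered(self):
        a = glmm.ModelSpec(("crowd_activity", "elo_z"))
        b = glmm.ModelSpec(("elo_z", "crowd_activity"))
        assert a == b and a.label == "Rank + Crowd Activity"


class TestMarginalLikelihood:
    def test_matches_brute_force_integration(self):
        rng = np.random.default_rng(42)
        spec = glmm.ModelSpec(("elo_z",))
        worst = 0.0
        for _ in range(100):
            table = toy_table(rng, int(rng.integers(4, 11)))
            beta = rng.normal(size=2)
            sigma = rng.uniform(0.2, 2.0)
            ll = glmm.marginal_loglik(table, spec, beta, sigma)
            worst = max(worst, abs(ll - trapezoid_loglik(table, spec, beta, sigma)))
        assert worst < 1e-4

    def test_six_row_two_group_toy(self):
        table = pd.DataFrame(
            {
                "individual_id": ["A", "A", "A", "B", "B", "B"],
                "outcome": [1, 0, 1, 0, 0, 1],
                "elo_z": [0.5, -0.3, 1.1, -0.9, 0.2, 0.4],
                "crowd_size_value": [5.0] * 6,
                "crowd_activity": ["calm"] * 6,
            }
        )
        spec = glmm.ModelSpec(("elo_z",))
        beta, sigma = np.array([0.3, -0.6]), 0.8
        assert glmm.marginal_loglik(table, spec, beta, sigma) == pytest.approx(
            trapezoid_loglik(table, spec, beta, sigma), abs=1e-4
        )


class TestFitGLMM:
    def test_sigma_zero_equals_plain_logistic(self):
        rng = np.random.default_rng(5)
        table = simulated_table(rng, n_groups=6, n_per=50)
        spec = glmm.ModelSpec(("elo_z", "crowd_activity"))
        fit = glmm.fit_glmm(table, spec, fix_sigma=0.0)
        X, _ = glmm.design_matrix(table, spec)
        ref = sm.Logit(table["outcome"].to_numpy(), X).fit(disp=0)
        assert np.abs(fit.beta - np.asarray(ref.params)).max() < 1e-6
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)

    def test_intercept_only_closed_form(self):
        table = pd.DataFrame(
            {
                "individual_id": ["A"] * 10,
                "outcome": [1, 1] + [0] * 8,
                "elo_z": 0.0,
                "crowd_size_value": 5.0,
                "crowd_activity": "calm",
            }
        )
        fit = glmm.fit_glmm(table, glmm.ModelSpec(()), fix_sigma=0.0)
        assert fit.coefficients["Intercept"] == pytest.approx(np.log(0.2 / 0.8), abs=1e-6)

    def test_recovers_moderate_scale_parameters(self):
        rng = np.random.default_rng(17)
        table = simulated_table(rng, n_groups=30, n_per=120, b_elo=0.8, sigma=0.7)
        fit = glmm.fit_glmm(table, glmm.ModelSpec(("elo_z", "crowd_activity")))
        assert fit.converged
        assert fit.coefficients["elo_z"] == pytest.approx(0.8, abs=0.15)
        assert fit.sigma_b == pytest.approx(0.7, abs=0.3)
        lo, hi = fit.ci95["elo_z"]
        assert lo < fit.coefficients["elo_z"] < hi

    def test_nested_loglik_ordering(self):
        rng = np.random.default_rng(23)
        table = simulated_table(rng, n_groups=8, n_per=60)
        full = glmm.fit_glmm(table, glmm.ModelSpec(("elo_z", "crowd_size_value", "crowd_activity")))
        reduced = glmm.fit_glmm(table, glmm.ModelSpec(("elo_z",)))
        assert full.loglik >= reduced.loglik - 1e-6

    def test_constant_outcome_rejected(self):
        table = pd.DataFrame(
            {
                "individual_id": ["A", "B"] * 3,
                "outcome": 0,
                "elo_z": np.arange(6, dtype=float),
                "crowd_size_value": 5.0,
                "crowd_activity": "calm",
            }
        )
        with pytest.raises(DomainError):
            glmm.fit_glmm(table, glmm.ModelSpec(("elo_z",)))

    def test_complete_separation_names_term(self):
        table = pd.DataFrame(
            {
                "individual_id": ["A", "B"] * 10,
                "outcome": [0, 1] * 10,
                "elo_z": [-1.0, 1.0] * 10,
                "crowd_size_value": 5.0,
                "crowd_activity": "calm",
            }
        )
        with pytest.raises(SeparationError, match="elo_z"):
            glmm.fit_glmm(table, glmm.ModelSpec(("elo_z",)))

    def test_wald_interval_coverage_frenetic(self):
        """Nominal 95% Wald intervals for the frenetic coefficient cover the
        generating value at roughly the nominal rate over 50 reduced-scale
        simulated datasets."""
        from rankwatch.pipeline import outcome_table_from_bundle
        from rankwatch.simulate import SyntheticConfig, generate

        spec = glmm.ModelSpec(("elo_z", "crowd_activity"))
        covered = 0
        for seed in range(50):
            cfg = SyntheticConfig(
                n_subjects=12, n_weeks=8, n_sessions=300, n_agonistic=250,
                sigma_b=0.5, beta0=-2.0, seed=20_000 + seed,
            )
            bundle, truth = generate(cfg)
            table, _, _ = outcome_table_from_bundle(bundle, cfg.start_date, cfg.n_weeks)
            fit = glmm.fit_glmm(table, spec)
            lo, hi = fit.ci95["crowd_activity[frenetic]"]
            covered += lo <= truth.coefficients["crowd_activity[frenetic]"] <= hi
        assert 0.85 <= covered / 50 <= 1.0

    def test_random_slope_variant_fits(self):
        rng = np.random.default_rng(31)
        table = simulated_table(rng, n_groups=8, n_per=60)
        fit = glmm.fit_glmm(
            table, glmm.ModelSpec(("elo_z",), random_slope=True), quadrature_nodes=7
        )
        assert fit.converged and fit.sigma_slope is not None and fit.sigma_slope >= 0


class TestAICc:
    def _fake_fit(self, loglik, k, n):
        rng = np.random.default_rng(0)
        fit = glmm.fit_glmm(
            simulated_table(rng, n_groups=4, n_per=20), glmm.ModelSpec(("elo_z",))
        )
        fit.loglik, fit.n_params, fit.n_obs = loglik, k, n
        return fit

    def test_closed_form(self):
        assert glmm.aicc(self._fake_fit(-10.0, 2, 10)) == pytest.approx(24 + 12 / 7)

    def test_correction_positive_and_vanishing(self):
        vals = [glmm.aicc(self._fake_fit(-10.0, 2, n)) for n in (10, 100, 10_000)]
        assert all(v > 24.0 for v in vals)  # AICc > AIC
        assert vals == sorted(vals, reverse=True)  # monotone toward AIC
        assert vals[-1] == pytest.approx(24.0, abs=0.01)

    def test_small_n_rejected(self):
        with pytest.raises(DomainError):
            glmm.aicc(self._fake_fit(-10.0, 5, 6))


@pytest.fixture(scope="module")
def comparison_table():
    rng = np.random.default_rng(41)
    return simulated_table(rng, n_groups=8, n_per=60)


class TestCompareModels:
    @pytest.fixture
    def table(self, comparison_table):
        return comparison_table

    def test_seven_candidates_ranked(self, table):
        comp = glmm.compare_models(table)
        assert len(comp.table) == 7
        assert sorted(comp.table["rank"]) == list(map(float, range(1, 8)))
        aiccs = comp.table.sort_values("rank")["AICc"].to_numpy()
        assert (np.diff(aiccs) >= 0).all()

    def test_submission_order_invariance(self, table):
        cands = glmm.default_candidates()
        a = glmm.compare_models(table, cands)
        b = glmm.compare_models(table, list(reversed(cands)))
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_duplicate_spec_tie_break_deterministic(self, table):
        spec = glmm.ModelSpec(("elo_z",))
        comp = glmm.compare_models(table, [spec, glmm.ModelSpec(("elo_z",))])
        assert comp.table["AICc"].nunique() == 1
        assert sorted(comp.table["rank"]) == [1.0, 2.0]


class TestLRT:
    def _fit_pair(self):
        rng = np.random.default_rng(53)
        table = simulated_table(rng, n_groups=8, n_per=60)
        full = glmm.fit_glmm(table, glmm.ModelSpec(("elo_z", "crowd_activity")))
        red = glmm.fit_glmm(table, glmm.ModelSpec(("elo_z",)))
        return full, red

    def test_chi_square_tail_oracle(self):
        full, red = self._fit_pair()
        full.loglik, red.loglik = -10.0, -12.0
        full.n_params, red.n_params = 4, 3
        res = glmm.lrt(full, red)
        assert res.chi2 == pytest.approx(4.0)
        assert res.p == pytest.approx(0.0455, abs=1e-4)

    def test_df2_exponential_tail(self):
        # for df=2 the chi-square survival function is exp(-x/2)
        full, red = self._fit_pair()
        full.loglik, red.loglik = -10.0, -10.0 - 5.43 / 2
        res = glmm.lrt(full, red)
        assert res.df == 2
        assert res.p == pytest.approx(np.exp(-5.43 / 2), abs=1e-6)
        assert res.p == pytest.approx(0.0662, abs=1e-4)

    def test_identical_fits_boundary(self):
        full, red = self._fit_pair()
        red.loglik = full.loglik
        res = glmm.lrt(full, red)
        assert res.chi2 == 0.0 and res.p == 1.0

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(59)
        table = simulated_table(rng, n_groups=8, n_per=40)
        a = glmm.fit_glmm(table, glmm.ModelSpec(("elo_z",)))
        b = glmm.fit_glmm(table, glmm.ModelSpec(("crowd_size_value",)))
        with pytest.raises(DomainError):
            glmm.lrt(a, b)


class TestTukey:
    def test_single_contrast_no_multiplicity(self):
        z = np.array([2.0])
        p = glmm.single_step_adjust(z, np.eye(1))
        assert p[0] == pytest.approx(2 * (1 - 0.9772498680518208), abs=1e-9)

    def test_independent_family_closed_form(self):
        from scipy.stats import norm

        z = norm.isf(0.01)  # two-sided p = 0.02
        p = glmm.single_step_adjust(np.array([z, z, z]), np.eye(3))
        assert p == pytest.approx([1 - 0.98**3] * 3, abs=3e-3)

    def test_bracketing_and_pairs(self):
        rng = np.random.default_rng(61)
        table = simulated_table(rng, n_groups=10, n_per=80)
        fit = glmm.fit_glmm(table, glmm.ModelSpec(("elo_z", "crowd_activity")))
        contrasts = glmm.tukey_contrasts(fit)
        assert [c.pair for c in contrasts] == [
            ("moderate", "calm"),
            ("frenetic", "calm"),
            ("frenetic", "moderate"),
        ]
        for c in contrasts:
            assert c.p_unadjusted <= c.p_adjusted <= min(1.0, 3 * c.p_unadjusted) + 1e-12

    def test_requires_activity_term(self):
        rng = np.random.default_rng(67)
        fit = glmm.fit_glmm(simulated_table(rng, n_groups=6, n_per=40), glmm.ModelSpec(("elo_z",)))
        with pytest.raises(DomainError):
            glmm.tukey_contrasts(fit)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(71)
        table = simulated_table(rng, n_groups=8, n_per=60)
        fit = glmm.fit_glmm(table, glmm.ModelSpec(("crowd_activity",)))
        a = glmm.tukey_contrasts(fit)
        b = glmm.tukey_contrasts(fit)
        assert [c.p_adjusted for c in a] == [c.p_adjusted for c in b]


class TestResidualDiagnostics:
    def test_calibrated_fit_mostly_inside_band(self):
        rng = np.random.default_rng(73)
        table = simulated_table(rng, n_groups=12, n_per=150)
        fit = glmm.fit_glmm(table, glmm.ModelSpec(("elo_z", "crowd_activity")))
        diag = glmm.residual_diagnostics(fit, table, n_bins=10)
        assert diag["inside_band"].mean() >= 0.7

    def test_degenerate_binning_no_crash(self):
        rng = np.random.default_rng(79)
        table = simulated_table(rng, n_groups=4, n_per=5)
        fit = glmm.fit_glmm(table, glmm.ModelSpec(()))
        diag = glmm.residual_diagnostics(fit, table, n_bins=100)
        assert len(diag) >= 1
        assert (diag["n"] >= 1).all()

    def test_constant_predictions_single_bin_zero_mean(self):
        rng = np.random.default_rng(83)
        table = simulated_table(rng, n_groups=6, n_per=50)
        fit = glmm.fit_glmm(table, glmm.ModelSpec(()), fix_sigma=0.0)
        diag = glmm.residual_diagnostics(fit, table, n_bins=20)
        assert len(diag) == 1  # all fitted probabilities identical
        assert diag["mean_resid"].iloc[0] == pytest.approx(0.0, abs=1e-5)
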