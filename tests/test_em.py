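import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrlova import (
    CohortData,
    LDMatrix,
    NoValidInstrumentsError,
    e_step,
    estimate_cov_yc,
    fit,
    fit_individual,
    inclusion_indicator,
    ld_adjust,
    m_step_ivw,
)
from mrlova.summary_io import exposure_pvalues

from conftest import synthetic_panel


class TestCovYC:
    def test_all_null_outcome_effects_give_zero(self):
        panel = synthetic_panel(m=5, noise=False)
        assert estimate_cov_yc(panel) == 0.0

    def test_single_nonzero_pair(self):
        panel = synthetic_panel(b_true=[0.2, 0.05], noise=False)
        object.__setattr__(panel, "g_hat", np.array([0.1, 0.0]))
        assert estimate_cov_yc(panel) == pytest.approx(0.02)

    def test_clipped_inside_unit_interval(self):
        panel = synthetic_panel(b_true=[2.0, 2.0], noise=False)
        object.__setattr__(panel, "g_hat", np.array([2.0, 2.0]))
        cov = estimate_cov_yc(panel)
        assert cov < 1.0  # keeps var(upsilon) positive for every tau

    def test_recovers_genetic_covariance_of_simulated_panel(self):
        # oracle: the population genetic covariance tau*sum(b^2) + sum(b*u)
        # of the standardized summary-level model
        rng = np.random.default_rng(11)
        n, m, tau = 200_000, 60, 0.15
        b = rng.uniform(0.03, 0.10, m)
        u = np.where(rng.random(m) < 0.3, rng.normal(0.05, 0.02, m), 0.0)
        panel = synthetic_panel(b_true=b, u=u, tau=tau, n=n, seed=7)
        truth = tau * float(b @ b) + float(b @ u)
        # sampling error of sum of m products of N(.,1/n) terms
        assert estimate_cov_yc(panel) == pytest.approx(truth, abs=5 * np.sqrt(m / n))

    def test_single_snp_rejected(self):
        panel = synthetic_panel(m=1)
        with pytest.raises(ValueError):
            estimate_cov_yc(panel)


class TestESTep:
    def test_tau_zero_is_identity(self, panel_factory):
        panel = panel_factory(m=20, seed=1)
        u, var_u = e_step(panel, 0.0, 0.3)
        assert np.array_equal(u, panel.g_hat)
        assert np.array_equal(var_u, panel.se_g**2)

    def test_direct_substitution(self):
        panel = synthetic_panel(b_true=[0.20, 0.05], n=10_000, noise=False)
        object.__setattr__(panel, "g_hat", np.array([0.10, 0.0]))
        u, var_u = e_step(panel, 0.5, 0.3)
        assert u[0] == pytest.approx(0.0)
        # var = 1e-4 + (0.25 - 0.3)/1e4
        assert var_u[0] == pytest.approx(9.5e-5)

    def test_variance_formula_example(self):
        panel = synthetic_panel(b_true=[0.1, 0.1], n=10_000, noise=False)
        _, var_u = e_step(panel, 0.2, 0.3)
        assert np.allclose(var_u, 9.2e-5)


class TestInclusion:
    def test_null_direct_effect_with_strong_instrument_included(self):
        inc = inclusion_indicator([0.0], [1e-4], [0.1], [0.01])
        assert inc.tolist() == [True]  # |z_b| = 10

    def test_weak_instrument_always_excluded(self):
        inc = inclusion_indicator([0.0], [1e-4], [0.01], [0.01])
        assert inc.tolist() == [False]  # |z_b| = 1

    def test_significant_direct_effect_excluded(self):
        inc = inclusion_indicator([0.03], [1e-4], [0.1], [0.01])
        assert inc.tolist() == [False]  # |z_u| = 3, p ~ 0.0027


class TestMStep:
    def test_single_instrument_ratio(self):
        assert m_step_ivw([0.05], [1e-4], [0.25], [True]) == pytest.approx(0.2)

    def test_null_direct_effects_give_zero(self):
        assert m_step_ivw([0.0, 0.0], [1e-4, 2e-4], [0.1, 0.2], [True, True]) == 0.0

    def test_empty_selection_raises(self):
        with pytest.raises(NoValidInstrumentsError):
            m_step_ivw([0.1], [1e-4], [0.1], [False])

    @given(st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_matches_weighted_normal_equations(self, seed):
        # oracle: explicit WLS solve of u on b through the origin
        rng = np.random.default_rng(seed)
        m = rng.integers(3, 25)
        u = rng.normal(0, 0.1, m)
        b = rng.uniform(0.01, 0.3, m)
        var_u = rng.uniform(1e-5, 1e-3, m)
        include = rng.random(m) < 0.7
        if not include.any():
            include[0] = True
        w = np.sqrt(1.0 / var_u[include])
        slope = np.linalg.lstsq(
            (w * b[include])[:, None], w * u[include], rcond=None
        )[0][0]
        assert m_step_ivw(u, var_u, b, include) == pytest.approx(slope, abs=1e-12)


class TestLDAdjust:
    def test_two_snp_oracle(self):
        omega = np.array([[1.0, 0.5], [0.5, 1.0]])
        u_adj, _ = ld_adjust([0.1, 0.1], 1.0, omega, 10_000)
        expect = np.linalg.solve(omega, [0.1, 0.1])
        assert np.allclose(u_adj, expect)
        assert u_adj[0] == pytest.approx(0.0667, abs=1e-4)

    def test_identity_matrix_reduces_to_marginal_effects(self):
        u = np.full(10, 1e-7)  # negligible R^2
        var_ups = 1.04
        u_adj, var_adj = ld_adjust(u, var_ups, np.eye(10), 10_000)
        assert np.allclose(u_adj, u)
        assert np.allclose(var_adj, var_ups / 10_000, atol=1e-8)

    def test_r2_capped_with_warning(self):
        with pytest.warns(RuntimeWarning, match="capping"):
            _, var_adj = ld_adjust([2.0, 2.0], 1.0, np.eye(2), 100)
        assert np.all(var_adj > 0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ld_adjust([0.1, 0.1, 0.1], 1.0, np.eye(2), 100)

    def test_near_singular_matrix_gets_ridge(self, caplog):
        omega = np.array([[1.0, 1.0], [1.0, 1.0]])  # perfectly collinear
        with caplog.at_level("WARNING"):
            u_adj, var_adj = ld_adjust([0.01, 0.01], 1.0, omega, 10_000)
        assert np.all(np.isfinite(u_adj)) and np.all(var_adj > 0)
        assert any("ridge" in r.message for r in caplog.records)


class TestLDMatrix:
    def test_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            LDMatrix(np.array([[1.0, 0.5], [0.2, 1.0]]), ("a", "b"))
        with pytest.raises(ValueError, match="diagonal"):
            LDMatrix(np.array([[2.0, 0.0], [0.0, 1.0]]), ("a", "b"))

    def test_file_round_trip_and_alignment(self, tmp_path):
        omega = np.array([[1.0, 0.3], [0.3, 1.0]])
        mpath, spath = tmp_path / "ld.txt", tmp_path / "ld.snps"
        np.savetxt(mpath, omega)
        spath.write_text("rs1\nrs2\n")
        ldm = LDMatrix.from_files(mpath, spath)
        aligned = ldm.aligned_to(["rs2", "rs1"])
        assert aligned[0, 1] == pytest.approx(0.3)
        with pytest.raises(ValueError, match="rs3"):
            ldm.aligned_to(["rs3"])


class TestFit:
    def test_null_outcome_gives_zero_tau_all_selected(self):
        panel = synthetic_panel(b_true=np.full(10, 0.2), n=10_000, noise=False)
        res = fit(panel)
        assert res.tau_hat == 0.0
        assert res.n_selected == 10
        assert res.converged

    def test_converged_tau_is_fixed_point(self, panel_factory):
        panel = panel_factory(m=50, n=20_000, tau=0.15, seed=9)
        res = fit(panel, p_exp=1.0, tol=1e-8)
        assert res.converged
        cov = estimate_cov_yc(panel)
        u, var_u = e_step(panel, res.tau_hat, cov)
        inc = inclusion_indicator(u, var_u, panel.b_hat, panel.se_b, p_exp=1.0)
        assert abs(m_step_ivw(u, var_u, panel.b_hat, inc)) < 1e-8

    def test_irrelevant_snps_never_selected(self):
        rng = np.random.default_rng(4)
        b = np.concatenate([np.full(10, 0.2), np.full(10, 1e-4)])
        panel = synthetic_panel(b_true=b, n=10_000, tau=0.1, seed=4)
        res = fit(panel, p_exp=5e-8)
        weak = {f"rs{j+1}" for j in range(10, 20)}
        assert not (set(res.selected_ids) & weak)
        # and at every traced iteration the relevance mask bounds selection
        assert exposure_pvalues(panel)[10:].min() > 5e-8

    def test_nonconvergence_is_flagged_not_raised(self, panel_factory):
        panel = panel_factory(m=50, n=20_000, tau=0.3, seed=2)
        res = fit(panel, p_exp=1.0, max_iter=1, tol=1e-12)
        assert not res.converged
        assert res.n_iter == 1

    def test_trace_starts_at_tau0_and_matches_estimate(self, panel_factory):
        panel = panel_factory(m=40, n=20_000, tau=0.1, seed=6)
        res = fit(panel, p_exp=1.0)
        assert res.trace[0] == (0, 0.0)
        assert res.trace[-1][1] == pytest.approx(res.tau_hat)

    def test_ld_identity_matches_independent_path(self):
        # exact proportionality g = tau*b leaves zero residual direct
        # effects, so the LD rotation with an identity matrix must agree
        # with the independent-SNP path
        panel = synthetic_panel(b_true=np.full(8, 0.2), tau=0.25, n=10_000,
                                noise=False)
        ldm = LDMatrix(np.eye(8), tuple(panel.snp_id))
        res_indep = fit(panel, p_exp=1.0)
        res_ld = fit(panel, p_exp=1.0, ld=ldm)
        assert res_ld.tau_hat == pytest.approx(res_indep.tau_hat, abs=1e-8)
        assert res_ld.se_tau == pytest.approx(res_indep.se_tau, rel=1e-6)

    def test_all_weak_instruments_error(self):
        panel = synthetic_panel(b_true=np.full(5, 1e-4), n=100, noise=False)
        with pytest.raises(NoValidInstrumentsError):
            fit(panel, p_exp=5e-8)


class TestFitIndividual:
    def test_latent_outcome_cancels_exactly_at_true_tau(self):
        # one-sample, noise-free outcome: y = 2c, so on standardized
        # traits the causal slope is exactly 1 and upsilon vanishes
        rng = np.random.default_rng(0)
        n, m = 400, 5
        X = rng.binomial(2, 0.3, size=(n, m))
        c = X @ rng.uniform(0.2, 0.5, m) + rng.normal(size=n)
        cohort = CohortData(X=X, c=c, y=2.0 * c)
        res = fit_individual(cohort, cohort, tau0=1.0, p_exp=1.0)
        assert res.tau_hat == pytest.approx(1.0)
        assert np.allclose(res.state.u_hat, 0.0, atol=1e-12)

    def test_direct_effects_match_per_snp_regression_oracle(self):
        # closed form cov(x, upsilon)/var(x) on standardized data
        rng = np.random.default_rng(8)
        n, m = 200, 5
        X1 = rng.binomial(2, 0.25, size=(n, m))
        X2 = rng.binomial(2, 0.25, size=(n, m))
        b = rng.uniform(0.3, 0.6, m)
        c1 = X1 @ b + rng.normal(size=n)
        c2 = X2 @ b + rng.normal(size=n)
        y2 = 0.4 * c2 + rng.normal(size=n)
        res = fit_individual(
            CohortData(X1, c1, np.zeros(n)), CohortData(X2, c2, y2), p_exp=1.0
        )
        tau = res.tau_hat
        # oracle recomputation
        Z1 = (X1 - X1.mean(0)) / X1.std(0)
        Z2 = (X2 - X2.mean(0)) / X2.std(0)
        c1z = (c1 - c1.mean()) / c1.std()
        y2z = (y2 - y2.mean()) / y2.std()
        b_hat = Z1.T @ c1z / n
        ups = y2z - tau * (Z2 @ b_hat)
        for j in range(m):
            x = Z2[:, j]
            expect = float(np.cov(x, ups, bias=True)[0, 1] / np.var(x))
            assert res.state.u_hat[j] == pytest.approx(expect, abs=1e-10)

    def test_constant_genotype_column_dropped(self, caplog):
        rng = np.random.default_rng(3)
        n = 300
        X = rng.binomial(2, 0.3, size=(n, 4))
        X[:, 2] = 1  # monomorphic
        c = X @ np.array([0.4, 0.4, 0.0, 0.4]) + rng.normal(size=n)
        y = 0.3 * c + rng.normal(size=n)
        cohortA = CohortData(X, c, y)
        with caplog.at_level("WARNING"):
            res = fit_individual(cohortA, cohortA, p_exp=1.0)
        assert "snp3" not in res.selected_ids
        assert any("constant genotype" in r.message for r in caplog.records)

    def test_concordant_with_summary_path(self):
        from mrlova import simulate as sim

        rng = np.random.default_rng(21)
        cfg = sim.SimulationConfig(scenario="no_pleiotropy", m=30, n=5_000,
                                   tau_scaled=0.2)
        rep = sim.simulate_replicate(cfg, rng)
        r_sum = fit(rep.panel, p_exp=1.0)
        r_ind = fit_individual(rep.exposure_cohort, rep.outcome_cohort,
                               p_exp=1.0, snp_ids=rep.panel.snp_id)
        assert abs(r_sum.tau_hat - r_ind.tau_hat) < max(r_sum.se_tau, r_ind.se_tau)
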