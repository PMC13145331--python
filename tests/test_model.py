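import math

import numpy as np
import pytest
from scipy import special, stats

from metaipm import model as M
from metaipm.data_io import CovariateSet
from metaipm import synthetic as syn

from oracles import brute_force_cell_probs


def _covs(T):
    return CovariateSet.zeros(M.N_GROUPS, T)


def _random_rates(T, rng, p_scale=1.0):
    """Random valid rates for oracle tests."""
    G = M.N_GROUPS
    gamma = rng.uniform(0.05, 0.3, (G, T))
    phiJ = rng.uniform(0.5, 0.95, (G, T - 1))
    phiA = rng.uniform(0.6, 0.95, (G, T - 1))
    psiJ = np.zeros((G, G, T - 1))
    psiA = np.zeros((G, G, T - 1))
    for s, d in M.juvenile_flows():
        psiJ[s, d] = rng.uniform(0, 0.15, T - 1)
    for s, d in M.adult_flows():
        psiA[s, d] = rng.uniform(0, 0.15, T - 1)
    p = rng.uniform(0.2, 0.95, (G, T)) * p_scale
    return M.DemographicRates(gamma, phiJ, phiA, psiJ, psiA, p)


class TestLinearPredictors:
    def test_fecundity_intercept_only(self):
        h = M.HyperParams.constant(5, alpha_gamma=0.12)
        assert M.fecundity_linpred(h, _covs(5), 0, 2) == pytest.approx(0.12)

    def test_fecundity_covariate_effect(self):
        h = M.HyperParams.constant(5, alpha_gamma=0.1)
        h.beta_fec[0, 0] = 0.2
        covs = _covs(5)
        covs.gdd_winter[0, :] = 1.0
        assert M.fecundity_linpred(h, covs, 0, 1) == pytest.approx(
            0.1 * math.exp(0.2), rel=1e-12)

    def test_fecundity_year_effect(self):
        h = M.HyperParams.constant(5, alpha_gamma=0.1)
        h.eps_gamma[1, 3] = 0.5
        assert M.fecundity_linpred(h, _covs(5), 1, 3) == pytest.approx(
            0.1 * math.exp(0.5))

    def test_fecundity_bad_intercept(self):
        h = M.HyperParams.constant(5)
        h.alpha_gamma[0] = 1.5
        with pytest.raises(ValueError):
            M.fecundity_linpred(h, _covs(5), 0, 0)

    def test_survival_intercept(self):
        h = M.HyperParams.constant(5, alpha_phiA=0.8)
        assert M.survival_linpred(h, _covs(5), 0, 1, "adult") == pytest.approx(0.8)

    def test_survival_hunting_shift(self):
        # +0.43 on the logit of 0.8 during protection level 1
        h = M.HyperParams.constant(5, alpha_phiA=0.8)
        h.hunt_A[0, 0] = 0.43
        covs = CovariateSet.zeros(M.N_GROUPS, 5, first_year=2004)  # spans level 1
        t = 2  # year 2006
        assert covs.hunt_level[t] == 1
        expected = special.expit(special.logit(0.8) + 0.43)
        assert M.survival_linpred(h, covs, 0, t, "adult") == pytest.approx(expected)
        assert expected == pytest.approx(0.860, abs=1e-3)

    def test_survival_monotone_in_storms(self):
        h = M.HyperParams.constant(8, alpha_phiJ=0.8)
        h.beta_storm_J[0] = -0.3
        covs = _covs(8)
        covs.storms[0] = np.linspace(-2, 2, 8)
        phis = [M.survival_linpred(h, covs, 0, t, "juv") for t in range(7)]
        assert all(b < a for a, b in zip(phis, phis[1:]))

    def test_unknown_age_errors(self):
        h = M.HyperParams.constant(5)
        with pytest.raises(ValueError):
            M.survival_linpred(h, _covs(5), 0, 0, "subadult")

    def test_elsewhere_juvenile_tied_to_focal_mean(self):
        h = M.HyperParams.constant(5, alpha_phiJ=[0.6, 0.7, 0.8])
        lps = [special.logit(a) for a in (0.6, 0.7, 0.8)]
        expected = special.expit(np.mean(lps))
        assert M.survival_linpred(h, _covs(5), M.E_INDEX, 1, "juv") \
            == pytest.approx(expected)


class TestMovementDetection:
    def test_constant_when_no_year_effects(self):
        h = M.HyperParams.constant(5, alpha_psi=0.05)
        pj0, pa0, _ = M.movement_detection(h, 0)
        pj3, pa3, _ = M.movement_detection(h, 3)
        np.testing.assert_allclose(pj0, pj3)
        np.testing.assert_allclose(pa0, pa3)
        assert pj0[0, 1] == pytest.approx(0.05)

    def test_zero_mean_pins_flow(self):
        h = M.HyperParams.constant(5, alpha_psi=0.05)
        h.alpha_psiJ[0] = 0.0
        h.eps_psiJ[0, :] = 3.0
        pj, _, _ = M.movement_detection(h, 2)
        s, d = M.juvenile_flows()[0]
        assert pj[s, d] == 0.0

    def test_fidelity_in_unit_interval(self, rng):
        h = M.HyperParams.constant(6, alpha_psi=0.15, sigma_psi=0.0)
        h.eps_psiA = rng.normal(0, 0.5, size=h.eps_psiA.shape)
        for t in range(5):
            _, pa, _ = M.movement_detection(h, t)
            fid = 1 - pa.sum(axis=1)
            assert np.all(fid > 0) and np.all(fid <= 1)

    def test_out_of_cap_errors(self):
        h = M.HyperParams.constant(5)
        h.alpha_psiA[0] = 0.3
        with pytest.raises(ValueError):
            M.movement_detection(h, 0)


class TestProcessExpectation:
    def test_conservation_no_birth_no_death(self):
        G = M.N_GROUPS
        psi = np.zeros((G, G))
        for s, d in M.adult_flows():
            psi[s, d] = 0.05
        state = {"J": np.array([10, 20, 5, 40]), "A": np.array([100, 200, 50, 400])}
        rates = {"phiJ": np.ones(G), "phiA": np.ones(G),
                 "psiJ": np.zeros((G, G)), "psiA": psi,
                 "gamma_next": np.zeros(G)}
        out = M.process_expectation(state, rates)
        assert out["A"].sum() == pytest.approx(
            state["J"].sum() + state["A"].sum())

    def test_no_movement_no_immigrants(self):
        G = M.N_GROUPS
        state = {"J": np.full(G, 50), "A": np.full(G, 500)}
        rates = {"phiJ": np.full(G, 0.7), "phiA": np.full(G, 0.8),
                 "psiJ": np.zeros((G, G)), "psiA": np.zeros((G, G))}
        out = M.process_expectation(state, rates)
        np.testing.assert_array_equal(out["I"], 0)

    def test_two_group_hand_example(self):
        # groups 0 and 1 exchange adults at 0.1; others empty
        G = M.N_GROUPS
        psiA = np.zeros((G, G))
        psiA[0, 1] = psiA[1, 0] = 0.1
        state = {"J": np.array([100, 100, 0, 0]),
                 "A": np.array([1000, 1000, 0, 0])}
        rates = {"phiJ": np.full(G, 1.0), "phiA": np.full(G, 0.8),
                 "psiJ": np.zeros((G, G)), "psiA": psiA,
                 "gamma_next": np.full(G, 0.1)}
        out = M.process_expectation(state, rates)
        assert out["N1"][0] == pytest.approx(100.0)        # φJ=1, no movement
        assert out["Nad"][0] == pytest.approx(0.8 * 0.9 * 1000)
        assert out["I"][0] == pytest.approx(0.8 * 0.1 * 1000)
        assert out["A"][0] == pytest.approx(100 + 720 + 80)
        assert out["J"][0] == pytest.approx(0.1 * 900)


class TestObservationLikelihoods:
    def test_counts_against_independent_density(self, rng):
        # independent closed form: N(log y | log Ntot, τ) − log y
        y = rng.uniform(50, 500, size=(2, 4))
        N = rng.uniform(50, 500, size=(2, 4))
        tau = 0.04
        expected = np.sum(stats.norm.logpdf(np.log(y), np.log(N),
                                            math.sqrt(tau)) - np.log(y))
        assert M.loglik_counts(y, N, tau) == pytest.approx(expected, rel=1e-12)

    def test_counts_unimodal_in_distance(self):
        base = M.loglik_counts([100.0], [100.0], 0.02)
        farther = [M.loglik_counts([100.0 * f], [100.0], 0.02)
                   for f in (1.1, 1.3, 2.0)]
        assert base > farther[0] > farther[1] > farther[2]

    def test_counts_scale_property(self):
        # scaling y and Ntot jointly shifts the density by −log(factor)
        l1 = M.loglik_counts([120.0], [100.0], 0.03)
        l2 = M.loglik_counts([240.0], [200.0], 0.03)
        assert l2 - l1 == pytest.approx(-math.log(2), rel=1e-10)

    def test_counts_errors(self):
        with pytest.raises(ValueError):
            M.loglik_counts([0.0], [10.0], 0.1)
        with pytest.raises(ValueError):
            M.loglik_counts([10.0], [10.0], 0.0)

    @pytest.mark.parametrize("jobs, J, expected", [
        (0, 5, -5.0),
        (2, 2, 2 * math.log(2) - 2 - math.log(2)),
        (3, 0, -np.inf),
        (0, 0, 0.0),
    ])
    def test_juveniles_values(self, jobs, J, expected):
        got = M.loglik_juveniles([float(jobs)], [float(J)])
        if np.isinf(expected):
            assert got == -np.inf
        else:
            assert got == pytest.approx(expected, rel=1e-10)

    def test_juveniles_non_integer_errors(self):
        with pytest.raises(ValueError):
            M.loglik_juveniles([2.5], [3.0])


class TestMArrayCellProbs:
    def test_sums_to_one(self, rng):
        rates = _random_rates(6, rng)
        for (g, age, y) in [(0, "juv", 0), (2, "adult", 3), (3, "adult", 0)]:
            probs = M.marray_cell_probs(rates, g, age, y)
            assert probs.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(probs >= -1e-15)

    def test_dead_birds_never_seen(self, rng):
        rates = _random_rates(5, rng)
        rates.phiJ[:] = 0
        rates.phiA[:] = 0
        probs = M.marray_cell_probs(rates, 0, "adult", 1)
        assert probs[-1] == pytest.approx(1.0)

    def test_one_interval_closed_form(self, rng):
        # perfect detection, single interval: cell(j) = φ ψ_{i→j} exactly
        rates = _random_rates(2, rng)
        rates.p[:] = 1.0
        probs = M.marray_cell_probs(rates, 0, "adult", 0)
        psi = rates.psiA[0, :, 0]
        phi = rates.phiA[0, 0]
        for j in range(M.N_GROUPS):
            expected = phi * (1 - psi.sum()) if j == 0 else phi * psi[j]
            assert probs[j] == pytest.approx(expected, abs=1e-14)

    def test_release_final_year(self, rng):
        rates = _random_rates(4, rng)
        probs = M.marray_cell_probs(rates, 1, "adult", 3)
        assert probs[-1] == 1.0 and probs[:-1].sum() == 0

    @pytest.mark.parametrize("release", [(0, "juv", 0), (1, "adult", 0),
                                         (2, "adult", 1), (3, "adult", 0)])
    def test_matches_exhaustive_enumeration(self, release, rng):
        rates = _random_rates(4, rng)
        g, age, y = release
        got = M.marray_cell_probs(rates, g, age, y)
        want = brute_force_cell_probs(rates, g, age, y)
        np.testing.assert_allclose(got, want, atol=1e-10)


class TestMArrayLoglik:
    def test_hand_multinomial(self):
        # single cohort, all mass in the first year: 3 stay-detections and
        # one never-seen under p chosen to make the cell probs (0.75, 0.25)
        T = 2
        rates = M.DemographicRates(
            gamma=np.full((4, T), 0.1),
            phiJ=np.full((4, 1), 1.0), phiA=np.full((4, 1), 1.0),
            psiJ=np.zeros((4, 4, 1)), psiA=np.zeros((4, 4, 1)),
            p=np.full((4, T), 0.75))
        m = M.MArray.empty(T)
        r = m.row_index(0, "adult", 0)
        m.counts[r, m.cell_index(1, 0)] = 3
        m.counts[r, -1] = 1
        expected = 3 * math.log(0.75) + math.log(0.25)
        assert M.loglik_marray(m, rates) == pytest.approx(expected, rel=1e-12)

    def test_certain_cells_give_zero(self):
        T = 2
        rates = M.DemographicRates(
            gamma=np.full((4, T), 0.1),
            phiJ=np.full((4, 1), 1.0), phiA=np.full((4, 1), 1.0),
            psiJ=np.zeros((4, 4, 1)), psiA=np.zeros((4, 4, 1)),
            p=np.ones((4, T)))
        m = M.MArray.empty(T)
        m.counts[m.row_index(1, "adult", 0), m.cell_index(1, 1)] = 7
        assert M.loglik_marray(m, rates) == pytest.approx(0.0, abs=1e-12)

    def test_impossible_cell_is_neg_inf(self):
        T = 3
        rates = M.DemographicRates(
            gamma=np.full((4, T), 0.1),
            phiJ=np.zeros((4, 2)), phiA=np.zeros((4, 2)),
            psiJ=np.zeros((4, 4, 2)), psiA=np.zeros((4, 4, 2)),
            p=np.full((4, T), 0.5))
        m = M.MArray.empty(T)
        m.counts[m.row_index(0, "adult", 0), m.cell_index(1, 0)] = 1
        assert M.loglik_marray(m, rates) == -np.inf

    def test_row_order_invariance(self, rng):
        rates = _random_rates(5, rng)
        m = M.MArray.empty(5)
        m.counts[m.row_index(0, "juv", 0), m.cell_index(1, 0)] = 4
        m.counts[m.row_index(0, "juv", 0), -1] = 2
        m.counts[m.row_index(2, "adult", 1), m.cell_index(3, 1)] = 5
        ll = M.loglik_marray(m, rates)
        contributions = []
        for r, (isj, g, y) in enumerate(m.row_meta()):
            row = m.counts[r]
            if row.sum():
                probs = M.marray_cell_probs(rates, g, "juv" if isj else "adult", y)
                contributions.append((row[row > 0] * np.log(probs[row > 0])).sum())
        assert ll == pytest.approx(sum(sorted(contributions)), rel=1e-12)


class TestLogPrior:
    def _hyper(self, T=5):
        h = M.HyperParams.constant(T, sigma_gamma=0.3, sigma_phiJ=0.2,
                                   sigma_phiA=0.2, sigma_psi=0.3, sigma_p=0.3)
        return h

    def test_movement_mean_outside_cap(self):
        h = self._hyper()
        h.alpha_psiJ = h.alpha_psiJ.copy()
        h.alpha_psiJ[0] = 0.3
        assert M.log_prior(h, [2000, 2000, 100, 2000]) == -np.inf

    def test_initial_adults_pmf(self):
        h = self._hyper()
        base = M.log_prior(h, [2000, 2000, 100, 2000])
        # Wexford year-1 prior: DiscreteUniform(1000, 4000) -> -log(3001)
        shifted = M.log_prior(h, [3500, 2000, 100, 2000])
        assert base == pytest.approx(shifted)
        assert M.log_prior(h, [999, 2000, 100, 2000]) == -np.inf
        assert M.log_prior(h, [2000, 2000, 401, 2000]) == -np.inf

    def test_laplace_at_location(self):
        h = self._hyper()
        h.lam_beta_A = 2.0     # scale b = 1/lambda^2 = 0.25
        h.mu_beta_A = 0.3
        h.beta_storm_A[:] = 0.3
        base = M.log_prior(h, [2000, 2000, 100, 2000])
        h2 = self._hyper()
        h2.lam_beta_A = 2.0
        h2.mu_beta_A = 0.3
        h2.beta_storm_A[:] = 0.3
        h2.beta_storm_A[0] = 0.55   # |x - mu| = 0.25 -> one unit of b
        assert base - M.log_prior(h2, [2000, 2000, 100, 2000]) \
            == pytest.approx(0.25 / 0.25)

    def test_tau_support(self):
        h = self._hyper()
        h.tau_y = -0.1
        assert M.log_prior(h, [2000, 2000, 100, 2000]) == -np.inf


class TestJointPosterior:
    def test_additivity(self, small_sim):
        data, truth = small_sim
        h = syn.default_hyper(data.n_years)
        rng = np.random.default_rng(3)
        h.eps_gamma = rng.normal(0, 0.1, h.eps_gamma.shape)
        lat = truth.latent
        total = M.joint_log_posterior(h, lat, data)
        rates = M.build_rates(h, data.covs)
        parts = (M.log_prior(h, lat.A1) + M.process_loglik(lat, rates)
                 + M.loglik_counts(data.y, lat.Ntot, h.tau_y)
                 + M.loglik_juveniles(data.Jobs, lat.J)
                 + M.loglik_marray(data.marray, rates))
        assert total == pytest.approx(parts, abs=1e-10)

    def test_finite_on_simulator_output(self, small_sim):
        data, truth = small_sim
        h = syn.default_hyper(data.n_years)
        assert np.isfinite(M.joint_log_posterior(h, truth.latent, data))

    def test_invalid_component_propagates(self, small_sim):
        data, truth = small_sim
        h = syn.default_hyper(data.n_years)
        h.alpha_psiA = h.alpha_psiA.copy()
        h.alpha_psiA[0] = 0.5
        assert M.joint_log_posterior(h, truth.latent, data) == -np.inf


class TestBuildRates:
    def test_matches_scalar_operations(self, rng):
        T = 7
        h = syn.default_hyper(T)
        h.eps_gamma = rng.normal(0, 0.2, h.eps_gamma.shape)
        h.eps_phiJ = rng.normal(0, 0.2, h.eps_phiJ.shape)
        h.eps_phiA = rng.normal(0, 0.2, h.eps_phiA.shape)
        h.eps_psiJ = rng.normal(0, 0.2, h.eps_psiJ.shape)
        h.eps_psiA = rng.normal(0, 0.2, h.eps_psiA.shape)
        h.eps_p = rng.normal(0, 0.2, h.eps_p.shape)
        covs = syn.gen_covariates(M.N_GROUPS, T, rng, first_year=2000)
        rates = M.build_rates(h, covs)
        for i in range(M.N_GROUPS):
            for t in range(T):
                assert rates.gamma[i, t] == pytest.approx(
                    M.fecundity_linpred(h, covs, i, t), rel=1e-12)
            for t in range(T - 1):
                assert rates.phiA[i, t] == pytest.approx(
                    M.survival_linpred(h, covs, i, t, "adult"), rel=1e-12)
                assert rates.phiJ[i, t] == pytest.approx(
                    M.survival_linpred(h, covs, i, t, "juv"), rel=1e-12)
        for t in range(T - 1):
            mj, ma, p = M.movement_detection(h, t)
            np.testing.assert_allclose(rates.psiJ[:, :, t], mj, rtol=1e-12)
            np.testing.assert_allclose(rates.psiA[:, :, t], ma, rtol=1e-12)
            np.testing.assert_allclose(rates.p[:, t], p, rtol=1e-12)


class TestModelSpecYaml:
    def test_roundtrip(self, tmp_path):
        p = tmp_path / "spec.yaml"
        M.spec_to_yaml(p, n_years=12)
        spec = M.spec_from_yaml(p)
        assert spec["groups"] == ["W", "Is", "LK", "E"]
        assert len(spec["juvenile_flows"]) == 9
        assert len(spec["adult_flows"]) == 12
        assert spec["priors"]["initial_adults"]["LK"] == [1, 400]

    def test_structure_mismatch_rejected(self, tmp_path):
        import yaml
        p = tmp_path / "spec.yaml"
        doc = M.model_spec()
        doc["adult_flows"] = doc["adult_flows"][:-1]
        p.write_text(yaml.safe_dump(doc))
        with pytest.raises(ValueError, match="adult_flows"):
            M.spec_from_yaml(p)
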