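import numpy as np
import pandas as pd
import pytest

from metaipm import demographics as dem
from metaipm import model as M
from metaipm import synthetic as syn


class TestRealizedGrowth:
    def test_constant_population(self):
        lam = dem.realized_growth(np.full((2, 5), 100.0))
        np.testing.assert_allclose(lam, 1.0)

    def test_simple_ratio(self):
        assert dem.realized_growth(np.array([100.0, 110.0]))[0] \
            == pytest.approx(1.1)

    def test_length(self):
        assert dem.realized_growth(np.arange(1.0, 8.0)).shape == (6,)

    def test_zero_errors(self):
        with pytest.raises(ValueError, match="growth undefined"):
            dem.realized_growth(np.array([10.0, 0.0, 5.0]))


def _theta(base, T=40):
    """Constant θ series around plausible magnitudes."""
    th = np.repeat(np.asarray(base, float)[:, None], T, axis=1)
    return th


BASE = np.array([0.12, 0.75, 0.85, 0.95, 0.93,
                 0.01, 0.005, 0.03, 0.10, 0.07, 0.60, 0.03])


class TestTltre:
    def test_constant_parameters_zero_contributions(self):
        contrib, _, varlam = dem.tltre_single(_theta(BASE))
        np.testing.assert_allclose(contrib, 0.0, atol=1e-14)
        assert varlam == pytest.approx(0.0, abs=1e-14)

    def test_single_varying_parameter_analytic(self, rng):
        # only fecundity varies: contribution = (dλ/dγ)^2 Var(γ) exactly
        th = _theta(BASE, T=2000)
        sd = 0.012
        th[0] += rng.normal(0, sd, size=th.shape[1])
        contrib, sens, _ = dem.tltre_single(th)
        expected = sens[0] ** 2 * th[0].var(ddof=1)
        assert contrib[0] == pytest.approx(expected, rel=1e-10)
        assert abs(contrib[1:]).max() < 1e-12 * max(contrib[0], 1)
        # and the analytic sensitivity matches a central finite difference
        eps = 1e-6
        up, dn = _theta(BASE), _theta(BASE)
        up[0] += eps
        dn[0] -= eps
        fd = (dem.lambda_from_theta(up[:, :1])[0]
              - dem.lambda_from_theta(dn[:, :1])[0]) / (2 * eps)
        assert sens[0] == pytest.approx(float(fd), rel=1e-6)

    def test_sensitivities_match_finite_differences(self, rng):
        th = _theta(BASE)
        _, sens, _ = dem.tltre_single(th)
        eps = 1e-6
        for k in range(12):
            up, dn = BASE.copy(), BASE.copy()
            up[k] += eps
            dn[k] -= eps
            fd = (dem.lambda_from_theta(up[:, None])[0]
                  - dem.lambda_from_theta(dn[:, None])[0]) / (2 * eps)
            assert sens[k] == pytest.approx(fd, rel=1e-5), k

    def test_first_order_identity_small_cv(self, rng):
        # all parameters fluctuate with cv <= 0.1: sum of contributions
        # approximates Var(λ) within 10% relative error
        th = _theta(BASE, T=5000)
        for k in range(12):
            th[k] *= 1.0 + 0.08 * rng.normal(size=th.shape[1]).clip(-3, 3)
        contrib, _, varlam = dem.tltre_single(th)
        assert contrib.sum() == pytest.approx(varlam, rel=0.10)

    def test_identity_tightens_as_variation_vanishes(self, rng):
        errs = []
        for scale in (0.08, 0.02, 0.005):
            th = _theta(BASE, T=3000)
            noise = rng.standard_normal((12, th.shape[1])).clip(-3, 3)
            th *= 1.0 + scale * noise
            contrib, _, varlam = dem.tltre_single(th)
            errs.append(abs(contrib.sum() - varlam) / varlam)
        assert errs[0] > errs[-1]
        assert errs[-1] < 0.01

    def test_decompose_pct_sums_to_100(self, default_sim):
        _, truth = default_sim
        res = dem.tltre_decompose(truth, 1)
        np.testing.assert_allclose(res.pct.sum(axis=1), 100.0, atol=1e-9)
        assert res.summary().shape[0] == 12

    def test_elsewhere_rejected(self, default_sim):
        _, truth = default_sim
        with pytest.raises(ValueError):
            dem.tltre_decompose(truth, M.E_INDEX)


class TestDeltaLambda:
    def test_no_change_no_contributions(self):
        ra_la = _constant_pseudo_draws()
        tab = dem.delta_lambda_contributions(ra_la, 0)
        drivers = dem.theta_labels(0)
        np.testing.assert_allclose(tab[drivers].to_numpy(), 0.0, atol=1e-12)
        np.testing.assert_allclose(tab["delta_lambda"], 0.0, atol=1e-12)

    def test_small_single_change_matches_sensitivity(self, default_sim):
        _, truth = default_sim
        th = dem.theta_series(truth, 0)
        tab = dem.delta_lambda_contributions(truth, 0)
        drivers = dem.theta_labels(0)
        # telescoping: driver contributions sum approximately to Δλ
        total = tab[drivers].sum(axis=1)
        resid = np.abs(total - tab["delta_lambda"])
        scale = np.abs(tab["delta_lambda"]).mean()
        assert resid.mean() < 0.15 * max(scale, 1e-6)

    def test_too_short_errors(self):
        ra_la = _constant_pseudo_draws(T=3)
        with pytest.raises(ValueError):
            dem.delta_lambda_contributions(ra_la, 0)


def _constant_pseudo_draws(T=10):
    """One pseudo-draw with time-constant rates and states."""
    G = M.N_GROUPS
    ra = dict(
        gamma=np.full((1, G, T), 0.12),
        phiJ=np.full((1, G, T - 1), 0.75), phiA=np.full((1, G, T - 1), 0.85),
        psiJ=np.full((1, 9, T - 1), 0.02), psiA=np.full((1, 12, T - 1), 0.02),
        fidJ=np.full((1, G, T - 1), 0.94), fidA=np.full((1, G, T - 1), 0.94),
        p=np.full((1, G, T), 0.9))
    la = dict(
        J=np.full((1, G, T), 100), N1=np.full((1, G, T), 80),
        Nad=np.full((1, G, T), 700), I=np.full((1, G, T), 30),
        A=np.full((1, G, T), 810), Ntot=np.full((1, G, T), 910))
    return ra, la


class TestDominantDriver:
    def test_single_driver(self):
        tab = pd.DataFrame({"a": [1.0, 2.0, -3.0], "b": [0.1, 0.2, 0.1]})
        out = dem.dominant_driver_summary(tab)
        assert out["a"] == pytest.approx(100.0)
        assert out["b"] == pytest.approx(0.0)

    def test_alternating_drivers(self):
        a = [1.0, 0.0] * 5
        b = [0.0, 1.0] * 5
        out = dem.dominant_driver_summary(pd.DataFrame({"a": a, "b": b}))
        assert out["a"] == pytest.approx(50.0)
        assert out["b"] == pytest.approx(50.0)

    def test_fractions_sum_to_100(self, default_sim):
        _, truth = default_sim
        tab = dem.delta_lambda_contributions(truth, 2)
        out = dem.dominant_driver_summary(tab)
        assert out.sum() == pytest.approx(100.0)

    def test_ties_split(self):
        tab = pd.DataFrame({"a": [1.0], "b": [1.0], "c": [0.5]})
        out = dem.dominant_driver_summary(tab)
        assert out["a"] == out["b"] == pytest.approx(50.0)


class TestNetImmigration:
    def test_symmetric_flows_cancel(self):
        ra, la = _constant_pseudo_draws()
        res = dem.net_immigration((ra, la))
        np.testing.assert_allclose(res.overall, 0.0, atol=1e-12)

    def test_hand_arithmetic(self):
        # one-way flow: in = phi*psi*A_s = 13, out = 0, A_i = 100
        G = M.N_GROUPS
        T = 5
        ra, la = _constant_pseudo_draws(T)
        ra["psiA"] = np.zeros((1, 12, T - 1))
        f_in = [f for f, (s, d) in enumerate(M.adult_flows())
                if (s, d) == (3, 0)][0]
        ra["psiA"][0, f_in] = 0.1
        ra["phiA"][:] = 0.65
        la["A"] = np.full((1, G, T), 100)
        la["A"][0, 3] = 200
        res = dem.net_immigration((ra, la))
        # inflow = 0.65 * 0.1 * 200 = 13 per 100 residents
        assert res.pairwise[0, 3, 0] == pytest.approx(0.13)
        assert res.overall[0, 0] == pytest.approx(0.13)

    def test_overall_is_sum_of_pairwise(self, default_sim):
        _, truth = default_sim
        res = dem.net_immigration(truth)
        np.testing.assert_allclose(res.overall,
                                   res.pairwise.sum(axis=1), atol=1e-12)

    def test_antisymmetry_scaled_by_abundance(self):
        # Inet_{s→i}·A_i = −Inet_{i→s}·A_s when abundances are constant
        ra, la = _constant_pseudo_draws()
        rng = np.random.default_rng(0)
        ra["psiA"] = rng.uniform(0, 0.1, ra["psiA"].shape)
        A = la["A"][0, :, 0].astype(float)
        res = dem.net_immigration((ra, la))
        for s in range(4):
            for i in range(s + 1, 4):
                assert res.pairwise[0, s, i] * A[i] == pytest.approx(
                    -res.pairwise[0, i, s] * A[s], rel=1e-9)


class TestProjections:
    def test_both_scenario_matches_expectation_recursion(self, default_sim):
        _, truth = default_sim
        res = dem.project_scenarios(truth, "both")
        r = truth.rates
        J = truth.latent.J[:, 0].astype(float)
        A = truth.latent.A[:, 0].astype(float)
        Ntot = [J + A]
        for t in range(r.n_years - 1):
            out = M.process_expectation(
                {"J": J, "A": A},
                {"phiJ": r.phiJ[:, t], "phiA": r.phiA[:, t],
                 "psiJ": r.psiJ[:, :, t], "psiA": r.psiA[:, :, t],
                 "gamma_next": r.gamma[:, t + 1]})
            J, A = out["J"], out["A"]
            Ntot.append(out["Ntot"])
        np.testing.assert_allclose(res.Ntot[0], np.array(Ntot).T, rtol=1e-9)

    def test_projection_tracks_estimates_on_truth(self, default_sim):
        _, truth = default_sim
        res = dem.project_scenarios(truth, "both")
        assert np.all(res.r[0] >= 0.95)
        assert np.all(res.pr_r_positive == 1.0)

    def test_emigration_only_growth_below_both(self, default_sim):
        _, truth = default_sim
        both = dem.project_scenarios(truth, "both")
        emi = dem.project_scenarios(truth, "emigration_only")
        assert np.all(emi.growth <= both.growth + 1e-12)

    def test_no_movement_constant_rates_eigenvalue(self):
        # two-stage oracle: with constant rates and no movement the growth
        # converges to the dominant eigenvalue of [[γφJ, γφA], [φJ, φA]]
        G = M.N_GROUPS
        T = 120
        gam, phJ, phA = 0.12, 0.75, 0.85
        ra = dict(
            gamma=np.full((1, G, T), gam),
            phiJ=np.full((1, G, T - 1), phJ), phiA=np.full((1, G, T - 1), phA),
            psiJ=np.zeros((1, 9, T - 1)), psiA=np.zeros((1, 12, T - 1)),
            fidJ=np.ones((1, G, T - 1)), fidA=np.ones((1, G, T - 1)),
            p=np.full((1, G, T), 0.9))
        la = dict(J=np.full((1, G, T), 100), N1=np.full((1, G, T), 0),
                  Nad=np.full((1, G, T), 800), I=np.full((1, G, T), 0),
                  A=np.full((1, G, T), 800), Ntot=np.full((1, G, T), 900))
        res = dem.project_scenarios((ra, la), "no_movement")
        mat = np.array([[gam * phJ, gam * phA], [phJ, phA]])
        lam_dom = np.max(np.abs(np.linalg.eigvals(mat)))
        lam_end = res.Ntot[0, 0, -1] / res.Ntot[0, 0, -2]
        assert lam_end == pytest.approx(lam_dom, rel=1e-10)

    def test_unknown_scenario(self, default_sim):
        _, truth = default_sim
        with pytest.raises(ValueError):
            dem.project_scenarios(truth, "teleportation")

    def test_trajectories_nonnegative(self, default_sim):
        _, truth = default_sim
        for sc in dem.SCENARIOS:
            res = dem.project_scenarios(truth, sc)
            assert np.all(res.Ntot >= 0)
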