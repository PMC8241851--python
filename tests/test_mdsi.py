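"""State-space estimator tests: smoother exactness, EM behavior, reductions."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from dynconn import mdsi, synth


def _always_on_design(T, tr=1.0, name="on"):
    events = pd.DataFrame({"onset": [0.0], "duration": [float(T) * tr],
                           "condition": [name]})
    return synth.design_from_events(events, tr, T, (name,))


def _identity_basis():
    return synth.HRFBasis(np.array([[1.0]]), 1.0)


class TestKalmanSmooth:
    def test_identity_observation_recovers_bold(self):
        # L=1, Phi=[1], b=1, sigma^2 tiny: the observation is (almost) the
        # state itself, so smoothed means must match the data
        rng = np.random.default_rng(0)
        T, M = 60, 3
        design = _always_on_design(T)
        C = 0.5 * np.eye(M)
        model = synth.MDSIModel(
            coupling=C[None], state_noise_var=1.0,
            hrf_weights=np.ones((M, 1)), obs_noise_var=np.full(M, 1e-10),
            basis=_identity_basis(), condition_names=("on",))
        subj = synth.simulate_subject(model, design, seed=1)
        sm = mdsi.kalman_smooth(subj.bold, design, model)
        np.testing.assert_allclose(sm.latent_mean, subj.bold, atol=1e-4)

    def test_matches_brute_force_joint_gaussian(self):
        # T=5, M=2, L=2 toy: condition the explicitly constructed joint
        # Gaussian of all augmented states and observations
        T, M, L = 5, 2, 2
        d = M * L
        rng = np.random.default_rng(3)
        C = np.array([[0.4, 0.2], [-0.1, 0.3]])
        basis = synth.HRFBasis(np.array([[1.0, 0.5], [0.2, -0.3]]), 1.0)
        b = np.array([[1.0, 0.3], [0.8, -0.2]])
        sig = np.array([0.3, 0.5])
        model = synth.MDSIModel(
            coupling=C[None], state_noise_var=0.7,
            hrf_weights=b, obs_noise_var=sig, basis=basis,
            condition_names=("on",))
        design = _always_on_design(T)
        y = rng.normal(size=(T, M))

        # ---- brute-force oracle: z stacked over time is linear-Gaussian
        F = np.zeros((d, d))
        F[:M, :M] = C
        F[M:, : d - M] = np.eye(d - M)
        G = np.zeros((d, M))
        G[:M] = np.eye(M)
        H = mdsi._observation_matrix(model, L)
        # z_0 ~ N(0, P0); z_t = F z_{t-1} + G w_t
        P0 = mdsi._PRIOR_VAR * model.state_noise_var * np.eye(d)
        big = np.zeros((T * d, T * d))
        big[:d, :d] = P0
        for t in range(1, T):
            Qf = model.state_noise_var * G @ G.T
            prev = big[(t - 1) * d: t * d]
            # Cov(z_t, z_s) = F Cov(z_{t-1}, z_s) for s < t
            for s in range(t):
                blk = F @ big[(t - 1) * d: t * d, s * d: (s + 1) * d]
                big[t * d: (t + 1) * d, s * d: (s + 1) * d] = blk
                big[s * d: (s + 1) * d, t * d: (t + 1) * d] = blk.T
            big[t * d: (t + 1) * d, t * d: (t + 1) * d] = (
                F @ big[(t - 1) * d: t * d, (t - 1) * d: t * d] @ F.T + Qf)
        Hbig = np.zeros((T * M, T * d))
        for t in range(T):
            Hbig[t * M: (t + 1) * M, t * d: (t + 1) * d] = H
        R = np.diag(np.tile(sig, T))
        S_yy = Hbig @ big @ Hbig.T + R
        S_zy = big @ Hbig.T
        post_mean = (S_zy @ np.linalg.solve(S_yy, y.ravel())).reshape(T, d)
        post_cov = big - S_zy @ np.linalg.solve(S_yy, S_zy.T)

        sm = mdsi.kalman_smooth(y, design, model)
        np.testing.assert_allclose(sm.means, post_mean, atol=1e-8)
        for t in range(T):
            np.testing.assert_allclose(
                sm.covs[t], post_cov[t * d: (t + 1) * d, t * d: (t + 1) * d],
                atol=1e-8)
        # exact marginal log-likelihood against the joint normal
        from scipy.stats import multivariate_normal

        ll = multivariate_normal(mean=np.zeros(T * M), cov=S_yy).logpdf(y.ravel())
        assert sm.loglik == pytest.approx(ll, abs=1e-8)

    def test_generating_parameters_beat_shrunk_coupling(self):
        # averaged over replicates, the likelihood at the truth exceeds the
        # likelihood with coupling shrunk toward zero
        basis = synth.make_hrf_basis(2.0, 8.0, 1)
        design = _always_on_design(120, tr=2.0)
        truth = synth.default_template_model(
            n_regions=3, basis=basis, condition_names=("on",), seed=4)
        truth = dataclasses.replace(truth, obs_noise_var=np.full(3, 2.0))
        shrunk = dataclasses.replace(truth, coupling=0.1 * truth.coupling)
        diffs = []
        for seed in range(20):
            subj = synth.simulate_subject(truth, design, seed=seed)
            ll_true = mdsi.kalman_smooth(subj.bold, design, truth).loglik
            ll_shrunk = mdsi.kalman_smooth(subj.bold, design, shrunk).loglik
            diffs.append(ll_true - ll_shrunk)
        assert np.mean(diffs) > 0

    def test_gauge_invariance(self):
        # scaling the latent (Q -> Q/4, b -> 2b) leaves the data likelihood
        # unchanged: only the product of hemodynamic gain and latent scale
        # is identified, which is why the estimator pins Q = 1
        basis = synth.make_hrf_basis(2.0, 8.0, 2)
        design = _always_on_design(80, tr=2.0)
        truth = synth.default_template_model(
            n_regions=3, basis=basis, condition_names=("on",), seed=5)
        subj = synth.simulate_subject(truth, design, seed=6)
        rescaled = dataclasses.replace(
            truth, state_noise_var=truth.state_noise_var / 4.0,
            hrf_weights=2.0 * truth.hrf_weights)
        ll1 = mdsi.kalman_smooth(subj.bold, design, truth).loglik
        ll2 = mdsi.kalman_smooth(subj.bold, design, rescaled).loglik
        assert ll1 == pytest.approx(ll2, abs=1e-6)


class TestFitMDSI:
    def test_ols_var_equivalence_with_identity_observation(self):
        # L=1, identity observation, tiny fixed noise: EM must reduce to
        # per-condition ordinary least-squares VAR on the data itself
        design = synth.make_nback_design(
            tr_seconds=1.0, frames_per_session=300, n_sessions=1,
            cue_seconds=0.0, fixation_blocks=0, blocks_per_session=6,
            trials_per_block=5, trial_seconds=10.0)
        basis = _identity_basis()
        truth = synth.default_template_model(
            n_regions=3, basis=basis, seed=7)
        truth = dataclasses.replace(
            truth, hrf_weights=np.ones((3, 1)),
            obs_noise_var=np.full(3, 1e-6))
        subj = synth.simulate_subject(truth, design, seed=8)
        cfg = mdsi.EstimationConfig(
            max_iterations=60, n_random_starts=1,
            fix_hrf_weights=True, fix_obs_noise=1e-6)
        fit = mdsi.fit_mdsi(subj.bold, design, basis, cfg)
        y = subj.bold - subj.bold.mean(axis=0)
        ci = design.condition_index()
        for j in range(2):
            rows = np.array([t for t in range(1, 300) if ci[t] == j])
            C_ols = np.linalg.lstsq(y[rows - 1], y[rows], rcond=None)[0].T
            np.testing.assert_allclose(fit.model.coupling[j], C_ols,
                                       atol=1e-2)

    def test_loglik_trace_monotone(self, fitted_subject):
        _, fit = fitted_subject
        assert (np.diff(fit.loglik_trace) >= -1e-6).all()

    def test_recovery_on_shared_fit(self, fitted_subject, small_truth):
        subj, fit = fitted_subject
        off = ~np.eye(4, dtype=bool)
        tv = np.concatenate([subj.truth.coupling[j][off] for j in range(2)])
        ev = np.concatenate([fit.model.coupling[j][off] for j in range(2)])
        assert np.corrcoef(tv, ev)[0, 1] > 0.7

    def test_recovery_improves_with_series_length(self):
        # median recovery correlation at T=1200 beats T=300 over replicates
        basis = synth.make_hrf_basis(2.0, 12.0 - 1e-9, 2)
        cfg = mdsi.EstimationConfig(max_iterations=25, n_random_starts=1)
        off = ~np.eye(3, dtype=bool)
        medians = {}
        for T in (300, 1200):
            design = synth.make_nback_design(
                tr_seconds=2.0, frames_per_session=T, n_sessions=1,
                cue_seconds=0.0, fixation_blocks=0,
                blocks_per_session=T // 13, trials_per_block=10,
                trial_seconds=2.5)
            rs = []
            for seed in range(6):
                truth = synth.default_template_model(
                    n_regions=3, basis=basis, seed=100 + seed)
                truth = synth.calibrate_obs_noise(truth, design, 1.0, seed=1)
                subj = synth.simulate_subject(truth, design, seed=seed)
                fit = mdsi.fit_mdsi(subj.bold, design, basis, cfg)
                tv = np.concatenate([truth.coupling[j][off] for j in range(2)])
                ev = np.concatenate(
                    [fit.model.coupling[j][off] for j in range(2)])
                rs.append(np.corrcoef(tv, ev)[0, 1])
            medians[T] = np.median(rs)
        assert medians[1200] >= medians[300]

    def test_short_series_warns(self, coarse_basis, tiny_design):
        y = np.random.default_rng(0).normal(size=(40, 4))
        cfg = mdsi.EstimationConfig(max_iterations=2, n_random_starts=1)
        with pytest.warns(UserWarning, match="frames"):
            mdsi.fit_mdsi(y, tiny_design, coarse_basis, cfg)


class TestExtractNetworks:
    def _dummy_fit(self, M=3, J=2):
        basis = _identity_basis()
        rng = np.random.default_rng(0)
        model = synth.MDSIModel(
            coupling=rng.normal(0, 0.1, (J, M, M)), state_noise_var=1.0,
            hrf_weights=np.ones((M, 1)), obs_noise_var=np.ones(M),
            basis=basis, condition_names=tuple(f"c{j}" for j in range(J)))
        return mdsi.FitResult(
            model=model, loglik_trace=np.array([-1.0]), converged=True,
            latent_mean=np.zeros((5, M)), config=mdsi.EstimationConfig(),
            region_names=[f"R{i}" for i in range(M)])

    def test_one_network_per_condition(self):
        nets = mdsi.extract_networks(self._dummy_fit())
        assert [n.condition for n in nets] == ["c0", "c1"]

    def test_weights_are_the_fitted_coupling(self):
        fit = self._dummy_fit()
        nets = mdsi.extract_networks(fit)
        for j, net in enumerate(nets):
            np.testing.assert_array_equal(net.weights, fit.model.coupling[j])

    def test_eleven_regions_have_110_connections(self):
        nets = mdsi.extract_networks(self._dummy_fit(M=11))
        assert nets[0].offdiagonal_vector().size == 110

    def test_baseline_excluded_by_default(self):
        fit = self._dummy_fit()
        assert len(mdsi.extract_networks(fit)) == 2
        assert len(mdsi.extract_networks(fit, include_baseline=True)) == 3
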