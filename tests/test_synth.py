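"""Generator tests: HRF basis, block design, simulation physics, cohorts."""

import dataclasses

import numpy as np
import pytest
from scipy import linalg as sla

from dynconn import synth


class TestHRFBasis:
    def test_shape_and_lag_zero(self):
        basis = synth.make_hrf_basis(0.72, 32.4, 2)
        assert basis.basis_matrix.shape == (2, 45)
        assert basis.basis_matrix[0, 0] == 0.0  # double-gamma vanishes at t=0

    def test_sampled_peak_brackets_dense_grid_peak(self):
        # dense-grid evaluation of the double-gamma is the oracle for where
        # the sampled canonical row must peak
        tr = 0.72
        basis = synth.make_hrf_basis(tr, 32.4, 1)
        grid = np.arange(0, 32.4, 0.01)
        peak_time = grid[np.argmax(synth.double_gamma(grid))]
        sampled_peak = np.argmax(basis.basis_matrix[0]) * tr
        assert abs(sampled_peak - peak_time) <= tr

    def test_rows_unit_peak(self):
        basis = synth.make_hrf_basis(1.0, 30.0, 2)
        assert np.max(np.abs(basis.basis_matrix), axis=1) == pytest.approx([1, 1])

    @pytest.mark.parametrize("tr,dur", [(-1, 30), (1, 0.5)])
    def test_invalid_arguments(self, tr, dur):
        with pytest.raises(ValueError):
            synth.make_hrf_basis(tr, dur)


class TestNbackDesign:
    def test_default_session_length(self, hcp_design):
        assert hcp_design.n_timepoints == 405
        assert hcp_design.indicators.shape == (2, 405)

    def test_conditions_mutually_exclusive(self, hcp_design):
        prod = hcp_design.indicators[0] * hcp_design.indicators[1]
        assert not prod.any()

    def test_matches_fine_timeline_oracle(self, hcp_design):
        # rebuild per-frame labels from a 0.01-s event timeline
        tr = hcp_design.tr_seconds
        fine = {}
        for _, row in hcp_design.events.iterrows():
            t0, t1 = row["onset"], row["onset"] + row["duration"]
            fine[row["condition"]] = (t0, t1)
        grid_labels = np.zeros_like(hcp_design.indicators)
        for f in range(hcp_design.n_timepoints):
            onset = f * tr
            for _, row in hcp_design.events.iterrows():
                if row["onset"] - 1e-9 <= onset < row["onset"] + row["duration"] - 1e-9:
                    j = list(hcp_design.condition_names).index(row["condition"])
                    grid_labels[j, f] = 1
        np.testing.assert_array_equal(grid_labels, hcp_design.indicators)

    def test_blocks_exceeding_session_raise(self):
        with pytest.raises(ValueError, match="session holds"):
            synth.make_nback_design(frames_per_session=100)

    def test_fixation_frames_unlabeled(self, hcp_design):
        # 4 x 15 s fixation + 8 x 2.5 s cues leave many unlabeled frames
        rest = hcp_design.n_timepoints - hcp_design.indicators.sum()
        assert rest > 100


class TestSimulateSubject:
    def test_zero_dynamics_zero_noise(self, tiny_design, coarse_basis):
        model = synth.MDSIModel(
            coupling=np.zeros((2, 3, 3)), state_noise_var=0.0,
            hrf_weights=np.column_stack([np.ones(3), np.zeros(3)]),
            obs_noise_var=np.full(3, 0.5), basis=coarse_basis,
            condition_names=tiny_design.condition_names,
            baseline_coupling=np.zeros((3, 3)))
        subj = synth.simulate_subject(model, tiny_design, seed=0)
        assert not subj.latent.any()
        # bold is then observation noise only
        assert subj.bold.var(axis=0) == pytest.approx(
            np.full(3, 0.5), rel=0.5)

    def test_impulse_reproduces_canonical_hrf(self, coarse_basis):
        # a unit latent impulse must appear in the BOLD as the HRF samples
        design = synth.make_nback_design(
            tr_seconds=2.0, frames_per_session=30, n_sessions=1,
            cue_seconds=0.0, fixation_blocks=0, blocks_per_session=2,
            trials_per_block=3, trial_seconds=4.0)
        M = 2
        model = synth.MDSIModel(
            coupling=np.zeros((2, M, M)), state_noise_var=0.0,
            hrf_weights=np.column_stack([np.ones(M), np.zeros(M)]),
            obs_noise_var=np.zeros(M), basis=coarse_basis,
            condition_names=design.condition_names,
            baseline_coupling=np.zeros((M, M)))
        latent = np.zeros((30, M))
        t0 = 5
        latent[t0, 1] = 1.0
        bold = synth._convolve_bold(model, latent, keep=30,
                                    rng=np.random.default_rng(0))
        hrf = coarse_basis.basis_matrix[0]
        np.testing.assert_allclose(
            bold[t0:t0 + len(hrf), 1], hrf[: 30 - t0], atol=1e-12)
        assert not bold[:, 0].any()

    def test_latent_variance_matches_lyapunov_fixed_point(self, coarse_basis):
        # constant-condition simulation converges to P = C P C' + Q I
        rng = np.random.default_rng(5)
        C = rng.normal(0, 0.3, (3, 3))
        C *= 0.7 / synth.spectral_radius(C)
        T = 20_000
        design = synth.design_from_events(
            events=__import__("pandas").DataFrame(
                {"onset": [0.0], "duration": [float(T)], "condition": ["on"]}),
            tr_seconds=1.0, n_timepoints=T, condition_names=("on",))
        model = synth.MDSIModel(
            coupling=C[None], state_noise_var=1.0,
            hrf_weights=np.column_stack([np.ones(3), np.zeros(3)]),
            obs_noise_var=np.zeros(3), basis=coarse_basis,
            condition_names=("on",))
        subj = synth.simulate_subject(model, design, seed=1)
        P = sla.solve_discrete_lyapunov(C, np.eye(3))
        emp = np.cov(subj.latent.T)
        assert np.abs(emp - P).max() / np.abs(P).max() < 0.05

    def test_unstable_coupling_raises_with_condition_name(self, tiny_design,
                                                          coarse_basis):
        coupling = np.zeros((2, 3, 3))
        coupling[1] = 1.2 * np.eye(3)
        model = synth.MDSIModel(
            coupling=coupling, state_noise_var=1.0,
            hrf_weights=np.column_stack([np.ones(3), np.zeros(3)]),
            obs_noise_var=np.ones(3), basis=coarse_basis,
            condition_names=tiny_design.condition_names)
        with pytest.raises(synth.UnstableSystemError, match="2-back.*1.2"):
            synth.simulate_subject(model, tiny_design, seed=0)

    def test_observation_noise_conservation(self, coarse_basis):
        # bold minus the noiseless reconstruction from the stored latent has
        # per-region variance close to sigma_m^2
        T = 2500
        design = synth.design_from_events(
            events=__import__("pandas").DataFrame(
                {"onset": [0.0], "duration": [float(T)], "condition": ["on"]}),
            tr_seconds=1.0, n_timepoints=T, condition_names=("on",))
        truth = synth.default_template_model(
            n_regions=3, basis=coarse_basis, condition_names=("on",), seed=2)
        truth = dataclasses.replace(truth, obs_noise_var=np.array([1.0, 2.0, 0.5]))
        subj = synth.simulate_subject(truth, design, seed=9, burn_in=0)
        noiseless = synth._convolve_bold(
            dataclasses.replace(truth, obs_noise_var=np.zeros(3)),
            subj.latent, keep=T, rng=np.random.default_rng(0))
        resid_var = (subj.bold - noiseless).var(axis=0)
        np.testing.assert_allclose(resid_var, truth.obs_noise_var, rtol=0.10)


class TestCohort:
    def test_determinism(self, tiny_design, coarse_basis):
        template = synth.default_template_model(
            n_regions=3, basis=coarse_basis, seed=1)
        spec = synth.CohortSpec(n_subjects=3, master_seed=7)
        c1 = synth.simulate_cohort(spec, template, tiny_design)
        c2 = synth.simulate_cohort(spec, template, tiny_design)
        for a, b in zip(c1, c2):
            np.testing.assert_array_equal(a.bold, b.bold)
            assert a.behavior == b.behavior

    def test_empty_cohort(self, tiny_design, coarse_basis):
        template = synth.default_template_model(
            n_regions=3, basis=coarse_basis, seed=1)
        assert synth.simulate_cohort(
            synth.CohortSpec(n_subjects=0), template, tiny_design) == []

    def test_behavior_loading_correlation_matches_variance_components(
            self, tiny_design, coarse_basis):
        # accuracy = baseline + w_s + noise with w_s ~ N(template, sd_b^2):
        # corr(w, acc) = sd_b / sqrt(sd_b^2 + sd_n^2)
        template = synth.default_template_model(
            n_regions=4, basis=coarse_basis, seed=1)
        sd_b, sd_n = 0.05, 0.1
        spec = synth.CohortSpec(
            n_subjects=500, between_subject_sd=sd_b,
            accuracy_loadings={("2-back", 3, 1): 1.0},
            behavior_noise_sd=sd_n, master_seed=13)
        cohort = synth.simulate_cohort(spec, template, tiny_design)
        w = np.array([s.truth.coupling[1, 3, 1] for s in cohort])
        acc = np.array([s.behavior["2-back"]["accuracy"] for s in cohort])
        expected = sd_b / np.hypot(sd_b, sd_n)
        assert np.corrcoef(w, acc)[0, 1] == pytest.approx(expected, abs=0.1)

    def test_stability_retry_bound(self, tiny_design, coarse_basis):
        template = synth.default_template_model(
            n_regions=4, basis=coarse_basis, seed=1)
        spec = synth.CohortSpec(n_subjects=1, between_subject_sd=5.0,
                                max_stability_retries=3)
        with pytest.raises(synth.UnstableSystemError, match="reduce"):
            synth.simulate_cohort(spec, template, tiny_design)


class TestVoxelROI:
    def test_noiseless_is_rank_one(self):
        tc = np.sin(np.linspace(0, 10, 100))
        mat = synth.simulate_voxel_roi(tc, 20, noise_sd=0.0, seed=0)
        assert np.linalg.matrix_rank(mat) == 1

    def test_single_voxel_proportional(self):
        tc = np.random.default_rng(0).normal(size=50)
        mat = synth.simulate_voxel_roi(tc, 1, noise_sd=0.0, seed=1)
        r = np.corrcoef(mat[:, 0], tc)[0, 1]
        assert abs(r) == pytest.approx(1.0)

    def test_first_singular_fraction_matches_variance_ratio(self):
        # SVD oracle: with voxel_i = a_i x + noise, the centered matrix's
        # s1^2 / sum(s^2) approaches E[a^2] var(x) / (E[a^2] var(x) + sd^2)
        rng = np.random.default_rng(2)
        tc = rng.normal(size=2000)
        loading_sd, noise_sd = 0.2, 0.5
        mat = synth.simulate_voxel_roi(tc, 400, loading_sd, noise_sd, seed=3)
        s = np.linalg.svd(mat - mat.mean(axis=0), compute_uv=False)
        frac = s[0] ** 2 / (s**2).sum()
        ea2 = 1.0 + loading_sd**2
        pred = ea2 * tc.var() / (ea2 * tc.var() + noise_sd**2)
        assert frac == pytest.approx(pred, abs=0.05)
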