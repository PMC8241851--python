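import numpy as np
import pytest

from dynconn import mdsi, synth


@pytest.fixture(scope="session")
def hcp_design():
    """One session of the HCP-like n-back block layout."""
    return synth.make_nback_design(n_sessions=1)


@pytest.fixture(scope="session")
def coarse_basis():
    """Short two-basis HRF sampled at TR = 2 s (6 lags)."""
    return synth.make_hrf_basis(2.0, 12.0 - 1e-9, 2)


@pytest.fixture(scope="session")
def dense_design():
    """Alternating-condition block design with no fixation: 2 sessions of
    400 frames at TR 2 s (the recovery-study layout)."""
    return synth.make_nback_design(
        tr_seconds=2.0, frames_per_session=400, n_sessions=2,
        cue_seconds=0.0, fixation_blocks=0, blocks_per_session=31,
        trials_per_block=10, trial_seconds=2.5)


@pytest.fixture(scope="session")
def tiny_design():
    """A 40-frame two-condition design for fast cohort-level tests."""
    return synth.make_nback_design(
        tr_seconds=1.0, frames_per_session=40, n_sessions=1,
        cue_seconds=0.0, fixation_blocks=0, blocks_per_session=4,
        trials_per_block=4, trial_seconds=2.0)


@pytest.fixture(scope="session")
def small_truth(coarse_basis, dense_design):
    truth = synth.default_template_model(
        n_regions=4, basis=coarse_basis, seed=3)
    return synth.calibrate_obs_noise(truth, dense_design, snr=1.0, seed=11)


@pytest.fixture(scope="session")
def fitted_subject(small_truth, dense_design, coarse_basis):
    """One simulated subject and its EM fit (shared across tests)."""
    subj = synth.simulate_subject(small_truth, dense_design, seed=42)
    cfg = mdsi.EstimationConfig(max_iterations=40, n_random_starts=1)
    fit = mdsi.fit_mdsi(subj.bold, dense_design, coarse_basis, cfg)
    return subj, fit


def planted_block_matrix(rng=None, within=0.8, between=-0.15, noise=0.05):
    """11-node signed directed matrix with four planted communities
    ({0,1,2}, {3,5,7}, {4,6,8}, {9,10})."""
    blocks = [(0, 1, 2), (3, 5, 7), (4, 6, 8), (9, 10)]
    rng = rng or np.random.default_rng(0)
    w = rng.normal(between, noise, (11, 11))
    for b in blocks:
        for i in b:
            for j in b:
                if i != j:
                    w[i, j] = within + rng.normal(0, noise)
    np.fill_diagonal(w, 0.0)
    return w, blocks
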