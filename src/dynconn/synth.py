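"""Synthetic multi-subject BOLD generator with known causal ground truth.

The generative model mirrors the analysis model: per-condition latent
first-order MVAR dynamics, convolved region-by-region with a two-basis
hemodynamic response (canonical double-gamma + temporal derivative), plus
iid Gaussian observation noise. A block n-back design controls which
coupling matrix drives the latent state at each frame; fixation frames use
an always-on baseline (intrinsic) coupling matrix so the dynamics stay
defined between task blocks.

Behavioral scores (accuracy, reaction time per condition) are a linear
function of each subject's true coupling weights plus Gaussian noise, which
gives downstream brain-behavior analyses a planted effect to recover.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from . import io

__all__ = [
    "HRFBasis",
    "TaskDesign",
    "MDSIModel",
    "SyntheticSubject",
    "CohortSpec",
    "make_hrf_basis",
    "double_gamma",
    "make_nback_design",
    "design_from_events",
    "simulate_subject",
    "simulate_cohort",
    "simulate_voxel_roi",
    "calibrate_obs_noise",
    "default_template_model",
    "write_subject_tsv",
]

REST = "rest"
DEFAULT_BURN_IN = 50


# ---------------------------------------------------------------------------
# HRF basis


def double_gamma(
    t,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_disp: float = 1.0,
    undershoot_disp: float = 1.0,
    undershoot_ratio: float = 1.0 / 6.0,
):
    """Canonical double-gamma HRF evaluated at times ``t`` (seconds).

    h(t) = g(t; a1, d1) - ratio * g(t; a2, d2) with gamma-density lobes
    parameterized by delay and dispersion (shape = delay / dispersion,
    scale = dispersion). Vanishes at t = 0 and for t < 0.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0

    def lobe(tt, delay, disp):
        a = delay / disp
        # gamma pdf with shape a, scale disp, in log space for stability
        return np.exp(
            (a - 1) * np.log(tt) - tt / disp - gammaln(a) - a * np.log(disp)
        )

    tt = t[pos]
    out[pos] = lobe(tt, peak_delay, peak_disp) - undershoot_ratio * lobe(
        tt, undershoot_delay, undershoot_disp
    )
    return out


def _double_gamma_deriv(t, **kw):
    dt = 1e-4
    return (double_gamma(np.asarray(t) + dt, **kw) - double_gamma(t, **kw)) / dt


@dataclass(frozen=True)
class HRFBasis:
    """Hemodynamic basis set: rows are basis functions sampled at the TR.

    Row 0 is the canonical double-gamma HRF; row 1 (when present) its
    temporal derivative. Rows are unit-peak normalized.
    """

    basis_matrix: np.ndarray  # p x L
    tr_seconds: float

    @property
    def n_basis(self) -> int:
        return self.basis_matrix.shape[0]

    @property
    def n_lags(self) -> int:
        return self.basis_matrix.shape[1]


def make_hrf_basis(
    tr_seconds: float = 0.72,
    duration_seconds: float = 32.4,
    n_basis: int = 2,
) -> HRFBasis:
    """Sample the canonical HRF (and optionally its derivative) at the TR.

    The number of lags is ``ceil(duration / TR)``; lag times are
    0, TR, ..., (L-1)*TR.
    """
    if tr_seconds <= 0:
        raise ValueError(f"tr_seconds must be positive, got {tr_seconds}")
    if duration_seconds < tr_seconds:
        raise ValueError("duration_seconds must be at least one TR")
    if n_basis not in (1, 2):
        raise ValueError("n_basis must be 1 or 2")
    n_lags = math.ceil(duration_seconds / tr_seconds)
    lags = np.arange(n_lags) * tr_seconds
    rows = [double_gamma(lags)]
    if n_basis == 2:
        rows.append(_double_gamma_deriv(lags))
    basis = np.stack(rows)
    peaks = np.max(np.abs(basis), axis=1, keepdims=True)
    peaks[peaks == 0] = 1.0
    return HRFBasis(basis_matrix=basis / peaks, tr_seconds=float(tr_seconds))


# ---------------------------------------------------------------------------
# Task design


@dataclass(frozen=True)
class TaskDesign:
    """Condition indicator time courses sampled at the TR (block design).

    ``indicators`` is J x T in {0, 1}; at most one analysis condition is
    active per frame, fixation frames are all-zero. ``session_lengths``
    partitions the T frames into acquisition sessions (the estimator treats
    session boundaries as likelihood breaks).
    """

    indicators: np.ndarray
    condition_names: tuple
    tr_seconds: float
    session_lengths: tuple
    events: pd.DataFrame = field(compare=False, repr=False, default=None)

    @property
    def n_conditions(self) -> int:
        return self.indicators.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.indicators.shape[1]

    def condition_index(self) -> np.ndarray:
        """Per-frame active condition index; frames with no active analysis
        condition (fixation/cue/trailing rest) get index J."""
        ind = self.indicators
        if ind.size and (ind.sum(axis=0) > 1).any():
            raise ValueError("more than one condition active on some frame")
        idx = np.full(self.n_timepoints, self.n_conditions, dtype=int)
        for j in range(self.n_conditions):
            idx[ind[j] > 0] = j
        return idx

    def validate(self) -> None:
        ind = self.indicators
        if ind.ndim != 2:
            raise ValueError("indicators must be J x T")
        if not np.isin(ind, (0, 1)).all():
            raise ValueError("indicators must be 0/1")
        if (ind.sum(axis=0) > 1).any():
            raise ValueError("overlapping condition blocks")
        if ind.shape[1] != sum(self.session_lengths):
            raise ValueError("session lengths do not sum to T")
        for j, name in enumerate(self.condition_names):
            if ind[j].sum() == 0:
                raise ValueError(f"condition {name!r} has no active frame")


def _default_schedule(blocks_per_session: int, fixation_blocks: int,
                      condition_names) -> list:
    """Interleave task blocks (alternating conditions) with evenly spaced
    fixation blocks: [task, task, fix, task, task, fix, ...]."""
    sched = []
    n_cond = len(condition_names)
    per_fix = blocks_per_session // max(fixation_blocks, 1) if fixation_blocks else 0
    placed_fix = 0
    for b in range(blocks_per_session):
        sched.append(condition_names[b % n_cond])
        if fixation_blocks and (b + 1) % per_fix == 0 and placed_fix < fixation_blocks:
            sched.append(REST)
            placed_fix += 1
    while placed_fix < fixation_blocks:
        sched.append(REST)
        placed_fix += 1
    return sched


def make_nback_design(
    tr_seconds: float = 0.72,
    n_sessions: int = 2,
    blocks_per_session: int = 8,
    trials_per_block: int = 10,
    trial_seconds: float = 2.5,
    cue_seconds: float = 2.5,
    fixation_blocks: int = 4,
    fixation_seconds: float = 15.0,
    frames_per_session: int = 405,
    condition_names=("0-back", "2-back"),
    schedule=None,
) -> TaskDesign:
    """Build an HCP-style block n-back design sampled at the TR.

    Defaults reproduce the HCP working-memory layout: per session, 8 task
    blocks (2.5 s cue followed by 10 trials of 2.5 s) and 4 fixation blocks
    of 15 s, acquired over 405 frames at TR 0.72 s. A frame is marked for a
    condition when its onset falls inside that block's trial period (the cue
    is not marked). 2-back and 0-back blocks alternate unless an explicit
    ``schedule`` (list of condition names and ``"rest"`` tokens) is given.
    """
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    for name, v in [
        ("n_sessions", n_sessions), ("blocks_per_session", blocks_per_session),
        ("trials_per_block", trials_per_block), ("fixation_blocks", fixation_blocks),
        ("frames_per_session", frames_per_session),
    ]:
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    if schedule is None:
        schedule = _default_schedule(blocks_per_session, fixation_blocks,
                                     condition_names)
    session_seconds = frames_per_session * tr_seconds
    events = []
    for s in range(n_sessions):
        t = 0.0
        offset = s * session_seconds
        for token in schedule:
            if token == REST:
                t += fixation_seconds
            else:
                if token not in condition_names:
                    raise ValueError(f"unknown schedule token {token!r}")
                t += cue_seconds
                events.append(
                    (offset + t, trials_per_block * trial_seconds, token))
                t += trials_per_block * trial_seconds
        if t > session_seconds + 1e-9:
            raise ValueError(
                f"blocks need {t:.1f} s but session holds only "
                f"{session_seconds:.1f} s ({frames_per_session} frames)")
    events = pd.DataFrame(events, columns=["onset", "duration", "condition"])
    T = n_sessions * frames_per_session
    design = design_from_events(events, tr_seconds, T, condition_names,
                                session_lengths=(frames_per_session,) * n_sessions)
    return design


def design_from_events(
    events: pd.DataFrame,
    tr_seconds: float,
    n_timepoints: int,
    condition_names=None,
    session_lengths=None,
) -> TaskDesign:
    """Sample indicator time courses from an onset/duration/condition table.

    A frame is marked when its onset time (frame_index * TR) lies in
    [onset, onset + duration) of a block of that condition.
    """
    if condition_names is None:
        condition_names = tuple(pd.unique(events["condition"]))
    onsets = np.arange(n_timepoints) * tr_seconds
    ind = np.zeros((len(condition_names), n_timepoints), dtype=int)
    for _, row in events.iterrows():
        j = list(condition_names).index(row["condition"])
        inside = (onsets >= row["onset"] - 1e-9) & (
            onsets < row["onset"] + row["duration"] - 1e-9)
        ind[j, inside] = 1
    if session_lengths is None:
        session_lengths = (n_timepoints,)
    design = TaskDesign(
        indicators=ind,
        condition_names=tuple(condition_names),
        tr_seconds=float(tr_seconds),
        session_lengths=tuple(session_lengths),
        events=events,
    )
    design.validate()
    return design


# ---------------------------------------------------------------------------
# Generative model


class UnstableSystemError(ValueError):
    """A coupling matrix has spectral radius >= 1."""


def spectral_radius(a: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(a))))


@dataclass
class MDSIModel:
    """Latent linear state-space model of condition-specific causal coupling.

    ``coupling[j]`` is the M x M matrix for condition j; entry (m, n) is the
    signed influence of region n on region m at a one-frame lag.
    ``baseline_coupling`` drives frames where no analysis condition is
    active. The BOLD observation convolves each region's lagged latent
    signal with the HRF ``hrf_weights[m] @ basis.basis_matrix`` and adds
    Gaussian noise with variance ``obs_noise_var[m]``. State noise is iid
    Gaussian with per-region variance ``state_noise_var``.
    """

    coupling: np.ndarray  # J x M x M
    state_noise_var: float
    hrf_weights: np.ndarray  # M x p
    obs_noise_var: np.ndarray  # M
    basis: HRFBasis
    condition_names: tuple
    baseline_coupling: np.ndarray = None  # M x M

    def __post_init__(self):
        self.coupling = np.asarray(self.coupling, dtype=float)
        if self.coupling.ndim != 3 or self.coupling.shape[1] != self.coupling.shape[2]:
            raise ValueError("coupling must be J x M x M")
        self.hrf_weights = np.asarray(self.hrf_weights, dtype=float)
        self.obs_noise_var = np.asarray(self.obs_noise_var, dtype=float)
        if self.baseline_coupling is None:
            self.baseline_coupling = 0.5 * np.eye(self.n_regions)
        self.baseline_coupling = np.asarray(self.baseline_coupling, dtype=float)
        if (self.obs_noise_var < 0).any():
            raise ValueError("obs_noise_var must be non-negative")
        if self.state_noise_var < 0:
            raise ValueError("state_noise_var must be non-negative")
        if self.hrf_weights.shape != (self.n_regions, self.basis.n_basis):
            raise ValueError("hrf_weights must be M x p")

    @property
    def n_regions(self) -> int:
        return self.coupling.shape[1]

    @property
    def n_conditions(self) -> int:
        return self.coupling.shape[0]

    def all_coupling(self) -> np.ndarray:
        """Condition matrices with the baseline appended as index J."""
        return np.concatenate(
            [self.coupling, self.baseline_coupling[None]], axis=0)

    def check_stable(self) -> None:
        for j, name in enumerate(list(self.condition_names) + [REST]):
            rho = spectral_radius(self.all_coupling()[j])
            if rho >= 1.0:
                raise UnstableSystemError(
                    f"coupling matrix for condition {name!r} has spectral "
                    f"radius {rho:.3f} >= 1")

    def region_hrfs(self) -> np.ndarray:
        """M x L matrix of per-region HRFs (b_m @ basis rows)."""
        return self.hrf_weights @ self.basis.basis_matrix

    def to_dict(self) -> dict:
        return {
            "coupling": self.coupling,
            "baseline_coupling": self.baseline_coupling,
            "state_noise_var": self.state_noise_var,
            "hrf_weights": self.hrf_weights,
            "obs_noise_var": self.obs_noise_var,
            "basis_matrix": self.basis.basis_matrix,
            "tr_seconds": self.basis.tr_seconds,
            "condition_names": list(self.condition_names),
            "orientation": "entry (m, n) = influence of region n on region m",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MDSIModel":
        basis = HRFBasis(np.asarray(d["basis_matrix"], dtype=float),
                         float(d["tr_seconds"]))
        return cls(
            coupling=np.asarray(d["coupling"], dtype=float),
            state_noise_var=float(d["state_noise_var"]),
            hrf_weights=np.asarray(d["hrf_weights"], dtype=float),
            obs_noise_var=np.asarray(d["obs_noise_var"], dtype=float),
            basis=basis,
            condition_names=tuple(d["condition_names"]),
            baseline_coupling=np.asarray(d["baseline_coupling"], dtype=float),
        )


def default_template_model(
    n_regions: int = 5,
    condition_names=("0-back", "2-back"),
    basis: HRFBasis = None,
    coupling_scale: float = 0.35,
    self_decay: float = 0.3,
    seed: int = 0,
) -> MDSIModel:
    """A stable template model with distinct coupling per condition.

    Off-diagonal weights are sparse (about 40% of directed pairs) and drawn
    once from N(0, coupling_scale^2), independently per condition so the two
    conditions differ — this is the planted contrast that classification and
    stability analyses are expected to detect. Matrices are rescaled to
    spectral radius <= 0.7.
    """
    rng = np.random.default_rng(seed)
    J = len(condition_names)
    coupling = np.zeros((J, n_regions, n_regions))
    for j in range(J):
        c = rng.normal(0, coupling_scale, (n_regions, n_regions))
        mask = rng.random((n_regions, n_regions)) < 0.4
        c = c * mask
        np.fill_diagonal(c, self_decay)
        rho = spectral_radius(c)
        if rho > 0.7:
            c *= 0.7 / rho
        coupling[j] = c
    if basis is None:
        basis = make_hrf_basis()
    hrf_weights = np.column_stack(
        [np.ones(n_regions), rng.normal(0, 0.1, n_regions)])[:, : basis.n_basis]
    model = MDSIModel(
        coupling=coupling,
        state_noise_var=1.0,
        hrf_weights=hrf_weights,
        obs_noise_var=np.full(n_regions, 1.0),
        basis=basis,
        condition_names=tuple(condition_names),
    )
    model.check_stable()
    return model


# ---------------------------------------------------------------------------
# Simulation


@dataclass
class SyntheticSubject:
    bold: np.ndarray  # T x M
    latent: np.ndarray  # T x M
    design: TaskDesign
    truth: MDSIModel
    behavior: dict  # condition -> {"accuracy": float, "rt": float}
    subject_id: str
    seed: int


def _simulate_latent(model: MDSIModel, cond_idx: np.ndarray, rng,
                     burn_in: int) -> np.ndarray:
    """Latent MVAR recursion with s(0) = 0, baseline dynamics on rest frames
    and during burn-in; burn-in frames are returned too (caller trims)."""
    M = model.n_regions
    mats = model.all_coupling()
    rest = model.n_conditions
    full_idx = np.concatenate([np.full(burn_in, rest, dtype=int), cond_idx])
    T = len(full_idx)
    sd = math.sqrt(model.state_noise_var)
    noise = rng.normal(0.0, sd, (T, M)) if sd > 0 else np.zeros((T, M))
    s = np.zeros((T, M))
    prev = np.zeros(M)
    for t in range(T):
        prev = mats[full_idx[t]] @ prev + noise[t]
        s[t] = prev
    return s


def _convolve_bold(model: MDSIModel, latent_full: np.ndarray,
                   keep: int, rng) -> np.ndarray:
    """BOLD = per-region HRF convolution of the latent signal + obs noise.

    ``latent_full`` includes burn-in pre-history; only the last ``keep``
    frames are returned. Pre-history before the very first frame is zero.
    """
    hrfs = model.region_hrfs()  # M x L
    T_full, M = latent_full.shape
    y = np.empty((keep, M))
    for m in range(M):
        conv = np.convolve(latent_full[:, m], hrfs[m])[:T_full]
        y[:, m] = conv[T_full - keep:]
    sds = np.sqrt(model.obs_noise_var)
    if (sds > 0).any():
        y = y + rng.normal(0.0, 1.0, y.shape) * sds
    return y


DEFAULT_BEHAVIOR_BASELINES = {
    # group-mean n-back performance: (accuracy, reaction time ms)
    "0-back": (0.93, 738.0),
    "2-back": (0.86, 966.0),
}


def _behavior(model: MDSIModel, accuracy_loadings, rt_loadings,
              noise_sd: float, rng) -> dict:
    out = {}
    for j, cond in enumerate(model.condition_names):
        acc0, rt0 = DEFAULT_BEHAVIOR_BASELINES.get(cond, (0.5, 500.0))
        acc = acc0 + sum(
            w * model.coupling[j, m, n]
            for (c, m, n), w in (accuracy_loadings or {}).items() if c == cond)
        rt = rt0 + sum(
            w * model.coupling[j, m, n]
            for (c, m, n), w in (rt_loadings or {}).items() if c == cond)
        if noise_sd > 0:
            acc += rng.normal(0, noise_sd)
            rt += rng.normal(0, noise_sd)
        out[cond] = {"accuracy": float(acc), "rt": float(rt)}
    return out


def simulate_subject(
    truth: MDSIModel,
    design: TaskDesign,
    seed: int,
    burn_in: int = DEFAULT_BURN_IN,
    subject_id: str = "sub-000",
    accuracy_loadings=None,
    rt_loadings=None,
    behavior_noise_sd: float = 0.0,
) -> SyntheticSubject:
    """Simulate one subject's latent dynamics, BOLD, and behavior.

    The latent state starts at zero, runs ``burn_in`` frames of baseline
    dynamics per session (discarded), then follows the condition-specific
    coupling matrix of each design frame. Sessions are simulated
    independently (no state carry-over). Reproducible given ``seed``.
    """
    truth.check_stable()
    if truth.n_conditions != design.n_conditions:
        raise ValueError("model and design disagree on number of conditions")
    rng = np.random.default_rng(seed)
    cond_idx = design.condition_index()
    bold_parts, latent_parts = [], []
    start = 0
    for seg_len in design.session_lengths:
        seg_idx = cond_idx[start:start + seg_len]
        latent_full = _simulate_latent(truth, seg_idx, rng, burn_in)
        latent_parts.append(latent_full[burn_in:])
        bold_parts.append(_convolve_bold(truth, latent_full, seg_len, rng))
        start += seg_len
    behavior = _behavior(truth, accuracy_loadings, rt_loadings,
                         behavior_noise_sd, rng)
    return SyntheticSubject(
        bold=np.vstack(bold_parts),
        latent=np.vstack(latent_parts),
        design=design,
        truth=truth,
        behavior=behavior,
        subject_id=subject_id,
        seed=seed,
    )


@dataclass
class CohortSpec:
    """How to vary the template model across subjects.

    ``accuracy_loadings`` / ``rt_loadings`` map (condition, m, n) to the
    linear weight of the subject's true coupling entry on that behavioral
    score; between-subject variation in the scores then comes from the
    coupling perturbations plus ``behavior_noise_sd`` Gaussian noise.
    """

    n_subjects: int
    between_subject_sd: float = 0.05
    accuracy_loadings: dict = field(default_factory=dict)
    rt_loadings: dict = field(default_factory=dict)
    behavior_noise_sd: float = 0.02
    master_seed: int = 0
    max_stability_retries: int = 50

    def validate(self, template: MDSIModel) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        M = template.n_regions
        for loadings in (self.accuracy_loadings, self.rt_loadings):
            for (cond, m, n) in loadings:
                if cond not in template.condition_names:
                    raise ValueError(f"loading references unknown condition {cond!r}")
                if not (0 <= m < M and 0 <= n < M) or m == n:
                    raise ValueError(
                        f"loading ({cond}, {m}, {n}) must reference a valid "
                        "off-diagonal entry")


def _perturb_model(template: MDSIModel, sd: float, rng,
                   max_retries: int) -> MDSIModel:
    M = template.n_regions
    off = ~np.eye(M, dtype=bool)
    for _ in range(max_retries):
        coupling = template.coupling.copy()
        for j in range(template.n_conditions):
            coupling[j][off] += rng.normal(0, sd, off.sum())
        model = dataclasses.replace(template, coupling=coupling)
        try:
            model.check_stable()
            return model
        except UnstableSystemError:
            continue
    raise UnstableSystemError(
        f"could not draw a stable subject model in {max_retries} tries; "
        "reduce between_subject_sd")


def simulate_cohort(
    spec: CohortSpec,
    template: MDSIModel,
    design: TaskDesign,
    burn_in: int = DEFAULT_BURN_IN,
) -> list:
    """Simulate a cohort: per-subject coupling = template + Gaussian
    perturbations on off-diagonal entries, resampled until stable.
    Deterministic given ``spec.master_seed``."""
    spec.validate(template)
    template.check_stable()
    subjects = []
    seeds = np.random.SeedSequence(spec.master_seed).spawn(spec.n_subjects)
    for s, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        model = _perturb_model(template, spec.between_subject_sd, rng,
                               spec.max_stability_retries)
        sub_seed = int(ss.generate_state(1)[0] % (2**31))
        subj = simulate_subject(
            model, design, seed=sub_seed, burn_in=burn_in,
            subject_id=f"sub-{s:03d}",
            accuracy_loadings=spec.accuracy_loadings,
            rt_loadings=spec.rt_loadings,
            behavior_noise_sd=spec.behavior_noise_sd,
        )
        subjects.append(subj)
    return subjects


def simulate_voxel_roi(
    eigen_timecourse: np.ndarray,
    n_voxels: int,
    loading_sd: float = 0.2,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """T x N voxel matrix: voxel i = loading_i * timecourse + iid noise,
    with loadings ~ N(1, loading_sd^2). Fixture for eigenvariate extraction."""
    if n_voxels < 1:
        raise ValueError("n_voxels must be >= 1")
    tc = np.asarray(eigen_timecourse, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    loadings = rng.normal(1.0, loading_sd, n_voxels)
    mat = np.outer(tc, loadings)
    if noise_sd > 0:
        mat = mat + rng.normal(0.0, noise_sd, mat.shape)
    return mat


def calibrate_obs_noise(
    truth: MDSIModel, design: TaskDesign, snr: float, seed: int = 0,
    burn_in: int = DEFAULT_BURN_IN,
) -> MDSIModel:
    """Return a copy of ``truth`` whose observation-noise variances give the
    requested SNR = var(noiseless BOLD) / sigma_m^2 per region, measured on
    one noiseless realization of the design."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    noiseless = dataclasses.replace(
        truth, obs_noise_var=np.zeros(truth.n_regions))
    subj = simulate_subject(noiseless, design, seed=seed, burn_in=burn_in)
    sig_var = subj.bold.var(axis=0)
    return dataclasses.replace(truth, obs_noise_var=sig_var / snr)


# ---------------------------------------------------------------------------
# Exports


def write_subject_tsv(subject: SyntheticSubject, out_dir, region_names=None):
    """Write a subject's BOLD TSV, events TSV, and truth JSON."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    M = subject.truth.n_regions
    if region_names is None:
        region_names = [f"R{i}" for i in range(M)]
    io.write_timeseries_tsv(
        out_dir / f"{subject.subject_id}_bold.tsv", subject.bold, region_names)
    if subject.design.events is not None:
        io.write_events_tsv(
            out_dir / f"{subject.subject_id}_events.tsv", subject.design.events)
    truth = subject.truth.to_dict()
    truth["seed"] = subject.seed
    truth["behavior"] = subject.behavior
    io.write_json(out_dir / f"{subject.subject_id}_truth.json", truth)
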