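"""Multivariate dynamical systems identification (MDSI).

Estimates condition-specific directed coupling between brain regions from
BOLD time series via a latent linear state-space model:

  state:        s(t) = C_{j(t)} s(t-1) + w(t),   w(t) ~ N(0, Q I)
  observation:  y_m(t) = b_m Phi x_m(t) + e_m(t),  e_m ~ N(0, sigma_m^2)

where j(t) is the condition active at frame t (an always-on baseline matrix
drives frames with no active condition), x_m(t) stacks the last L latent
values of region m, and Phi holds HRF basis functions so each region has its
own hemodynamic response b_m Phi.

Estimation is maximum-likelihood EM: the E-step runs an exact Kalman
filter / RTS smoother on the companion-form augmented state (the L stacked
lags), and the M-step updates each C_j, the HRF weights b_m, and the
observation noise in closed form from smoothed second moments. The state
noise variance Q is fixed to 1 as the identifiability gauge (latent scale
and hemodynamic gain trade off exactly; the gauge pins the latent scale and
b_m absorbs the gain — the coupling matrices are invariant to this choice).

Per-frame condition weighting follows the block design: each frame's
transition uses the single active condition's matrix, so each C_j update
pools exactly the frames of condition j.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

from .synth import REST, HRFBasis, MDSIModel, TaskDesign, spectral_radius

__all__ = [
    "EstimationConfig",
    "FitResult",
    "CausalNetwork",
    "kalman_smooth",
    "fit_mdsi",
    "extract_networks",
    "SmoothResult",
]

_PRIOR_VAR = 10.0  # diffuse-ish prior variance on the initial augmented state


class EstimationFailure(RuntimeError):
    pass


class NumericalFailure(RuntimeError):
    pass


@dataclass
class EstimationConfig:
    max_iterations: int = 50
    loglik_tolerance: float = 1e-5   # relative change stopping rule
    n_random_starts: int = 3
    seed: int = 0
    estimate_baseline: bool = True   # False freezes C_rest at diagonal decay
    n_lags: int | None = None        # override L (truncate/extend HRF window)
    fix_hrf_weights: bool = False    # keep b_m at initialization
    fix_obs_noise: float | None = None  # freeze all sigma_m^2 at this value
    init_regularization: float = 1.0

    def __post_init__(self):
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.loglik_tolerance <= 0:
            raise ValueError("loglik_tolerance must be positive")


@dataclass
class CausalNetwork:
    """One signed weighted directed coupling matrix.

    Orientation: ``weights[m, n]`` is the influence of region n on region m.
    """

    weights: np.ndarray
    condition: str
    region_names: list
    subject_id: str = ""

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise ValueError("weights must be square")
        if not np.isfinite(self.weights).all():
            raise ValueError("non-finite weights")
        if len(self.region_names) != self.weights.shape[0]:
            raise ValueError("region_names length must match matrix size")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def offdiagonal_vector(self) -> np.ndarray:
        """Row-major vector of the M(M-1) off-diagonal weights."""
        m = self.weights
        mask = ~np.eye(m.shape[0], dtype=bool)
        return m[mask]


@dataclass
class SmoothResult:
    """Posterior latent moments from the Kalman filter / RTS smoother."""

    loglik: float
    latent_mean: np.ndarray       # T x M smoothed E[s(t) | y]
    means: np.ndarray = field(repr=False)        # T x d augmented means
    covs: np.ndarray = field(repr=False)         # T x d x d augmented covs
    lag_one: np.ndarray = field(repr=False)      # T x d x d Cov(z_t, z_{t-1})
    segment_starts: np.ndarray = field(repr=False)


def _observation_matrix(model: MDSIModel, n_lags: int) -> np.ndarray:
    """M x (M*L) matrix: row m applies b_m Phi to region m's lag window."""
    M = model.n_regions
    hrfs = model.region_hrfs()  # M x L_basis
    L = n_lags
    H = np.zeros((M, M * L))
    for m in range(M):
        h = hrfs[m][:L]
        H[m, np.arange(len(h)) * M + m] = h
    return H


def _segments(design: TaskDesign):
    starts, stops = [], []
    t = 0
    for seg in design.session_lengths:
        starts.append(t)
        stops.append(t + seg)
        t += seg
    return starts, stops


def kalman_smooth(
    bold: np.ndarray,
    design: TaskDesign,
    model: MDSIModel,
    n_lags: int | None = None,
) -> SmoothResult:
    """Exact Gaussian smoothing of the latent state given BOLD and a model.

    Runs a forward Kalman filter and backward RTS smoother on the
    companion-form augmented state z(t) = [s(t); s(t-1); ...; s(t-L+1)].
    The transition applies the active condition's coupling matrix to the
    first block and shifts the rest; the observation row for region m is
    b_m Phi on region m's lag window. Sessions are filtered independently
    (state prior re-initialized at each session start). Returns posterior
    means, covariances, lag-one cross-covariances and the exact marginal
    log-likelihood.
    """
    y = np.asarray(bold, dtype=float)
    T, M = y.shape
    if M != model.n_regions:
        raise ValueError("bold columns must match model regions")
    if T != design.n_timepoints:
        raise ValueError("bold frames must match design")
    L = n_lags if n_lags is not None else model.basis.n_lags
    d = M * L
    H = _observation_matrix(model, L)
    R = np.diag(np.maximum(model.obs_noise_var, 1e-12))
    mats = model.all_coupling()
    cond_idx = design.condition_index()
    Q = model.state_noise_var

    m_filt = np.zeros((T, d))
    P_filt = np.zeros((T, d, d))
    m_pred = np.zeros((T, d))
    P_pred = np.zeros((T, d, d))
    loglik = 0.0
    eye_d = np.eye(d)
    seg_starts, seg_stops = _segments(design)
    seg_start_set = set(seg_starts)

    for t in range(T):
        if t in seg_start_set:
            # prior scales with Q so the latent-scale gauge is exact
            mp = np.zeros(d)
            Pp = _PRIOR_VAR * max(Q, 1e-12) * eye_d
        else:
            A = mats[cond_idx[t]]
            prev_m = m_filt[t - 1]
            prev_P = P_filt[t - 1]
            mp = np.empty(d)
            mp[:M] = A @ prev_m[:M]
            mp[M:] = prev_m[: d - M]
            FP = np.empty((d, d))
            FP[:M] = A @ prev_P[:M]
            FP[M:] = prev_P[: d - M]
            Pp = np.empty((d, d))
            Pp[:, :M] = FP[:, :M] @ A.T
            Pp[:, M:] = FP[:, : d - M]
            Pp = 0.5 * (Pp + Pp.T)
            Pp[:M, :M] += Q * np.eye(M)
        m_pred[t] = mp
        P_pred[t] = Pp

        v = y[t] - H @ mp
        PHt = Pp @ H.T
        S = H @ PHt + R
        S = 0.5 * (S + S.T)
        try:
            cf = sla.cho_factor(S, lower=True, check_finite=False)
        except sla.LinAlgError as exc:
            raise NumericalFailure(
                f"innovation covariance not PD at frame {t}") from exc
        Sinv_v = sla.cho_solve(cf, v, check_finite=False)
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        loglik += -0.5 * (M * np.log(2 * np.pi) + logdet + v @ Sinv_v)
        K = sla.cho_solve(cf, PHt.T, check_finite=False).T
        m_filt[t] = mp + K @ v
        IKH = eye_d - K @ H
        Pf = IKH @ Pp @ IKH.T + K @ R @ K.T   # Joseph form
        P_filt[t] = 0.5 * (Pf + Pf.T)

    if not np.isfinite(loglik):
        raise NumericalFailure("non-finite log-likelihood")

    # RTS smoother, per segment
    m_sm = np.zeros((T, d))
    P_sm = np.zeros((T, d, d))
    lag_one = np.zeros((T, d, d))  # lag_one[t] = Cov(z_t, z_{t-1} | y)
    for start, stop in zip(seg_starts, seg_stops):
        m_sm[stop - 1] = m_filt[stop - 1]
        P_sm[stop - 1] = P_filt[stop - 1]
        for t in range(stop - 2, start - 1, -1):
            A = mats[cond_idx[t + 1]]
            prev_P = P_filt[t]
            # F P_filt' computed structurally: (F prev_P)' = prev_P F'
            FP = np.empty((d, d))
            FP[:M] = A @ prev_P[:M]
            FP[M:] = prev_P[: d - M]
            # J = P_filt F' P_pred^{-1}  -> solve P_pred J' = F P_filt
            J = np.linalg.solve(P_pred[t + 1], FP).T
            m_sm[t] = m_filt[t] + J @ (m_sm[t + 1] - m_pred[t + 1])
            Ps = prev_P + J @ (P_sm[t + 1] - P_pred[t + 1]) @ J.T
            P_sm[t] = 0.5 * (Ps + Ps.T)
            lag_one[t + 1] = P_sm[t + 1] @ J.T

    return SmoothResult(
        loglik=float(loglik),
        latent_mean=m_sm[:, :M].copy(),
        means=m_sm,
        covs=P_sm,
        lag_one=lag_one,
        segment_starts=np.asarray(seg_starts),
    )


@dataclass
class FitResult:
    model: MDSIModel
    loglik_trace: np.ndarray
    converged: bool
    latent_mean: np.ndarray
    config: EstimationConfig
    region_names: list
    subject_id: str = ""

    def to_dict(self) -> dict:
        d = self.model.to_dict()
        d.update(
            loglik_trace=self.loglik_trace,
            converged=self.converged,
            region_names=self.region_names,
            subject_id=self.subject_id,
            config={k: v for k, v in dataclasses.asdict(self.config).items()},
        )
        return d


def _deconvolve(y, design, basis, lam):
    """Regularized least-squares deconvolution of the canonical HRF,
    session by session: argmin_s ||y - h * s||^2 + lam ||s||^2."""
    h = basis.basis_matrix[0]
    T, M = y.shape
    s_hat = np.empty_like(y)
    start = 0
    for seg in design.session_lengths:
        Hc = np.zeros((seg, seg))
        for l, hv in enumerate(h[:seg]):
            idx = np.arange(seg - l)
            Hc[idx + l, idx] = hv
        G = Hc.T @ Hc + lam * np.eye(seg)
        s_hat[start:start + seg] = np.linalg.solve(G, Hc.T @ y[start:start + seg])
        start += seg
    return s_hat


def _init_coupling(y, design, basis, n_conditions, estimate_baseline,
                   lam: float = 1.0):
    """Per-condition ridge VAR(1) on HRF-deconvolved BOLD — a proxy for the
    latent dynamics used only to initialize EM."""
    M = y.shape[1]
    s_hat = _deconvolve(y, design, basis, lam)
    cond_idx = design.condition_index()
    seg_starts = set(_segments(design)[0])
    coupling = np.zeros((n_conditions + 1, M, M))
    for j in range(n_conditions + 1):
        rows = [t for t in range(1, y.shape[0])
                if cond_idx[t] == j and t not in seg_starts]
        if len(rows) < M + 2:
            coupling[j] = 0.3 * np.eye(M)
            continue
        Y1 = s_hat[rows]
        Y0 = s_hat[np.asarray(rows) - 1]
        G = Y0.T @ Y0
        G += 1e-3 * np.trace(G) / M * np.eye(M)
        Cj = np.linalg.solve(G, Y0.T @ Y1).T
        rho = spectral_radius(Cj)
        if rho >= 0.95:
            Cj *= 0.9 / rho
        coupling[j] = Cj
    if not estimate_baseline:
        coupling[-1] = 0.5 * np.eye(M)
    return coupling


def _m_step(y, design, model, sm, config, n_lags):
    """Closed-form parameter updates from smoothed moments."""
    T, M = y.shape
    L = n_lags
    d = M * L
    cond_idx = design.condition_index()
    seg_start_set = set(_segments(design)[0])
    Phi = model.basis.basis_matrix[:, :L]
    p = Phi.shape[0]

    means, covs, lag_one = sm.means, sm.covs, sm.lag_one

    # ---- coupling updates: per-condition pooled moments of (s(t), s(t-1))
    n_groups = model.n_conditions + 1
    S10 = np.zeros((n_groups, M, M))
    S00 = np.zeros((n_groups, M, M))
    usable = np.array([t for t in range(T) if t not in seg_start_set])
    for j in range(n_groups):
        ts = usable[cond_idx[usable] == j]
        if not len(ts):
            continue
        m_t = means[ts][:, :M]
        m_p = means[ts - 1][:, :M]
        # E[s(t) s(t-1)'] via the lag-one augmented cross-covariance
        S10[j] = lag_one[ts][:, :M, :M].sum(axis=0) + m_t.T @ m_p
        S00[j] = covs[ts - 1][:, :M, :M].sum(axis=0) + m_p.T @ m_p
    new_coupling = model.all_coupling().copy()
    for j in range(n_groups):
        if j == model.n_conditions and not config.estimate_baseline:
            continue
        if not np.trace(S00[j]):
            continue
        try:
            new_coupling[j] = np.linalg.solve(
                S00[j] + 1e-8 * np.eye(M), S10[j].T).T
        except np.linalg.LinAlgError:
            new_coupling[j] = S10[j] @ np.linalg.pinv(S00[j])

    # ---- HRF weight and observation-noise updates
    # lag-window indices of region m within the augmented state
    new_b = model.hrf_weights.copy()
    new_sig = model.obs_noise_var.copy()
    cov_sum = covs.sum(axis=0)
    for m in range(M):
        idx = np.arange(L) * M + m
        mu = means[:, idx]                       # T x L
        Exx_sum = cov_sum[np.ix_(idx, idx)] + mu.T @ mu
        A_m = Phi @ Exx_sum @ Phi.T
        c_m = Phi @ (y[:, m] @ mu)
        yy = float(y[:, m] @ y[:, m])
        if config.fix_hrf_weights:
            b = model.hrf_weights[m]
        else:
            try:
                b = np.linalg.solve(A_m + 1e-10 * np.eye(p), c_m)
            except np.linalg.LinAlgError:
                b = np.linalg.pinv(A_m) @ c_m
        new_b[m] = b
        if config.fix_obs_noise is not None:
            new_sig[m] = config.fix_obs_noise
        else:
            resid = (yy - 2.0 * b @ c_m + b @ A_m @ b) / T
            new_sig[m] = max(float(resid), 1e-10)

    return dataclasses.replace(
        model,
        coupling=new_coupling[: model.n_conditions],
        baseline_coupling=new_coupling[model.n_conditions],
        hrf_weights=new_b,
        obs_noise_var=new_sig,
    )


def _project_stable(model: MDSIModel, margin: float = 0.98) -> MDSIModel:
    """Rescale any coupling matrix whose spectral radius reached 1 back
    inside the unit circle (rare; keeps the filter well-posed)."""
    mats = model.all_coupling().copy()
    changed = False
    for j in range(mats.shape[0]):
        rho = spectral_radius(mats[j])
        if rho >= 1.0:
            mats[j] *= margin / rho
            changed = True
    if not changed:
        return model
    return dataclasses.replace(
        model, coupling=mats[: model.n_conditions],
        baseline_coupling=mats[model.n_conditions])


def _run_em(y, design, model0, config, n_lags):
    model = model0
    trace = []
    prev_ll = -np.inf
    converged = False
    sm = None
    for _ in range(config.max_iterations):
        sm = kalman_smooth(y, design, model, n_lags=n_lags)
        trace.append(sm.loglik)
        if sm.loglik - prev_ll < config.loglik_tolerance * (1.0 + abs(sm.loglik)):
            converged = True
            break
        prev_ll = sm.loglik
        # the M-step may transiently leave a sparsely sampled matrix (often
        # the baseline) with spectral radius >= 1; the finite-horizon filter
        # tolerates that, and projecting here would break EM monotonicity
        model = _m_step(y, design, model, sm, config, n_lags)
    return model, np.asarray(trace), converged, sm


def fit_mdsi(
    bold: np.ndarray,
    design: TaskDesign,
    basis: HRFBasis,
    config: EstimationConfig | None = None,
    region_names=None,
    subject_id: str = "",
) -> FitResult:
    """Fit the latent state-space model by EM with Kalman smoothing.

    Multi-start: the first start initializes the coupling matrices from a
    ridge VAR(1) on the BOLD itself; further starts perturb that
    initialization. The best final likelihood wins. The state-noise variance
    is fixed to 1 (gauge); HRF gain is absorbed into the basis weights.
    """
    if config is None:
        config = EstimationConfig()
    y = np.asarray(bold, dtype=float)
    T, M = y.shape
    if region_names is None:
        region_names = [f"R{i}" for i in range(M)]
    J = design.n_conditions
    if T < 10 * M * J:
        warnings.warn(
            f"only {T} frames for {M} regions x {J} conditions; estimates "
            "may be unstable", stacklevel=2)
    y = y - y.mean(axis=0)
    L = config.n_lags if config.n_lags is not None else basis.n_lags
    if L < 1:
        raise ValueError("n_lags must be >= 1")
    if L > basis.n_lags:
        raise ValueError(
            f"n_lags override ({L}) cannot exceed the basis length "
            f"({basis.n_lags}); build a longer basis instead")

    b0 = np.zeros((M, basis.n_basis))
    b0[:, 0] = 1.0
    sig0 = np.maximum(y.var(axis=0) / 2.0, 1e-6)

    def make_start(coupling0):
        model = MDSIModel(
            coupling=coupling0[:J],
            state_noise_var=1.0,
            hrf_weights=b0.copy(),
            obs_noise_var=sig0.copy(),
            basis=basis,
            condition_names=tuple(design.condition_names),
            baseline_coupling=coupling0[J],
        )
        return _project_stable(model)

    # starts differ in the deconvolution regularization of the initializer;
    # further starts add random perturbations on top
    lams = [config.init_regularization, 0.2 * config.init_regularization,
            5.0 * config.init_regularization]
    rng = np.random.default_rng(config.seed)
    best = None
    failures = []
    for start in range(max(config.n_random_starts, 1)):
        lam = lams[start % len(lams)]
        coupling0 = _init_coupling(y, design, basis, J,
                                   config.estimate_baseline, lam=lam)
        if start >= len(lams):
            coupling0 = coupling0 + rng.normal(0, 0.1, (J + 1, M, M))
        model0 = make_start(coupling0)
        try:
            model, trace, converged, sm = _run_em(y, design, model0, config, L)
        except NumericalFailure as exc:
            failures.append(str(exc))
            continue
        if best is None or trace[-1] > best[1][-1]:
            best = (model, trace, converged, sm)
    if best is None:
        raise EstimationFailure(
            "no stable EM solution found across starts: " + "; ".join(failures))
    model, trace, converged, sm = best
    return FitResult(
        model=model,
        loglik_trace=trace,
        converged=converged,
        latent_mean=sm.latent_mean,
        config=config,
        region_names=list(region_names),
        subject_id=subject_id,
    )


def extract_networks(
    fit: FitResult,
    include_baseline: bool = False,
    allow_nonconverged: bool = True,
) -> list:
    """One :class:`CausalNetwork` per analysis condition of a fit."""
    if not fit.converged and not allow_nonconverged:
        raise EstimationFailure("fit did not converge")
    nets = [
        CausalNetwork(
            weights=fit.model.coupling[j],
            condition=name,
            region_names=fit.region_names,
            subject_id=fit.subject_id,
        )
        for j, name in enumerate(fit.model.condition_names)
    ]
    if include_baseline:
        nets.append(CausalNetwork(
            weights=fit.model.baseline_coupling,
            condition=REST,
            region_names=fit.region_names,
            subject_id=fit.subject_id,
        ))
    return nets
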