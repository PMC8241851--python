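"""ROI signal extraction and denoising.

Covers the standard region-level pipeline between voxel data and model
fitting: first-eigenvariate extraction of a representative ROI time course,
nuisance regression against motion parameters plus discrete-cosine high-pass
filtering, and a block GLM for per-region activation contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .synth import HRFBasis, TaskDesign

__all__ = [
    "ROITimeSeries",
    "GLMResult",
    "first_eigenvariate",
    "clean_timeseries",
    "dct_highpass_basis",
    "roi_glm_contrast",
]


@dataclass
class ROITimeSeries:
    """T x M table of region time courses with a processing provenance log."""

    values: np.ndarray
    region_names: list
    tr_seconds: float
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be T x M")
        if self.values.shape[1] != len(self.region_names):
            raise ValueError("column count must match region count")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite values in time series")


@dataclass
class GLMResult:
    betas: dict            # condition -> per-region beta vector
    contrast: np.ndarray   # per-region (2-back - 0-back) estimate
    t_stat: np.ndarray
    p_value: np.ndarray
    residual_var: np.ndarray
    contrast_pair: tuple
    region_names: list


class DegenerateInputError(ValueError):
    pass


def first_eigenvariate(roi_matrix: np.ndarray) -> np.ndarray:
    """Representative time course of a T x N voxel matrix.

    Columns are mean-centered; the output is the first left singular vector
    scaled by s1 / sqrt(N), the convention that preserves the scale of the
    average voxel. Sign is chosen so the output correlates positively with
    the ROI mean time course (if that correlation is exactly zero, the first
    nonzero element is made positive).
    """
    x = np.asarray(roi_matrix, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    T, N = x.shape
    if T < 2 or N < 1:
        raise ValueError("need at least 2 frames and 1 voxel")
    if not np.isfinite(x).all():
        raise ValueError("non-finite entries in ROI matrix")
    xc = x - x.mean(axis=0)
    if not xc.any():
        raise DegenerateInputError("ROI matrix is constant (all-zero after centering)")
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    v = u[:, 0] * (s[0] / np.sqrt(N))
    mean_tc = xc.mean(axis=1)
    align = float(v @ mean_tc)
    if align < 0:
        v = -v
    elif align == 0:
        nz = np.nonzero(v)[0]
        if nz.size and v[nz[0]] < 0:
            v = -v
    return v


def dct_highpass_basis(n_frames: int, tr_seconds: float,
                       highpass_hz: float) -> np.ndarray:
    """Discrete-cosine basis spanning frequencies below ``highpass_hz``.

    Component k has frequency k / (2 * T * TR); all components with
    frequency < cutoff are returned (constant term excluded — the intercept
    handles it). May be empty.
    """
    t = np.arange(n_frames)
    n_comp = int(np.floor(2.0 * n_frames * tr_seconds * highpass_hz))
    cols = [np.cos(np.pi * k * (2 * t + 1) / (2.0 * n_frames))
            for k in range(1, n_comp + 1)]
    if not cols:
        return np.empty((n_frames, 0))
    return np.column_stack(cols)


def clean_timeseries(
    ts: ROITimeSeries,
    confounds: np.ndarray | None = None,
    highpass_hz: float | None = 0.008,
) -> ROITimeSeries:
    """Residualize region time courses against nuisance regressors.

    Projects out, in one joint least-squares fit, an intercept, the confound
    columns (e.g. 6 motion parameters), and a discrete-cosine low-frequency
    subspace with cutoff ``highpass_hz`` (pass ``None`` to disable the
    filter). The joint projection leaves residuals orthogonal to every
    regressor. Idempotent up to numerical precision.
    """
    T = ts.values.shape[0]
    parts = [np.ones((T, 1))]
    log = ["mean-centered"]
    if confounds is not None:
        confounds = np.asarray(confounds, dtype=float)
        if confounds.ndim == 1:
            confounds = confounds[:, None]
        if confounds.shape[0] != T:
            raise ValueError(
                f"confounds have {confounds.shape[0]} rows but time series "
                f"has {T} frames")
        parts.append(confounds)
        log.append(f"regressed {confounds.shape[1]} confound columns")
    if highpass_hz is not None and highpass_hz > 0:
        nyquist = 0.5 / ts.tr_seconds
        if highpass_hz >= nyquist:
            raise ValueError("highpass cutoff must be below Nyquist")
        dct = dct_highpass_basis(T, ts.tr_seconds, highpass_hz)
        # a linear trend is not exactly in the truncated DCT span; include it
        # so slow drifts are removed completely rather than attenuated
        trend = (np.arange(T) - (T - 1) / 2.0)[:, None] / T
        parts.extend([trend, dct])
        log.append(f"high-pass: linear trend + DCT > {highpass_hz} Hz "
                   f"({dct.shape[1]} components)")
    X = np.column_stack(parts)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn("rank-deficient nuisance design; using pseudo-inverse",
                      stacklevel=2)
    beta, *_ = np.linalg.lstsq(X, ts.values, rcond=None)
    resid = ts.values - X @ beta
    return ROITimeSeries(
        values=resid,
        region_names=list(ts.region_names),
        tr_seconds=ts.tr_seconds,
        provenance=list(ts.provenance) + log,
    )


def _hrf_regressors(design: TaskDesign, basis: HRFBasis) -> np.ndarray:
    """Condition indicators convolved with the canonical HRF (basis row 0),
    session by session."""
    hrf = basis.basis_matrix[0]
    T = design.n_timepoints
    reg = np.zeros((T, design.n_conditions))
    start = 0
    for seg_len in design.session_lengths:
        for j in range(design.n_conditions):
            seg = design.indicators[j, start:start + seg_len].astype(float)
            reg[start:start + seg_len, j] = np.convolve(seg, hrf)[:seg_len]
        start += seg_len
    return reg


def roi_glm_contrast(
    ts: ROITimeSeries,
    design: TaskDesign,
    basis: HRFBasis,
    contrast_pair: tuple = ("2-back", "0-back"),
) -> GLMResult:
    """Per-region block GLM and activation contrast.

    Regressors are the condition indicators convolved with the canonical
    HRF, plus an intercept; ordinary least squares per region; the contrast
    is the difference of the two named condition betas with its t statistic.
    """
    if ts.values.shape[0] != design.n_timepoints:
        raise ValueError("time series and design frame counts differ")
    for name in contrast_pair:
        if name not in design.condition_names:
            raise ValueError(f"contrast condition {name!r} not in design")
    reg = _hrf_regressors(design, basis)
    X = np.column_stack([np.ones(design.n_timepoints), reg])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify which condition regressors are linearly dependent
        bad = []
        for j, name in enumerate(design.condition_names):
            others = np.delete(X, 1 + j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(name)
        raise np.linalg.LinAlgError(
            f"rank-deficient GLM design; collinear regressors: {bad}")
    Y = ts.values
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = Y.shape[0] - X.shape[1]
    resid_var = (resid ** 2).sum(axis=0) / dof
    names = list(design.condition_names)
    betas = {name: beta[1 + j] for j, name in enumerate(names)}
    c = np.zeros(X.shape[1])
    c[1 + names.index(contrast_pair[0])] = 1.0
    c[1 + names.index(contrast_pair[1])] = -1.0
    xtx_inv = np.linalg.inv(X.T @ X)
    cvar = float(c @ xtx_inv @ c)
    contrast = betas[contrast_pair[0]] - betas[contrast_pair[1]]
    t = contrast / np.sqrt(resid_var * cvar)
    p = 2 * stats.t.sf(np.abs(t), dof)
    return GLMResult(
        betas=betas, contrast=contrast, t_stat=t, p_value=p,
        residual_var=resid_var, contrast_pair=tuple(contrast_pair),
        region_names=list(ts.region_names),
    )
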