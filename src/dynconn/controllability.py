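"""Functional network controllability of estimated coupling matrices.

Treats a condition-specific coupling matrix as the transition matrix A of a
linear time-invariant system x(k+1) = A x(k) + B u(k), with B selecting the
controlled node(s). Average controllability is the trace of the
controllability Gramian W: higher trace means less input energy is needed
to steer the network from that node. The infinite-horizon discrete Gramian
solves A W A' - W + B B' = 0; a continuous-time reading (A W + W A' + B B'
= 0) is also provided and selectable — the two conventions correspond to
the two standard forms of the Lyapunov equation. Because the trace is a
modular set function of the Gramian, network-level controllability of a
node set is the mean of its members' node-level traces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla

from .mdsi import CausalNetwork
from .synth import spectral_radius

__all__ = [
    "LTISystem",
    "GramianResult",
    "prepare_system",
    "gramian_trace",
    "node_controllability",
    "network_controllability",
    "UnstableSystemError",
]


class UnstableSystemError(ValueError):
    pass


@dataclass
class LTISystem:
    """Discrete or continuous LTI system (A, B) with provenance of the
    transformations applied to A."""

    A: np.ndarray
    time_convention: str = "discrete"   # or "continuous"
    region_names: list = None
    transform_log: list = None

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise ValueError("A must be square")
        if self.time_convention not in ("discrete", "continuous"):
            raise ValueError("time_convention must be discrete or continuous")
        if self.transform_log is None:
            self.transform_log = []

    @property
    def n_regions(self) -> int:
        return self.A.shape[0]

    @property
    def spectral_radius(self) -> float:
        return spectral_radius(self.A)


@dataclass
class GramianResult:
    gramian: np.ndarray
    trace: float
    solver: str
    horizon: str
    nodes: tuple


def prepare_system(
    net: CausalNetwork | np.ndarray,
    stabilization: str = "strict",
    weight_normalization: str = "none",
    time_convention: str = "discrete",
) -> LTISystem:
    """Turn a coupling matrix into an LTI system ready for Gramian solves.

    ``weight_normalization="mean_abs"`` divides all weights by the mean
    absolute off-diagonal entry (the robustness variant on normalized
    weights). ``stabilization="strict"`` raises on spectral radius >= 1;
    ``"spectral"`` rescales A by 1/(1 + rho(A)), which maps any radius to
    rho/(1 + rho) < 1.
    """
    if isinstance(net, CausalNetwork):
        A = net.weights.copy()
        names = list(net.region_names)
    else:
        A = np.asarray(net, dtype=float).copy()
        names = [f"R{i}" for i in range(A.shape[0])]
    if not np.isfinite(A).all():
        raise ValueError("non-finite coupling weights")
    log = []
    if weight_normalization == "mean_abs":
        off = ~np.eye(A.shape[0], dtype=bool)
        denom = np.abs(A[off]).mean()
        if denom == 0:
            raise ValueError("cannot normalize an all-zero off-diagonal matrix")
        A = A / denom
        log.append(f"mean_abs normalization (/ {denom:.6g})")
    elif weight_normalization != "none":
        raise ValueError(f"unknown weight_normalization {weight_normalization!r}")
    rho = spectral_radius(A)
    if stabilization == "strict":
        if time_convention == "discrete" and rho >= 1.0:
            raise UnstableSystemError(
                f"spectral radius {rho:.4f} >= 1; use stabilization='spectral' "
                "or normalize weights")
    elif stabilization == "spectral":
        A = A / (1.0 + rho)
        log.append(f"spectral rescaling (/ (1 + {rho:.6g}))")
    else:
        raise ValueError(f"unknown stabilization {stabilization!r}")
    return LTISystem(A=A, time_convention=time_convention,
                     region_names=names, transform_log=log)


def _input_matrix(sys: LTISystem, nodes) -> np.ndarray:
    nodes = np.atleast_1d(np.asarray(nodes, dtype=int))
    M = sys.n_regions
    if (nodes < 0).any() or (nodes >= M).any():
        raise ValueError("node index out of range")
    B = np.zeros((M, len(nodes)))
    B[nodes, np.arange(len(nodes))] = 1.0
    return B


def gramian_trace(sys: LTISystem, nodes) -> GramianResult:
    """Infinite-horizon controllability Gramian and its trace for inputs at
    ``nodes`` (an index or list of indices).

    Discrete convention solves A W A' - W + B B' = 0 and requires spectral
    radius < 1; continuous solves A W + W A' + B B' = 0 and requires all
    eigenvalue real parts < 0.
    """
    B = _input_matrix(sys, nodes)
    BBt = B @ B.T
    if sys.time_convention == "discrete":
        if sys.spectral_radius >= 1.0:
            raise UnstableSystemError(
                f"discrete Gramian needs rho(A) < 1, got {sys.spectral_radius:.4f}")
        W = sla.solve_discrete_lyapunov(sys.A, BBt)
        solver = "solve_discrete_lyapunov"
    else:
        eig = np.linalg.eigvals(sys.A)
        if (eig.real >= 0).any():
            raise UnstableSystemError(
                "continuous Gramian needs all eigenvalue real parts < 0 "
                f"(max {eig.real.max():.4f})")
        W = sla.solve_continuous_lyapunov(sys.A, -BBt)
        solver = "solve_continuous_lyapunov"
    W = 0.5 * (W + W.T)
    if not np.isfinite(W).all():
        raise RuntimeError("Lyapunov solver returned non-finite Gramian")
    return GramianResult(
        gramian=W,
        trace=float(np.trace(W)),
        solver=solver,
        horizon="infinite",
        nodes=tuple(np.atleast_1d(nodes).tolist()),
    )


def node_controllability(
    net: CausalNetwork | np.ndarray,
    stabilization: str = "strict",
    weight_normalization: str = "none",
    time_convention: str = "discrete",
) -> np.ndarray:
    """Average controllability of each region: trace of the Gramian with
    B = e_i, on one shared prepared system."""
    sys = prepare_system(net, stabilization, weight_normalization,
                         time_convention)
    return np.array(
        [gramian_trace(sys, i).trace for i in range(sys.n_regions)])


def network_controllability(
    net: CausalNetwork | np.ndarray,
    region_sets: dict,
    **prep_options,
) -> dict:
    """Controllability of named node sets: the mean of member node traces
    (trace of the Gramian is a modular set function, so the set-level value
    aggregates from single-node values)."""
    values = node_controllability(net, **prep_options)
    out = {}
    for name, members in region_sets.items():
        members = list(members)
        if not members:
            raise ValueError(f"region set {name!r} is empty")
        out[name] = float(np.mean([values[i] for i in members]))
    return out
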