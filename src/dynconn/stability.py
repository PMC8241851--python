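"""Bootstrap subsampling analyses of result robustness vs sample size.

Two procedures, both drawing subsamples without replacement from the cohort
and repeating over a grid of subsample sizes:

* pattern stability — per replicate, rebuild the thresholded group
  connectivity matrix (edgewise t tests, FDR threshold, significant edges
  keep their mean signed weight) and correlate its off-diagonal entries
  with the full-sample matrix built the same way;
* finding stability — per replicate, evaluate a boolean scientific finding
  (a pluggable predicate such as "region r has significantly higher outflow
  than every other region") and report the fraction of replicates where it
  holds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .mdsi import CausalNetwork

__all__ = [
    "StabilityCurve",
    "pattern_stability",
    "finding_stability",
    "thresholded_group_matrix",
    "DEFAULT_SIZE_GRID",
]

DEFAULT_SIZE_GRID = (20, 30, 40, 50, 60, 70, 80, 90, 100,
                     150, 200, 250, 300, 400, 600)


@dataclass
class StabilityCurve:
    sizes: np.ndarray
    values: np.ndarray       # len(sizes) x n_boot replicate values
    mean: np.ndarray
    n_boot: int
    seed: int
    metric: str

    def to_records(self):
        recs = []
        for i, size in enumerate(self.sizes):
            for b, v in enumerate(self.values[i]):
                recs.append({"size": int(size), "replicate": b,
                             "value": float(v)})
        return recs


def _stack_offdiag(nets) -> np.ndarray:
    """subjects x M(M-1) array of off-diagonal weights."""
    return np.asarray([n.offdiagonal_vector() for n in nets])


def thresholded_group_matrix(
    weights: np.ndarray,
    alpha: float = 0.01,
    contrast_weights: np.ndarray | None = None,
) -> np.ndarray:
    """FDR-thresholded mean connectivity vector.

    ``weights`` is subjects x edges. Each edge gets a one-sample (or paired,
    when ``contrast_weights`` is given) two-sided t test; edges surviving
    Benjamini-Hochberg at ``alpha`` keep their mean signed weight, all
    others are set to zero.
    """
    w = np.asarray(weights, dtype=float)
    if contrast_weights is not None:
        w = w - np.asarray(contrast_weights, dtype=float)
    mean = w.mean(axis=0)
    sd = w.std(axis=0, ddof=1)
    p = np.ones(w.shape[1])
    usable = sd > 0
    if usable.any():
        res = sps.ttest_1samp(w[:, usable], 0.0)
        p[usable] = res.pvalue
    reject, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    out = np.where(reject, mean, 0.0)
    return out


def _as_edge_matrix(subject_nets):
    if isinstance(subject_nets, np.ndarray):
        return np.asarray(subject_nets, dtype=float)
    if len(subject_nets) and isinstance(subject_nets[0], CausalNetwork):
        return _stack_offdiag(subject_nets)
    return np.asarray(subject_nets, dtype=float)


def pattern_stability(
    subject_nets,
    sizes=DEFAULT_SIZE_GRID,
    n_boot: int = 500,
    alpha: float = 0.01,
    seed: int = 0,
    contrast_nets=None,
) -> StabilityCurve:
    """Stability of the multivariate causal-influence pattern vs sample size.

    ``subject_nets`` is a list of per-subject :class:`CausalNetwork` (one
    condition) or a subjects x edges array. With ``contrast_nets`` the
    procedure thresholds the paired between-condition contrast instead. Per
    size and replicate, a subsample is drawn without replacement, the
    thresholded group matrix is rebuilt, and its correlation with the
    full-sample thresholded matrix (same pipeline) is recorded.
    """
    w = _as_edge_matrix(subject_nets)
    cw = _as_edge_matrix(contrast_nets) if contrast_nets is not None else None
    n = w.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    sizes = np.asarray(sorted(set(int(s) for s in sizes)))
    if (sizes > n).any():
        raise ValueError(f"subsample sizes {sizes[sizes > n].tolist()} exceed "
                         f"cohort size {n}")
    if (sizes < 2).any():
        raise ValueError("subsample sizes must be >= 2")
    reference = thresholded_group_matrix(w, alpha, cw)
    rng = np.random.default_rng(seed)
    values = np.empty((len(sizes), n_boot))
    for i, size in enumerate(sizes):
        for b in range(n_boot):
            idx = np.sort(rng.choice(n, size=size, replace=False))
            sub = thresholded_group_matrix(
                w[idx], alpha, cw[idx] if cw is not None else None)
            values[i, b] = _safe_corr(sub, reference)
    return StabilityCurve(
        sizes=sizes, values=values, mean=values.mean(axis=1),
        n_boot=n_boot, seed=seed, metric="pattern-correlation")


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.array_equal(a, b):
        return 1.0
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def plot_stability(curve: StabilityCurve, path=None, ax=None):
    """Plot a stability curve (mean with replicate spread) vs subsample size.

    Writes to ``path`` when given; returns the matplotlib axes.
    """
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    lo = np.percentile(curve.values, 2.5, axis=1)
    hi = np.percentile(curve.values, 97.5, axis=1)
    ax.fill_between(curve.sizes, lo, hi, alpha=0.25, label="95% of replicates")
    ax.plot(curve.sizes, curve.mean, "o-", label="mean")
    ax.set_xlabel("subsample size")
    ax.set_ylabel(curve.metric)
    ax.legend(frameon=False)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=120)
        plt.close(ax.figure)
    return ax


def finding_stability(
    subject_results,
    finding_test,
    sizes=DEFAULT_SIZE_GRID,
    n_boot: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> StabilityCurve:
    """Probability that a scientific finding replicates at each sample size.

    ``subject_results`` is any sequence indexable by subject (list or
    array); ``finding_test(subset, alpha)`` is a predicate receiving the
    subsampled per-subject results and returning True when the finding
    holds at level ``alpha``.
    """
    n = len(subject_results)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    sizes = np.asarray(sorted(set(int(s) for s in sizes)))
    if (sizes > n).any():
        raise ValueError("subsample size exceeds cohort size")
    as_array = isinstance(subject_results, np.ndarray)
    rng = np.random.default_rng(seed)
    values = np.empty((len(sizes), n_boot))
    for i, size in enumerate(sizes):
        for b in range(n_boot):
            idx = np.sort(rng.choice(n, size=size, replace=False))
            subset = (subject_results[idx] if as_array
                      else [subject_results[j] for j in idx])
            values[i, b] = float(bool(finding_test(subset, alpha)))
    return StabilityCurve(
        sizes=sizes, values=values, mean=values.mean(axis=1),
        n_boot=n_boot, seed=seed, metric="finding-probability")
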