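"""Group inference: paired tests with multiplicity correction, repeated-
measures ANOVA, condition classification, and brain-behavior CCA.

Effect sizes are reported in two labeled variants, because the two common
conventions disagree for paired designs: ``d_pooled`` standardizes the mean
difference by the pooled condition SD, while ``d_t`` = t / sqrt(n)
standardizes by the SD of the paired differences. Permutation p-values use
the (1 + b) / (1 + B) estimator, which never returns zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PairedTestTable",
    "ClassificationResult",
    "CCAResult",
    "paired_tests_fdr",
    "rm_anova",
    "svm_cv_perm",
    "cca_perm",
    "cohen_d_pooled",
    "cohen_d_from_t",
    "canonical_correlations",
]


def cohen_d_pooled(mean1: float, sd1: float, mean2: float, sd2: float) -> float:
    """Cohen's d with the pooled-SD convention:
    (mean1 - mean2) / sqrt((sd1^2 + sd2^2) / 2)."""
    return (mean1 - mean2) / np.sqrt((sd1**2 + sd2**2) / 2.0)


def cohen_d_from_t(t: float, n: int) -> float:
    """Cohen's d recovered from a paired t statistic: d = t / sqrt(n)."""
    return t / np.sqrt(n)


@dataclass
class PairedTestTable:
    table: pd.DataFrame   # one row per measure
    condition_pair: tuple
    correction: str
    excluded: list

    def __getitem__(self, col):
        return self.table[col]


def paired_tests_fdr(
    values1: np.ndarray,
    values2: np.ndarray,
    condition_pair: tuple = ("cond1", "cond2"),
    measure_names=None,
    correction: str = "fdr",
    alpha: float = 0.05,
) -> PairedTestTable:
    """Two-sided paired t tests across measures with multiplicity correction.

    ``values1`` / ``values2`` are subjects x measures arrays of paired
    observations. Measures whose paired difference has zero variance are
    excluded with a warning. ``correction`` is ``"fdr"``
    (Benjamini-Hochberg) or ``"bonferroni"``.
    """
    v1 = np.atleast_2d(np.asarray(values1, dtype=float).T).T
    v2 = np.atleast_2d(np.asarray(values2, dtype=float).T).T
    if v1.shape != v2.shape:
        raise ValueError("paired arrays must have identical shape")
    n, k = v1.shape
    if n < 2:
        raise ValueError("paired tests need at least 2 subjects")
    if measure_names is None:
        measure_names = [f"m{i}" for i in range(k)]
    diff = v1 - v2
    sd_diff = diff.std(axis=0, ddof=1)
    usable = sd_diff > 0
    zero_diff = np.all(diff == 0, axis=0)
    excluded = [measure_names[i] for i in range(k)
                if not usable[i] and not zero_diff[i]]
    # identical paired samples: t = 0 and d = 0 by convention
    t = np.zeros(k)
    p = np.ones(k)
    if excluded:
        warnings.warn(f"zero-variance non-identical measures excluded: "
                      f"{excluded}", stacklevel=2)
        t[~usable & ~zero_diff] = np.nan
        p[~usable & ~zero_diff] = np.nan
    if usable.any():
        res = sps.ttest_rel(v1[:, usable], v2[:, usable])
        t[usable] = res.statistic
        p[usable] = res.pvalue
    mean1, mean2 = v1.mean(axis=0), v2.mean(axis=0)
    s1, s2 = v1.std(axis=0, ddof=1), v2.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        d_pooled = np.where(
            (s1 + s2) > 0, cohen_d_pooled(mean1, s1, mean2, s2), 0.0)
    d_t = t / np.sqrt(n)
    q = np.full(k, np.nan)
    p_bonf = np.full(k, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        _, q[ok], *_ = multipletests(p[ok], alpha=alpha, method="fdr_bh")
        p_bonf[ok] = np.minimum(p[ok] * ok.sum(), 1.0)
    table = pd.DataFrame({
        "measure": measure_names,
        f"mean_{condition_pair[0]}": mean1,
        f"mean_{condition_pair[1]}": mean2,
        "mean_diff": mean1 - mean2,
        "t": t,
        "df": n - 1,
        "p": p,
        "d_pooled": d_pooled,
        "d_t": d_t,
        "q_fdr": q,
        "p_bonferroni": p_bonf,
    })
    return PairedTestTable(
        table=table, condition_pair=tuple(condition_pair),
        correction=correction, excluded=excluded)


def rm_anova(values: np.ndarray, factor_a_levels=None,
             factor_b_levels=None) -> pd.DataFrame:
    """Two-way repeated-measures ANOVA on a subjects x A x B array.

    Both factors are within-subject; returns F, dfs and p for the two main
    effects and the interaction (single-factor input — B with one level —
    returns just the A main effect, whose F equals the paired t^2 when A has
    two levels).
    """
    import pingouin as pg

    values = np.asarray(values, dtype=float)
    if values.ndim == 2:
        values = values[:, :, None]
    if values.ndim != 3:
        raise ValueError("values must be subjects x factorA x factorB")
    if not np.isfinite(values).all():
        raise ValueError("missing cells are not supported")
    n, a, b = values.shape
    if factor_a_levels is None:
        factor_a_levels = [f"a{i}" for i in range(a)]
    if factor_b_levels is None:
        factor_b_levels = [f"b{i}" for i in range(b)]
    rows = []
    for s in range(n):
        for i in range(a):
            for j in range(b):
                rows.append((s, factor_a_levels[i], factor_b_levels[j],
                             values[s, i, j]))
    df = pd.DataFrame(rows, columns=["subject", "A", "B", "y"])
    if b == 1:
        res = pg.rm_anova(data=df, dv="y", within="A", subject="subject",
                          detailed=True)
        res = res.rename(columns={"Source": "effect"})
    else:
        res = pg.rm_anova(data=df, dv="y", within=["A", "B"],
                          subject="subject", detailed=False)
        res = res.rename(columns={"Source": "effect"})
    keep = [c for c in ("effect", "ddof1", "ddof2", "F", "p-unc", "p_unc")
            if c in res]
    out = res[keep].rename(columns={"p-unc": "p", "p_unc": "p",
                                    "ddof1": "df1", "ddof2": "df2"})
    out["F"] = out["F"].fillna(0.0)
    return out


def _perm_p(null: np.ndarray, observed: float, greater: bool = True) -> float:
    null = np.asarray(null, dtype=float)
    b = (null >= observed).sum() if greater else (null <= observed).sum()
    return float((1 + b) / (1 + len(null)))


@dataclass
class ClassificationResult:
    fold_accuracies: np.ndarray
    mean_accuracy: float
    null_accuracies: np.ndarray
    permutation_p: float
    n_folds: int
    n_permutations: int
    seed: int


def _grouped_folds(groups: np.ndarray, k: int, rng) -> list:
    """Assign whole groups to folds (all samples of a subject share a fold)."""
    uniq = np.unique(groups)
    order = rng.permutation(len(uniq))
    assignment = {g: order[i] % k for i, g in enumerate(uniq)}
    folds = [np.where([assignment[g] == f for g in groups])[0]
             for f in range(k)]
    return [f for f in folds if len(f)]


def _cv_accuracy(X, y, folds) -> np.ndarray:
    accs = []
    for test in folds:
        train = np.setdiff1d(np.arange(len(y)), test)
        if len(np.unique(y[train])) < 2:
            raise ValueError(
                "a training fold contains a single class; use more groups "
                "or fewer folds")
        clf = SVC(kernel="linear", C=1.0)
        clf.fit(X[train], y[train])
        accs.append(float((clf.predict(X[test]) == y[test]).mean()))
    return np.asarray(accs)


def svm_cv_perm(
    features: np.ndarray,
    labels,
    k: int = 10,
    n_perm: int = 100,
    group_ids=None,
    seed: int = 0,
) -> ClassificationResult:
    """Linear-SVM condition classification with grouped k-fold CV and a
    within-group label-permutation null.

    ``group_ids`` ties samples (a subject's two condition rows) to the same
    fold, preventing leakage; the permutation null swaps each group's labels
    with probability 1/2, preserving the pairing structure.
    """
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("classification requires exactly two classes")
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    y = (labels == classes[1]).astype(int)
    if group_ids is None:
        group_ids = np.arange(len(y))
    group_ids = np.asarray(group_ids)
    rng = np.random.default_rng(seed)
    folds = _grouped_folds(group_ids, k, rng)
    fold_acc = _cv_accuracy(X, y, folds)
    observed = float(fold_acc.mean())
    null = np.empty(n_perm)
    uniq = np.unique(group_ids)
    for b in range(n_perm):
        y_perm = y.copy()
        flips = rng.random(len(uniq)) < 0.5
        for g, flip in zip(uniq, flips):
            if flip:
                idx = group_ids == g
                y_perm[idx] = 1 - y_perm[idx]
        null[b] = _cv_accuracy(X, y_perm, folds).mean()
    return ClassificationResult(
        fold_accuracies=fold_acc,
        mean_accuracy=observed,
        null_accuracies=null,
        permutation_p=_perm_p(null, observed),
        n_folds=len(folds),
        n_permutations=n_perm,
        seed=seed,
    )


def canonical_correlations(X: np.ndarray, Y: np.ndarray):
    """Canonical correlations and weight vectors of column-centered X, Y.

    Computed via QR decompositions and an SVD of Q_x' Q_y — the numerically
    standard route. Returns (correlations, x_weights, y_weights) with
    correlations clipped to [0, 1], non-increasing.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    qx, rx = np.linalg.qr(Xc)
    qy, ry = np.linalg.qr(Yc)
    u, s, vt = np.linalg.svd(qx.T @ qy)
    r = np.clip(s, 0.0, 1.0)
    k = min(Xc.shape[1], Yc.shape[1])
    a = np.linalg.lstsq(rx, u[:, :k], rcond=None)[0]
    b = np.linalg.lstsq(ry, vt.T[:, :k], rcond=None)[0]
    return r[:k], a, b


@dataclass
class CCAResult:
    correlations: np.ndarray
    first_r: float
    pillai: float
    permutation_p: float
    null_pillai: np.ndarray
    x_weights: np.ndarray
    y_weights: np.ndarray
    dropped_columns: list
    n_permutations: int
    seed: int


def cca_perm(
    X: np.ndarray,
    Y: np.ndarray,
    n_perm: int = 5000,
    seed: int = 0,
) -> CCAResult:
    """Canonical correlation between brain and behavior blocks with a
    row-permutation test on Pillai's trace (sum of squared canonical
    correlations). Constant columns are dropped with a warning."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    n = X.shape[0]
    if n <= Y.shape[1]:
        raise ValueError("need more subjects than behavior columns")
    dropped = []

    def drop_constant(A, tag):
        keep = A.std(axis=0) > 0
        if not keep.all():
            cols = list(np.where(~keep)[0])
            dropped.extend([(tag, c) for c in cols])
            warnings.warn(f"dropping constant {tag} columns {cols}",
                          stacklevel=3)
        return A[:, keep]

    X = drop_constant(X, "X")
    Y = drop_constant(Y, "Y")
    if X.shape[1] >= n:
        warnings.warn("more brain features than subjects; canonical "
                      "correlations will saturate", stacklevel=2)
    r, a, b = canonical_correlations(X, Y)
    pillai = float((r**2).sum())
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        rp, *_ = canonical_correlations(X, Y[perm])
        null[i] = (rp**2).sum()
    return CCAResult(
        correlations=r,
        first_r=float(r[0]),
        pillai=pillai,
        permutation_p=_perm_p(null, pillai),
        null_pillai=null,
        x_weights=a,
        y_weights=b,
        dropped_columns=dropped,
        n_permutations=n_perm,
        seed=seed,
    )
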