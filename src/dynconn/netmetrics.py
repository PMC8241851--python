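"""Hub metrics and community structure of signed directed causal networks.

Causal flow degrees summarize each region's role: outflow (mean outgoing
off-diagonal weight), inflow (mean incoming), and their difference (net).
The region with the largest significantly positive net degree across
subjects is the causal outflow hub; the most negative, the inflow hub.

Community structure uses Louvain modularity maximization adapted to signed
directed weighted graphs: modularity is computed separately on the positive
and negative parts of the matrix (each with its own directed null term) and
combined asymmetrically, Q = Q+ - s- / (s+ + s-) * Q-. Because Louvain is
stochastic, it is repeated many times; the co-classification frequencies
form a co-occurrence matrix that is thresholded and re-clustered to a fixed
point (consensus clustering).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .mdsi import CausalNetwork

__all__ = [
    "FlowDegrees",
    "CommunityPartition",
    "HubTestResult",
    "flow_degrees",
    "group_hub_test",
    "louvain_consensus",
    "signed_directed_modularity",
    "louvain_once",
]


# ---------------------------------------------------------------------------
# Flow degrees and group hub statistics


@dataclass
class FlowDegrees:
    outflow: np.ndarray
    inflow: np.ndarray
    net: np.ndarray
    region_names: list

    def as_dict(self) -> dict:
        return {
            name: {"outflow": float(o), "inflow": float(i), "net": float(n)}
            for name, o, i, n in zip(
                self.region_names, self.outflow, self.inflow, self.net)
        }


def flow_degrees(net: CausalNetwork | np.ndarray,
                 region_names=None) -> FlowDegrees:
    """Per-region causal flow: outflow = mean outgoing off-diagonal weight,
    inflow = mean incoming, net = outflow - inflow.

    With weights oriented (m, n) = influence of n on m, region n's outgoing
    weights are column n and region m's incoming weights are row m. Net
    degrees sum to zero exactly: every off-diagonal entry enters one
    region's outflow and another's inflow with the same 1/(M-1) weight.
    """
    if isinstance(net, CausalNetwork):
        w = net.weights
        region_names = net.region_names
    else:
        w = np.asarray(net, dtype=float)
        if region_names is None:
            region_names = [f"R{i}" for i in range(w.shape[0])]
    M = w.shape[0]
    if w.shape != (M, M):
        raise ValueError("weights must be square")
    if M < 2:
        raise ValueError("flow degrees need at least 2 regions")
    off = w - np.diag(np.diag(w))
    outflow = off.sum(axis=0) / (M - 1)   # column sums: n -> others
    inflow = off.sum(axis=1) / (M - 1)    # row sums: others -> m
    return FlowDegrees(
        outflow=outflow, inflow=inflow, net=outflow - inflow,
        region_names=list(region_names))


@dataclass
class HubTestResult:
    region_names: list
    mean_net: np.ndarray
    t_stat: np.ndarray
    p_value: np.ndarray
    q_value: np.ndarray
    significant: np.ndarray
    outflow_hub: str | None
    inflow_hub: str | None
    excluded: list
    mode: str


def _net_degree_matrix(nets) -> tuple:
    names = nets[0].region_names
    rows = []
    for n in nets:
        if list(n.region_names) != list(names):
            raise ValueError("all networks must share region names")
        rows.append(flow_degrees(n).net)
    return np.asarray(rows), list(names)


def group_hub_test(
    nets,
    alpha: float = 0.05,
    contrast_nets=None,
) -> HubTestResult:
    """Across-subject test of net causal flow against zero (or between two
    conditions, when ``contrast_nets`` gives the paired second condition).

    Per region: one-sample (or paired) two-sided t test of the net degree,
    Benjamini-Hochberg corrected. The outflow hub is the region with the
    largest significantly positive net degree; the inflow hub the most
    negative. Regions with zero variance across subjects are excluded with a
    warning (their t statistic is undefined).
    """
    if len(nets) < 2:
        raise ValueError("group hub test needs at least 2 subjects")
    values, names = _net_degree_matrix(nets)
    mode = "one-sample"
    if contrast_nets is not None:
        if len(contrast_nets) != len(nets):
            raise ValueError("contrast_nets must pair with nets")
        other, _ = _net_degree_matrix(contrast_nets)
        values = values - other
        mode = "paired-contrast"
    M = values.shape[1]
    sd = values.std(axis=0, ddof=1)
    usable = sd > 0
    excluded = [names[i] for i in range(M) if not usable[i]]
    if excluded:
        warnings.warn(
            f"regions with zero across-subject variance excluded: {excluded}",
            stacklevel=2)
    t = np.full(M, np.nan)
    p = np.full(M, np.nan)
    q = np.full(M, np.nan)
    if usable.any():
        res = stats.ttest_1samp(values[:, usable], 0.0)
        t[usable] = res.statistic
        p[usable] = res.pvalue
        rej, qv, *_ = multipletests(p[usable], alpha=alpha, method="fdr_bh")
        q[usable] = qv
    mean_net = values.mean(axis=0)
    sig = usable & (q <= alpha)
    outflow_hub = inflow_hub = None
    pos = sig & (mean_net > 0)
    neg = sig & (mean_net < 0)
    if pos.any():
        outflow_hub = names[int(np.argmax(np.where(pos, mean_net, -np.inf)))]
    if neg.any():
        inflow_hub = names[int(np.argmin(np.where(neg, mean_net, np.inf)))]
    return HubTestResult(
        region_names=names, mean_net=mean_net, t_stat=t, p_value=p,
        q_value=q, significant=sig, outflow_hub=outflow_hub,
        inflow_hub=inflow_hub, excluded=excluded, mode=mode)


# ---------------------------------------------------------------------------
# Signed directed Louvain + consensus


def _signed_parts(w: np.ndarray):
    wp = np.where(w > 0, w, 0.0)
    wn = np.where(w < 0, -w, 0.0)
    return wp, wn


def _directed_modularity(w: np.ndarray, labels: np.ndarray,
                         gamma: float) -> float:
    """Directed Newman modularity of a non-negative matrix:
    Q = (1/s) sum_ij [w_ij - gamma k_i^out k_j^in / s] delta(c_i, c_j)."""
    s = w.sum()
    if s == 0:
        return 0.0
    k_out = w.sum(axis=0)   # column sums: outgoing strength of j... see below
    k_in = w.sum(axis=1)
    same = labels[:, None] == labels[None, :]
    # orientation does not matter for Q as long as in/out are consistent
    null = np.outer(k_in, k_out) / s
    return float(((w - gamma * null) * same).sum() / s)


def signed_directed_modularity(w: np.ndarray, labels: np.ndarray,
                               gamma: float = 1.0) -> float:
    """Q = Q+ - s-/(s+ + s-) Q- (asymmetric signed combination)."""
    wp, wn = _signed_parts(np.asarray(w, dtype=float))
    sp, sn = wp.sum(), wn.sum()
    qp = _directed_modularity(wp, labels, gamma)
    qn = _directed_modularity(wn, labels, gamma)
    if sp + sn == 0:
        return 0.0
    return qp - (sn / (sp + sn)) * qn


def _louvain_local_move(wp, wn, kin_p, kout_p, kin_n, kout_n,
                        sp, sn, gamma, labels, rng):
    """Greedy label-moving passes on the signed directed graph.

    For directed graphs the gain of moving node i into community c
    aggregates both in- and out-edges between i and c, with null term
    (k_i^out K_c^in + k_i^in K_c^out) / s, evaluated on the positive and
    negative layers with the asymmetric combination. Per-community sums are
    computed with bincount over labels.
    """
    n = len(labels)
    n_lab = n  # labels live in 0..n-1
    neg_w = sn / (sp + sn) if (sp + sn) > 0 else 0.0
    improved_any = False
    moved = True
    while moved:
        moved = False
        for i in rng.permutation(n):
            li = labels[i]
            # edge weight between i and each community (both directions)
            e_p = np.bincount(labels, weights=wp[i] + wp[:, i],
                              minlength=n_lab)
            e_n = np.bincount(labels, weights=wn[i] + wn[:, i],
                              minlength=n_lab)
            Kin_p = np.bincount(labels, weights=kin_p, minlength=n_lab)
            Kout_p = np.bincount(labels, weights=kout_p, minlength=n_lab)
            gain = np.zeros(n_lab)
            if sp > 0:
                null_p = (kout_p[i] * (Kin_p - (labels == li) * kin_p[i])
                          + kin_p[i] * (Kout_p - (labels == li) * kout_p[i]))
                gain += (e_p - gamma * null_p / sp) / sp
            if sn > 0 and neg_w > 0:
                Kin_n = np.bincount(labels, weights=kin_n, minlength=n_lab)
                Kout_n = np.bincount(labels, weights=kout_n, minlength=n_lab)
                null_n = (kout_n[i] * (Kin_n - (labels == li) * kin_n[i])
                          + kin_n[i] * (Kout_n - (labels == li) * kout_n[i]))
                gain -= neg_w * (e_n - gamma * null_n / sn) / sn
            # delta of moving i from its own community (minus i) to c
            gain = gain - gain[li]
            gain[li] = 0.0
            # only occupied communities are candidates
            occupied = np.bincount(labels, minlength=n_lab) > 0
            gain[~occupied] = -np.inf
            best_c = int(np.argmax(gain))
            if gain[best_c] > 1e-12 and best_c != li:
                labels[i] = best_c
                moved = True
                improved_any = True
    return improved_any


def _aggregate(w, labels):
    comms = np.unique(labels)
    k = len(comms)
    agg = np.zeros((k, k))
    for a, ca in enumerate(comms):
        ma = labels == ca
        for b, cb in enumerate(comms):
            mb = labels == cb
            agg[a, b] = w[np.ix_(ma, mb)].sum()
    return agg, comms


def louvain_once(w: np.ndarray, gamma: float = 1.0, rng=None) -> np.ndarray:
    """One stochastic Louvain run (local moving + aggregation phases) on a
    signed directed weighted matrix. Returns integer labels."""
    if rng is None:
        rng = np.random.default_rng()
    w = np.asarray(w, dtype=float).copy()
    np.fill_diagonal(w, 0.0)
    n = w.shape[0]
    node_labels = np.arange(n)          # labels on original nodes
    cur_w = w
    while True:
        m = cur_w.shape[0]
        wp, wn = _signed_parts(cur_w)
        sp, sn = wp.sum(), wn.sum()
        kin_p, kout_p = wp.sum(axis=1), wp.sum(axis=0)
        kin_n, kout_n = wn.sum(axis=1), wn.sum(axis=0)
        labels = np.arange(m)
        improved = _louvain_local_move(
            wp, wn, kin_p, kout_p, kin_n, kout_n, sp, sn, gamma, labels, rng)
        if not improved:
            break
        # map original nodes through this level's communities
        agg, comms = _aggregate(cur_w, labels)
        remap = {c: i for i, c in enumerate(comms)}
        node_labels = np.array([remap[labels[l]] for l in node_labels])
        cur_w = agg
        if agg.shape[0] == m:
            break
    # canonicalize: relabel by first appearance so identical partitions
    # always yield identical label arrays
    _, first_idx, inv = np.unique(node_labels, return_index=True,
                                  return_inverse=True)
    rank_by_appearance = np.argsort(np.argsort(first_idx))
    return rank_by_appearance[inv]


@dataclass
class CommunityPartition:
    labels: np.ndarray
    co_occurrence: np.ndarray
    gamma: float
    n_iterations: int
    seed: int
    region_names: list
    modularity: float

    @property
    def n_communities(self) -> int:
        return len(np.unique(self.labels))


def _coclassification(labels: np.ndarray) -> np.ndarray:
    return (labels[:, None] == labels[None, :]).astype(float)


def louvain_consensus(
    mean_net: CausalNetwork | np.ndarray,
    gamma: float = 1.0,
    n_iterations: int = 1000,
    seed: int = 0,
    consensus_threshold: float = 0.5,
    region_names=None,
) -> CommunityPartition:
    """Consensus community structure of a signed directed weighted matrix.

    Runs Louvain ``n_iterations`` times; each run's co-classification matrix
    (1 where two nodes share a module) is averaged into a co-occurrence
    matrix. The co-occurrence matrix, thresholded at
    ``consensus_threshold``, is re-clustered repeatedly until the partition
    reaches a fixed point (all runs agree).
    """
    if isinstance(mean_net, CausalNetwork):
        w = mean_net.weights
        region_names = mean_net.region_names
    else:
        w = np.asarray(mean_net, dtype=float)
        if region_names is None:
            region_names = [f"R{i}" for i in range(w.shape[0])]
    n = w.shape[0]
    rng = np.random.default_rng(seed)
    off = w - np.diag(np.diag(w))
    if not off.any():
        warnings.warn("all-zero matrix: returning a single community",
                      stacklevel=2)
        return CommunityPartition(
            labels=np.zeros(n, dtype=int), co_occurrence=np.ones((n, n)),
            gamma=gamma, n_iterations=n_iterations, seed=seed,
            region_names=list(region_names), modularity=0.0)

    co = np.zeros((n, n))
    for _ in range(n_iterations):
        labels = louvain_once(w, gamma=gamma, rng=rng)
        co += _coclassification(labels)
    co /= n_iterations
    np.fill_diagonal(co, 1.0)

    # consensus: re-cluster the thresholded co-occurrence matrix to a fixed point
    mat = np.where(co >= consensus_threshold, co, 0.0)
    labels = None
    for _ in range(100):
        runs = [louvain_once(mat, gamma=gamma, rng=rng) for _ in range(32)]
        arr = np.asarray(runs)
        if all((r == arr[0]).all() for r in arr):
            labels = arr[0]
            break
        co2 = np.mean([_coclassification(r) for r in runs], axis=0)
        np.fill_diagonal(co2, 1.0)
        mat = np.where(co2 >= consensus_threshold, co2, 0.0)
    if labels is None:  # pragma: no cover - degenerate oscillation
        labels = louvain_once(mat, gamma=gamma, rng=rng)
    q = signed_directed_modularity(w, labels, gamma)
    return CommunityPartition(
        labels=labels, co_occurrence=co, gamma=gamma,
        n_iterations=n_iterations, seed=seed,
        region_names=list(region_names), modularity=q)
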