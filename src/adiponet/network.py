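"""Coexpression-network core: shrinkage correlation, partial correlation,
empirical-mixture edge FDR, graph assembly, fast-greedy modularity
communities, and lncRNA neighborhood extraction.

The shrinkage estimator is the analytic convex combination of the sample
correlation matrix with the identity (intensity chosen from the variance of
the empirical correlations), which keeps the inversion stable in the
samples << genes regime this pipeline operates in.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import linalg, optimize, special


# ---------------------------------------------------------------------------
# Shrinkage correlation
# ---------------------------------------------------------------------------

@dataclass
class ShrinkageCorrelation:
    r: np.ndarray          # shrunk correlation matrix R*
    lam: float             # shrinkage intensity in [0, 1]
    n: int                 # sample count
    gene_ids: list[str]


def shrinkage_intensity(x: np.ndarray) -> tuple[float, np.ndarray]:
    """Analytic shrinkage intensity for a samples-by-genes matrix.

    lambda* = sum_{i<j} Var^(r_ij) / sum_{i<j} r_ij^2, truncated to [0, 1],
    with Var^(r_ij) = n / (n-1)^3 * sum_k (w_kij - wbar_ij)^2 for
    w_kij = z_ki z_kj the products of the standardized data.
    Returns (lambda*, sample correlation matrix).
    """
    n, p = x.shape
    if n < 3:
        raise ValueError(f"need n >= 3 samples, got {n}")
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance gene present; drop before shrinking")
    z = (x - x.mean(axis=0)) / sd
    r = z.T @ z / (n - 1)
    np.fill_diagonal(r, 1.0)
    # sum_k w_kij^2 = (Z^2)^T (Z^2); wbar_ij = (n-1)/n * r_ij
    z2 = z * z
    sum_w2 = z2.T @ z2
    wbar = (n - 1) / n * r
    ss = sum_w2 - n * wbar * wbar
    var_r = n / (n - 1) ** 3 * ss
    iu = np.triu_indices(p, k=1)
    denom = float(np.sum(r[iu] ** 2))
    if denom == 0.0:
        warnings.warn("all off-diagonal correlations are zero; lambda set to 1")
        return 1.0, r
    lam = float(np.sum(var_r[iu]) / denom)
    return min(1.0, max(0.0, lam)), r


def shrink_correlation(x, gene_ids=None,
                       lam: float | None = None) -> ShrinkageCorrelation:
    """Shrunk correlation R* = (1 - lambda*) R + lambda* I of samples x genes."""
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(p)]
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [g for g, k in zip(gene_ids, keep) if not k]
        warnings.warn(f"dropping {len(dropped)} zero-variance gene(s)")
        x = x[:, keep]
        gene_ids = [g for g, k in zip(gene_ids, keep) if k]
    est_lam, r = shrinkage_intensity(x)
    if lam is None:
        lam = est_lam
    r_star = (1.0 - lam) * r
    np.fill_diagonal(r_star, 1.0)
    return ShrinkageCorrelation(r=r_star, lam=lam, n=n, gene_ids=list(gene_ids))


def partial_correlation(r_star: np.ndarray) -> np.ndarray:
    """P = -scale(R*^-1): p_ij = -w_ij / sqrt(w_ii w_jj), unit diagonal."""
    try:
        omega = linalg.inv(np.asarray(r_star, dtype=float))
    except linalg.LinAlgError as exc:
        raise ValueError(
            "correlation matrix is singular; re-run with a shrinkage floor "
            "(lambda > 0)"
        ) from exc
    d = np.sqrt(np.diag(omega))
    p = -omega / np.outer(d, d)
    np.fill_diagonal(p, 1.0)
    return np.clip(p, -1.0, 1.0)


# ---------------------------------------------------------------------------
# Mixture-null edge FDR
# ---------------------------------------------------------------------------

@dataclass
class EdgeFdrModel:
    """Two-component mixture over observed partial correlations.

    The null density is f0(p; kappa) proportional to (1 - p^2)^((kappa-3)/2)
    on [-1, 1] (the sampling distribution of a partial correlation under the
    global null, kappa playing the role of degrees of freedom); eta0 is the
    null proportion.
    """

    eta0: float
    kappa: float

    def null_logpdf(self, p) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        k = self.kappa
        log_z = special.betaln(0.5, (k - 1) / 2)
        with np.errstate(divide="ignore"):
            return (k - 3) / 2 * np.log1p(-p * p) - log_z

    def null_pdf(self, p) -> np.ndarray:
        return np.exp(self.null_logpdf(p))

    def null_tail(self, t) -> np.ndarray:
        """P0(|p| >= t); uses p^2 ~ Beta(1/2, (kappa-1)/2)."""
        t = np.asarray(t, dtype=float)
        return special.betainc((self.kappa - 1) / 2, 0.5, 1.0 - t * t)


def _fit_kappa(vals: np.ndarray, cutoff: float) -> float:
    """ML fit of kappa on |p| <= cutoff under the truncated null density."""
    central = vals[np.abs(vals) <= cutoff]
    if central.size < 10:
        central = vals
    log1m = np.log1p(-central * central)
    s = float(np.sum(log1m))
    m = central.size
    c2 = min(cutoff * cutoff, 1.0 - 1e-12)

    def nll(log_kappa: float) -> float:
        k = np.exp(log_kappa) + 3.0  # kappa > 3
        log_z_full = special.betaln(0.5, (k - 1) / 2)
        mass = special.betainc(0.5, (k - 1) / 2, c2)
        log_z = log_z_full + np.log(max(mass, 1e-300))
        return -((k - 3) / 2 * s - m * log_z)

    res = optimize.minimize_scalar(nll, bounds=(-2.0, 14.0), method="bounded")
    return float(np.exp(res.x) + 3.0)


def _eta0_estimate(vals: np.ndarray, kappa: float) -> float:
    """Observed central mass over null central mass at the half-mass radius
    of the fitted null; conservative, truncated to [0, 1]."""
    eps = float(np.sqrt(special.betaincinv(0.5, (kappa - 1) / 2, 0.5)))
    observed = float(np.mean(np.abs(vals) <= eps))
    return min(1.0, observed / 0.5)


def _kappa_quantile_match(vals: np.ndarray, q: float) -> float:
    """kappa such that the q-th quantile of |p| under f0 matches the data."""
    emp = float(np.quantile(np.abs(vals), q))
    if emp <= 0 or emp >= 1:
        raise ValueError(f"cannot quantile-match at q={q}: quantile {emp}")

    def gap(log_km3: float) -> float:
        k = np.exp(log_km3) + 3.0
        model_q = float(np.sqrt(special.betaincinv(0.5, (k - 1) / 2, q)))
        return model_q - emp

    lo, hi = -2.0, 16.0
    if gap(lo) * gap(hi) > 0:  # no crossing: fall back to nearest bound
        return float(np.exp(lo if abs(gap(lo)) < abs(gap(hi)) else hi) + 3.0)
    root = optimize.brentq(gap, lo, hi)
    return float(np.exp(root) + 3.0)


def fit_edge_null(pcor_values, *, central_quantile: float = 0.8) -> EdgeFdrModel:
    """Fit the mixture null to observed off-diagonal partial correlations.

    kappa is first fitted by maximum likelihood on the assumed-null-dominated
    central region (|p| below the ``central_quantile`` of |values|).  Because
    the central ML fit can understate the null's tails in the high-dimensional
    regime (inflating tail-area FDR optimism), kappa is then floored against a
    tail-sensitive quantile-matched fit, taken at a quantile safely inside the
    null-dominated region given the initial eta0 estimate; the smaller
    (wider-null, more conservative) kappa wins.  eta0 is a conservative
    density-ratio estimate around p = 0, truncated to [0, 1].
    """
    vals = np.asarray(pcor_values, dtype=float).ravel()
    if vals.size < 100:
        raise ValueError(f"need >= 100 values to fit the null, got {vals.size}")
    if np.allclose(vals, vals[0]):
        raise ValueError("degenerate input: all values identical")
    cutoff = float(np.quantile(np.abs(vals), central_quantile))
    if cutoff <= 0:
        cutoff = float(np.max(np.abs(vals))) or 1e-6
    kappa_ml = _fit_kappa(vals, cutoff)
    eta0_init = _eta0_estimate(vals, kappa_ml)
    q_match = min(0.95, 1.0 - 3.0 * (1.0 - eta0_init))
    kappa = kappa_ml
    if q_match > 0.5:
        try:
            kappa_q = _kappa_quantile_match(vals, q_match)
            kappa = min(kappa_ml, kappa_q)
        except ValueError:
            pass
    return EdgeFdrModel(eta0=_eta0_estimate(vals, kappa), kappa=kappa)


def edge_statistics(pcor: np.ndarray, model: EdgeFdrModel,
                    gene_ids: list[str]) -> pd.DataFrame:
    """Per-pair two-sided tail-area FDR (and report-only local fdr).

    Tail-area FDR at threshold t = |pcor| is eta0 * P0(|P| >= t) divided by
    the empirical fraction of pairs at least as extreme, monotonized so that
    FDR is non-increasing in |pcor| (q-value style running minimum).
    """
    p = np.asarray(pcor, dtype=float)
    iu = np.triu_indices(p.shape[0], k=1)
    vals = p[iu]
    absvals = np.abs(vals)
    m = absvals.size

    order = np.argsort(absvals, kind="mergesort")
    # empirical survival: fraction of pairs with |v| >= t (self inclusive)
    ranks = np.empty(m, dtype=float)
    ranks[order] = np.arange(m)
    s_emp = (m - ranks) / m
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = model.eta0 * model.null_tail(absvals) / s_emp
    raw = np.minimum(raw, 1.0)
    # running minimum along increasing |pcor|
    fdr = np.empty(m, dtype=float)
    sorted_raw = raw[order]
    fdr[order] = np.minimum.accumulate(sorted_raw)

    # local fdr from a histogram density estimate (reported, not selective)
    hist, edges = np.histogram(vals, bins=201, range=(-1.0, 1.0), density=True)
    bin_idx = np.clip(np.digitize(vals, edges) - 1, 0, len(hist) - 1)
    f_hat = np.maximum(hist[bin_idx], 1e-12)
    lfdr = np.minimum(model.eta0 * model.null_pdf(vals) / f_hat, 1.0)

    ga = np.asarray(gene_ids, dtype=object)[iu[0]]
    gb = np.asarray(gene_ids, dtype=object)[iu[1]]
    return pd.DataFrame(
        {"gene_a": ga, "gene_b": gb, "pcor": vals, "fdr": fdr, "lfdr": lfdr}
    )


def select_edges(pcor: np.ndarray, model: EdgeFdrModel, gene_ids: list[str],
                 *, fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Edges with tail-area FDR strictly below the threshold."""
    stats_df = edge_statistics(pcor, model, gene_ids)
    selected = stats_df[stats_df["fdr"] < fdr_threshold].copy()
    swap = selected["gene_a"] > selected["gene_b"]
    a = selected["gene_a"].where(~swap, selected["gene_b"])
    b = selected["gene_b"].where(~swap, selected["gene_a"])
    selected["gene_a"], selected["gene_b"] = a, b
    return selected.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)


def build_network(edges: pd.DataFrame, biotypes: dict[str, str],
                  nodes=None) -> nx.Graph:
    """Undirected |pcor|-weighted graph with biotype-tagged nodes."""
    g = nx.Graph()
    if nodes is None:
        nodes = sorted(set(edges["gene_a"]) | set(edges["gene_b"]))
    for node in nodes:
        g.add_node(node, biotype=biotypes.get(node, ""))
    for row in edges.itertuples(index=False):
        if row.gene_a == row.gene_b:
            raise ValueError(f"self-loop on {row.gene_a!r}")
        g.add_edge(
            row.gene_a, row.gene_b,
            pcor=float(row.pcor), fdr=float(row.fdr),
            weight=abs(float(row.pcor)),
        )
    return g


# ---------------------------------------------------------------------------
# Fast-greedy modularity (Clauset-Newman-Moore) communities
# ---------------------------------------------------------------------------

@dataclass
class CommunityPartition:
    assignment: dict[str, int]
    q: float


def modularity(graph: nx.Graph, assignment: dict[str, int]) -> float:
    """Weighted Newman modularity Q = sum_c (w_in_c / W - (d_c / 2W)^2)."""
    w_total = sum(d.get("weight", 1.0) for _, _, d in graph.edges(data=True))
    if w_total == 0:
        return 0.0
    w_in: dict[int, float] = {}
    deg: dict[int, float] = {}
    for u, v, d in graph.edges(data=True):
        w = d.get("weight", 1.0)
        cu, cv = assignment[u], assignment[v]
        deg[cu] = deg.get(cu, 0.0) + w
        deg[cv] = deg.get(cv, 0.0) + w
        if cu == cv:
            w_in[cu] = w_in.get(cu, 0.0) + w
    q = 0.0
    for c in set(assignment.values()):
        q += w_in.get(c, 0.0) / w_total - (deg.get(c, 0.0) / (2 * w_total)) ** 2
    return q


def detect_communities(graph: nx.Graph) -> CommunityPartition:
    """CNM greedy modularity agglomeration on the |pcor|-weighted graph.

    Merges the community pair with the largest modularity gain; ties are
    broken by the smallest (cluster-id, cluster-id) pair.  Isolated nodes stay
    singleton clusters.  Returns the partition at the maximal encountered Q.
    Deterministic given the edge list.
    """
    nodes = sorted(graph.nodes)
    if graph.number_of_edges() == 0:
        return CommunityPartition(
            assignment={n: i for i, n in enumerate(nodes)}, q=0.0
        )
    w_total = sum(d.get("weight", 1.0) for _, _, d in graph.edges(data=True))
    node_cid = {n: i for i, n in enumerate(nodes)}
    # community state
    a = {}           # cid -> weighted degree / (2W)
    e = {}           # cid -> {other_cid: weight between}
    members = {cid: {n} for n, cid in node_cid.items()}
    version = {cid: 0 for cid in members}
    for cid, n in zip(node_cid.values(), nodes):
        a[cid] = sum(
            d.get("weight", 1.0) for _, _, d in graph.edges(n, data=True)
        ) / (2 * w_total)
        e[cid] = {}
    for u, v, d in graph.edges(data=True):
        cu, cv = node_cid[u], node_cid[v]
        w = d.get("weight", 1.0)
        e[cu][cv] = e[cu].get(cv, 0.0) + w
        e[cv][cu] = e[cv].get(cu, 0.0) + w

    q = -sum(ai * ai for ai in a.values())
    best_q = q
    best_assignment = dict(node_cid)

    heap: list[tuple[float, int, int, int, int]] = []
    for c in e:
        for d_, w in e[c].items():
            if c < d_:
                dq = w / w_total - 2 * a[c] * a[d_]
                heapq.heappush(heap, (-dq, c, d_, version[c], version[d_]))

    alive = set(members)
    while heap:
        neg_dq, c, d_, vc, vd = heapq.heappop(heap)
        if c not in alive or d_ not in alive:
            continue
        if version[c] != vc or version[d_] != vd:
            continue
        dq = -neg_dq
        # merge d_ into c (c < d_ by construction)
        q += dq
        members[c] |= members.pop(d_)
        alive.discard(d_)
        a[c] += a[d_]
        neigh_c = e.pop(c)
        neigh_d = e.pop(d_)
        merged: dict[int, float] = {}
        for nb, w in neigh_c.items():
            if nb != d_:
                merged[nb] = merged.get(nb, 0.0) + w
        for nb, w in neigh_d.items():
            if nb != c:
                merged[nb] = merged.get(nb, 0.0) + w
        e[c] = merged
        version[c] += 1
        for nb, w in merged.items():
            e[nb].pop(d_, None)
            e[nb][c] = w
            lo, hi = (c, nb) if c < nb else (nb, c)
            new_dq = w / w_total - 2 * a[c] * a[nb]
            heapq.heappush(
                heap, (-new_dq, lo, hi, version[lo], version[hi])
            )
        if q > best_q + 1e-12:
            best_q = q
            best_assignment = {
                n: cid for cid, ms in members.items() for n in ms
            }

    # relabel cluster ids densely and deterministically
    relabel: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for n in nodes:
        cid = best_assignment[n]
        if cid not in relabel:
            relabel[cid] = len(relabel)
        assignment[n] = relabel[cid]
    return CommunityPartition(assignment=assignment, q=best_q)


def lncrna_neighborhood(graph: nx.Graph, lnc_id: str) -> set:
    """mRNA nodes directly adjacent to the given lncRNA."""
    if lnc_id not in graph:
        raise KeyError(f"node {lnc_id!r} absent from network")
    if graph.nodes[lnc_id].get("biotype") != "lncRNA":
        raise ValueError(f"node {lnc_id!r} is not a lncRNA")
    return {
        nb for nb in graph.neighbors(lnc_id)
        if graph.nodes[nb].get("biotype") == "mRNA"
    }
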