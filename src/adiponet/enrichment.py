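"""Set-level statistics: hypergeometric overlap, binomial overrepresentation,
Benjamini-Hochberg adjustment, preranked GSEA, and the guilt-by-association
drivers that annotate lncRNAs and network clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp


@dataclass(frozen=True)
class EnrichmentResult:
    name: str
    k: int      # overlap count
    K: int      # set size within the universe
    n: int      # query size
    N: int      # universe size
    p: float
    q: float | None = None


@dataclass(frozen=True)
class GseaResult:
    name: str
    es: float
    nes: float
    p_perm: float
    n_perm: int
    seed: int
    size: int


def hypergeom_overlap(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n), in log space."""
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(
            f"inconsistent counts: k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    hi = min(K, n)
    support = np.arange(k, hi + 1)
    logp = stats.hypergeom.logpmf(support, N, K, n)
    return float(min(1.0, np.exp(logsumexp(logp))))


def binomial_overrep(k: int, n: int, p0: float) -> float:
    """Upper-tail P(X >= k) for X ~ Binomial(n, p0), in log space."""
    if not 0 <= k <= n:
        raise ValueError(f"inconsistent counts: k={k}, n={n}")
    if not 0 < p0 < 1:
        raise ValueError(f"p0 must be in (0,1), got {p0}")
    if k == 0:
        return 1.0
    support = np.arange(k, n + 1)
    logp = stats.binom.logpmf(support, n, p0)
    return float(min(1.0, np.exp(logsumexp(logp))))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, preserving input order.

    Stable under ties; the step-up monotonicity (cumulative minimum from the
    largest p downward) is enforced, so applying the procedure twice is
    idempotent.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        bad = p[(p < 0) | (p > 1) | ~np.isfinite(p)][0]
        raise ValueError(f"p-value outside [0,1]: {bad}")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return out


# ---------------------------------------------------------------------------
# Preranked GSEA
# ---------------------------------------------------------------------------

def _running_es(hit_mask: np.ndarray, scores: np.ndarray, weight: float):
    """Signed extremum of the GSEA running sum for one ordered hit mask."""
    inc = np.where(hit_mask, np.abs(scores) ** weight, 0.0)
    nr = inc.sum()
    if nr == 0:
        # all hit scores are zero: fall back to equal increments
        inc = hit_mask.astype(float)
        nr = inc.sum()
    n_miss = len(scores) - int(hit_mask.sum())
    dec = np.where(hit_mask, 0.0, 1.0 / n_miss)
    running = np.cumsum(inc / nr - dec)
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx]), running


def preranked_gsea(scores: pd.Series, gene_set, *, weight: float = 1.0,
                   n_perm: int = 1000, seed: int = 0,
                   name: str = "") -> GseaResult:
    """Classic weighted running-sum GSEA with a gene-label permutation null.

    ``scores`` maps gene id -> ranking metric; genes are sorted descending
    (ties broken by gene id for determinism).  Unknown genes in the set are
    dropped; an empty or universe-covering set is an error.
    """
    s = pd.Series(scores).astype(float)
    if not np.all(np.isfinite(s.to_numpy())):
        raise ValueError("scores must be finite")
    ordering = sorted(s.index, key=lambda g: (-s[g], str(g)))
    s = s.loc[ordering]
    universe = set(s.index)
    members = set(gene_set) & universe
    dropped = set(gene_set) - universe
    if not members:
        raise ValueError("gene set has no members in the ranked universe")
    if members == universe:
        raise ValueError("gene set equals the ranked universe")
    hit = np.array([g in members for g in s.index])
    values = s.to_numpy()
    es, _ = _running_es(hit, values, weight)

    rng = np.random.default_rng(seed)
    k = len(members)
    null = np.empty(n_perm)
    n_genes = len(values)
    for i in range(n_perm):
        idx = rng.choice(n_genes, size=k, replace=False)
        mask = np.zeros(n_genes, dtype=bool)
        mask[idx] = True
        null[i], _ = _running_es(mask, values, weight)

    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    if same_sign.size:
        nes = es / np.mean(np.abs(same_sign))
    else:
        nes = float("nan")
    n_extreme = int(np.sum(np.abs(same_sign) >= abs(es)))
    p_perm = (1 + n_extreme) / (n_perm + 1)
    _ = dropped  # reported by callers that care
    return GseaResult(name=name, es=es, nes=float(nes), p_perm=float(p_perm),
                      n_perm=n_perm, seed=seed, size=k)


# ---------------------------------------------------------------------------
# Guilt-by-association drivers
# ---------------------------------------------------------------------------

def annotate_lncrnas(graph, collection, *, alpha: float = 0.01,
                     universe=None) -> pd.DataFrame:
    """Hypergeometric enrichment of each lncRNA's direct-mRNA neighborhood.

    One row per (lncRNA, gene set); ``significant`` marks p < alpha.  The
    universe defaults to the network's mRNA nodes.  lncRNAs with an empty
    neighborhood are skipped (noted in the ``note`` column of an empty row
    set, i.e. simply absent).
    """
    from .network import lncrna_neighborhood

    if universe is None:
        universe = {
            n for n, d in graph.nodes(data=True) if d.get("biotype") == "mRNA"
        }
    universe = set(universe)
    N = len(universe)
    rows = []
    lncs = sorted(
        n for n, d in graph.nodes(data=True) if d.get("biotype") == "lncRNA"
    )
    for lnc in lncs:
        neigh = lncrna_neighborhood(graph, lnc) & universe
        if not neigh:
            continue
        n = len(neigh)
        for set_name, members in collection:
            K = len(set(members) & universe)
            if K == 0:
                continue
            k = len(neigh & set(members))
            p = hypergeom_overlap(k, K, n, N)
            rows.append((lnc, set_name, k, K, n, N, p))
    df = pd.DataFrame(
        rows, columns=["lncrna", "set", "k", "K", "n", "N", "p"]
    )
    if len(df):
        df["q"] = np.concatenate([
            bh_adjust(sub["p"].to_numpy())
            for _, sub in df.groupby("lncrna", sort=False)
        ])
        df["significant"] = df["p"] < alpha
    else:
        df["q"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df


def cluster_overrep(graph, partition, collection, *, universe=None,
                    tier_p: float = 1e-9) -> pd.DataFrame:
    """Binomial overrepresentation of gene sets in each network cluster.

    The tested list for a cluster is its mRNAs directly connected to at least
    one lncRNA; p0 for a set is the set's fraction of the reference universe.
    ``tier_p`` labels highly significant rows, it does not filter.
    """
    if universe is None:
        universe = {
            n for n, d in graph.nodes(data=True) if d.get("biotype") == "mRNA"
        }
    universe = set(universe)
    N = len(universe)
    for set_name, members in collection:
        if not set(members) & universe:
            raise ValueError(
                f"gene set {set_name!r} has no members in the universe"
            )
    clusters: dict[int, set] = {}
    for node, cid in partition.assignment.items():
        clusters.setdefault(cid, set()).add(node)
    rows = []
    for cid in sorted(clusters):
        members_c = clusters[cid]
        tested = set()
        for node in members_c:
            if graph.nodes[node].get("biotype") != "mRNA":
                continue
            if any(
                graph.nodes[nb].get("biotype") == "lncRNA"
                for nb in graph.neighbors(node)
            ):
                tested.add(node)
        tested &= universe
        if not tested:
            continue  # skipped with note: no lncRNA-connected mRNAs
        n = len(tested)
        for set_name, members in collection:
            K = len(set(members) & universe)
            p0 = K / N
            k = len(tested & set(members))
            p = binomial_overrep(k, n, p0)
            rows.append((cid, set_name, k, n, K, N, p0, p))
    df = pd.DataFrame(
        rows,
        columns=["cluster", "set", "k", "n", "K", "N", "p0", "p"],
    )
    if len(df):
        df = df.sort_values(["cluster", "p", "set"], kind="mergesort")
        df["highly_significant"] = df["p"] < tier_p
        df = df.reset_index(drop=True)
    else:
        df["highly_significant"] = pd.Series(dtype=bool)
    return df
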