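"""Tissue-specificity calling, BAT-selective gene listing, strand-aware
promoter windows, and ChIP peak / promoter overlap enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import EnrichmentResult, bh_adjust, hypergeom_overlap
from .io_formats import GeneRecord, PeakSet


# ---------------------------------------------------------------------------
# Tissue specificity
# ---------------------------------------------------------------------------

def tissue_specific_sets(panel: pd.DataFrame, *, ratio: float = 5.0,
                         min_fpkm: float = 1.0,
                         max_tissues: int = 2) -> dict[str, set]:
    """Per-tissue specific gene sets from a genes-by-tissues FPKM panel.

    A gene is assigned to tissue t iff FPKM_t >= min_fpkm and FPKM_t >=
    ratio * median over the other tissues; genes qualifying for more than
    ``max_tissues`` tissues are considered non-specific and dropped.
    """
    if panel.shape[1] < 2:
        raise ValueError("panel must contain at least 2 tissues")
    if panel.columns.duplicated().any():
        raise ValueError("tissue labels must be unique")
    values = panel.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("panel contains negative FPKM")
    n_tissues = panel.shape[1]
    qualifies = np.zeros_like(values, dtype=bool)
    for j in range(n_tissues):
        others = np.delete(values, j, axis=1)
        med = np.median(others, axis=1)
        qualifies[:, j] = (values[:, j] >= min_fpkm) & (
            values[:, j] >= ratio * med
        )
    n_qual = qualifies.sum(axis=1)
    specific = (n_qual >= 1) & (n_qual <= max_tissues)
    sets: dict[str, set] = {t: set() for t in panel.columns}
    for j, tissue in enumerate(panel.columns):
        for gene in panel.index[qualifies[:, j] & specific]:
            sets[tissue].add(gene)
    return sets


def specificity_overlap(de_set, tissue_sets: dict[str, set],
                        universe) -> list[EnrichmentResult]:
    """Hypergeometric overlap of a DE set with each tissue set, BH across
    tissues."""
    universe = set(universe)
    de_set = set(de_set)
    outside = de_set - universe
    if outside:
        raise ValueError(
            f"DE set has genes outside the universe: {sorted(outside)[:5]}"
        )
    N = len(universe)
    n = len(de_set)
    names, pvals, rows = [], [], []
    for tissue in sorted(tissue_sets):
        members = set(tissue_sets[tissue]) & universe
        K = len(members)
        k = len(de_set & members)
        p = hypergeom_overlap(k, K, n, N) if K else 1.0
        names.append(tissue)
        pvals.append(p)
        rows.append((tissue, k, K, n, N, p))
    qvals = bh_adjust(pvals) if pvals else []
    return [
        EnrichmentResult(name=t, k=k, K=K, n=n_, N=N_, p=p, q=float(q))
        for (t, k, K, n_, N_, p), q in zip(rows, qvals)
    ]


def bat_selective_genes(expr_bat: pd.Series, expr_iwat: pd.Series,
                        expr_ewat: pd.Series, *, fold: float = 3.0,
                        min_fpkm: float = 1.0) -> list[str]:
    """Genes enriched in BAT relative to both white depots.

    Retains genes with FPKM_BAT >= min_fpkm and FPKM_BAT >= fold *
    max(FPKM_iWAT, FPKM_eWAT).
    """
    if not (expr_bat.index.equals(expr_iwat.index)
            and expr_bat.index.equals(expr_ewat.index)):
        raise ValueError("depot expression vectors cover different catalogs")
    wat_max = np.maximum(expr_iwat.to_numpy(float), expr_ewat.to_numpy(float))
    bat = expr_bat.to_numpy(float)
    keep = (bat >= min_fpkm) & (bat >= fold * wat_max)
    return list(expr_bat.index[keep])


# ---------------------------------------------------------------------------
# Promoter windows and peak overlap
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PromoterWindow:
    gene_id: str
    chrom: str
    start: int
    end: int


def promoter_windows(annotation: dict[str, GeneRecord],
                     width: int = 50_000) -> dict[str, PromoterWindow]:
    """Strand-aware upstream windows: [tss-width, tss) on +, [tss, tss+width)
    on -, clipped at the contig start."""
    windows = {}
    for gid, rec in annotation.items():
        if rec.strand == "+":
            start, end = max(0, rec.tss - width), rec.tss
        else:
            start, end = rec.tss, rec.tss + width
        if end <= start:
            continue  # TSS at contig start on + strand: empty window
        windows[gid] = PromoterWindow(gene_id=gid, chrom=rec.chrom,
                                      start=start, end=end)
    return windows


def _bound_genes(peaks: PeakSet, windows: dict[str, PromoterWindow],
                 known_chroms: set) -> set:
    """Genes whose window overlaps >= 1 peak by >= 1 bp (half-open)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end, _ in peaks.records:
        if chrom not in known_chroms:
            warnings.warn(
                f"peak chrom {chrom!r} absent from annotation; peak ignored"
            )
            continue
        by_chrom.setdefault(chrom, []).append((start, end))
    index = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts = np.array([s for s, _ in ivs])
        ends = np.array([e for _, e in ivs])
        index[chrom] = (starts, np.maximum.accumulate(ends))
    bound = set()
    for gid, w in windows.items():
        if w.chrom not in index:
            continue
        starts, cummax_ends = index[w.chrom]
        i = np.searchsorted(starts, w.end, side="left")  # peaks with start < end
        if i > 0 and cummax_ends[i - 1] > w.start:
            bound.add(gid)
    return bound


def peak_promoter_enrichment(peak_sets: list[PeakSet],
                             windows: dict[str, PromoterWindow],
                             query_genes, universe) -> tuple[pd.DataFrame,
                                                             pd.DataFrame]:
    """Per-source bound fraction of query genes and hypergeometric enrichment.

    A gene is "bound" iff at least one peak of the source overlaps its
    promoter window by >= 1 bp.  Returns (per-source summary with BH q across
    sources, per-gene bound flags).
    """
    universe = set(universe)
    query = set(query_genes)
    outside = query - universe
    if outside:
        raise ValueError(
            f"query genes outside the universe: {sorted(outside)[:5]}"
        )
    known_chroms = {w.chrom for w in windows.values()}
    N = len(universe)
    n = len(query)
    rows, pvals = [], []
    flags = pd.DataFrame(index=sorted(universe))
    for peaks in peak_sets:
        bound = _bound_genes(peaks, windows, known_chroms) & universe
        k = len(bound & query)
        K = len(bound)
        p = hypergeom_overlap(k, K, n, N) if K and n else 1.0
        frac = k / n if n else float("nan")
        rows.append(
            {"source": peaks.source, "bound_in_query": k, "bound_total": K,
             "query_size": n, "universe_size": N, "bound_fraction": frac,
             "p": p}
        )
        pvals.append(p)
        flags[peaks.source] = [g in bound for g in flags.index]
    summary = pd.DataFrame(rows)
    if len(summary):
        summary["q"] = bh_adjust(pvals)
    return summary, flags
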