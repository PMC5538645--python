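"""Per-contrast differential-regulation calling and cross-condition consensus.

The contrast test is Welch's t on log2(FPKM + pseudocount) with BH
adjustment; the decision thresholds (FDR <= alpha, |log2FC| >= tau, both
inclusive) are what downstream stages consume, so an externally produced
contrast table with the same columns can be substituted.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_adjust, hypergeom_overlap
from .io_formats import ExpressionMatrix

CONTRAST_COLUMNS = ("gene_id", "contrast", "log2fc", "p", "q", "direction")


def _select_samples(meta: pd.DataFrame, label) -> list[str]:
    """Resolve a condition label or (depot, condition) pair to sample ids."""
    if isinstance(label, tuple):
        depot, condition = label
        mask = (meta["depot"] == depot) & (meta["condition"] == condition)
    else:
        mask = meta["condition"] == label
    return list(meta.index[mask])


def compute_contrast(expr: ExpressionMatrix, treatment, control, *,
                     contrast: str | None = None, pseudocount: float = 1.0,
                     alpha: float = 0.05,
                     min_abs_log2fc: float = 1.0) -> pd.DataFrame:
    """Welch-t contrast of treatment vs control on log2(FPKM + pseudocount).

    With a single replicate per arm only log2fc is computed (p/q are NaN and
    every direction is "ns").  Zero variance in both arms with unequal means
    yields p = 0 with a ``degenerate`` flag.
    """
    t_ids = _select_samples(expr.meta, treatment)
    c_ids = _select_samples(expr.meta, control)
    if not t_ids:
        raise ValueError(f"treatment label {treatment!r} absent from metadata")
    if not c_ids:
        raise ValueError(f"control label {control!r} absent from metadata")
    if expr.values.shape[0] == 0:
        raise ValueError("expression matrix has zero genes")
    if contrast is None:
        tn = treatment[1] if isinstance(treatment, tuple) else treatment
        contrast = str(tn)

    lt = np.log2(expr.values[t_ids].to_numpy() + pseudocount)
    lc = np.log2(expr.values[c_ids].to_numpy() + pseudocount)
    log2fc = lt.mean(axis=1) - lc.mean(axis=1)

    n_genes = len(expr.gene_ids)
    degenerate = np.zeros(n_genes, dtype=bool)
    if len(t_ids) < 2 or len(c_ids) < 2:
        p = np.full(n_genes, np.nan)
        q = np.full(n_genes, np.nan)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(lt, lc, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
        var_t = lt.var(axis=1, ddof=1)
        var_c = lc.var(axis=1, ddof=1)
        both_const = (var_t == 0) & (var_c == 0)
        equal_means = np.isclose(log2fc, 0.0)
        p[both_const & equal_means] = 1.0
        degenerate = both_const & ~equal_means
        if degenerate.any():
            warnings.warn(
                f"{int(degenerate.sum())} gene(s) with zero variance in both "
                "arms but unequal means: p set to 0",
                stacklevel=2,
            )
            p[degenerate] = 0.0
        q = bh_adjust(p)

    direction = np.full(n_genes, "ns", dtype=object)
    with np.errstate(invalid="ignore"):
        qual = q <= alpha
    direction[qual & (log2fc >= min_abs_log2fc)] = "up"
    direction[qual & (log2fc <= -min_abs_log2fc)] = "down"

    return pd.DataFrame(
        {
            "gene_id": expr.gene_ids,
            "contrast": contrast,
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "direction": direction,
            "degenerate": degenerate,
        }
    )


def apply_de_filter(results: pd.DataFrame, *, alpha: float = 0.05,
                    min_abs_log2fc: float = 1.0,
                    fold_change_only: bool = False) -> tuple[set, set]:
    """Partition qualifying genes into (up, down) sets; thresholds inclusive."""
    q = results["q"].to_numpy(dtype=float)
    fc = results["log2fc"].to_numpy(dtype=float)
    genes = results["gene_id"].to_numpy()
    if np.all(np.isnan(q)):
        if not fold_change_only:
            raise ValueError(
                "q-values are absent; pass fold_change_only=True to filter on "
                "log2fc alone"
            )
        qual = np.ones(len(q), dtype=bool)
    else:
        with np.errstate(invalid="ignore"):
            qual = q <= alpha
    up = set(genes[qual & (fc >= min_abs_log2fc)])
    down = set(genes[qual & (fc <= -min_abs_log2fc)])
    return up, down


@dataclass
class ConsensusTable:
    """Per-gene consensus qualification across the five contrasts."""

    table: pd.DataFrame
    k_min: int
    mode: str

    def genes(self) -> list[str]:
        return list(self.table["gene_id"])


# Sign convention: +1 contrasts are browning/BAT-activation (induction counts
# as concordant-up), -1 contrasts are whitening (repression counts as
# concordant-up).
def consensus_filter(results: dict[str, pd.DataFrame], *, k_min: int,
                     mode: str = "any",
                     sign_conventions: dict[str, int] | None = None,
                     alpha: float = 0.05,
                     min_abs_log2fc: float = 1.0) -> ConsensusTable:
    """Cross-condition consensus over exactly five contrasts.

    ``mode="any"`` counts qualification regardless of sign (network input);
    ``mode="concordant"`` counts only sign-consistent qualifications under the
    browning convention declared in ``sign_conventions``.
    """
    if len(results) != 5:
        raise ValueError(f"exactly 5 contrasts required, got {len(results)}")
    if mode not in ("any", "concordant"):
        raise ValueError(f"unknown mode {mode!r}")
    if k_min > 5:
        raise ValueError(f"k_min={k_min} exceeds the 5 available contrasts")
    if sign_conventions is None:
        sign_conventions = {}
    missing = [c for c in results if c not in sign_conventions]
    if mode == "concordant" and missing:
        raise ValueError(f"contrasts missing sign convention: {missing}")

    per_gene: dict[str, dict] = {}
    for cname, df in results.items():
        up, down = apply_de_filter(
            df, alpha=alpha, min_abs_log2fc=min_abs_log2fc
        )
        sign = sign_conventions.get(cname, 1)
        for g in up:
            rec = per_gene.setdefault(g, {"any": set(), "cu": set(), "cd": set()})
            rec["any"].add(cname)
            (rec["cu"] if sign == 1 else rec["cd"]).add(cname)
        for g in down:
            rec = per_gene.setdefault(g, {"any": set(), "cu": set(), "cd": set()})
            rec["any"].add(cname)
            (rec["cd"] if sign == 1 else rec["cu"]).add(cname)

    rows = []
    for g in sorted(per_gene):
        rec = per_gene[g]
        if mode == "any":
            qualifying = rec["any"]
            direction = ""
        else:
            if len(rec["cu"]) >= len(rec["cd"]):
                qualifying, direction = rec["cu"], "up"
            else:
                qualifying, direction = rec["cd"], "down"
        if len(qualifying) >= k_min:
            rows.append(
                {
                    "gene_id": g,
                    "qualifying": ",".join(sorted(qualifying)),
                    "n_qualifying": len(qualifying),
                    "consensus_direction": direction,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=["gene_id", "qualifying", "n_qualifying", "consensus_direction"],
    )
    return ConsensusTable(table=table, k_min=k_min, mode=mode)


def overlap_tabulate(sets: dict[str, set], universe: set) -> dict:
    """All Venn region counts for <=5 sets plus pairwise hypergeometric p.

    The universe must be declared explicitly; elements outside it are an
    error.  Pairwise overlap significance delegates to
    :func:`adiponet.enrichment.hypergeom_overlap`.
    """
    if len(sets) > 5:
        raise ValueError("at most 5 sets supported")
    universe = set(universe)
    for name, s in sets.items():
        outside = set(s) - universe
        if outside:
            raise ValueError(
                f"set {name!r} has elements outside the universe: "
                f"{sorted(outside)[:5]}"
            )
    names = list(sets)
    # region key: frozenset of set names containing the element
    counts: dict[frozenset, int] = {}
    for e in universe:
        key = frozenset(n for n in names if e in sets[n])
        counts[key] = counts.get(key, 0) + 1
    for combo_size in range(len(names) + 1):
        for combo in itertools.combinations(names, combo_size):
            counts.setdefault(frozenset(combo), 0)
    pairwise = []
    N = len(universe)
    for a, b in itertools.combinations(names, 2):
        k = len(sets[a] & sets[b])
        p = hypergeom_overlap(k, len(sets[a]), len(sets[b]), N)
        pairwise.append({"set_a": a, "set_b": b, "k": k, "p": p})
    regions = {
        "&".join(sorted(key)) if key else "(none)": v
        for key, v in counts.items()
    }
    return {"regions": regions, "pairwise": pairwise, "universe_size": N}
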