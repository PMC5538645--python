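"""UGU-density scan over 3'UTR sequences in 100-nt sliding windows.

Counts are of (possibly overlapping) occurrences of the literal trimer "UGU"
fully inside each window; a 100-nt window can pack at most 49 overlapping
occurrences.  Scanning is strand/orientation specific and operates on the
sense-strand UTR sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ALPHABET = set("ACGUN")
MOTIF = "UGU"


@dataclass(frozen=True)
class WindowScore:
    gene_id: str
    start: int
    end: int
    ugu_count: int


def max_packed_count(window: int) -> int:
    """Maximum overlapping UGU occurrences in a window of the given length."""
    if window < len(MOTIF):
        return 0
    return (window - 1) // 2


def find_motif_positions(seq: str, motif: str = MOTIF) -> list[int]:
    """Start positions of all (overlapping) motif occurrences."""
    positions = []
    idx = seq.find(motif)
    while idx != -1:
        positions.append(idx)
        idx = seq.find(motif, idx + 1)
    return positions


def count_ugu_windows(seq: str, *, window: int = 100, step: int = 1,
                      gene_id: str = "") -> list[WindowScore]:
    """Sliding-window UGU occurrence counts over an RNA-alphabet sequence.

    Windows slide by ``step``; a final partial window is included if it is at
    least 3 nt long.  Occurrences must lie fully inside the window; 'N' never
    matches.
    """
    seq = seq.upper()
    bad = set(seq) - ALPHABET
    if bad:
        raise ValueError(
            f"non-ACGUN characters in sequence: {sorted(bad)} "
            "(DNA input? normalize T->U first)"
        )
    length = len(seq)
    if length < len(MOTIF):
        raise ValueError(f"sequence shorter than {len(MOTIF)} nt")
    positions = np.asarray(find_motif_positions(seq), dtype=int)

    if length <= window:
        starts = [0]
    else:
        starts = list(range(0, length - window + 1, step))
        tail = starts[-1] + step
        if tail < length and length - tail >= len(MOTIF):
            starts.append(tail)

    scores = []
    for s in starts:
        e = min(s + window, length)
        if positions.size:
            lo = np.searchsorted(positions, s, side="left")
            hi = np.searchsorted(positions, e - len(MOTIF), side="right")
            count = int(hi - lo)
        else:
            count = 0
        scores.append(WindowScore(gene_id=gene_id, start=s, end=e,
                                  ugu_count=count))
    return scores


def best_window(seq: str, *, window: int = 100, step: int = 1,
                gene_id: str = "") -> WindowScore:
    """Maximal-count window for one sequence (ties -> smallest start)."""
    scores = count_ugu_windows(seq, window=window, step=step, gene_id=gene_id)
    return max(scores, key=lambda w: (w.ugu_count, -w.start))


def rank_cbs_candidates(seqs: dict[str, str], *, window: int = 100,
                        step: int = 1, tier_threshold: int = 20,
                        genes=None) -> pd.DataFrame:
    """Rank genes by their maximal UGU window; label the top tier.

    ``genes`` restricts the scan (e.g. to a BAT-selective list); the ranking
    is descending by count with ties broken by gene id.
    """
    if genes is not None:
        missing = [g for g in genes if g not in seqs]
        if missing:
            raise KeyError(f"genes absent from sequence map: {missing[:5]}")
        seqs = {g: seqs[g] for g in genes}
    if not seqs:
        raise ValueError("no sequences to scan")
    rows = []
    for gene_id in seqs:
        w = best_window(seqs[gene_id], window=window, step=step,
                        gene_id=gene_id)
        rows.append(
            {
                "gene_id": gene_id,
                "window_start": w.start,
                "window_end": w.end,
                "ugu_count": w.ugu_count,
                "tier": "top" if w.ugu_count >= tier_threshold else "",
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["ugu_count", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
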