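"""Genomic interval utilities.

All coordinates are 0-based, half-open (BED convention): an interval
``[start, end)`` covers bases ``start .. end-1``.  Two intervals overlap iff
``a.start < b.end and b.start < a.end``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

INTERVAL_COLUMNS = ["chrom", "start", "end"]


def validate_intervals(df: pd.DataFrame, name: str = "intervals") -> None:
    """Raise ``ValueError`` if *df* is not a valid interval table."""
    missing = [c for c in INTERVAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{name}: missing columns {missing}")
    if len(df) and not (df["start"] < df["end"]).all():
        bad = df.index[~(df["start"] < df["end"])][:5].tolist()
        raise ValueError(f"{name}: start >= end at rows {bad}")
    if len(df) and (df["start"] < 0).any():
        raise ValueError(f"{name}: negative start coordinates")


def count_overlaps(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Number of *subject* intervals overlapping (>= 1 bp) each *query* interval.

    Sort-based: for each query, ``#{s.start < q.end} - #{s.end <= q.start}``.
    The second set is contained in the first (s.start < s.end <= q.start < q.end),
    so the difference is exactly the overlap count.  O((n+m) log m) per chromosome.
    """
    out = np.zeros(len(query), dtype=np.int64)
    if len(query) == 0 or len(subject) == 0:
        return out
    for chrom, sub in subject.groupby("chrom", sort=False):
        mask = (query["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        starts = np.sort(sub["start"].to_numpy())
        ends = np.sort(sub["end"].to_numpy())
        qs = query.loc[mask, "start"].to_numpy()
        qe = query.loc[mask, "end"].to_numpy()
        n_start_before = np.searchsorted(starts, qe, side="left")
        n_end_before = np.searchsorted(ends, qs, side="right")
        out[mask] = n_start_before - n_end_before
    return out


def nearest_distance(points: pd.DataFrame, targets: pd.DataFrame,
                     point_col: str = "pos", target_col: str = "pos") -> np.ndarray:
    """Per-point distance (bp) to the nearest target position on the same
    chromosome; NaN where the chromosome carries no target."""
    out = np.full(len(points), np.nan)
    if len(points) == 0 or len(targets) == 0:
        return out
    for chrom, tgt in targets.groupby("chrom", sort=False):
        mask = (points["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        tpos = np.sort(tgt[target_col].to_numpy(dtype=float))
        ppos = points.loc[mask, point_col].to_numpy(dtype=float)
        idx = np.searchsorted(tpos, ppos)
        left = np.where(idx > 0, np.abs(ppos - tpos[np.clip(idx - 1, 0, None)]), np.inf)
        right = np.where(idx < len(tpos), np.abs(tpos[np.clip(idx, None, len(tpos) - 1)] - ppos), np.inf)
        out[mask] = np.minimum(left, right)
    return out
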