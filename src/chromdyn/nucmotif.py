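"""Nucleosome dyad modelling, PWM motif scanning and motif-dyad
displacement statistics.

Nucleosome dyads are modelled from the midpoints of large (> 100 bp) ATAC
fragments: a Gaussian-smoothed midpoint density is scanned for local maxima,
which are accepted greedily by descending density with a 147 bp exclusion
zone (one nucleosome footprint).  A motif is "nucleosome-occluded" when its
midpoint lies within 73 bp of a dyad — inside the wrap of DNA around the
histone octamer.  Pioneer-factor activity shows up as a loss of occlusion
(and a growth of motif-to-dyad distances) after factor binding.

Motif scanning uses summed log-odds against a background model, reported as
a min-max-normalised relative score; a site is a window with relative score
>= 0.8 by default (an "80% match").
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from . import io as cio
from .intervals import nearest_distance

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class DegeneratePWMError(ValueError):
    """PWM carries no information (max score equals min score)."""


@dataclass
class PWM:
    """Position weight matrix with pseudocount-regularised probabilities and
    log-odds scores against a background base composition."""

    probs: np.ndarray        # (4, w)
    background: np.ndarray   # (4,)

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.shape[0] != 4 or self.probs.shape[1] < 4:
            raise ValueError("PWM must be 4 x width with width >= 4")
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")
        self.logodds = np.log2(self.probs / self.background[:, None])
        self.min_score = float(self.logodds.min(axis=0).sum())
        self.max_score = float(self.logodds.max(axis=0).sum())
        if not self.max_score > self.min_score:
            raise DegeneratePWMError("uniform PWM: max score equals min score")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    def rel_score(self, score) -> np.ndarray:
        return (np.asarray(score) - self.min_score) / (self.max_score - self.min_score)

    def reverse_complement(self) -> "PWM":
        return PWM(probs=self.probs[::-1, ::-1].copy(), background=self.background[::-1].copy())

    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.probs, axis=0))

    @classmethod
    def from_counts(cls, counts: np.ndarray, pseudocount: float = 0.25,
                    background=None) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        if (counts < 0).any():
            raise ValueError("negative PFM counts")
        probs = (counts + pseudocount) / (counts.sum(axis=0) + 4 * pseudocount)
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        return cls(probs=probs, background=bg)


def read_pfm(text_or_path, pseudocount: float = 0.25, background=None) -> PWM:
    """JASPAR-style 4-row count text -> PWM (probabilities =
    (count + 0.25) / (column sum + 1) at the default pseudocount)."""
    text = text_or_path
    if "\n" not in str(text_or_path):
        try:
            text = open(text_or_path).read()
        except (OSError, ValueError):
            pass
    counts = cio.read_pfm_text(str(text))
    return PWM.from_counts(counts, pseudocount=pseudocount, background=background)


# ---------------------------------------------------------------- scanning

def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype="S1")
    out = np.full(len(arr), -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == base.encode()] = idx
    return out


def _window_scores(code: np.ndarray, logodds: np.ndarray) -> np.ndarray:
    """Summed log-odds per window; windows containing non-ACGT bases -> -inf."""
    w = logodds.shape[1]
    n_win = len(code) - w + 1
    if n_win <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(code, w)
    valid = (windows >= 0).all(axis=1)
    scores = np.full(n_win, -np.inf)
    if valid.any():
        idx = windows[valid]
        cols = np.arange(w)
        scores[valid] = logodds[idx, cols].sum(axis=1)
    return scores


def scan_motifs(seq: str, pwm: PWM, rel_min: float = 0.8,
                chrom: str = "chr1", offset: int = 0) -> pd.DataFrame:
    """Report every window (both strands) with relative score >= ``rel_min``.

    A window hit on both strands is reported once with the higher score
    (ties keep the plus strand).  Windows containing N are skipped.
    """
    code = _encode(seq)
    fwd = _window_scores(code, pwm.logodds)
    rev = _window_scores(code, pwm.reverse_complement().logodds)
    if len(fwd) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "strand", "score", "rel_score"])
    take_fwd = fwd >= rev
    best = np.where(take_fwd, fwd, rev)
    rel = pwm.rel_score(best)
    hit = rel >= rel_min
    starts = np.flatnonzero(hit)
    df = pd.DataFrame({
        "chrom": chrom,
        "start": starts + offset,
        "end": starts + offset + pwm.width,
        "strand": np.where(take_fwd[hit], "+", "-"),
        "score": best[hit],
        "rel_score": rel[hit],
    })
    return df


def count_motifs_per_interval(hits: pd.DataFrame, intervals: pd.DataFrame) -> pd.Series:
    """Number of hits lying fully within each interval."""
    index = intervals["name"] if "name" in intervals.columns else intervals.index
    out = np.zeros(len(intervals), dtype=int)
    if len(hits):
        for chrom, sub in hits.groupby("chrom", sort=False):
            mask = (intervals["chrom"] == chrom).to_numpy()
            if not mask.any():
                continue
            hs = np.sort(sub["start"].to_numpy())
            he = np.sort(sub["end"].to_numpy())
            qs = intervals.loc[mask, "start"].to_numpy()
            qe = intervals.loc[mask, "end"].to_numpy()
            # fully-within: hit.start >= q.start and hit.end <= q.end.
            # count = #{end <= q.end} - #{paired start < q.start}; valid because
            # hits have fixed width so start order == end order.
            n_end_ok = np.searchsorted(he, qe, side="right")
            n_start_before = np.searchsorted(hs, qs, side="left")
            out[mask] = np.maximum(n_end_ok - n_start_before, 0)
    return pd.Series(out, index=index, name="n_motifs")


# ---------------------------------------------------------------- dyads

def call_dyads(fragments: pd.DataFrame, sigma: float = 20.0,
               min_spacing: int = 147, min_support: int = 5,
               half_wrap: int = 73) -> pd.DataFrame:
    """Model nucleosome dyads from large-fragment midpoints.

    Midpoints are histogrammed at 1 bp, smoothed with a Gaussian kernel of
    ``sigma`` bp, and local maxima are accepted greedily by descending
    density subject to a ``min_spacing`` exclusion zone.  ``support`` counts
    midpoints within +-``half_wrap`` of the dyad; dyads with support below
    ``min_support`` are dropped.  Returns chrom/pos/support, sorted.
    """
    if len(fragments) == 0:
        return pd.DataFrame(columns=["chrom", "pos", "support"])
    lengths = fragments["end"] - fragments["start"]
    if (lengths <= 100).any():
        raise ValueError("call_dyads expects nucleosomal fragments (length > 100)")
    records = []
    for chrom, sub in fragments.groupby("chrom", sort=True):
        mids = ((sub["start"] + sub["end"]) // 2).to_numpy()
        lo, hi = int(mids.min()), int(mids.max())
        pad = int(4 * sigma)
        origin = max(lo - pad, 0)
        hist = np.bincount(mids - origin, minlength=hi - origin + pad + 1).astype(float)
        dens = gaussian_filter1d(hist, sigma=sigma, mode="constant")
        peaks, _ = find_peaks(dens)
        if len(peaks) == 0:
            continue
        order = peaks[np.argsort(dens[peaks])[::-1]]
        accepted: list[int] = []
        for p in order:
            if all(abs(p - a) >= min_spacing for a in accepted):
                accepted.append(int(p))
        for p in sorted(accepted):
            pos = p + origin
            support = int(((mids >= pos - half_wrap) & (mids <= pos + half_wrap)).sum())
            if support >= min_support:
                records.append({"chrom": chrom, "pos": pos, "support": support})
    return pd.DataFrame(records, columns=["chrom", "pos", "support"])


# ---------------------------------------------------------------- displacement

def motif_dyad_distance(hits: pd.DataFrame, dyads: pd.DataFrame) -> pd.Series:
    """Per-motif distance (bp) from motif midpoint to the nearest dyad on the
    same chromosome; NaN (excluded, counted) where the chromosome has no dyad."""
    pts = pd.DataFrame({
        "chrom": hits["chrom"],
        "pos": (hits["start"] + hits["end"]) // 2,
    })
    dist = nearest_distance(pts, dyads)
    return pd.Series(dist, index=hits.index, name="dyad_distance")


def footprint_fraction(distances, half_wrap: int = 73) -> float:
    """Fraction of motifs within ``half_wrap`` bp of a dyad (inclusive),
    i.e. inside the nucleosome wrap.  NaN distances are excluded."""
    d = np.asarray(pd.Series(distances).dropna(), dtype=float)
    if len(d) == 0:
        raise ValueError("footprint_fraction needs at least one defined distance")
    return float((d <= half_wrap).mean())


def mean_distance_shift(distances_before: pd.Series, distances_after: pd.Series) -> float:
    """Mean change (bp) in motif-to-dyad distance, paired by motif id."""
    before = pd.Series(distances_before).dropna()
    after = pd.Series(distances_after).dropna()
    common = before.index.intersection(after.index)
    if len(common) == 0:
        raise ValueError("no motifs with defined distances in both conditions")
    return float((after.loc[common] - before.loc[common]).mean())


# ---------------------------------------------------------------- permutation

def permutation_mean_test(group_a, group_b, n_perm: int = 100_000,
                          tail: str = "greater", seed: int = 0,
                          exact: str | bool = "auto",
                          exact_limit: int = 100_000) -> float:
    """One-tailed permutation test on the difference in group means.

    The statistic is mean(A) - mean(B); the null pools both groups and
    redraws groups of the observed ("proportional") sizes.  Exact
    enumeration over all C(n, |A|) partitions activates automatically when
    that count is <= ``exact_limit`` (p = exceedance count / total);
    otherwise ``n_perm`` Monte-Carlo partitions give the add-one estimator
    p = (1 + #{perm >= obs}) / (1 + n_perm), which is never zero.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if tail not in ("greater", "less"):
        raise ValueError("tail must be 'greater' or 'less'")
    sign = 1.0 if tail == "greater" else -1.0
    obs = sign * (a.mean() - b.mean())
    pool = np.concatenate([a, b])
    n, na = len(pool), len(a)
    total = pool.sum()
    eps = 1e-9 * max(1.0, abs(obs))

    do_exact = exact is True or (exact == "auto" and comb(n, na) <= exact_limit)
    if do_exact:
        from itertools import combinations

        count = 0
        n_part = 0
        for idx in combinations(range(n), na):
            sa = pool[list(idx)].sum()
            stat = sign * (sa / na - (total - sa) / (n - na))
            count += stat >= obs - eps
            n_part += 1
        return count / n_part

    rng = np.random.default_rng(seed)
    count = 0
    chunk = max(1, min(n_perm, 2_000_000 // max(n, 1)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        keys = rng.random((m, n))
        idx = np.argpartition(keys, na - 1, axis=1)[:, :na]
        sa = pool[idx].sum(axis=1)
        stats_ = sign * (sa / na - (total - sa) / (n - na))
        count += int((stats_ >= obs - eps).sum())
        done += m
    return (1 + count) / (1 + n_perm)
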