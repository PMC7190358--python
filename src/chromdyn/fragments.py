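"""Fragment filtering, open/nucleosomal partitioning, peak counting,
CPM coverage and condition-profile scaling.

The counting unit is the sequenced fragment (a properly paired read pair),
not individual mates.  Fragments of mapped length <= 100 bp are treated as
arising from open (nucleosome-free) chromatin; longer fragments as
nucleosome-associated.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .intervals import count_overlaps, validate_intervals
from .simulate import CONDITION_NAMES


def filter_fragments(fragments: pd.DataFrame, min_mapq: int = 10) -> pd.DataFrame:
    """Keep properly paired, non-duplicate fragments with MAPQ >= ``min_mapq``.

    Order is preserved.  The duplicate flag is assumed to have been set
    upstream (flag-level contract); flagged fragments are removed, not marked.
    """
    keep = (fragments["proper_pair"].astype(bool)
            & ~fragments["duplicate"].astype(bool)
            & (fragments["mapq"] >= min_mapq))
    return fragments.loc[keep]


def partition_by_length(fragments: pd.DataFrame, open_max: int = 100):
    """Split fragments into (open, nucleosomal) by mapped length.

    length <= ``open_max`` -> open; length > ``open_max`` -> nucleosomal.
    The partition is exhaustive and disjoint.
    """
    length = fragments["end"] - fragments["start"]
    is_open = length <= open_max
    return fragments.loc[is_open], fragments.loc[~is_open]


def count_fragments_in_peaks(fragments: pd.DataFrame, peaks: pd.DataFrame) -> pd.Series:
    """Open-fragment count per peak (>= 1 bp overlap; a fragment spanning two
    peaks increments both, but each fragment counts at most once per peak).

    Fragments on chromosomes absent from the peak set are ignored with a
    warning.  Returns a Series indexed by peak name (or positional index).
    """
    validate_intervals(peaks, "peaks")
    index = peaks["name"] if "name" in peaks.columns else peaks.index
    unknown = ~fragments["chrom"].isin(peaks["chrom"].unique())
    if unknown.any():
        warnings.warn(f"{int(unknown.sum())} fragments on chromosomes without peaks were ignored")
    counts = count_overlaps(peaks, fragments.loc[~unknown])
    return pd.Series(counts, index=index, name="count")


def build_count_matrix(fragments: pd.DataFrame, peaks: pd.DataFrame,
                       sample_meta: pd.DataFrame):
    """Per-sample open-fragment counts over peaks -> CountMatrix.

    ``sample_meta`` must be indexed by sample id with genotype/time columns;
    every sample in the metadata gets a column (zero if it has no fragments).
    """
    from .diffacc import CountMatrix

    cols = {}
    by_sample = dict(tuple(fragments.groupby("sample", sort=False)))
    for sample in sample_meta.index:
        sub = by_sample.get(sample)
        if sub is None:
            cols[sample] = np.zeros(len(peaks), dtype=int)
        else:
            cols[sample] = count_fragments_in_peaks(sub, peaks).to_numpy()
    index = peaks["name"] if "name" in peaks.columns else peaks.index
    counts = pd.DataFrame(cols, index=index).rename_axis("region")
    return CountMatrix(counts=counts, sample_meta=sample_meta.copy())


def coverage_cpm(fragments: pd.DataFrame, chrom_sizes: dict[str, int],
                 bin_size: int = 1) -> dict[str, np.ndarray]:
    """Depth-normalised coverage: per bin, (fragments overlapping the bin)
    x 1e6 / total fragments.  Returns chrom -> per-bin array."""
    total = len(fragments)
    if total == 0:
        raise ValueError("coverage_cpm is undefined for zero fragments")
    scale = 1e6 / total
    tracks = {}
    for chrom, size in chrom_sizes.items():
        n_bins = int(np.ceil(size / bin_size))
        diff = np.zeros(n_bins + 1)
        sub = fragments[fragments["chrom"] == chrom]
        if len(sub):
            first = np.clip(sub["start"].to_numpy() // bin_size, 0, n_bins - 1)
            last = np.clip((sub["end"].to_numpy() - 1) // bin_size, 0, n_bins - 1)
            np.add.at(diff, first, 1.0)
            np.add.at(diff, last + 1, -1.0)
        tracks[chrom] = np.cumsum(diff[:-1]) * scale
    return tracks


def scale_condition_profiles(matrix) -> pd.DataFrame:
    """Scaled accessibility profile per region over the four genotype x time
    conditions: mean raw count per condition, divided by the sum of the four
    condition means, so each defined row sums to 1.

    Regions whose condition means are all zero get NaN rows (undefined;
    excluded from downstream displays).
    """
    meta = matrix.sample_meta
    means = {}
    for cname in CONDITION_NAMES:
        g, t = cname.split("_")
        samples = meta.index[(meta["genotype"] == g) & (meta["time"] == t)]
        if len(samples) == 0:
            raise ValueError(f"condition {cname} has no samples")
        means[cname] = matrix.counts[samples].mean(axis=1)
    prof = pd.DataFrame(means)
    total = prof.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = prof.div(total, axis=0)
    scaled[total == 0] = np.nan
    return scaled
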