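"""Synthetic single-embryo ATAC-seq data with planted ground truth.

The generator emulates the statistical structure of a 2 genotype x 2 timepoint
x n replicate chromatin-accessibility study:

* per-peak open-fragment counts drawn from a negative binomial with
  variance = mu + alpha * mu**2 (``alpha`` is the NB dispersion);
* a bimodal fragment-length mixture: sub-nucleosomal "open" fragments
  (<= 100 bp) starting uniformly within accessible peaks, and
  mono-nucleosomal fragments whose midpoints scatter normally around
  planted nucleosome dyads;
* consensus instances of a position weight matrix planted inside peaks,
  either under a dyad (nucleosome-occluded) or in linker DNA;
* binomial allele counts at a marker SNP for post-hoc embryo genotyping.

Each of the twelve region labels (dynamic classes 1-10, ambiguous,
nondynamic) prescribes the four contrast log2 fold-changes
(T_wt, T_mut, G_12, G_72) in units of ``planted_lfc``; per-condition expected
means are derived from them, so the planted class structure and the count
model are consistent by construction.

The four contrasts of a 2x2 design satisfy the cycle identity
``T_mut - T_wt = G_72 - G_12`` (both sides equal the interaction), so a
pattern with exactly one nonzero contrast cannot arise from condition means.
The "ambiguous" label therefore plants (-1, -0.4, -0.3, +0.3) x planted_lfc:
with the conventional |log2FC| > 1 call threshold and planted_lfc = 2 only
T_wt crosses it, which is the expected single-significant outcome.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio

GENOTYPES = ("wt", "mut")
TIMEPOINTS = ("t12", "t72")
CONDITIONS = [(g, t) for g in GENOTYPES for t in TIMEPOINTS]
CONDITION_NAMES = [f"{g}_{t}" for g, t in CONDITIONS]
CONTRAST_NAMES = ("T_wt", "T_mut", "G_12", "G_72")

CLASS_LABELS = [str(i) for i in range(1, 11)] + ["ambiguous", "nondynamic"]

# Per-label contrast pattern (T_wt, T_mut, G_12, G_72) in units of planted_lfc.
# Genotype contrasts are mutant-over-wild-type; "down" = higher in wild type.
CLASS_CONTRAST_PATTERN: dict[str, tuple[float, float, float, float]] = {
    "1": (-1, -1, 0, 0),      # uniform loss of accessibility
    "2": (-1, 0, 0, +1),      # early uniform, lost in wild type only
    "3": (0, -1, 0, -1),      # early uniform, lost in mutant only
    "4": (-1, 0, -1, 0),      # wt-biased early, lost late
    "5": (0, -1, +1, 0),      # mut-biased early, lost late
    "6": (0, 0, -1, -1),      # constitutively wt-biased
    "7": (0, 0, +1, +1),      # constitutively mut-biased
    "8": (+1, +1, 0, 0),      # uniform gain
    "9": (+1, 0, 0, -1),      # late wt-biased gain
    "10": (0, +1, 0, +1),     # late mut-biased gain
    "ambiguous": (-1, -0.4, -0.3, +0.3),
    "nondynamic": (0, 0, 0, 0),
}

# Per-label log2 offsets of the condition means (wt_t12, wt_t72, mut_t12,
# mut_t72), again in units of planted_lfc, anchored so the largest mean equals
# baseline_mean.  These reproduce CLASS_CONTRAST_PATTERN exactly:
# T_wt = wt_t72 - wt_t12, T_mut = mut_t72 - mut_t12,
# G_12 = mut_t12 - wt_t12, G_72 = mut_t72 - wt_t72.
CLASS_CONDITION_OFFSETS: dict[str, tuple[float, float, float, float]] = {
    "1": (0, -1, 0, -1),
    "2": (0, -1, 0, 0),
    "3": (0, 0, 0, -1),
    "4": (0, -1, -1, -1),
    "5": (-1, -1, 0, -1),
    "6": (0, 0, -1, -1),
    "7": (-1, -1, 0, 0),
    "8": (-1, 0, -1, 0),
    "9": (-1, 0, -1, -1),
    "10": (-1, -1, -1, 0),
    "ambiguous": (0, -1, -0.3, -0.7),
    "nondynamic": (0, 0, 0, 0),
}

# A short, strongly informative zinc-finger-like PFM used when no PWM is
# supplied; consensus GGGTGGTC.
DEFAULT_PFM = np.array([
    [2, 1, 0, 2, 1, 0, 1, 1],     # A
    [2, 1, 2, 3, 1, 1, 2, 92],    # C
    [94, 96, 95, 5, 96, 97, 3, 4],  # G
    [2, 2, 3, 90, 2, 2, 94, 3],   # T
], dtype=float)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class CapacityError(ValueError):
    """Requested peaks do not fit on the simulated chromosomes."""


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Defaults follow the study design the generator emulates: 2 genotypes x
    2 timepoints x 3 single-embryo replicates, a baseline of 200 expected
    open fragments per peak per sample, NB dispersion 0.05, planted effects
    of |log2FC| = 2, and a marker SNP read at depth 60 (the reported depth
    range is 47-104).  ``open_frac`` = 0.6 is a free parameter of the
    generator (the empirical library mixture is not published).
    """

    n_chroms: int = 2
    chrom_length: int = 200_000
    n_peaks_per_class: int | dict = 10
    peak_width: int = 500
    baseline_mean: float = 200.0
    dispersion: float = 0.05
    planted_lfc: float = 2.0
    n_replicates: int = 3
    open_frac: float = 0.6
    open_len_range: tuple = (20, 100)
    nuc_len_range: tuple = (150, 250)
    dyad_sd: float = 30.0
    motif_pwm: np.ndarray | None = None
    motif_frac: float = 1.0          # fraction of peaks carrying one planted motif
    occluded_frac: float = 0.5       # fraction of planted motifs placed under the dyad
    snp_depth: int = 60
    snp_error: float = 0.01
    snp_genotype: str = "het"
    contaminant_frac: float = 0.0    # opt-in duplicate/low-MAPQ/improper fragments
    seed: int = 0

    def __post_init__(self):
        if self.n_chroms < 1 or self.chrom_length < 1 or self.peak_width < 1:
            raise ConfigError("n_chroms, chrom_length and peak_width must be positive")
        if not 0 < self.open_frac < 1 and self.open_frac not in (0.0, 1.0):
            raise ConfigError("open_frac must lie in [0, 1]")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        if self.open_len_range[1] > 100:
            raise ConfigError("open_len_range must lie entirely <= 100 bp")
        if self.nuc_len_range[0] <= 100:
            raise ConfigError("nuc_len_range must lie entirely > 100 bp")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if not 0 <= self.snp_error < 0.5:
            raise ConfigError("snp_error must lie in [0, 0.5)")
        if self.snp_genotype not in ("hom_ref", "het", "hom_alt"):
            raise ConfigError(f"unknown snp_genotype {self.snp_genotype!r}")

    def peaks_per_class(self) -> dict[str, int]:
        if isinstance(self.n_peaks_per_class, dict):
            unknown = set(self.n_peaks_per_class) - set(CLASS_LABELS)
            if unknown:
                raise ConfigError(f"unknown class labels {sorted(unknown)}")
            return {lab: int(self.n_peaks_per_class.get(lab, 0)) for lab in CLASS_LABELS}
        return {lab: int(self.n_peaks_per_class) for lab in CLASS_LABELS}

    def pfm(self) -> np.ndarray:
        return DEFAULT_PFM if self.motif_pwm is None else np.asarray(self.motif_pwm, float)


@dataclass
class PlantedTruth:
    """Ground truth planted by :func:`build_truth`.

    peaks: per-peak interval, class label and the four per-condition expected
    means; contrast_lfcs: planted log2FC for T_wt/T_mut/G_12/G_72;
    motif_sites: planted PWM instances; dyads: planted nucleosome dyads
    (one per peak, at the peak centre); snp: the marker SNP.
    """

    peaks: pd.DataFrame
    contrast_lfcs: pd.DataFrame
    motif_sites: pd.DataFrame
    dyads: pd.DataFrame
    snp: dict
    config: SimulationConfig


def _rng(seed, *stream) -> np.random.Generator:
    """Independent child generator for a named stream of the root seed."""
    h = hashlib.sha256(("/".join(map(str, stream)) + f"#{seed}").encode()).digest()
    return np.random.default_rng(int.from_bytes(h[:8], "little"))


def build_truth(config: SimulationConfig) -> PlantedTruth:
    """Lay out non-overlapping peaks, assign class labels, derive per-condition
    expected means, and plant dyads, motif sites and the marker SNP."""
    per_class = config.peaks_per_class()
    n_peaks = sum(per_class.values())
    if n_peaks == 0:
        raise ConfigError("no peaks requested")
    spacing = 2 * config.peak_width
    margin = config.peak_width
    per_chrom_capacity = max(0, (config.chrom_length - 2 * margin) // spacing)
    if per_chrom_capacity * config.n_chroms < n_peaks:
        raise CapacityError(
            f"{n_peaks} peaks of width {config.peak_width} (spacing {spacing}) do not fit "
            f"on {config.n_chroms} x {config.chrom_length} bp; enlarge chrom_length")

    labels = np.repeat([lab for lab in CLASS_LABELS for _ in range(per_class[lab])], 1)
    rng = _rng(config.seed, "truth")
    labels = labels[rng.permutation(n_peaks)]

    recs = []
    for i in range(n_peaks):
        chrom_i, slot = divmod(i, per_chrom_capacity)
        start = margin + slot * spacing
        recs.append({
            "chrom": f"chr{chrom_i + 1}",
            "start": int(start),
            "end": int(start + config.peak_width),
            "name": f"peak_{i + 1:05d}",
            "label": labels[i],
        })
    peaks = pd.DataFrame(recs)

    L = config.planted_lfc
    offsets = np.array([CLASS_CONDITION_OFFSETS[lab] for lab in peaks["label"]])
    means = config.baseline_mean * 2.0 ** (offsets * L)
    for j, cname in enumerate(CONDITION_NAMES):
        peaks[f"mean_{cname}"] = means[:, j]

    patt = np.array([CLASS_CONTRAST_PATTERN[lab] for lab in peaks["label"]])
    contrast_lfcs = pd.DataFrame(patt * L, columns=list(CONTRAST_NAMES),
                                 index=peaks["name"]).rename_axis("region")

    dyads = pd.DataFrame({
        "chrom": peaks["chrom"],
        "pos": (peaks["start"] + peaks["end"]) // 2,
        "peak": peaks["name"],
    })

    # motif planting: one instance in a deterministic-by-seed subset of peaks,
    # either under the peak's dyad (occluded) or 110-180 bp into linker DNA
    pfm = config.pfm()
    width = pfm.shape[1]
    m_rng = _rng(config.seed, "motifs")
    carry = m_rng.random(n_peaks) < config.motif_frac
    msites = []
    for i in np.flatnonzero(carry):
        dyad = int(dyads["pos"].iloc[i])
        occluded = bool(m_rng.random() < config.occluded_frac)
        if occluded:
            mid = dyad + int(m_rng.integers(-50, 51))
        else:
            side = 1 if m_rng.random() < 0.5 else -1
            mid = dyad + side * int(m_rng.integers(110, 181))
        start = mid - width // 2
        strand = "+" if m_rng.random() < 0.5 else "-"
        msites.append({"chrom": peaks["chrom"].iloc[i], "start": int(start),
                       "end": int(start + width), "strand": strand,
                       "peak": peaks["name"].iloc[i], "occluded": occluded})
    motif_sites = pd.DataFrame(msites, columns=["chrom", "start", "end", "strand", "peak", "occluded"])

    snp = {"chrom": "chr1", "pos": int(config.chrom_length - config.peak_width // 2),
           "ref": "G", "alt": "A", "genotype": config.snp_genotype}

    return PlantedTruth(peaks=peaks, contrast_lfcs=contrast_lfcs,
                        motif_sites=motif_sites, dyads=dyads, snp=snp, config=config)


# ---------------------------------------------------------------- counts

def nb_draw(rng: np.random.Generator, mean, dispersion: float, size=None):
    """NB draws with variance = mean + dispersion * mean**2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 1e-12:
        return rng.poisson(mean, size=size)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


def sample_table(config: SimulationConfig) -> pd.DataFrame:
    rows = [{"sample": f"{g}_{t}_r{r + 1}", "genotype": g, "time": t, "replicate": r + 1}
            for g, t in CONDITIONS for r in range(config.n_replicates)]
    return pd.DataFrame(rows).set_index("sample")


def simulate_count_matrix(truth: PlantedTruth, config: SimulationConfig | None = None):
    """Peaks x samples open-fragment counts: NB(condition mean, dispersion).

    Returns a :class:`chromdyn.diffacc.CountMatrix`.
    """
    from .diffacc import CountMatrix

    config = config or truth.config
    if config.n_replicates < 2:
        raise ConfigError("simulate_count_matrix needs n_replicates >= 2")
    meta = sample_table(config)
    rng = _rng(config.seed, "counts")
    cols = {}
    for sample, row in meta.iterrows():
        mu = truth.peaks[f"mean_{row['genotype']}_{row['time']}"].to_numpy()
        cols[sample] = nb_draw(rng, mu, config.dispersion)
    counts = pd.DataFrame(cols, index=truth.peaks["name"]).rename_axis("region")
    return CountMatrix(counts=counts, sample_meta=meta)


# ---------------------------------------------------------------- fragments

def simulate_fragments(truth: PlantedTruth, sample: str, n_fragments: int,
                       config: SimulationConfig | None = None) -> pd.DataFrame:
    """Fragment records for one sample.

    A Binomial(n, open_frac) share of fragments are "open": length uniform in
    ``open_len_range``, start uniform within a peak chosen with probability
    proportional to that sample's planted condition mean.  The rest are
    nucleosomal: length uniform in ``nuc_len_range``, midpoint normal around a
    uniformly chosen planted dyad with sd ``dyad_sd``.  All fragments carry
    MAPQ 60, proper_pair, non-duplicate, unless ``contaminant_frac`` > 0.
    """
    config = config or truth.config
    if len(truth.peaks) == 0 or len(truth.dyads) == 0:
        raise ConfigError("truth must contain at least one peak and one dyad")
    if n_fragments == 0:
        return pd.DataFrame(columns=cio.FRAGMENT_COLUMNS)
    genotype, time = sample.split("_")[:2]
    rng = _rng(config.seed, "fragments", sample)

    n_open = int(rng.binomial(n_fragments, config.open_frac))
    n_nuc = n_fragments - n_open

    parts = []
    if n_open:
        w = truth.peaks[f"mean_{genotype}_{time}"].to_numpy(dtype=float)
        p = w / w.sum()
        idx = rng.choice(len(truth.peaks), size=n_open, p=p)
        lo, hi = config.open_len_range
        lengths = rng.integers(lo, hi + 1, size=n_open)
        pk_start = truth.peaks["start"].to_numpy()[idx]
        pk_end = truth.peaks["end"].to_numpy()[idx]
        span = np.maximum(pk_end - pk_start - lengths, 1)
        starts = pk_start + (rng.random(n_open) * span).astype(int)
        parts.append(pd.DataFrame({
            "chrom": truth.peaks["chrom"].to_numpy()[idx],
            "start": starts, "end": starts + lengths}))
    if n_nuc:
        didx = rng.integers(0, len(truth.dyads), size=n_nuc)
        lo, hi = config.nuc_len_range
        lengths = rng.integers(lo, hi + 1, size=n_nuc)
        mids = rng.normal(truth.dyads["pos"].to_numpy(dtype=float)[didx], config.dyad_sd)
        starts = np.maximum(np.round(mids - lengths / 2).astype(int), 0)
        parts.append(pd.DataFrame({
            "chrom": truth.dyads["chrom"].to_numpy()[didx],
            "start": starts, "end": starts + lengths}))

    frags = pd.concat(parts, ignore_index=True)
    frags["end"] = np.minimum(frags["end"], config.chrom_length)
    frags["mapq"] = 60
    frags["proper_pair"] = True
    frags["duplicate"] = False
    frags["sample"] = sample

    if config.contaminant_frac > 0:
        bad = rng.random(len(frags)) < config.contaminant_frac
        kind = rng.integers(0, 3, size=len(frags))
        frags.loc[bad & (kind == 0), "duplicate"] = True
        frags.loc[bad & (kind == 1), "mapq"] = rng.integers(0, 10)
        frags.loc[bad & (kind == 2), "proper_pair"] = False
    return frags[cio.FRAGMENT_COLUMNS]


def simulate_dyad_fragments(positions, n_per_dyad: int, sd: float,
                            length_range=(150, 250), chrom: str = "chr1",
                            seed: int = 0, sample: str = "s1") -> pd.DataFrame:
    """Nucleosomal fragments around explicit dyad positions (test/analysis helper)."""
    rng = np.random.default_rng(seed)
    pos = np.repeat(np.asarray(positions, dtype=float), n_per_dyad)
    lo, hi = length_range
    lengths = rng.integers(lo, hi + 1, size=len(pos))
    mids = rng.normal(pos, sd)
    starts = np.maximum(np.round(mids - lengths / 2).astype(int), 0)
    return pd.DataFrame({
        "chrom": chrom, "start": starts, "end": starts + lengths,
        "mapq": 60, "proper_pair": True, "duplicate": False, "sample": sample,
    })[cio.FRAGMENT_COLUMNS]


# ---------------------------------------------------------------- SNP pileup

@dataclass
class Pileup:
    chrom: str
    position: int
    ref_count: int
    alt_count: int

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count


def simulate_snp_pileup(genotype: str, depth: int, error: float = 0.01,
                        seed: int | np.random.Generator = 0,
                        chrom: str = "chr1", position: int = 0) -> Pileup:
    """Binomial allele counts at a marker SNP.

    Alt-read probability is ``error`` for hom_ref, 0.5 for het and
    ``1 - error`` for hom_alt.
    """
    if depth < 1:
        raise ConfigError("depth must be >= 1")
    if not 0 <= error < 0.5:
        raise ConfigError("error must lie in [0, 0.5)")
    probs = {"hom_ref": error, "het": 0.5, "hom_alt": 1.0 - error}
    if genotype not in probs:
        raise ConfigError(f"unknown genotype label {genotype!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    alt = int(rng.binomial(depth, probs[genotype]))
    return Pileup(chrom=chrom, position=position, ref_count=depth - alt, alt_count=alt)


# ---------------------------------------------------------------- genome & bundle

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def consensus(pfm: np.ndarray) -> str:
    return "".join("ACGT"[i] for i in np.argmax(pfm, axis=0))


def simulate_genome(truth: PlantedTruth, config: SimulationConfig | None = None) -> dict[str, str]:
    """Random genome with the PWM consensus planted at every motif site."""
    config = config or truth.config
    rng = _rng(config.seed, "genome")
    cons = consensus(config.pfm())
    seqs = {}
    for i in range(config.n_chroms):
        chrom = f"chr{i + 1}"
        arr = rng.integers(0, 4, size=config.chrom_length)
        seq = np.frombuffer(b"ACGT", dtype="S1")[arr]
        sites = truth.motif_sites[truth.motif_sites["chrom"] == chrom]
        for _, site in sites.iterrows():
            planted = cons if site["strand"] == "+" else revcomp(cons)
            seq[site["start"]:site["end"]] = np.frombuffer(planted.encode(), dtype="S1")
        seqs[chrom] = seq.tobytes().decode()
    return seqs


def write_fixture_bundle(truth: PlantedTruth, matrix, fragments: pd.DataFrame,
                         out_dir) -> dict[str, str]:
    """Write peaks.bed, fragments.tsv, counts.tsv, pwm.pfm, genome.fa and
    truth.json under *out_dir*; returns the file manifest (name -> path).

    Every file round-trips bit-exactly through the package readers.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        manifest = {}
        cio.write_bed(truth.peaks, out / "peaks.bed")
        manifest["peaks.bed"] = str(out / "peaks.bed")
        cio.write_fragments(fragments, out / "fragments.tsv")
        manifest["fragments.tsv"] = str(out / "fragments.tsv")
        cio.write_counts_tsv(matrix.counts, out / "counts.tsv")
        manifest["counts.tsv"] = str(out / "counts.tsv")
        cio.write_pfm(truth.config.pfm(), out / "pwm.pfm")
        manifest["pwm.pfm"] = str(out / "pwm.pfm")
        cio.write_fasta(simulate_genome(truth), out / "genome.fa")
        manifest["genome.fa"] = str(out / "genome.fa")
        cfg = asdict(truth.config)
        cfg["motif_pwm"] = None if truth.config.motif_pwm is None else np.asarray(truth.config.motif_pwm).tolist()
        cio.write_json({
            "peaks": truth.peaks.to_dict(orient="records"),
            "contrast_lfcs": truth.contrast_lfcs.reset_index().to_dict(orient="records"),
            "motif_sites": truth.motif_sites.to_dict(orient="records"),
            "dyads": truth.dyads.to_dict(orient="records"),
            "snp": truth.snp,
            "config": cfg,
        }, out / "truth.json")
        manifest["truth.json"] = str(out / "truth.json")
    except OSError as exc:
        raise OSError(f"failed writing fixture bundle under {out}: {exc}") from exc
    return manifest
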