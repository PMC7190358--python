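"""Pipeline orchestration: validated flat-key config, staged execution,
and a run manifest with content hashes for reproducibility checks.

Config files are INI-style ``key = value`` text with sections; every
stochastic stage receives a child seed derived deterministically from the
root seed, so two runs with identical config and seed produce bit-identical
outputs (the manifest records a SHA-256 per output file).
"""

from __future__ import annotations

import configparser
import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as cio
from .classify import CallThresholds, classify_all, sample_control_regions
from .diffacc import run_four_contrasts
from .fragments import (build_count_matrix, filter_fragments, partition_by_length,
                        scale_condition_profiles)
from .genotyping import GenotypeThresholds, genotype_pileup
from .nucmotif import (call_dyads, footprint_fraction, motif_dyad_distance,
                       read_pfm, scan_motifs)
from .simulate import (PlantedTruth, SimulationConfig, build_truth, sample_table,
                       simulate_count_matrix, simulate_fragments,
                       simulate_snp_pileup, write_fixture_bundle, _rng)


@dataclass
class RunConfig:
    """Validated parameters of a pipeline run."""

    out_dir: str = "chromdyn_run"
    seed: int = 0
    # stage toggles
    run_simulate: bool = True
    run_count: bool = True
    run_test: bool = True
    run_classify: bool = True
    run_nucmotif: bool = True
    run_annotate: bool = False
    # inputs (used when simulate is off)
    peaks_bed: str | None = None
    fragments_tsv: str | None = None
    counts_tsv: str | None = None
    genome_fa: str | None = None
    pwm_pfm: str | None = None
    # analysis parameters
    alpha: float = 0.01
    lfc_min: float = 1.0
    min_mapq: int = 10
    open_max: int = 100
    rel_min: float = 0.8
    sigma: float = 20.0
    min_spacing: int = 147
    half_wrap: int = 73
    n_perm: int = 100_000
    controls_n: int = 10_000
    genotype_wt_max: float = 0.15
    genotype_het_lo: float = 0.30
    genotype_het_hi: float = 0.70
    genotype_alt_min: float = 0.85
    genotype_min_depth: int = 20
    # simulation scale
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    fragments_per_sample: int = 20_000


_DOMAINS = {
    "alpha": (0.0, 1.0, False),
    "lfc_min": (0.0, np.inf, True),
    "rel_min": (0.0, 1.0, True),
    "sigma": (0.0, np.inf, False),
    "min_spacing": (1, np.inf, True),
    "half_wrap": (0, np.inf, True),
    "n_perm": (1, np.inf, True),
    "controls_n": (1, np.inf, True),
    "min_mapq": (0, np.inf, True),
    "open_max": (1, np.inf, True),
    "fragments_per_sample": (0, np.inf, True),
    "genotype_min_depth": (1, np.inf, True),
}

_BOOL_KEYS = {"run_simulate", "run_count", "run_test", "run_classify",
              "run_nucmotif", "run_annotate"}
_PATH_KEYS = {"out_dir", "peaks_bed", "fragments_tsv", "counts_tsv",
              "genome_fa", "pwm_pfm"}
_SIM_INT = {"n_chroms", "chrom_length", "n_peaks_per_class", "peak_width",
            "n_replicates", "snp_depth", "seed"}
_SIM_FLOAT = {"baseline_mean", "dispersion", "planted_lfc", "open_frac",
              "dyad_sd", "snp_error", "motif_frac", "occluded_frac",
              "contaminant_frac"}


def validate_config(text: str):
    """Parse flat key=value config text; returns (RunConfig | None, errors).

    All problems are collected and reported at once.  A missing seed is a
    warning-level entry (default 0 is applied, the run proceeds).
    """
    errors: list[str] = []
    warnings_: list[str] = []
    parser = configparser.ConfigParser()
    try:
        parser.read_string(text if text.lstrip().startswith("[") else "[run]\n" + text)
    except configparser.Error as exc:
        return None, [f"config parse error: {exc}"], []

    cfg = RunConfig()
    seen_seed = False
    for section in parser.sections():
        for key, raw in parser.items(section):
            if section == "simulate" and (key in _SIM_INT or key in _SIM_FLOAT):
                try:
                    setattr(cfg.sim, key, int(raw) if key in _SIM_INT else float(raw))
                except ValueError:
                    errors.append(f"{section}.{key}: cannot parse {raw!r}")
                continue
            if not hasattr(cfg, key):
                errors.append(f"unknown key {section}.{key}")
                continue
            if key == "seed":
                seen_seed = True
            try:
                if key in _BOOL_KEYS:
                    setattr(cfg, key, parser.getboolean(section, key))
                elif key in _PATH_KEYS:
                    setattr(cfg, key, raw)
                elif isinstance(getattr(cfg, key), int) and key not in _BOOL_KEYS:
                    setattr(cfg, key, int(raw))
                else:
                    setattr(cfg, key, float(raw))
            except ValueError:
                errors.append(f"{section}.{key}: cannot parse {raw!r}")
    for key, (lo, hi, inclusive) in _DOMAINS.items():
        v = getattr(cfg, key)
        ok = (lo <= v <= hi) if inclusive else (lo < v < hi)
        if not ok:
            errors.append(f"{key}={v} outside domain "
                          f"{'[' if inclusive else '('}{lo}, {hi}{']' if inclusive else ')'}")
    try:
        GenotypeThresholds(cfg.genotype_wt_max, cfg.genotype_het_lo,
                           cfg.genotype_het_hi, cfg.genotype_alt_min)
    except ValueError as exc:
        errors.append(str(exc))
    if not seen_seed:
        warnings_.append("seed not specified; defaulting to 0")
    if errors:
        return None, errors, warnings_
    cfg.sim.__post_init__()
    return cfg, [], warnings_


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the run manifest.

    Stage order: simulate -> count (filter/partition/count) -> test ->
    classify -> nucmotif -> annotate.  Every output file is recorded with a
    SHA-256 content hash; rerunning with the same config and seed reproduces
    identical hashes.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"chromdyn {__version__}"]
    params = {k: v for k, v in asdict(config).items() if k != "sim"}
    params["sim"] = {k: (v if not isinstance(v, np.ndarray) else v.tolist())
                     for k, v in asdict(config.sim).items()}
    outputs: dict[str, str] = {}
    stage = "setup"
    truth: PlantedTruth | None = None
    try:
        if config.run_simulate:
            stage = "simulate"
            config.sim.seed = int(_rng(config.seed, "simulate").integers(2 ** 31))
            truth = build_truth(config.sim)
            matrix = simulate_count_matrix(truth)
            frags = pd.concat(
                [simulate_fragments(truth, s, config.fragments_per_sample)
                 for s in sample_table(config.sim).index], ignore_index=True)
            manifest = write_fixture_bundle(truth, matrix, frags, out / "fixture")
            for name, path in manifest.items():
                outputs[f"fixture/{name}"] = path
            log.append(f"simulate: {len(truth.peaks)} peaks, {len(frags)} fragments")
            peaks = truth.peaks
            genome_path = manifest["genome.fa"]
            pwm_path = manifest["pwm.pfm"]
            pileup = simulate_snp_pileup(config.sim.snp_genotype, config.sim.snp_depth,
                                         config.sim.snp_error,
                                         _rng(config.seed, "snp"))
            call = genotype_pileup(pileup,
                                   GenotypeThresholds(config.genotype_wt_max,
                                                      config.genotype_het_lo,
                                                      config.genotype_het_hi,
                                                      config.genotype_alt_min),
                                   config.genotype_min_depth)
            log.append(f"genotype: {call.call} (alt fraction {call.alt_fraction:.3f}, "
                       f"depth {call.depth})")
        else:
            stage = "load"
            if not config.peaks_bed or not config.fragments_tsv:
                raise ValueError("simulate disabled: peaks_bed and fragments_tsv required")
            peaks = cio.read_bed(config.peaks_bed)
            frags = cio.read_fragments(config.fragments_tsv)
            genome_path, pwm_path = config.genome_fa, config.pwm_pfm

        matrix = None
        if config.run_count:
            stage = "count"
            kept = filter_fragments(frags, config.min_mapq)
            open_f, nuc_f = partition_by_length(kept, config.open_max)
            meta = sample_table(config.sim) if config.run_simulate else (
                pd.DataFrame({"sample": sorted(frags["sample"].unique())})
                .assign(genotype=lambda d: d["sample"].str.split("_").str[0],
                        time=lambda d: d["sample"].str.split("_").str[1])
                .set_index("sample"))
            matrix = build_count_matrix(open_f, peaks, meta)
            cio.write_counts_tsv(matrix.counts, out / "open_counts.tsv")
            outputs["open_counts.tsv"] = str(out / "open_counts.tsv")
            log.append(f"count: {len(kept)}/{len(frags)} fragments kept, "
                       f"{len(open_f)} open / {len(nuc_f)} nucleosomal")

        contrasts = None
        if config.run_test:
            stage = "test"
            if matrix is None:
                raise ValueError("test stage needs the count stage (or counts_tsv input)")
            contrasts = run_four_contrasts(matrix)
            for cname, sub in contrasts.groupby("contrast"):
                path = out / f"contrast_{cname}.tsv"
                sub.drop(columns=["contrast"]).to_csv(path, sep="\t", index=False,
                                                      float_format="%.6g")
                outputs[path.name] = str(path)
            log.append(f"test: {len(contrasts)} contrast results")

        labels = None
        if config.run_classify:
            stage = "classify"
            if contrasts is None:
                raise ValueError("classify stage needs the test stage")
            labels, counts = classify_all(contrasts,
                                          CallThresholds(config.alpha, config.lfc_min))
            labels.to_csv(out / "dynamics_labels.tsv", sep="\t")
            outputs["dynamics_labels.tsv"] = str(out / "dynamics_labels.tsv")
            counts.rename("n_regions").to_csv(out / "class_counts.tsv", sep="\t")
            outputs["class_counts.tsv"] = str(out / "class_counts.tsv")
            scaled = scale_condition_profiles(matrix)
            scaled.to_csv(out / "scaled_profiles.tsv", sep="\t", float_format="%.6g")
            outputs["scaled_profiles.tsv"] = str(out / "scaled_profiles.tsv")
            controls = sample_control_regions(peaks, labels, config.controls_n,
                                              seed=int(_rng(config.seed, "controls").integers(2 ** 31)))
            cio.write_bed(controls, out / "control_regions.bed")
            outputs["control_regions.bed"] = str(out / "control_regions.bed")
            log.append("classify: " + ", ".join(f"{k}={v}" for k, v in counts.items()))

        if config.run_nucmotif:
            stage = "nucmotif"
            kept = filter_fragments(frags, config.min_mapq)
            _, nuc_f = partition_by_length(kept, config.open_max)
            dyads = call_dyads(nuc_f, sigma=config.sigma,
                               min_spacing=config.min_spacing,
                               half_wrap=config.half_wrap)
            dyads.to_csv(out / "dyads.tsv", sep="\t", index=False)
            outputs["dyads.tsv"] = str(out / "dyads.tsv")
            if genome_path and pwm_path:
                pwm = read_pfm(pwm_path)
                genome = cio.read_fasta(genome_path)
                hits = pd.concat([scan_motifs(seq, pwm, config.rel_min, chrom=chrom)
                                  for chrom, seq in genome.items()], ignore_index=True)
                hits["name"] = [f"motif_{i + 1:05d}" for i in range(len(hits))]
                cio.write_bed(hits, out / "motif_hits.bed")
                outputs["motif_hits.bed"] = str(out / "motif_hits.bed")
                dist = motif_dyad_distance(hits, dyads)
                dist_df = hits[["chrom", "start", "end"]].assign(dyad_distance=dist)
                dist_df.to_csv(out / "motif_dyad_distance.tsv", sep="\t", index=False,
                               float_format="%.6g")
                outputs["motif_dyad_distance.tsv"] = str(out / "motif_dyad_distance.tsv")
                if dist.notna().any():
                    frac = footprint_fraction(dist, config.half_wrap)
                    log.append(f"nucmotif: {len(dyads)} dyads, {len(hits)} motif hits, "
                               f"footprint fraction {frac:.3f}")
            else:
                log.append(f"nucmotif: {len(dyads)} dyads (no genome/PWM supplied)")

        stage = "manifest"
        manifest = {
            "version": __version__,
            "parameters": params,
            "log": log,
            "outputs": {name: _sha256(Path(path)) for name, path in sorted(outputs.items())},
        }
        cio.write_json(manifest, out / "manifest.json")
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
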