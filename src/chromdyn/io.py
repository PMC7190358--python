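"""Readers and writers for the plain-text formats the package exchanges.

Formats: BED (peaks, motif hits, control regions), a fragment TSV
(chrom, start, end, mapq, proper_pair, duplicate, sample), count-matrix TSV
(first column region id, header = sample ids), JASPAR-style PFM text,
FASTA genomes, bedGraph coverage, BED12 gene models and small TSV tables.
All interval coordinates are 0-based half-open.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import validate_intervals

FRAGMENT_COLUMNS = ["chrom", "start", "end", "mapq", "proper_pair", "duplicate", "sample"]


class ParseError(ValueError):
    """Raised when an input file does not conform to its declared format."""


# ---------------------------------------------------------------- BED

def read_bed(path) -> pd.DataFrame:
    """Read a BED3+ file; returns chrom/start/end (+ name if a 4th column exists)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            rec = {"chrom": parts[0], "start": start, "end": end}
            if len(parts) >= 4:
                rec["name"] = parts[3]
            rows.append(rec)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"] if rows and "name" in rows[0] else ["chrom", "start", "end"])
    validate_intervals(df, str(path))
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = ["chrom", "start", "end"] + [c for c in ("name",) if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------- fragments

def read_fragments(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    missing = [c for c in FRAGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing fragment columns {missing}")
    df["proper_pair"] = df["proper_pair"].astype(bool)
    df["duplicate"] = df["duplicate"].astype(bool)
    return df[FRAGMENT_COLUMNS]


def write_fragments(df: pd.DataFrame, path) -> None:
    out = df[FRAGMENT_COLUMNS].copy()
    out["proper_pair"] = out["proper_pair"].astype(int)
    out["duplicate"] = out["duplicate"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_bedpe_fragments(path, sample: str, mapq: int = 60) -> pd.DataFrame:
    """Import shim: BEDPE rows (chrom1,s1,e1,chrom2,s2,e2,...) to fragment records.

    The fragment spans min(start) .. max(end) of the two mates; rows whose mates
    map to different chromosomes are rejected.
    """
    raw = pd.read_csv(path, sep="\t", header=None)
    if raw.shape[1] < 6:
        raise ParseError(f"{path}: BEDPE needs >=6 columns")
    if (raw[0] != raw[3]).any():
        raise ParseError(f"{path}: inter-chromosomal mate pairs are not fragments")
    df = pd.DataFrame({
        "chrom": raw[0].astype(str),
        "start": np.minimum(raw[1], raw[4]).astype(int),
        "end": np.maximum(raw[2], raw[5]).astype(int),
        "mapq": raw[7].astype(int) if raw.shape[1] > 7 else mapq,
        "proper_pair": True,
        "duplicate": False,
        "sample": sample,
    })
    return df


# ---------------------------------------------------------------- count matrix

def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ParseError(f"{path}: negative counts")
    return df


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="region")


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("sample", "genotype", "time"):
        if col not in df.columns:
            raise ParseError(f"{path}: sample sheet missing column '{col}'")
    return df.set_index("sample")


# ---------------------------------------------------------------- PFM

def read_pfm_text(text: str) -> np.ndarray:
    """Parse JASPAR-style 4-row (A,C,G,T) count matrix text into a (4, w) array."""
    rows = []
    for line in text.strip().splitlines():
        line = line.strip()
        if not line or line.startswith(">"):
            continue
        # tolerate "A [ 1 2 3 ]" JASPAR decoration
        fields = [f for f in line.replace("[", " ").replace("]", " ").split()
                  if f not in ("A", "C", "G", "T")]
        try:
            rows.append([float(x) for x in fields])
        except ValueError as exc:
            raise ParseError(f"unparseable PFM row: {line!r}") from exc
    if len(rows) != 4:
        raise ParseError(f"PFM must have 4 rows (A,C,G,T), got {len(rows)}")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ParseError("ragged PFM rows")
    arr = np.asarray(rows, dtype=float)
    if (arr < 0).any():
        raise ParseError("negative PFM counts")
    return arr


def read_pfm_file(path) -> np.ndarray:
    return read_pfm_text(Path(path).read_text())


def write_pfm(counts: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        for base, row in zip("ACGT", counts):
            fh.write(base + "  " + "  ".join(f"{v:.6g}" for v in row) + "\n")


# ---------------------------------------------------------------- FASTA

def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from pyfaidx import Fasta

    fa = Fasta(str(path), as_raw=True, rebuild=True)
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


# ---------------------------------------------------------------- bedGraph

def write_bedgraph(tracks: dict[str, np.ndarray], bin_size: int, path) -> None:
    """Write per-bin values as bedGraph, merging runs of equal value."""
    with open(path, "w") as fh:
        for chrom in tracks:
            vals = np.asarray(tracks[chrom])
            if len(vals) == 0:
                continue
            change = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(vals)]])
            for s, e in zip(starts, ends):
                if vals[s] != 0:
                    fh.write(f"{chrom}\t{s * bin_size}\t{e * bin_size}\t{vals[s]:.6g}\n")


# ---------------------------------------------------------------- BED12 / genes

def read_bed12(path) -> pd.DataFrame:
    """BED12 gene models: returns chrom/start/end/name/strand/exons (list of (s,e))."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            p = line.split("\t")
            if len(p) < 12:
                raise ParseError(f"{path}:{lineno}: BED12 needs 12 fields")
            start, end = int(p[1]), int(p[2])
            sizes = [int(x) for x in p[10].rstrip(",").split(",")]
            offs = [int(x) for x in p[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + s) for o, s in zip(offs, sizes)]
            rows.append({"chrom": p[0], "start": start, "end": end, "name": p[3],
                         "strand": p[5], "exons": exons})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- term map / misc

def read_term_map(path) -> dict[str, set]:
    """TSV (id, comma-separated terms) -> id -> set of terms."""
    out: dict[str, set] = {}
    df = pd.read_csv(path, sep="\t", dtype=str)
    id_col, term_col = df.columns[:2]
    for _, row in df.iterrows():
        terms = {t.strip() for t in str(row[term_col]).split(",") if t.strip()}
        out[str(row[id_col])] = terms
    return out


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
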