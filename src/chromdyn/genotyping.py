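"""Post-hoc zygotic genotyping of single embryos from marker-SNP allele
fractions.

An embryo from a heterozygote x heterozygote cross carries the causative
allele in ~0%, ~50% or ~100% of base calls at the marker position.  Calls are
made from the alt-allele fraction with guard bands; indeterminate fractions
or insufficient depth yield ``nocall`` rather than a forced call.  The
default bands (<= 0.15 hom_ref, 0.30-0.70 het, >= 0.85 hom_alt, min depth 20)
keep binomial misclassification below 1% at sequencing depth 47, the lower
end of the depth range such markers are typically recovered at.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .simulate import Pileup

GENOTYPE_LABELS = ("hom_ref", "het", "hom_alt", "nocall")


@dataclass(frozen=True)
class GenotypeThresholds:
    wt_max: float = 0.15
    het_lo: float = 0.30
    het_hi: float = 0.70
    alt_min: float = 0.85

    def __post_init__(self):
        if not 0 <= self.wt_max < self.het_lo <= self.het_hi < self.alt_min <= 1:
            raise ValueError(
                f"genotype thresholds must satisfy 0 <= wt_max < het_lo <= het_hi < alt_min <= 1, "
                f"got {self}")


@dataclass
class GenotypeCall:
    call: str
    alt_fraction: float
    depth: int


def allele_fraction(pileup: Pileup) -> tuple[float, int]:
    """Alt-allele fraction and depth; depth 0 is an error."""
    depth = pileup.ref_count + pileup.alt_count
    if depth < 1:
        raise ValueError("allele_fraction undefined at depth 0")
    return pileup.alt_count / depth, depth


def call_genotype(fraction: float, depth: int,
                  thresholds: GenotypeThresholds = GenotypeThresholds(),
                  min_depth: int = 20) -> GenotypeCall:
    """Threshold the alt fraction into hom_ref / het / hom_alt / nocall."""
    if not 0 <= fraction <= 1:
        raise ValueError(f"fraction {fraction} outside [0, 1]")
    t = thresholds
    if depth < min_depth:
        call = "nocall"
    elif fraction <= t.wt_max:
        call = "hom_ref"
    elif t.het_lo <= fraction <= t.het_hi:
        call = "het"
    elif fraction >= t.alt_min:
        call = "hom_alt"
    else:
        call = "nocall"
    return GenotypeCall(call=call, alt_fraction=fraction, depth=depth)


def genotype_pileup(pileup: Pileup, thresholds: GenotypeThresholds = GenotypeThresholds(),
                    min_depth: int = 20) -> GenotypeCall:
    frac, depth = allele_fraction(pileup)
    return call_genotype(frac, depth, thresholds, min_depth)


def genotype_table(df: pd.DataFrame, thresholds: GenotypeThresholds = GenotypeThresholds(),
                   min_depth: int = 20) -> pd.DataFrame:
    """Call genotypes for a TSV-style table with ref_count/alt_count columns."""
    out = df.copy()
    calls = []
    for _, row in df.iterrows():
        p = Pileup(chrom=row.get("chrom", "."), position=int(row.get("pos", 0)),
                   ref_count=int(row["ref_count"]), alt_count=int(row["alt_count"]))
        calls.append(genotype_pileup(p, thresholds, min_depth))
    out["alt_fraction"] = [c.alt_fraction for c in calls]
    out["depth"] = [c.depth for c in calls]
    out["call"] = [c.call for c in calls]
    return out
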