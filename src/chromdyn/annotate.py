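"""Peak-set overlap bookkeeping, CRM accessibility scoring, genomic feature
assignment and controlled-vocabulary term enrichment.

CRMs (cis-regulatory modules / enhancers from a curated catalogue) inherit
the accessibility behaviour of their best-overlapping ATAC peak; feature
classes are assigned by peak midpoint with precedence
promoter > exon > intron > intergenic, the promoter being the strand-aware
window [TSS-500, TSS+150).  Term enrichment is a one-sided (greater)
hypergeometric test per term, BH-adjusted across tested terms.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .diffacc import bh_adjust
from .intervals import validate_intervals

PROMOTER_UP = 500
PROMOTER_DOWN = 150


def overlap_sets(set_a: pd.DataFrame, set_b: pd.DataFrame, min_bp: int = 1):
    """Per-A flags for overlapping any B interval by >= ``min_bp`` bp, plus
    the flagged fraction of A.  Empty A is an error; empty B gives 0."""
    if len(set_a) == 0:
        raise ValueError("overlap_sets: set A is empty")
    validate_intervals(set_a, "set A")
    flags = np.zeros(len(set_a), dtype=bool)
    if len(set_b):
        validate_intervals(set_b, "set B")
        b = set_b[(set_b["end"] - set_b["start"]) >= min_bp]
        a_len_ok = (set_a["end"] - set_a["start"]).to_numpy() >= min_bp
        for chrom, sub in b.groupby("chrom", sort=False):
            mask = ((set_a["chrom"] == chrom).to_numpy()) & a_len_ok
            if not mask.any():
                continue
            starts = np.sort(sub["start"].to_numpy())
            ends = np.sort(sub["end"].to_numpy())
            qs = set_a.loc[set_a.index[mask], "start"].to_numpy()
            qe = set_a.loc[set_a.index[mask], "end"].to_numpy()
            # overlap >= min_bp <=> b.start <= a.end - min_bp and b.end >= a.start + min_bp;
            # intervals shorter than min_bp are excluded above, so the non-
            # qualifying set {b.end < a.start + min_bp} is nested in the first.
            n_candidates = np.searchsorted(starts, qe - min_bp, side="right")
            n_too_left = np.searchsorted(ends, qs + min_bp, side="left")
            flags[mask] = (n_candidates - n_too_left) > 0
    return flags, float(flags.mean())


def _max_overlap_peak(crm_row, peaks: pd.DataFrame):
    """Best-overlapping peak index: maximal overlap bp, ties to the larger
    peak, then the leftmost."""
    same = peaks[peaks["chrom"] == crm_row["chrom"]]
    if len(same) == 0:
        return None
    ov = (np.minimum(same["end"], crm_row["end"])
          - np.maximum(same["start"], crm_row["start"]))
    cand = same[ov > 0]
    if len(cand) == 0:
        return None
    ov = ov.loc[cand.index]
    width = cand["end"] - cand["start"]
    order = pd.DataFrame({"ov": ov, "width": width, "start": cand["start"]})
    order = order.sort_values(["ov", "width", "start"], ascending=[False, False, True])
    return order.index[0]


def score_crm_accessibility(crms: pd.DataFrame, peaks: pd.DataFrame,
                            labels: pd.DataFrame, contrast_table: pd.DataFrame,
                            scaled_profiles: pd.DataFrame) -> pd.DataFrame:
    """Inherit each CRM's dynamics label and scaled accessibility from its
    best-overlapping peak.

    A CRM undergoes a "significant temporal change" when the inherited
    peak's wild-type time contrast (T_wt) is not ns.  CRMs overlapping no
    peak get null records (not accessible).
    """
    validate_intervals(crms, "CRMs")
    t_wt = labels["T_wt"] if "T_wt" in labels.columns else None
    if t_wt is None:
        piv = contrast_table.pivot(index="region", columns="contrast", values="log2fc")
        raise ValueError("labels table must carry per-contrast outcomes" if piv is None else
                         "labels table must carry per-contrast outcomes (run classify_all first)")
    key = peaks["name"] if "name" in peaks.columns else peaks.index.to_series()
    records = []
    for idx, crm in crms.iterrows():
        best = _max_overlap_peak(crm, peaks)
        rec = {"crm": crm.get("name", idx), "chrom": crm["chrom"],
               "start": crm["start"], "end": crm["end"]}
        if best is None:
            rec.update({"peak": None, "label": None, "significant_temporal_change": False})
        else:
            peak_name = key.loc[best]
            rec["peak"] = peak_name
            rec["label"] = labels["label"].get(peak_name)
            rec["significant_temporal_change"] = bool(t_wt.get(peak_name, "ns") != "ns")
            if peak_name in scaled_profiles.index:
                for cond in scaled_profiles.columns:
                    rec[f"scaled_{cond}"] = scaled_profiles.at[peak_name, cond]
        records.append(rec)
    return pd.DataFrame(records)


def assign_feature_class(peaks: pd.DataFrame, genes: pd.DataFrame) -> pd.Series:
    """Per-peak feature label by midpoint, precedence
    promoter > exon > intron > intergenic.

    Genes need chrom/start/end/strand/exons; the promoter is
    [TSS-500, TSS+150) on the gene's strand.  Missing strand is treated as
    '+' with a warning.
    """
    validate_intervals(peaks, "peaks")
    index = peaks["name"] if "name" in peaks.columns else peaks.index
    mids = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
    labels = np.full(len(peaks), "intergenic", dtype=object)
    gene_rows = list(genes.iterrows())
    warned = False
    for gi, (_, gene) in enumerate(gene_rows):
        strand = gene.get("strand", "+")
        if strand not in ("+", "-"):
            if not warned:
                warnings.warn("gene without strand treated as '+'")
                warned = True
            strand = "+"
        on_chrom = (peaks["chrom"] == gene["chrom"]).to_numpy()
        if strand == "+":
            prom_lo, prom_hi = gene["start"] - PROMOTER_UP, gene["start"] + PROMOTER_DOWN
        else:
            prom_lo, prom_hi = gene["end"] - PROMOTER_DOWN, gene["end"] + PROMOTER_UP
        in_prom = on_chrom & (mids >= prom_lo) & (mids < prom_hi)
        labels[in_prom] = "promoter"
        in_exon = np.zeros(len(peaks), dtype=bool)
        for es, ee in gene["exons"]:
            in_exon |= on_chrom & (mids >= es) & (mids < ee)
        labels[in_exon & (labels != "promoter")] = "exon"
        in_gene = on_chrom & (mids >= gene["start"]) & (mids < gene["end"])
        intronic = in_gene & ~in_exon & ~np.isin(labels, ["promoter", "exon"])
        labels[intronic] = "intron"
    return pd.Series(labels, index=index, name="feature_class")


def term_enrichment(selected, universe, term_map: dict, min_count: int = 3) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of annotation terms in a selected
    region set against a universe.

    Per term with >= ``min_count`` occurrences in the universe:
    p = P(X >= k) with X ~ Hypergeom(N=|universe|, K=term carriers,
    n=|selected|); odds ratios from the 2x2 table; BH across tested terms.
    """
    selected = list(dict.fromkeys(selected))
    universe = list(dict.fromkeys(universe))
    sel_set = set(selected)
    uni_set = set(universe)
    if not sel_set <= uni_set:
        raise ValueError("selected ids must be a subset of the universe")
    term_counts: dict[str, int] = {}
    for uid in universe:
        for term in term_map.get(uid, ()):
            term_counts[term] = term_counts.get(term, 0) + 1
    N, n = len(universe), len(selected)
    rows = []
    for term, K in sorted(term_counts.items()):
        if K < min_count:
            continue
        k = sum(1 for uid in selected if term in term_map.get(uid, ()))
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        a, b_, c, d = k, n - k, K - k, (N - n) - (K - k)
        with np.errstate(divide="ignore", invalid="ignore"):
            oddsratio = (a * d) / (b_ * c) if b_ * c > 0 else np.inf if a * d > 0 else np.nan
        rows.append({"term": term, "selected_with": k, "universe_with": K,
                     "odds_ratio": oddsratio, "pvalue": p})
    out = pd.DataFrame(rows, columns=["term", "selected_with", "universe_with",
                                      "odds_ratio", "pvalue"])
    out["padj"] = bh_adjust(out["pvalue"].to_numpy()) if len(out) else []
    return out
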