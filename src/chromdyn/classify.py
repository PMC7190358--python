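"""Ten-class chromatin dynamics classification from paired contrast tests.

Each region's four contrast results (T_wt, T_mut, G_12, G_72) are reduced to
up/down/ns outcomes at padj < alpha (strict) and |log2FC| > lfc_min (strict),
then matched against an ordered truth table of class predicates.  Classes
1-10 all require at least two significant tests ("paired" evidence); regions
significant in exactly one test, or matching no predicate, are ambiguous;
all-ns regions are nondynamic.  Genotype contrasts are mutant-over-wild-type,
so "down" means accessibility is higher in wild type.

Patterning-dependent predicates are more specific than the uniform ones and
are evaluated first; the first matching predicate wins, which makes the
mapping total and deterministic on the 3^4 = 81 outcome patterns.  The table
lives in one module-level constant so the predicate-to-class mapping can be
revised without touching the engine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .diffacc import CountMatrix
from .simulate import CONTRAST_NAMES

OUTCOMES = ("up", "down", "ns")

#: ordered (label, predicate) pairs; a predicate maps contrast -> required outcome
CLASS_PREDICATES: list[tuple[str, dict]] = [
    ("6", {"G_12": "down", "G_72": "down"}),   # constitutively wt-biased
    ("7", {"G_12": "up", "G_72": "up"}),       # constitutively mut-biased
    ("4", {"G_12": "down", "T_wt": "down"}),   # wt-biased early, lost late
    ("5", {"G_12": "up", "T_mut": "down"}),    # mut-biased early, lost late
    ("2", {"G_12": "ns", "T_wt": "down", "G_72": "up"}),    # lost in wt only
    ("3", {"G_12": "ns", "T_mut": "down", "G_72": "down"}), # lost in mutant only
    ("9", {"T_wt": "up", "G_72": "down"}),     # late wt-biased gain
    ("10", {"T_mut": "up", "G_72": "up"}),     # late mut-biased gain
    ("1", {"T_wt": "down", "T_mut": "down", "G_12": "ns", "G_72": "ns"}),  # uniform loss
    ("8", {"T_wt": "up", "T_mut": "up", "G_12": "ns", "G_72": "ns"}),      # uniform gain
]


@dataclass(frozen=True)
class CallThresholds:
    alpha: float = 0.01
    lfc_min: float = 1.0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be >= 0")


def call_outcome(log2fc: float, padj: float,
                 thresholds: CallThresholds = CallThresholds()) -> str:
    """up / down / ns from one contrast's log2FC and adjusted p.

    Significance is strict on both sides: padj exactly equal to alpha, or
    |log2FC| exactly equal to lfc_min, is ns.  Untestable results (NaN padj)
    are ns.
    """
    if padj is None or np.isnan(padj) or not padj < thresholds.alpha:
        return "ns"
    if log2fc > thresholds.lfc_min:
        return "up"
    if log2fc < -thresholds.lfc_min:
        return "down"
    return "ns"


def classify_region(outcomes: dict) -> str:
    """Map the four contrast outcomes to a class label (first matching
    predicate wins); all-ns -> nondynamic, otherwise unmatched -> ambiguous."""
    for name in CONTRAST_NAMES:
        if outcomes.get(name) not in OUTCOMES:
            raise ValueError(f"missing or invalid outcome for contrast {name}")
    for label, pred in CLASS_PREDICATES:
        if all(outcomes[k] == v for k, v in pred.items()):
            return label
    n_sig = sum(outcomes[k] != "ns" for k in CONTRAST_NAMES)
    return "nondynamic" if n_sig == 0 else "ambiguous"


def classify_all(contrast_table: pd.DataFrame,
                 thresholds: CallThresholds = CallThresholds()):
    """Label every region from a long contrast table (region, contrast,
    log2fc, padj).  Regions missing any contrast are ambiguous (flagged).

    Returns (per-region table with outcomes + label, class-count Series).
    """
    lfc = contrast_table.pivot(index="region", columns="contrast", values="log2fc")
    padj = contrast_table.pivot(index="region", columns="contrast", values="padj")
    rows = []
    for region in lfc.index:
        rec = {"region": region, "flag": ""}
        missing = [c for c in CONTRAST_NAMES if c not in lfc.columns or np.isnan(lfc.at[region, c])]
        if missing:
            for c in CONTRAST_NAMES:
                rec[c] = "ns" if c in missing else call_outcome(lfc.at[region, c], padj.at[region, c], thresholds)
            rec["label"] = "ambiguous"
            rec["flag"] = "missing_contrast"
        else:
            for c in CONTRAST_NAMES:
                rec[c] = call_outcome(lfc.at[region, c], padj.at[region, c], thresholds)
            rec["label"] = classify_region({c: rec[c] for c in CONTRAST_NAMES})
        rows.append(rec)
    labels = pd.DataFrame(rows).set_index("region")
    counts = labels["label"].value_counts()
    return labels, counts


# ---------------------------------------------------------------- PCA

def pca_dynamic_regions(matrix: CountMatrix, labels: pd.DataFrame | pd.Series,
                        n_components: int | None = None):
    """PCA of samples over the dynamic (non-nondynamic) regions.

    The transform is log2(normalised count + 1); samples are the
    observations, centred over regions.  Returns (variance fraction array,
    sample-scores DataFrame).
    """
    lab = labels["label"] if isinstance(labels, pd.DataFrame) else labels
    dynamic = lab.index[lab != "nondynamic"]
    dynamic = [r for r in matrix.region_ids if r in set(dynamic)]
    if len(dynamic) < 2 or len(matrix.sample_ids) < 2:
        raise ValueError("PCA needs >= 2 dynamic regions and >= 2 samples")
    X = np.log2(matrix.normalized().loc[dynamic].to_numpy().T + 1.0)
    if np.allclose(X, X.mean(axis=0), atol=1e-12):
        raise ValueError("degenerate (rank-0) matrix: all samples identical")
    n_comp = n_components or min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X - X.mean(axis=0))
    score_df = pd.DataFrame(scores, index=matrix.sample_ids,
                            columns=[f"PC{i + 1}" for i in range(scores.shape[1])])
    return pca.explained_variance_ratio_, score_df


# ---------------------------------------------------------------- controls

def sample_control_regions(peaks: pd.DataFrame, labels: pd.DataFrame | pd.Series,
                           n: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Seeded uniform sample (without replacement) of nondynamic peaks, the
    background set for motif/term enrichment."""
    lab = labels["label"] if isinstance(labels, pd.DataFrame) else labels
    key = peaks["name"] if "name" in peaks.columns else peaks.index
    nondyn = peaks.loc[key.map(lab).eq("nondynamic").fillna(False).to_numpy()]
    if len(nondyn) == 0:
        raise ValueError("no nondynamic peaks to sample controls from")
    rng = np.random.default_rng(seed)
    if len(nondyn) < n:
        warnings.warn(f"only {len(nondyn)} nondynamic peaks available; sampling all")
        return nondyn.copy()
    idx = rng.choice(len(nondyn), size=n, replace=False)
    return nondyn.iloc[np.sort(idx)].copy()


# ---------------------------------------------------------------- k-means

def kmeans_explore(profiles: pd.DataFrame, k: int, seed: int = 0):
    """Seeded k-means over scaled accessibility profiles (exploratory only;
    the predicate classifier is the reproducible deliverable).

    Returns (centers, assignments Series, within-cluster sum of squares).
    """
    X = profiles.dropna().to_numpy(dtype=float)
    kept = profiles.dropna().index
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(X):
        raise ValueError(f"k={k} exceeds the {len(X)} usable profiles")
    if not np.isfinite(X).all():
        raise ValueError("profiles must be finite")
    km = KMeans(n_clusters=k, init="k-means++", n_init=1, random_state=seed,
                algorithm="lloyd", max_iter=300)
    assign = km.fit_predict(X)
    return km.cluster_centers_, pd.Series(assign, index=kept, name="cluster"), float(km.inertia_)
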