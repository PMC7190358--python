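"""Negative-binomial differential accessibility testing.

Per-peak open-fragment counts are modelled as NB(mu, alpha) with
variance = mu + alpha * mu**2 and log link; sequencing depth enters through
median-of-ratios size factors, and the quasi-likelihood score is evaluated
on normalised counts so that fold-changes are exactly invariant under
per-sample depth rescaling.  The engine follows the standard count-based
workflow:

* median-of-ratios size factors;
* per-region method-of-moments dispersion pooled within condition groups,
  shrunk toward a parametric mean-dispersion trend ``a0 + a1/mu`` by
  weighted averaging;
* IRLS maximum-likelihood fits of the NB GLM, coefficients reported in
  log2 units;
* Wald z-tests on contrasts and Benjamini-Hochberg adjustment per contrast.

The four contrasts the dynamics classifier consumes are stratified pairwise
two-group tests: T_wt (t72 vs t12 within wild type), T_mut (within mutant),
G_12 (mut vs wt at t12) and G_72 (mut vs wt at t72).  Genotype contrasts are
mutant-over-wild-type.  No fold-change shrinkage is applied; classification
thresholds raw log2 fold-changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

LN2 = np.log(2.0)
ALPHA_MIN = 1e-8
CONTRAST_SPECS = {
    "T_wt": (("genotype", "wt"), "time", "t72", "t12"),
    "T_mut": (("genotype", "mut"), "time", "t72", "t12"),
    "G_12": (("time", "t12"), "genotype", "mut", "wt"),
    "G_72": (("time", "t72"), "genotype", "mut", "wt"),
}


@dataclass
class CountMatrix:
    """Regions x samples integer counts with sample metadata.

    ``sample_meta`` is indexed by sample id and carries at least genotype and
    time columns; ``size_factors`` (when set) are positive per-sample scalars.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    size_factors: pd.Series | None = None

    def __post_init__(self):
        missing = set(self.counts.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.size_factors is not None and (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")

    @property
    def region_ids(self):
        return self.counts.index

    @property
    def sample_ids(self):
        return self.counts.columns

    def with_size_factors(self) -> "CountMatrix":
        if self.size_factors is None:
            self.size_factors = estimate_size_factors(self.counts)
        return self

    def normalized(self) -> pd.DataFrame:
        self.with_size_factors()
        return self.counts / self.size_factors


@dataclass
class DesignSpec:
    """Factors and contrasts of a testing design (``~genotype + time +
    genotype:time`` when ``interaction`` is set, else additive/one-factor)."""

    factors: tuple = ("genotype", "time")
    interaction: bool = False

    def matrix(self, meta: pd.DataFrame) -> tuple[np.ndarray, list]:
        cols = [np.ones(len(meta))]
        names = ["intercept"]
        indicators = {}
        for f in self.factors:
            levels = sorted(meta[f].unique())
            if len(levels) < 2:
                continue
            ref = levels[0]
            for lev in levels[1:]:
                ind = (meta[f] == lev).to_numpy(float)
                cols.append(ind)
                names.append(f"{f}_{lev}")
                indicators[f] = ind
        if self.interaction and len(indicators) == 2:
            a, b = (indicators[f] for f in self.factors)
            cols.append(a * b)
            names.append("interaction")
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is not full rank")
        return X, names


# ---------------------------------------------------------------- size factors

def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalisation over regions positive in every sample."""
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no region with all-positive counts; median-of-ratios "
                         "needs at least one (consider a pseudo-reference fallback)")
    logs = np.log(arr[positive])
    log_geo_mean = logs.mean(axis=1)
    factors = np.exp(np.median(logs - log_geo_mean[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


# ---------------------------------------------------------------- dispersion

def estimate_dispersion(counts: pd.DataFrame, groups: pd.Series,
                        size_factors: pd.Series | None = None,
                        prior_df: float = 10.0) -> pd.Series:
    """Per-region NB dispersion with trend shrinkage.

    Method-of-moments ``(s2 - m) / m**2`` on normalised counts, pooled over
    condition groups with >= 2 replicates (weights = group df), then averaged
    with the fitted trend ``a0 + a1/mu`` using weight
    ``df / (df + prior_df)`` on the per-region estimate.  Floored at 1e-8.
    """
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    norm = (counts / size_factors).to_numpy(dtype=float)
    glabels = pd.Series(groups, index=counts.columns) if not isinstance(groups, pd.Series) else groups
    total_df = 0
    num = np.zeros(norm.shape[0])
    base_mean = norm.mean(axis=1)
    for g in glabels.unique():
        cols = np.flatnonzero((glabels == g).to_numpy())
        n_g = len(cols)
        if n_g < 2:
            continue
        sub = norm[:, cols]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a_g = np.where(m > 0, (v - m) / np.maximum(m, 1e-12) ** 2, 0.0)
        num += (n_g - 1) * a_g
        total_df += n_g - 1
    if total_df == 0:
        raise ValueError("dispersion estimation needs >= 2 replicates in some group")
    alpha_mom = np.clip(num / total_df, 0.0, None)

    # parametric trend a0 + a1/mu, least squares on regions with positive mean
    ok = base_mean > 0
    if ok.sum() >= 2:
        A = np.column_stack([np.ones(ok.sum()), 1.0 / base_mean[ok]])
        coef, *_ = np.linalg.lstsq(A, alpha_mom[ok], rcond=None)
        a0, a1 = np.clip(coef, 0.0, None)
    else:
        a0, a1 = float(alpha_mom.mean()), 0.0
    with np.errstate(divide="ignore"):
        alpha_trend = a0 + a1 / np.maximum(base_mean, 1e-12)

    w = total_df / (total_df + prior_df)
    alpha = np.maximum(w * alpha_mom + (1 - w) * alpha_trend, ALPHA_MIN)
    return pd.Series(alpha, index=counts.index, name="dispersion")


# ---------------------------------------------------------------- GLM

@dataclass
class NBFit:
    """A fitted NB GLM for one region: coefficients and covariance in log2
    units, plus convergence/testability flags."""

    beta: np.ndarray
    cov: np.ndarray
    converged: bool
    testable: bool
    names: list = field(default_factory=list)


def _irls_batch(Y: np.ndarray, X: np.ndarray, offset: np.ndarray,
                alpha: np.ndarray, tol: float = 1e-8, max_iter: int = 100):
    """Vectorised IRLS over regions sharing one design matrix.

    Y: (R, S) counts; X: (S, p); offset: (S,) log size factors; alpha: (R,).
    Returns beta (R, p) on the natural-log scale, covariance (R, p, p),
    and a per-region convergence flag.
    """
    R, S = Y.shape
    p = X.shape[1]
    pinv = np.linalg.pinv(X)
    beta = ((np.log((Y + 0.5)) - offset[None, :]) @ pinv.T)
    alpha = np.asarray(alpha, dtype=float).reshape(R, 1)
    converged = np.zeros(R, dtype=bool)
    for _ in range(max_iter):
        eta = np.clip(beta @ X.T + offset[None, :], -30, 30)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha * mu)
        z = (eta - offset[None, :]) + (Y - mu) / mu
        A = np.einsum("sp,rs,sq->rpq", X, W, X)
        A += np.eye(p)[None, :, :] * 1e-12
        b = np.einsum("rs,sp->rp", W * z, X)
        new_beta = np.linalg.solve(A, b[..., None])[..., 0]
        delta = np.abs(new_beta - beta).max(axis=1)
        beta = new_beta
        converged = delta < tol
        if converged.all():
            break
    eta = np.clip(beta @ X.T + offset[None, :], -30, 30)
    mu = np.exp(eta)
    W = mu / (1.0 + alpha * mu)
    A = np.einsum("sp,rs,sq->rpq", X, W, X) + np.eye(p)[None, :, :] * 1e-12
    cov = np.linalg.inv(A)
    return beta, cov, converged


def fit_nb_glm_batch(counts: np.ndarray, X: np.ndarray, size_factors: np.ndarray,
                     alpha: np.ndarray, tol: float = 1e-8, max_iter: int = 100):
    """Batch NB GLM fit; coefficients/covariance in log2 units.

    The quasi-likelihood score is evaluated on size-factor-normalised counts
    (equivalently, a sample-weight-stabilised IRLS): for a group of
    replicates the fitted mean is the plain average of normalised counts,
    which makes fold-changes exactly invariant under per-sample depth
    rescaling.  All-zero rows are untestable: zero coefficients, infinite
    variances.  Returns (beta2, cov2, converged, testable).
    """
    Y = np.asarray(counts, dtype=float) / np.asarray(size_factors, dtype=float)
    offset = np.zeros(Y.shape[1])
    testable = Y.sum(axis=1) > 0
    R, p = Y.shape[0], X.shape[1]
    beta2 = np.zeros((R, p))
    cov2 = np.full((R, p, p), np.inf)
    converged = np.zeros(R, dtype=bool)
    if testable.any():
        b, c, conv = _irls_batch(Y[testable], X, offset,
                                 np.asarray(alpha, float)[testable], tol, max_iter)
        beta2[testable] = b / LN2
        cov2[testable] = c / LN2 ** 2
        converged[testable] = conv
    return beta2, cov2, converged, testable


def fit_nb_glm(y, X, size_factors, alpha: float, tol: float = 1e-8,
               max_iter: int = 100, names: list | None = None) -> NBFit:
    """Fit one region's NB GLM (log link; depth handled via size factors)."""
    y = np.asarray(y, dtype=float)[None, :]
    X = np.asarray(X, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is not full rank")
    beta2, cov2, conv, testable = fit_nb_glm_batch(
        y, X, np.asarray(size_factors, float), np.array([alpha]), tol, max_iter)
    return NBFit(beta=beta2[0], cov=cov2[0], converged=bool(conv[0]),
                 testable=bool(testable[0]), names=names or [])


def wald_contrast(fit: NBFit, contrast) -> tuple[float, float, float]:
    """Wald test of a coefficient combination: (log2fc, se, two-sided p)."""
    c = np.asarray(contrast, dtype=float)
    if not fit.testable:
        return 0.0, np.inf, 1.0
    lfc = float(c @ fit.beta)
    se = float(np.sqrt(c @ fit.cov @ c))
    if not np.isfinite(se) or se == 0:
        return lfc, se, 1.0
    z = lfc / se
    return lfc, se, float(2.0 * stats.norm.sf(abs(z)))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up; NaNs are excluded from m and propagated."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        if ((p[ok] < 0) | (p[ok] > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------- contrasts

def _two_group_test(matrix: CountMatrix, samples, group_mask: np.ndarray,
                    contrast_name: str) -> pd.DataFrame:
    counts = matrix.counts[samples]
    sf = matrix.size_factors.loc[samples].to_numpy()
    groups = pd.Series(np.where(group_mask, "num", "den"), index=samples)
    alpha = estimate_dispersion(counts, groups, matrix.size_factors.loc[samples])
    X = np.column_stack([np.ones(len(samples)), group_mask.astype(float)])
    beta2, cov2, conv, testable = fit_nb_glm_batch(
        counts.to_numpy(), X, sf, alpha.to_numpy())
    lfc = beta2[:, 1]
    se = np.sqrt(cov2[:, 1, 1])
    with np.errstate(invalid="ignore"):
        z = np.where(se > 0, lfc / se, 0.0)
    pval = np.where(testable & np.isfinite(se), 2.0 * stats.norm.sf(np.abs(z)), 1.0)
    base_mean = (counts / matrix.size_factors.loc[samples]).mean(axis=1).to_numpy()
    return pd.DataFrame({
        "region": matrix.region_ids,
        "contrast": contrast_name,
        "baseMean": base_mean,
        "log2fc": np.where(testable, lfc, 0.0),
        "se": se,
        "pvalue": pval,
        "padj": bh_adjust(pval),
        "testable": testable,
        "converged": conv,
    })


def run_two_group(matrix: CountMatrix, factor: str, num: str, den: str,
                  contrast_name: str | None = None) -> pd.DataFrame:
    """One-factor NB test (``~genotype`` style design) over all samples."""
    matrix.with_size_factors()
    meta = matrix.sample_meta
    samples = matrix.sample_ids
    levels = set(meta.loc[samples, factor])
    for lev in (num, den):
        if lev not in levels:
            raise ValueError(f"level {lev!r} of factor {factor!r} has no samples")
    mask = (meta.loc[samples, factor] == num).to_numpy()
    return _two_group_test(matrix, samples, mask, contrast_name or f"{factor}_{num}_vs_{den}")


def run_four_contrasts(matrix: CountMatrix) -> pd.DataFrame:
    """The four stratified pairwise contrasts of the 2x2 genotype x time
    design, BH-adjusted within each contrast.

    T_wt / T_mut: t72 vs t12 within genotype; G_12 / G_72: mut vs wt within
    timepoint.  Requires >= 2 replicates in each of the four cells.
    """
    matrix.with_size_factors()
    meta = matrix.sample_meta
    for g in ("wt", "mut"):
        for t in ("t12", "t72"):
            n = ((meta["genotype"] == g) & (meta["time"] == t)).sum()
            if n < 2:
                raise ValueError(f"design cell (genotype={g}, time={t}) has {n} samples; need >= 2")
    tables = []
    for cname, ((strat_col, strat_val), factor, num, den) in CONTRAST_SPECS.items():
        samples = meta.index[meta[strat_col] == strat_val]
        samples = [s for s in matrix.sample_ids if s in set(samples)]
        mask = (meta.loc[samples, factor] == num).to_numpy()
        tables.append(_two_group_test(matrix, samples, mask, cname))
    return pd.concat(tables, ignore_index=True)
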