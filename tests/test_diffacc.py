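"""The NB differential-accessibility engine: size factors, dispersion,
GLM fits, Wald tests, BH and the four stratified contrasts."""

import numpy as np
import pandas as pd
import pytest

import chromdyn as cd
from chromdyn.diffacc import (CountMatrix, estimate_dispersion,
                              estimate_size_factors, run_two_group)


def two_group_matrix(counts, n_per_group=3):
    samples = [f"wt_t12_r{i+1}" for i in range(n_per_group)] + \
              [f"mut_t12_r{i+1}" for i in range(n_per_group)]
    meta = pd.DataFrame({"sample": samples,
                         "genotype": ["wt"] * n_per_group + ["mut"] * n_per_group,
                         "time": "t12"}).set_index("sample")
    df = pd.DataFrame(counts, columns=samples,
                      index=[f"r{i}" for i in range(len(counts))])
    return CountMatrix(counts=df, sample_meta=meta)


class TestSizeFactors:
    def test_identical_samples_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        np.testing.assert_allclose(estimate_size_factors(counts), 1.0)

    def test_scale_equivariance(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        f = estimate_size_factors(counts)
        assert f["b"] / f["a"] == pytest.approx(2.0)

    def test_matches_median_of_ratios_oracle(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(1, 500, size=(100, 5)),
                              columns=list("abcde"))
        got = estimate_size_factors(counts)
        logs = np.log(counts.to_numpy(dtype=float))
        want = np.exp(np.median(logs - logs.mean(axis=1, keepdims=True), axis=0))
        np.testing.assert_allclose(got.to_numpy(), want)

    def test_no_allpositive_region_error(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="all-positive"):
            estimate_size_factors(counts)


class TestDispersion:
    def _estimate(self, counts, n_per_group=3):
        samples = [f"s{i}" for i in range(2 * n_per_group)]
        groups = pd.Series(["A"] * n_per_group + ["B"] * n_per_group, index=samples)
        df = pd.DataFrame(counts, columns=samples)
        return estimate_dispersion(df, groups, pd.Series(1.0, index=samples))

    def test_poisson_counts_give_small_alpha(self):
        rng = np.random.default_rng(1)
        alpha = self._estimate(rng.poisson(100, size=(500, 6)))
        assert np.median(alpha) <= 0.01

    def test_planted_alpha_recovered(self):
        rng = np.random.default_rng(2)
        mu, a = 200.0, 0.05
        counts = rng.negative_binomial(1 / a, (1 / a) / (1 / a + mu), size=(500, 6))
        alpha = self._estimate(counts)
        assert 0.025 <= alpha.mean() <= 0.10

    def test_constant_counts_floor(self):
        alpha = self._estimate(np.full((10, 6), 50))
        np.testing.assert_allclose(alpha, 1e-8)

    def test_single_replicate_error(self):
        df = pd.DataFrame([[1, 2]], columns=["s0", "s1"])
        groups = pd.Series(["A", "B"], index=df.columns)
        with pytest.raises(ValueError, match="replicates"):
            estimate_dispersion(df, groups, pd.Series(1.0, index=df.columns))


class TestGLM:
    def test_poisson_limit_lfc_equals_log2_ratio(self):
        """alpha -> 0, balanced two-group design: the fitted log2FC is the
        log2 ratio of group means, exactly."""
        X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
        fit = cd.fit_nb_glm([100, 100, 100, 400, 400, 400], X, np.ones(6), 0.0)
        assert fit.beta[1] == pytest.approx(2.0, abs=1e-6)
        fit2 = cd.fit_nb_glm([90, 110, 100, 350, 420, 430], X, np.ones(6), 0.0)
        want = np.log2(400 / 100)
        assert fit2.beta[1] == pytest.approx(want, abs=1e-6)

    def test_constant_counts_zero_effects(self):
        X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
        fit = cd.fit_nb_glm([50] * 6, X, np.ones(6), 0.05)
        assert fit.beta[1] == pytest.approx(0.0, abs=1e-8)

    def test_all_zero_row_untestable(self):
        X = np.column_stack([np.ones(4), [0, 0, 1, 1]])
        fit = cd.fit_nb_glm([0, 0, 0, 0], X, np.ones(4), 0.05)
        assert not fit.testable
        assert cd.wald_contrast(fit, [0, 1])[2] == 1.0

    def test_interaction_recovery(self):
        """2x2 design with a planted interaction log2FC of 2: the mean
        estimate over 500 simulated regions lands within [1.6, 2.4]."""
        rng = np.random.default_rng(3)
        mu = np.array([200, 200, 200, 800])   # wt12, wt72, mut12, mut72
        g = np.array([0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1], float)
        t = np.array([0, 0, 0, 1, 1, 1] * 2, float)
        X = np.column_stack([np.ones(12), g, t, g * t])
        a = 0.05
        Y = rng.negative_binomial(1 / a, (1 / a) / (1 / a + np.repeat(mu, 3)),
                                  size=(500, 12))
        beta, _, _, _ = cd.fit_nb_glm_batch(Y, X, np.ones(12), np.full(500, a))
        assert 1.6 <= beta[:, 3].mean() <= 2.4


class TestWaldAndBH:
    def test_zero_lfc_p_one(self):
        X = np.column_stack([np.ones(4), [0, 0, 1, 1]])
        fit = cd.fit_nb_glm([50, 50, 50, 50], X, np.ones(4), 0.05)
        assert cd.wald_contrast(fit, [0, 1])[2] == pytest.approx(1.0)

    def test_normal_quantile(self):
        from scipy import stats
        assert 2 * stats.norm.sf(1.959964) == pytest.approx(0.05, abs=1e-6)

    def test_bh_analytic_example(self):
        np.testing.assert_allclose(cd.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_bh_single_p_unchanged(self):
        np.testing.assert_allclose(cd.bh_adjust([0.3]), [0.3])

    def test_bh_matches_stepup_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            p = rng.random(int(rng.integers(1, 50)))
            got = cd.bh_adjust(p)
            # brute-force step-up: padj_i = min_{j: p_j >= p_i} (m * p_j / rank_j)
            m = len(p)
            order = np.argsort(p)
            ranked = p[order] * m / np.arange(1, m + 1)
            monotone = np.minimum.accumulate(ranked[::-1])[::-1]
            want = np.empty(m)
            want[order] = np.minimum(monotone, 1.0)
            np.testing.assert_allclose(got, want)

    def test_bh_nan_propagated(self):
        out = cd.bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1]) and not np.isnan(out[0])


class TestFourContrasts:
    def test_class8_peaks_detected_in_both_time_tests(self, study_truth, study_contrasts):
        """Uniform-gain peaks: both time contrasts significant positive,
        genotype contrasts ns, in >= 90% of planted class-8 peaks."""
        names = study_truth.peaks.query("label == '8'")["name"]
        piv_l = study_contrasts.pivot(index="region", columns="contrast", values="log2fc").loc[names]
        piv_p = study_contrasts.pivot(index="region", columns="contrast", values="padj").loc[names]
        hit = ((piv_p["T_wt"] < 0.01) & (piv_l["T_wt"] > 1)
               & (piv_p["T_mut"] < 0.01) & (piv_l["T_mut"] > 1)
               & ~((piv_p["G_12"] < 0.01) & (piv_l["G_12"].abs() > 1))
               & ~((piv_p["G_72"] < 0.01) & (piv_l["G_72"].abs() > 1)))
        assert hit.mean() >= 0.90

    def test_genotype_label_swap_negates_genotype_contrasts(self, small_matrix):
        res = cd.run_four_contrasts(small_matrix)
        flipped_meta = small_matrix.sample_meta.copy()
        flipped_meta["genotype"] = flipped_meta["genotype"].map({"wt": "mut", "mut": "wt"})
        flipped = CountMatrix(counts=small_matrix.counts, sample_meta=flipped_meta)
        res_f = cd.run_four_contrasts(flipped)
        for cname in ("G_12", "G_72"):
            a = res.query("contrast == @cname").set_index("region")["log2fc"]
            b = res_f.query("contrast == @cname").set_index("region")["log2fc"]
            np.testing.assert_allclose(a, -b, atol=1e-6)

    def test_missing_cell_error(self, small_matrix):
        meta = small_matrix.sample_meta
        keep = meta.index[~((meta["genotype"] == "mut") & (meta["time"] == "t72"))]
        sub = CountMatrix(counts=small_matrix.counts[keep],
                          sample_meta=meta.loc[keep])
        with pytest.raises(ValueError, match="mut.*t72"):
            cd.run_four_contrasts(sub)

    def test_lfc_invariant_under_sample_rescaling(self):
        rng = np.random.default_rng(5)
        counts = rng.negative_binomial(20, 20 / 220, size=(200, 6))
        m1 = two_group_matrix(counts)
        scaled = counts.copy()
        scaled[:, 0] *= 3
        m2 = two_group_matrix(scaled)
        r1 = run_two_group(m1, "genotype", "mut", "wt")
        r2 = run_two_group(m2, "genotype", "mut", "wt")
        np.testing.assert_allclose(r1["log2fc"], r2["log2fc"], atol=1e-6)


class TestAgainstReferenceEngine:
    def test_lfc_agreement_with_deseq2_port(self):
        """Independent cross-check: two-group log2FCs track pydeseq2's
        unshrunken Wald estimates on a shared simulated dataset."""
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        rng = np.random.default_rng(6)
        n = 150
        mu = rng.uniform(50, 500, size=n)
        lfc = rng.choice([0.0, 1.5, -1.5], size=n, p=[0.6, 0.2, 0.2])
        a = 0.05
        muA = np.repeat(mu[:, None], 3, axis=1)
        muB = np.repeat((mu * 2.0 ** lfc)[:, None], 3, axis=1)
        Y = np.concatenate([
            rng.negative_binomial(1 / a, (1 / a) / (1 / a + muA)),
            rng.negative_binomial(1 / a, (1 / a) / (1 / a + muB))], axis=1)
        matrix = two_group_matrix(Y)
        mine = run_two_group(matrix, "genotype", "mut", "wt").set_index("region")

        meta = matrix.sample_meta.copy()
        dds = DeseqDataSet(counts=matrix.counts.T, metadata=meta,
                           design="~genotype", quiet=True)
        dds.deseq2()
        stat = DeseqStats(dds, contrast=["genotype", "mut", "wt"], quiet=True)
        stat.summary()
        ref = stat.results_df["log2FoldChange"]
        both = mine.join(ref.rename("ref"))
        r = np.corrcoef(both["log2fc"], both["ref"])[0, 1]
        assert r > 0.95
        assert (both["log2fc"] - both["ref"]).abs().median() < 0.3
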