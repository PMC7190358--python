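"""PWM scanning, dyad modelling, motif-dyad displacement and the
permutation test."""

import itertools

import numpy as np
import pandas as pd
import pytest

import chromdyn as cd
from chromdyn.nucmotif import DegeneratePWMError, PWM
from chromdyn.simulate import DEFAULT_PFM, revcomp, simulate_dyad_fragments


@pytest.fixture(scope="module")
def pwm():
    return PWM.from_counts(DEFAULT_PFM)


class TestPWM:
    def test_uniform_counts_degenerate(self):
        with pytest.raises(DegeneratePWMError):
            PWM.from_counts(np.ones((4, 6)))

    def test_consensus_scores_rel_one(self, pwm):
        hits = cd.scan_motifs(pwm.consensus(), pwm, rel_min=0.99)
        assert len(hits) == 1
        assert hits["rel_score"].iloc[0] == pytest.approx(1.0)

    def test_pseudocount_probabilities(self):
        p = PWM.from_counts(np.array([[3.0], [0.0], [0.0], [0.0]] ).repeat(4, axis=1))
        np.testing.assert_allclose(p.probs[:, 0], [3.25 / 4, 0.25 / 4, 0.25 / 4, 0.25 / 4])

    def test_roundtrip_through_pfm_text(self, pwm, tmp_path):
        from chromdyn import io as cio
        cio.write_pfm(DEFAULT_PFM, tmp_path / "m.pfm")
        back = cd.read_pfm(str(tmp_path / "m.pfm"))
        np.testing.assert_allclose(back.probs, pwm.probs, atol=1e-12)


class TestScan:
    def test_reverse_complement_symmetry(self, pwm):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 2000)) + pwm.consensus() + \
              "".join(rng.choice(list("ACGT"), 100))
        fwd = cd.scan_motifs(seq, pwm, rel_min=0.8)
        rev = cd.scan_motifs(revcomp(seq), pwm, rel_min=0.8)
        assert len(fwd) == len(rev)
        np.testing.assert_allclose(np.sort(fwd["score"]), np.sort(rev["score"]), atol=1e-9)

    def test_matches_per_window_rescoring_oracle(self, pwm):
        """Hit set on 10 kb of random sequence equals brute-force rescoring of
        every window on both strands."""
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 10_000))
        hits = cd.scan_motifs(seq, pwm, rel_min=0.75)
        w = pwm.width
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        expected = {}
        for i in range(len(seq) - w + 1):
            win = seq[i:i + w]
            sf = sum(pwm.logodds[idx[b], j] for j, b in enumerate(win))
            sr = sum(pwm.logodds[idx[b], j] for j, b in enumerate(revcomp(win)))
            best, strand = (sf, "+") if sf >= sr else (sr, "-")
            if pwm.rel_score(best) >= 0.75:
                expected[i] = (strand, best)
        assert dict(zip(hits["start"], zip(hits["strand"], hits["score"]))) == \
            {k: (s, pytest.approx(v)) for k, (s, v) in expected.items()}

    def test_n_windows_skipped(self, pwm):
        seq = pwm.consensus()[:4] + "N" + pwm.consensus()[5:]
        assert len(cd.scan_motifs(seq, pwm, rel_min=0.0)) == 0

    def test_short_sequence_empty(self, pwm):
        assert len(cd.scan_motifs("ACG", pwm)) == 0


class TestMotifCounts:
    def test_planted_motifs_counted(self, pwm):
        hits = pd.DataFrame({"chrom": "chr1", "start": [10, 50, 90, 300],
                             "end": [18, 58, 98, 308]})
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100],
                              "name": ["p"]})
        assert cd.count_motifs_per_interval(hits, peaks)["p"] == 3

    def test_partial_overlap_not_counted(self):
        hits = pd.DataFrame({"chrom": "chr1", "start": [95], "end": [103]})
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100],
                              "name": ["p"]})
        assert cd.count_motifs_per_interval(hits, peaks)["p"] == 0

    def test_matches_allpairs_bruteforce(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n_hits = int(rng.integers(0, 200))
            starts = rng.integers(0, 3000, size=n_hits)
            hits = pd.DataFrame({"chrom": rng.choice(["chr1", "chr2"], n_hits),
                                 "start": starts, "end": starts + 8})
            p_starts = rng.integers(0, 3000, size=50)
            peaks = pd.DataFrame({"chrom": rng.choice(["chr1", "chr2"], 50),
                                  "start": p_starts,
                                  "end": p_starts + rng.integers(10, 400, 50)})
            got = cd.count_motifs_per_interval(hits, peaks).to_numpy()
            want = np.array([
                sum(1 for h in hits.itertuples(index=False)
                    if h.chrom == p.chrom and h.start >= p.start and h.end <= p.end)
                for p in peaks.itertuples(index=False)])
            np.testing.assert_array_equal(got, want)


class TestDyads:
    def test_single_dyad_recovered(self):
        frags = simulate_dyad_fragments([5000], 200, 30, seed=0)
        dyads = cd.call_dyads(frags)
        assert len(dyads) == 1
        assert abs(dyads["pos"].iloc[0] - 5000) <= 20

    def test_two_distant_dyads_both_recovered(self):
        frags = simulate_dyad_fragments([5000, 5400], 200, 30, seed=1)
        dyads = cd.call_dyads(frags)
        assert len(dyads) == 2
        assert np.abs(np.sort(dyads["pos"]) - [5000, 5400]).max() <= 20
        assert np.diff(np.sort(dyads["pos"]))[0] >= 147

    def test_close_dyads_collapse_to_one(self):
        """Two planted dyads 100 bp apart fall inside one 147 bp exclusion
        zone and are reported as a single dyad."""
        frags = simulate_dyad_fragments([5000, 5100], 200, 30, seed=2)
        assert len(cd.call_dyads(frags)) == 1

    def test_open_fragments_rejected(self):
        frags = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [80],
                              "mapq": 60, "proper_pair": True,
                              "duplicate": False, "sample": "s"})
        with pytest.raises(ValueError, match="length > 100"):
            cd.call_dyads(frags)

    def test_empty_input_empty_track(self):
        assert len(cd.call_dyads(pd.DataFrame(columns=["chrom", "start", "end"]))) == 0


class TestDistances:
    def test_motif_at_dyad_zero(self):
        hits = pd.DataFrame({"chrom": ["chr1"], "start": [996], "end": [1004]})
        dyads = pd.DataFrame({"chrom": ["chr1"], "pos": [1000]})
        assert cd.motif_dyad_distance(hits, dyads).iloc[0] == 0

    def test_nearest_of_two(self):
        hits = pd.DataFrame({"chrom": ["chr1"], "start": [1396], "end": [1404]})
        dyads = pd.DataFrame({"chrom": "chr1", "pos": [1000, 2000]})
        assert cd.motif_dyad_distance(hits, dyads).iloc[0] == 400

    def test_chromosome_without_dyads_nan(self):
        hits = pd.DataFrame({"chrom": ["chrX"], "start": [0], "end": [8]})
        dyads = pd.DataFrame({"chrom": ["chr1"], "pos": [5]})
        assert np.isnan(cd.motif_dyad_distance(hits, dyads).iloc[0])

    def test_matches_bruteforce_min_scan(self):
        rng = np.random.default_rng(3)
        starts = rng.integers(0, 100_000, size=300)
        hits = pd.DataFrame({"chrom": rng.choice(["chr1", "chr2"], 300),
                             "start": starts, "end": starts + 8})
        dyads = pd.DataFrame({"chrom": rng.choice(["chr1", "chr2"], 100),
                              "pos": rng.integers(0, 100_000, size=100)})
        got = cd.motif_dyad_distance(hits, dyads).to_numpy()
        mids = (hits["start"] + hits["end"]) // 2
        want = np.array([
            min((abs(m - d.pos) for d in dyads.itertuples(index=False)
                 if d.chrom == h.chrom), default=np.nan)
            for (_, h), m in zip(hits.iterrows(), mids)], dtype=float)
        np.testing.assert_allclose(got, want)


class TestFootprint:
    def test_fraction_and_inclusive_boundary(self):
        assert cd.footprint_fraction([0, 50, 100]) == pytest.approx(2 / 3)
        assert cd.footprint_fraction([73, 73, 73]) == 1.0

    def test_monotone_in_half_wrap(self):
        rng = np.random.default_rng(4)
        d = rng.uniform(0, 300, 500)
        fracs = [cd.footprint_fraction(d, hw) for hw in (20, 73, 150, 300)]
        assert fracs == sorted(fracs)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            cd.footprint_fraction([np.nan])

    def test_matches_planted_occlusion_fraction(self):
        """Generator planting 50% of motifs under dyads: measured footprint
        fraction lands within +-0.05 at ~400 motifs."""
        cfg = cd.SimulationConfig(n_peaks_per_class={"nondynamic": 400},
                                  n_chroms=8, occluded_frac=0.5, seed=5)
        truth = cd.build_truth(cfg)
        frac = cd.footprint_fraction(
            cd.motif_dyad_distance(truth.motif_sites, truth.dyads))
        assert abs(frac - 0.5) <= 0.05


class TestShift:
    def test_identical_inputs_zero(self):
        d = pd.Series([10.0, 50.0, 90.0])
        assert cd.mean_distance_shift(d, d) == 0.0

    def test_constant_displacement(self):
        d = pd.Series([10.0, 50.0, 90.0])
        assert cd.mean_distance_shift(d, d + 80) == pytest.approx(80.0)

    def test_disjoint_sets_error(self):
        with pytest.raises(ValueError):
            cd.mean_distance_shift(pd.Series([1.0], index=["a"]),
                                   pd.Series([2.0], index=["b"]))

    @pytest.mark.parametrize("displacement", [40, 80])
    def test_planted_dyad_displacement_recovered(self, displacement):
        """Dyads moved D bp away from motifs between conditions: the paired
        mean shift recovers D within 10%."""
        rng = np.random.default_rng(6)
        motif_pos = 2000 + 2000 * np.arange(100)
        offs = rng.integers(-40, 41, size=100)
        before_pos = motif_pos + offs
        after_pos = before_pos + displacement * np.where(offs >= 0, 1, -1)
        d_before = cd.motif_dyad_distance(
            pd.DataFrame({"chrom": "chr1", "start": motif_pos - 4, "end": motif_pos + 4}),
            cd.call_dyads(simulate_dyad_fragments(before_pos, 200, 30, seed=7)))
        d_after = cd.motif_dyad_distance(
            pd.DataFrame({"chrom": "chr1", "start": motif_pos - 4, "end": motif_pos + 4}),
            cd.call_dyads(simulate_dyad_fragments(after_pos, 200, 30, seed=8)))
        shift = cd.mean_distance_shift(d_before, d_after)
        assert abs(shift - displacement) <= 0.1 * displacement


class TestPermutation:
    def test_exchangeable_groups_large_p(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        p = cd.permutation_mean_test(vals, vals, n_perm=10_000, exact=False, seed=0)
        assert 0.4 <= p <= 0.6

    def test_exact_enumeration_4_3(self):
        """Group sizes (4,3) from 7 values: p equals exhaustive enumeration
        over all C(7,4) = 35 partitions."""
        a, b = [5.0, 6.0, 7.0, 8.0], [1.0, 2.0, 3.0]
        p = cd.permutation_mean_test(a, b, exact=True)
        pool = np.array(a + b)
        obs = np.mean(a) - np.mean(b)
        count = sum(
            pool[list(idx)].mean() - np.delete(pool, list(idx)).mean() >= obs - 1e-12
            for idx in itertools.combinations(range(7), 4))
        assert p == pytest.approx(count / 35)
        # auto mode enumerates too (C(7,4) is tiny)
        assert cd.permutation_mean_test(a, b, exact="auto") == pytest.approx(p)

    def test_add_one_estimator_never_zero(self):
        a = [100.0] * 5
        b = [1.0] * 5
        p = cd.permutation_mean_test(a, b, n_perm=1000, exact=False, seed=1)
        assert p >= 1 / 1001

    def test_null_pvalues_approximately_uniform(self):
        """Null calibration: fraction of p < 0.05 within [0.03, 0.07] over
        1000 null trials at n_perm 10^4."""
        rng = np.random.default_rng(2)
        hits = 0
        trials = 1000
        for t in range(trials):
            pool = rng.normal(size=20)
            p = cd.permutation_mean_test(pool[:10], pool[10:], n_perm=10_000,
                                         exact=False, seed=t)
            hits += p < 0.05
        assert 0.03 <= hits / trials <= 0.07

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            cd.permutation_mean_test([], [1.0])
        with pytest.raises(ValueError):
            cd.permutation_mean_test([1.0], [1.0], n_perm=0)
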