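import math

import numpy as np
import pandas as pd
import pytest

from panpav.io_formats import GenotypeMatrix, WindowTrack
from panpav.popgen import (
    half_decay_distance,
    lai,
    ld_decay,
    rod_track,
    site_pi,
    sweep_filter,
    weir_cockerham_fst,
    window_pi,
)

from _oracles import brute_sweep_filter, wc_fst_oracle, window_pi_oracle


def geno_from_dosage(dosage, positions=None, chrom="chr1", haplotypes=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    S, N = dosage.shape
    pos = positions if positions is not None else np.arange(1, S + 1) * 10
    sites = pd.DataFrame({"chrom": [chrom] * S, "pos": pos,
                          "ref": ["A"] * S, "alt": ["G"] * S})
    return GenotypeMatrix(sites, [f"s{i}" for i in range(N)], dosage,
                          haplotypes)


class TestWindowPi:
    def test_monomorphic_window_is_zero(self):
        g = geno_from_dosage([[0, 0, 0], [2, 2, 2]])
        t = window_pi(g, window=100, step=100, chrom_lengths={"chr1": 100})
        assert t.values[0] == 0.0

    def test_single_site_hand_value(self):
        # n = 4 alleles, c = 2: pi_site = 2*2*2/(4*3) = 2/3; window 100 bp
        g = geno_from_dosage([[1, 1]])
        t = window_pi(g, window=100, step=100, chrom_lengths={"chr1": 100})
        assert t.values[0] == pytest.approx((2 / 3) / 100)

    def test_missing_genotypes_excluded_sitewise(self):
        g = geno_from_dosage([[1, 1, -1]])
        t = window_pi(g, window=100, step=100, chrom_lengths={"chr1": 100})
        assert t.values[0] == pytest.approx((2 / 3) / 100)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        S, N = int(rng.integers(10, 80)), int(rng.integers(2, 12))
        dosage = rng.integers(0, 3, size=(S, N)).astype(np.int8)
        dosage[rng.random(dosage.shape) < 0.1] = -1
        pos = np.sort(rng.choice(2000, size=S, replace=False)) + 1
        g = geno_from_dosage(dosage, positions=pos)
        t = window_pi(g, window=500, step=250, chrom_lengths={"chr1": 2000})
        expected = window_pi_oracle(dosage, pos, t.starts, t.ends)
        assert np.allclose(t.values, expected, rtol=1e-12, atol=1e-15)


class TestWeirCockerham:
    def test_fixed_difference_is_one(self):
        g = geno_from_dosage([[2, 2, 0, 0]])
        fst = weir_cockerham_fst(g, {"s0": "A", "s1": "A", "s2": "B", "s3": "B"})
        assert fst == 1.0

    def test_no_differentiation_nonpositive(self):
        # both pops {AA, aa}: p = 0.5 each, no heterozygotes
        g = geno_from_dosage([[2, 0, 2, 0]])
        fst = weir_cockerham_fst(g, {"s0": "A", "s1": "A", "s2": "B", "s3": "B"})
        assert fst <= 0

    def test_mixed_genotypes_match_component_oracle(self):
        # pop1 {AA, Aa}, pop2 {aa, aa}
        dosage = np.array([[2, 1, 0, 0]], dtype=np.int8)
        g = geno_from_dosage(dosage)
        labels = {"s0": "A", "s1": "A", "s2": "B", "s3": "B"}
        fst = weir_cockerham_fst(g, labels)
        assert fst == pytest.approx(wc_fst_oracle(dosage, [[0, 1], [2, 3]]),
                                    abs=1e-12)

    def test_too_small_group_is_error(self):
        g = geno_from_dosage([[0, 1, 2]])
        with pytest.raises(ValueError):
            weir_cockerham_fst(g, {"s0": "A", "s1": "A", "s2": "B"})

    def test_windowed_output_grid(self):
        rng = np.random.default_rng(0)
        dosage = rng.integers(0, 3, size=(50, 8)).astype(np.int8)
        g = geno_from_dosage(dosage, positions=np.arange(1, 51) * 10)
        labels = {f"s{i}": ("A" if i < 4 else "B") for i in range(8)}
        genome, track = weir_cockerham_fst(g, labels, windows=(200, 100),
                                           chrom_lengths={"chr1": 500})
        assert len(track) == 5
        assert genome == pytest.approx(
            wc_fst_oracle(dosage, [[0, 1, 2, 3], [4, 5, 6, 7]]), abs=1e-12)


class TestLdDecay:
    def test_duplicated_column_perfect_ld(self):
        hap = np.zeros((2, 4, 2), dtype=np.int8)
        hap[0, :2] = 1
        hap[1, :2] = 1       # site 2 identical to site 1
        g = geno_from_dosage(hap.sum(axis=2), positions=[10, 500],
                             haplotypes=hap)
        curve, _ = ld_decay(g, max_dist=1000, bin_width=1000)
        assert curve.mean_r2.iloc[0] == pytest.approx(1.0)

    def test_hand_computed_haplotype_case(self):
        # haplotype pairs per individual: (A,B),(A,b),(a,B),(A,B)
        # p_A = 0.75, p_B = 0.75, p_AB = 0.5, D = -0.0625, r2 = 1/9
        hapA = np.array([1, 1, 0, 1], dtype=np.int8)
        hapB = np.array([1, 0, 1, 1], dtype=np.int8)
        hap = np.zeros((2, 2, 2), dtype=np.int8)
        hap[0] = hapA.reshape(2, 2)
        hap[1] = hapB.reshape(2, 2)
        g = geno_from_dosage(hap.sum(axis=2), positions=[10, 100],
                             haplotypes=hap)
        curve, _ = ld_decay(g, max_dist=1000, bin_width=1000)
        assert curve.mean_r2.iloc[0] == pytest.approx(1 / 9)

    def test_r2_always_in_unit_interval(self, rng):
        hap = (rng.random((40, 20, 2)) < 0.4).astype(np.int8)
        g = geno_from_dosage(hap.sum(axis=2),
                             positions=np.sort(rng.choice(5000, 40,
                                                          replace=False)) + 1,
                             haplotypes=hap)
        curve, _ = ld_decay(g, max_dist=5000, bin_width=500)
        vals = curve.mean_r2.dropna()
        assert ((vals >= -1e-12) & (vals <= 1 + 1e-12)).all()

    def test_half_decay_matches_analytic_curve(self):
        lam = 20_000.0
        mids = np.arange(500, 100_000, 1000).astype(float)
        r2 = np.exp(-mids / lam)
        hd = half_decay_distance(mids, r2, smooth_width=1)
        assert abs(hd - lam * math.log(2)) <= 1000

    def test_unphased_fallback_squared_correlation(self):
        dosage = np.array([[0, 1, 2, 0, 2], [0, 1, 2, 0, 2]], dtype=np.int8)
        g = geno_from_dosage(dosage, positions=[10, 200])
        curve, _ = ld_decay(g, max_dist=1000, bin_width=1000)
        assert curve.mean_r2.iloc[0] == pytest.approx(1.0)


def make_tracks(scores, pi_wild, pi_dom, window=100):
    W = len(scores)
    chroms = np.array(["chr1"] * W, dtype=object)
    starts = np.arange(W) * window
    ends = starts + window
    return (WindowTrack(chroms, starts, ends, scores, "score"),
            WindowTrack(chroms.copy(), starts.copy(), ends.copy(), pi_wild, "pi"),
            WindowTrack(chroms.copy(), starts.copy(), ends.copy(), pi_dom, "pi"))


class TestSweepFilter:
    def test_stage_counts_100_windows(self, rng):
        scores = rng.permutation(100).astype(float) + 1
        pw = rng.uniform(0.5, 1.5, 100)
        pdm = rng.uniform(0.5, 1.5, 100)
        score, w, d = make_tracks(scores, pw, pdm)
        sweeps, audit = sweep_filter(score, w, d)
        assert len(audit["selected"]) == 5      # ceil(0.05 * 100)
        assert len(audit["survivors"]) == 3     # ceil(0.5 * 5)

    def test_bookended_windows_merge(self):
        scores = np.ones(10)
        scores[[3, 4]] = 50.0
        pw = np.ones(10)
        pdm = np.ones(10)
        pdm[[3, 4]] = 0.1
        score, w, d = make_tracks(scores, pw, pdm)
        # overlapping grid: window 200, step 100
        W = 10
        chroms = np.array(["chr1"] * W, dtype=object)
        starts = np.arange(W) * 100
        ends = starts + 200
        t = lambda v, n: WindowTrack(chroms, starts, ends, v, n)
        sweeps, _ = sweep_filter(t(scores, "s"), t(pw, "w"), t(pdm, "d"),
                                 top_score=0.2, top_rod=1.0)
        assert [(s.start, s.end) for s in sweeps] == [(300, 600)]

    def test_zero_pi_wild_windows_excluded(self, caplog):
        scores = np.arange(20, dtype=float) + 1
        pw = np.ones(20)
        pw[19] = 0.0          # the top-score window has no wild diversity
        pdm = np.ones(20)
        score, w, d = make_tracks(scores, pw, pdm)
        _, audit = sweep_filter(score, w, d, top_score=0.1, top_rod=1.0)
        assert 19 not in audit["selected"]["window"].tolist()

    def test_infinite_rod_ranked_highest(self):
        scores = np.arange(10, dtype=float) + 1
        pw = np.ones(10)
        pdm = np.ones(10)
        pdm[8] = 0.0          # window 8 selected, pi_dom = 0 -> ROD = inf
        score, w, d = make_tracks(scores, pw, pdm)
        _, audit = sweep_filter(score, w, d, top_score=0.2, top_rod=0.5)
        assert audit["survivors"]["window"].tolist() == [8]

    def test_mismatched_grids_error(self):
        score, w, d = make_tracks(np.ones(5), np.ones(5), np.ones(5))
        other = WindowTrack(np.array(["chr1"] * 4, dtype=object),
                            np.arange(4) * 100, np.arange(4) * 100 + 100,
                            np.ones(4), "pi")
        with pytest.raises(ValueError):
            sweep_filter(score, w, other)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        W = int(rng.integers(20, 200))
        scores = rng.lognormal(0, 1, W)
        pw = rng.uniform(0, 2, W)
        pdm = rng.uniform(0.01, 2, W)
        pdm[rng.random(W) < 0.05] = 0.0
        score, w, d = make_tracks(scores, pw, pdm)
        sweeps, audit = sweep_filter(score, w, d)
        sel, surv, merged = brute_sweep_filter(
            score.chroms, score.starts, score.ends, scores, pw, pdm)
        assert audit["selected"]["window"].tolist() == sel
        assert audit["survivors"]["window"].tolist() == surv
        assert [(s.chrom, s.start, s.end) for s in sweeps] == merged


class TestRodAndLai:
    def test_rod_orientation_and_infinity(self):
        _, w, d = make_tracks(np.ones(3), np.array([1.0, 2.0, 1.0]),
                              np.array([0.5, 1.0, 0.0]))
        rod = rod_track(w, d)
        assert rod.values[0] == 2.0
        assert math.isinf(rod.values[2])

    @pytest.mark.parametrize("intact,total,expected", [
        (2000, 2000, 100.0), (0, 2000, 0.0), (500, 2000, 25.0)])
    def test_lai_values(self, intact, total, expected):
        assert lai(intact, total) == expected

    def test_lai_invalid_inputs(self):
        with pytest.raises(ValueError):
            lai(1, 0)
        with pytest.raises(ValueError):
            lai(5, 2)
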