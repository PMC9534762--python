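import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from panpav.pav_analysis import (
    AccumulationCurve,
    classify_occupancy,
    classify_pan_genes,
    enrich_terms,
    fit_saturation_models,
    pan_core_curves,
    unique_group_genes,
)
from panpav.pav_build import PAVMatrix
from panpav.simdata import simulate_pav

from _oracles import fisher_one_sided_oracle


def make_pav(rows, accessions=None, labels=None):
    mat = pd.DataFrame(np.array(rows, dtype=bool))
    mat.index = [f"pg{i}" for i in range(mat.shape[0])]
    mat.columns = accessions or [f"a{j}" for j in range(mat.shape[1])]
    labels = labels or {a: "X" for a in mat.columns}
    return PAVMatrix(mat, labels)


class TestClassification:
    @pytest.mark.parametrize("count,n,expected", [
        (115, 116, "core"),      # 0.99 * 116 = 114.84
        (114, 116, "softcore"),
        (18, 116, "shell"),      # 18/116 = 0.1552
        (17, 116, "cloud"),      # 17/116 = 0.1466
        (2, 2, "core"),
        (105, 116, "softcore"),  # 0.90 * 116 = 104.4
        (104, 116, "shell"),
    ])
    def test_band_boundaries(self, count, n, expected):
        assert classify_occupancy(count, n) == expected

    def test_totals_sum_to_cluster_count(self, small_config):
        pav, _ = simulate_pav(small_config)
        table, totals = classify_pan_genes(pav)
        assert totals.sum() == pav.matrix.shape[0]
        assert len(table) == pav.matrix.shape[0]

    def test_group_restricted_classification(self):
        pav = make_pav([[1, 1, 1, 0, 0]],
                       accessions=list("abcde"),
                       labels={"a": "X", "b": "X", "c": "X", "d": "Y", "e": "Y"})
        table, _ = classify_pan_genes(pav, group="X")
        assert table["class"].iloc[0] == "core"

    def test_zero_presence_is_invariant_violation(self):
        mat = pd.DataFrame([[True], [False]], index=["pg0", "pg1"],
                           columns=["a"])
        with pytest.raises(ValueError):
            PAVMatrix(mat, {"a": "X"})


@settings(derandomize=True, max_examples=200)
@given(st.integers(min_value=2, max_value=500), st.data())
def test_class_bands_partition_occupancy_space(n, data):
    """Every occupancy count in [1, n] falls in exactly one class."""
    count = data.draw(st.integers(min_value=1, max_value=n))
    cls = classify_occupancy(count, n)
    f = count / n
    in_band = {
        "core": 100 * count >= 99 * n,
        "softcore": 90 * n <= 100 * count < 99 * n,
        "shell": 15 * n <= 100 * count < 90 * n,
        "cloud": 100 * count < 15 * n,
    }
    assert in_band[cls]
    assert sum(in_band.values()) == 1
    assert 0 < f <= 1


class TestCurves:
    def test_single_genome_pan_equals_core(self):
        pav = make_pav([[1, 0], [1, 1], [0, 1]])
        c = pan_core_curves(pav, n_perm=10, seed=0)
        assert c.pan_mean[0] == c.core_mean[0]

    def test_identical_accessions_give_constant_curves(self):
        pav = make_pav([[1, 1, 1], [1, 1, 1], [0, 0, 0], [1, 1, 1]][:2])
        c = pan_core_curves(pav, n_perm=5, seed=1)
        assert np.ptp(c.pan_mean) == 0 and np.ptp(c.core_mean) == 0

    def test_exhaustive_matches_brute_enumeration_n4(self, rng):
        mat = rng.integers(0, 2, size=(12, 4)).astype(bool)
        mat[0] = True                      # keep every accession nonempty
        pav = make_pav(mat)
        c = pan_core_curves(pav, exhaustive=True)
        # independent enumeration with python sets
        gene_sets = [set(np.flatnonzero(mat[:, j])) for j in range(4)]
        pan_tot = np.zeros(4)
        core_tot = np.zeros(4)
        n_orders = 0
        for order in itertools.permutations(range(4)):
            n_orders += 1
            for k in range(1, 5):
                u = set().union(*(gene_sets[j] for j in order[:k]))
                i = set.intersection(*(gene_sets[j] for j in order[:k]))
                pan_tot[k - 1] += len(u)
                core_tot[k - 1] += len(i)
        assert np.allclose(c.pan_mean, pan_tot / n_orders)
        assert np.allclose(c.core_mean, core_tot / n_orders)

    def test_monotone_means_on_generated_data(self, small_config):
        pav, _ = simulate_pav(small_config)
        c = pan_core_curves(pav, n_perm=20, seed=2)
        assert (np.diff(c.pan_mean) >= 0).all()
        assert (np.diff(c.core_mean) <= 0).all()


class TestSaturationFit:
    def test_heaps_exponent_recovery(self):
        n = np.arange(1, 41)
        pan = 500 * n ** 0.3 + 100
        core = 600 * np.exp(-n / 7) + 200
        c = AccumulationCurve(n, pan, 0 * n, core, 0 * n, 1)
        fit = fit_saturation_models(c)
        assert fit.pan_params[1] == pytest.approx(0.3, abs=0.02)
        assert fit.core_params[2] == pytest.approx(200, rel=0.01)
        assert fit.verdict == "open"

    def test_constant_core_flagged_degenerate(self):
        n = np.arange(1, 10)
        c = AccumulationCurve(n, 100 + 10 * np.sqrt(n), 0 * n,
                              np.full_like(n, 55.0, dtype=float), 0 * n, 1)
        fit = fit_saturation_models(c)
        assert "core_degenerate_constant" in fit.flags
        assert fit.core_params[2] == 55.0

    def test_omega_close_to_planted_strict_core(self, small_config):
        pav, truth = simulate_pav(small_config)
        planted_strict = int((truth.pav_matrix.sum(axis=1)
                              == truth.pav_matrix.shape[1]).sum())
        c = pan_core_curves(pav, n_perm=50, seed=3)
        fit = fit_saturation_models(c)
        assert fit.core_params is not None
        assert fit.core_params[2] == pytest.approx(planted_strict,
                                                   rel=0.05, abs=2)


class TestUniqueGroupGenes:
    labels = {"a": "X", "b": "X", "c": "Y", "d": "Y"}

    def test_present_in_one_group_only(self):
        pav = make_pav([[1, 1, 0, 0]], accessions=list("abcd"),
                       labels=self.labels)
        u = unique_group_genes(pav)
        assert u["X"]["unique_pan"] == ["pg0"]
        assert u["Y"]["unique_pan"] == []

    def test_shared_between_two_groups_unique_to_none(self):
        pav = make_pav([[1, 0, 1, 0]], accessions=list("abcd"),
                       labels=self.labels)
        u = unique_group_genes(pav)
        assert u["X"]["unique_pan"] == [] and u["Y"]["unique_pan"] == []

    def test_unique_core_requires_group_core_occupancy(self):
        pav = make_pav([[1, 1, 0, 0], [1, 0, 0, 0]], accessions=list("abcd"),
                       labels=self.labels)
        u = unique_group_genes(pav)
        assert u["X"]["unique_core"] == ["pg0"]

    def test_simdata_preferred_genes_recovered_exactly(self, small_config):
        pav, truth = simulate_pav(small_config)   # preferred_leak_max = 0
        u = unique_group_genes(pav)
        for g in ("G1", "G2"):
            expected = set(truth.gene_class.index[
                truth.gene_class == f"preferred_{g}"])
            # other planted classes can land in a single group by chance
            got = set(u[g]["unique_pan"])
            assert expected <= got
            leaked = {c for c in got - expected
                      if truth.gene_class[c].startswith("preferred_")}
            assert not leaked


class TestEnrichment:
    def test_extreme_overlap_probability(self):
        genes = [f"g{i}" for i in range(20)]
        fg = set(genes[:10])
        tm = {g: (["T1"] if g in fg else []) for g in genes}
        df = enrich_terms(fg, set(genes), tm)
        assert df.loc[df.term == "T1", "p"].iloc[0] == pytest.approx(
            1 / 184756, rel=1e-9)   # 1 / C(20, 10)

    def test_overlap_at_independence_not_significant(self, rng):
        genes = [f"g{i}" for i in range(100)]
        fg = set(genes[:50])
        term_members = genes[25:75]   # overlap 25 = expectation
        tm = {g: (["T"] if g in term_members else []) for g in genes}
        df = enrich_terms(fg, set(genes), tm)
        assert df.loc[df.term == "T", "p"].iloc[0] >= 0.5

    @staticmethod
    def bh_by_hand(ps):
        """q_(i) = min over j >= i of p_(j) * m / j, clipped at 1."""
        m = len(ps)
        order = np.argsort(ps)
        q = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            idx = order[rank - 1]
            running = min(running, ps[idx] * m / rank)
            q[idx] = running
        return q

    def test_bh_adjustment_example(self):
        # p = (0.01, 0.02, 0.03, 0.04), m = 4 -> every q = 0.04
        assert np.allclose(self.bh_by_hand([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_q_values_follow_bh_formula(self, rng):
        genes = [f"g{i}" for i in range(40)]
        fg = set(rng.choice(genes, size=15, replace=False))
        tm = {g: [] for g in genes}
        for t in range(6):
            for g in rng.choice(genes, size=int(rng.integers(4, 20)),
                                replace=False):
                tm[g].append(f"T{t}")
        df = enrich_terms(fg, set(genes), tm)
        assert np.allclose(df["q"], self.bh_by_hand(df["p"].to_numpy()))

    def test_matches_exact_enumeration_on_small_tables(self, rng):
        genes = [f"g{i}" for i in range(25)]
        bg = set(genes)
        fg = set(rng.choice(genes, size=10, replace=False))
        tm = {g: [] for g in genes}
        for t in range(5):
            for g in rng.choice(genes, size=int(rng.integers(3, 15)),
                                replace=False):
                tm[g].append(f"T{t}")
        df = enrich_terms(fg, bg, tm)
        for _, row in df.iterrows():
            exact = fisher_one_sided_oracle(int(row.overlap), 25,
                                            int(row.term_size), 10)
            assert row.p == pytest.approx(exact, abs=1e-10)

    def test_foreground_must_be_subset(self):
        with pytest.raises(ValueError):
            enrich_terms({"a"}, {"b"}, {"a": ["T"], "b": ["T"]})
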