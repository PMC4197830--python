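import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from popdiffscan import popdiff
from popdiffscan.popdiff import (cv_daf, daf, delta_daf, fst_from_counts,
                                 ld_r2, rank_pvalues)
from popdiffscan.genodata import PopulationPanel

from conftest import make_gts


def _panel(n_samples, pops):
    """pops: list of (code, continent, n_samples_in_pop)."""
    d = {}
    i = 0
    for code, cont, k in pops:
        for _ in range(k):
            d[f"s{i}"] = (code, cont)
            i += 1
    assert i == n_samples
    return PopulationPanel(d)


class TestDaf:
    def test_single_pop_quarter(self):
        H = np.array([[1, 0, 0, 0]], dtype=np.int8)
        gts = make_gts(H)
        panel = _panel(2, [("P1", "C1", 2)])
        ft = daf(gts, panel)
        assert ft.daf.loc[0, "P1"] == pytest.approx(0.25)
        assert ft.pooled.iloc[0] == pytest.approx(0.25)

    def test_all_ancestral_site_is_zero_everywhere(self):
        H = np.zeros((1, 8), dtype=np.int8)
        gts = make_gts(H)
        panel = _panel(4, [("P1", "C1", 2), ("P2", "C1", 2)])
        ft = daf(gts, panel)
        assert (ft.daf.iloc[0] == 0).all()

    def test_three_pops_hand_counts(self):
        # 8 haplotypes per pop; 6, 2, 1 derived
        row = [1] * 6 + [0] * 2 + [1] * 2 + [0] * 6 + [1] + [0] * 7
        gts = make_gts(np.array([row], dtype=np.int8))
        panel = _panel(12, [("A", "C1", 4), ("B", "C1", 4), ("C", "C2", 4)])
        ft = daf(gts, panel)
        assert ft.daf.loc[0, "A"] == pytest.approx(0.75)
        assert ft.daf.loc[0, "B"] == pytest.approx(0.25)
        assert ft.daf.loc[0, "C"] == pytest.approx(0.125)
        # pooled = total derived / total observed
        assert ft.pooled.iloc[0] == pytest.approx(9 / 24)

    def test_missing_alleles_reduce_denominator(self):
        H = np.array([[1, -1, 0, -1]], dtype=np.int8)
        gts = make_gts(H)
        ft = daf(gts, _panel(2, [("P", "C", 2)]))
        assert ft.daf.loc[0, "P"] == pytest.approx(0.5)

    def test_empty_group_is_missing(self):
        H = np.array([[1, -1, -1, -1]], dtype=np.int8)
        gts = make_gts(H)
        panel = _panel(2, [("P", "C", 1), ("Q", "C", 1)])
        ft = daf(gts, panel)
        assert np.isnan(ft.daf.loc[0, "Q"])


class TestDeltaDaf:
    def test_high_differentiation_site(self):
        """The ΔDAF of a strongly differentiated variant: frequencies
        0.96 vs 0.13 give 0.83 assigned to the high-DAF group."""
        ft = _freq_table({"ASN": [0.96], "AFR": [0.13]})
        dd = delta_daf(ft, ("ASN", "AFR"))
        assert dd.loc[0, "value"] == pytest.approx(0.83)
        assert dd.loc[0, "direction"] == "ASN"

    def test_equal_dafs_give_zero(self):
        ft = _freq_table({"A": [0.4], "B": [0.4]})
        dd = delta_daf(ft, ("A", "B"))
        assert dd.loc[0, "value"] == 0.0
        assert dd.loc[0, "direction"] == ""

    def test_extreme_difference_signed(self):
        ft = _freq_table({"A": [0.0], "B": [1.0]})
        dd = delta_daf(ft, ("A", "B"))
        assert dd.loc[0, "value"] == pytest.approx(-1.0)
        assert dd.loc[0, "score"] == pytest.approx(1.0)
        assert dd.loc[0, "direction"] == "B"

    def test_missing_group_daf_skips_site(self):
        ft = _freq_table({"A": [0.5, np.nan], "B": [0.2, 0.3]})
        dd = delta_daf(ft, ("A", "B"))
        assert len(dd) == 1
        assert dd.attrs["skipped"] == 1


def _freq_table(dafs: dict) -> popdiff.FrequencyTable:
    n = len(next(iter(dafs.values())))
    sites = pd.DataFrame({"chrom": ["1"] * n,
                          "pos": np.arange(1, n + 1) * 100,
                          "ref": ["A"] * n, "alt": ["T"] * n,
                          "vclass": ["SNP"] * n, "impq": [None] * n})
    df = pd.DataFrame(dafs)
    tot = pd.DataFrame({g: [100] * n for g in dafs})
    der = (df * 100).fillna(0).astype(int)
    return popdiff.FrequencyTable(sites=sites, daf=df, derived=der,
                                  total=tot, pooled=df.mean(axis=1),
                                  level="population")


class TestCvDaf:
    def test_identical_dafs_have_zero_cv(self):
        ft = _freq_table({f"P{i}": [0.5] for i in range(10)})
        assert cv_daf(ft).loc[0, "cv"] == pytest.approx(0.0)

    def test_hand_computed_cv(self):
        ft = _freq_table({"A": [0.4], "B": [0.5], "C": [0.6]})
        assert cv_daf(ft).loc[0, "cv"] == pytest.approx(0.2)

    def test_hand_computed_cv_sample_sd(self):
        ft = _freq_table({"A": [0.5], "B": [0.5], "C": [0.45]})
        sd = np.std([0.5, 0.5, 0.45], ddof=1)
        expected = sd / np.mean([0.5, 0.5, 0.45])
        assert expected == pytest.approx(0.0598, abs=2e-4)
        assert cv_daf(ft).loc[0, "cv"] == pytest.approx(expected)

    def test_zero_mean_is_skipped(self):
        ft = _freq_table({"A": [0.0], "B": [0.0]})
        assert np.isnan(cv_daf(ft).loc[0, "cv"])

    @given(st.floats(0.01, 1.0),
           st.lists(st.floats(0.01, 1.0), min_size=3, max_size=10))
    @settings(max_examples=50, deadline=None)
    def test_scale_free(self, c, dafs):
        """Multiplying all group DAFs by c leaves cvDAF unchanged."""
        ft1 = _freq_table({f"P{i}": [v] for i, v in enumerate(dafs)})
        ft2 = _freq_table({f"P{i}": [v * c] for i, v in enumerate(dafs)})
        a = cv_daf(ft1).loc[0, "cv"]
        b = cv_daf(ft2).loc[0, "cv"]
        assert a == pytest.approx(b, rel=1e-9)


def _wc_oracle(d1, n1, d2, n2):
    """Independently coded textbook Weir & Cockerham (1984) a/(a+b)
    variance-components estimator for two haploid samples."""
    p1, p2 = d1 / n1, d2 / n2
    r = 2
    nbar = (n1 + n2) / r
    nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2)
                       / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2)
    if a + b == 0:
        return np.nan
    return a / (a + b)


class TestWeirCockerhamFst:
    def test_identical_counts_nonpositive(self):
        f = fst_from_counts([5], [20], [5], [20])
        assert f[0] <= 0

    def test_fixed_difference_is_one(self):
        f = fst_from_counts([10], [10], [0], [10])
        assert f[0] == pytest.approx(1.0)

    def test_hand_counts_vs_oracle(self):
        f = fst_from_counts([14], [20], [4], [20])
        assert f[0] == pytest.approx(_wc_oracle(14, 20, 4, 20), abs=1e-12)

    def test_monomorphic_in_both_is_missing(self):
        f = fst_from_counts([0], [20], [0], [20])
        assert np.isnan(f[0])

    def test_matches_oracle_on_random_tables(self):
        rng = np.random.default_rng(1234)
        for _ in range(100):
            n1, n2 = rng.integers(4, 60, size=2)
            d1 = rng.integers(0, n1 + 1)
            d2 = rng.integers(0, n2 + 1)
            got = fst_from_counts([d1], [n1], [d2], [n2])[0]
            exp = _wc_oracle(d1, n1, d2, n2)
            if np.isnan(exp):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(exp, abs=1e-12)


class TestRankPvalues:
    def _scores(self, values):
        return pd.DataFrame({"chrom": "1",
                             "pos": np.arange(1, len(values) + 1) * 10,
                             "score": values})

    def test_max_of_hundred_gets_p_001(self):
        df = rank_pvalues(self._scores(np.linspace(0, 0.99, 100)))
        assert df.loc[df["score"].idxmax(), "rank_p"] == pytest.approx(0.01)

    def test_ascending_order_ranks_minimum_first(self):
        df = rank_pvalues(self._scores([0.5, 0.1, 0.9]), order="ascending")
        assert df.loc[1, "rank"] == 1

    def test_positional_tie_break(self):
        df = rank_pvalues(self._scores([0.9, 0.9, 0.1]))
        assert list(df["rank_p"]) == pytest.approx([1 / 3, 2 / 3, 1.0])

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            rank_pvalues(self._scores([]))

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1,
                    max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_bijection_onto_k_over_n(self, values):
        df = rank_pvalues(self._scores(values))
        n = len(values)
        assert sorted(df["rank"]) == list(range(1, n + 1))
        assert sorted(df["rank_p"]) == pytest.approx(
            [k / n for k in range(1, n + 1)])


class TestLd:
    def test_perfect_ld(self):
        H = np.array([[1, 1, 0, 0], [1, 1, 0, 0]], dtype=np.int8)
        r2, dp = ld_r2(make_gts(H), 0, 1)
        assert r2 == pytest.approx(1.0)
        assert dp == pytest.approx(1.0)

    def test_hand_counts(self):
        # haplotype counts AB=4, Ab=1, aB=1, ab=4 → r² = 0.36
        a = [1] * 4 + [1] + [0] + [0] * 4
        b = [1] * 4 + [0] + [1] + [0] * 4
        H = np.array([a, b], dtype=np.int8)
        r2, _ = ld_r2(make_gts(H), 0, 1)
        assert r2 == pytest.approx(0.36)

    def test_monomorphic_site_is_undefined(self):
        H = np.array([[0, 0, 0, 0], [1, 0, 1, 0]], dtype=np.int8)
        r2, dp = ld_r2(make_gts(H), 0, 1)
        assert np.isnan(r2)

    def test_independent_sites_in_large_panel(self):
        rng = np.random.default_rng(9)
        H = rng.integers(0, 2, size=(2, 2000)).astype(np.int8)
        r2, _ = ld_r2(make_gts(H, samples=[f"x{i}" for i in range(1000)]),
                      0, 1)
        assert r2 < 0.01
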