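import numpy as np
import pytest
from scipy.stats import hypergeom

from popdiffscan import sweepclass as sw

from conftest import make_gts


def _carrier_gts(strings, counts, focal_first=True):
    """Build genotypes whose focal-derived carriers show the given
    window haplotypes (plus non-carriers of ancestral background)."""
    n_sites = len(strings[0])
    cols = []
    for s, c in zip(strings, counts):
        for _ in range(c):
            cols.append([1] + [int(x) for x in s])
    # two non-carrier haplotypes, one carrying flanking derived alleles
    cols.append([0] + [0] * n_sites)
    cols.append([0] + [1] * n_sites)
    H = np.array(cols, dtype=np.int8).T
    if H.shape[1] % 2:
        H = np.concatenate([H, np.zeros((H.shape[0], 1), np.int8)], axis=1)
    positions = [1000] + [1000 + 10 * (i + 1) for i in range(n_sites)]
    return make_gts(H, positions=positions,
                    samples=[f"x{i}" for i in range(H.shape[1] // 2)])


class TestExtractHaplotypes:
    def test_identical_carriers_single_haplotype(self):
        gts = _carrier_gts(["0101"], [10])
        hs = sw.extract_haplotypes(gts, 0)
        assert hs.n_distinct == 1
        assert hs.freqs[0] == pytest.approx(1.0)
        assert hs.n_carriers == 10

    def test_aggregation_and_major(self):
        gts = _carrier_gts(["0101", "0111"], [4, 2])
        hs = sw.extract_haplotypes(gts, 0)
        assert hs.n_distinct == 2
        assert sorted(hs.freqs) == pytest.approx([1 / 3, 2 / 3])
        assert hs.major == "0101"

    def test_major_tie_broken_lexicographically(self):
        gts = _carrier_gts(["0111", "0101"], [3, 3])
        hs = sw.extract_haplotypes(gts, 0)
        assert hs.major == "0101"

    def test_no_carriers_is_an_error(self):
        H = np.zeros((2, 4), dtype=np.int8)
        H[1, 0] = 1
        gts = make_gts(H)
        with pytest.raises(ValueError, match="carrier"):
            sw.extract_haplotypes(gts, 0)

    def test_no_flanking_sites_is_degenerate(self):
        H = np.array([[1, 1, 0, 0]], dtype=np.int8)
        gts = make_gts(H)
        hs = sw.extract_haplotypes(gts, 0)
        assert hs.degenerate
        assert sw.weighted_levenshtein(hs) == 0.0

    def test_window_respects_span(self):
        # flanking site beyond ±1 kb is excluded
        H = np.array([[1, 1], [1, 0], [1, 0]], dtype=np.int8)
        gts = make_gts(H, positions=[5000, 5400, 6500])
        hs = sw.extract_haplotypes(gts, 0, window_bp=2000)
        assert list(hs.site_positions) == [5400]


def _dp_levenshtein(a, b):
    """Brute-force dynamic-programming edit distance (test oracle)."""
    m, n = len(a), len(b)
    D = np.zeros((m + 1, n + 1), dtype=int)
    D[:, 0] = np.arange(m + 1)
    D[0, :] = np.arange(n + 1)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            D[i, j] = min(D[i - 1, j] + 1, D[i, j - 1] + 1,
                          D[i - 1, j - 1] + (a[i - 1] != b[j - 1]))
    return D[m, n]


class TestWeightedLevenshtein:
    def test_single_haplotype_is_zero(self):
        hs = sw.HaplotypeSet(0, 2000, np.arange(4), ["0101"],
                             np.array([7]), 7)
        assert sw.weighted_levenshtein(hs) == 0.0

    def test_two_haplotypes_even_split(self):
        """50/50 split differing at 1 of 10 sites: the per-site variant
        gives 0.5 × 1/10 = 0.05; the default (unnormalized) scale gives
        0.5 × 1 = 0.5."""
        hs = sw.HaplotypeSet(0, 2000, np.arange(10),
                             ["0000000000", "0000000001"],
                             np.array([5, 5]), 10)
        assert sw.weighted_levenshtein(hs, per_site=True) == \
            pytest.approx(0.05)
        assert sw.weighted_levenshtein(hs) == pytest.approx(0.5)

    def test_three_haplotypes_hand_weighting(self):
        """f = (0.6, 0.3, 0.1), distances from major (0, 2, 5) over 20
        sites: per-site D = (0.3·2 + 0.1·5)/20 = 0.055."""
        major = "0" * 20
        h2 = "1" * 2 + "0" * 18          # distance 2
        h3 = "1" * 5 + "0" * 15          # distance 5
        hs = sw.HaplotypeSet(0, 2000, np.arange(20), [major, h2, h3],
                             np.array([6, 3, 1]), 10)
        assert sw.weighted_levenshtein(hs, per_site=True) == \
            pytest.approx(0.055)
        assert sw.weighted_levenshtein(hs) == pytest.approx(1.1)

    def test_renormalized_alternative_weighting(self):
        hs = sw.HaplotypeSet(0, 2000, np.arange(10),
                             ["0000000000", "1000000000"],
                             np.array([9, 1]), 10)
        assert sw.weighted_levenshtein(hs, renormalize_alternatives=True) \
            == pytest.approx(1.0)
        assert sw.weighted_levenshtein(hs) == pytest.approx(0.1)

    def test_matches_dp_oracle_on_random_sets(self):
        rng = np.random.default_rng(77)
        for _ in range(200):
            n_sites = int(rng.integers(1, 9))
            n_haps = int(rng.integers(2, 7))
            strings = sorted({
                "".join(rng.choice(["0", "1"], n_sites))
                for _ in range(n_haps)})
            counts = rng.integers(1, 10, size=len(strings))
            hs = sw.HaplotypeSet(0, 2000, np.arange(n_sites), strings,
                                 counts, int(counts.sum()))
            major = hs.major
            f = counts / counts.sum()
            expected = sum(fi * _dp_levenshtein(major, h)
                           for fi, h in zip(f, strings))
            assert sw.weighted_levenshtein(hs) == \
                pytest.approx(expected, abs=1e-12)

    def test_invariant_to_allele_relabeling(self):
        """Flipping 0↔1 consistently at a column leaves D unchanged."""
        rng = np.random.default_rng(5)
        gts = _carrier_gts(["01011", "01111", "00011"], [5, 3, 2])
        base = sw.weighted_levenshtein(sw.extract_haplotypes(gts, 0))
        H2 = gts.H.copy()
        for col_site in (1, 3):
            H2[col_site] = 1 - H2[col_site]
        gts2 = make_gts(H2, positions=[v.pos for v in gts.variants],
                        samples=gts.samples)
        flipped = sw.weighted_levenshtein(sw.extract_haplotypes(gts2, 0))
        assert flipped == pytest.approx(base, abs=1e-12)


class TestClassify:
    def test_hard_sweep_exemplar(self):
        call = sw.classify_sweep(0.001, 0.01)
        assert call.classification == "hard-like"

    def test_standing_variation_exemplar(self):
        call = sw.classify_sweep(0.183, 0.01)
        assert call.classification == "not-hard-like"

    def test_boundaries_inclusive(self):
        assert sw.classify_sweep(0.026, 0.025).classification == "hard-like"
        assert sw.classify_sweep(0.0261, 0.025).classification == \
            "not-hard-like"
        assert sw.classify_sweep(0.02, 0.0251).classification == \
            "not-hard-like"

    def test_missing_rate_unclassifiable(self):
        assert sw.classify_sweep(0.01, None).classification == \
            "unclassifiable"


class TestExcessHardFraction:
    def _calls(self, n_hard, n_not):
        return ([sw.SweepCall(0.0, 1, 0.01, "hard-like")] * n_hard
                + [sw.SweepCall(0.5, 5, 0.01, "not-hard-like")] * n_not)

    def test_observed_minus_chance(self):
        """66% hard-like among targets vs 36% among controls → the
        chance-corrected excess is 30%."""
        obs, chance, excess, p = sw.excess_hard_fraction(
            self._calls(66, 34), self._calls(36, 64))
        assert obs == pytest.approx(0.66)
        assert chance == pytest.approx(0.36)
        assert excess == pytest.approx(0.30)
        assert p < 0.05

    def test_identical_distributions(self):
        obs, chance, excess, p = sw.excess_hard_fraction(
            self._calls(5, 5), self._calls(5, 5))
        assert excess == 0
        assert p == pytest.approx(1.0)

    def test_fisher_matches_hypergeometric_enumeration(self):
        """2×2 (8,2 / 2,8): two-sided Fisher P by brute-force
        enumeration of the hypergeometric tail probabilities."""
        _, _, _, p = sw.excess_hard_fraction(self._calls(8, 2),
                                             self._calls(2, 8))
        M, n, N = 20, 10, 10  # total, hard-like total, target total
        p0 = hypergeom.pmf(8, M, n, N)
        exact = sum(hypergeom.pmf(k, M, n, N)
                    for k in range(0, 11)
                    if hypergeom.pmf(k, M, n, N) <= p0 + 1e-12)
        assert p == pytest.approx(exact, rel=1e-9)

    def test_empty_sets_error(self):
        with pytest.raises(ValueError):
            sw.excess_hard_fraction([], self._calls(1, 1))


class TestCallSite:
    def test_end_to_end_call_uses_local_rate(self):
        from popdiffscan.genodata import GeneticMap
        gts = _carrier_gts(["0101"], [10])
        gm = GeneticMap.uniform(0.01, 10_000)
        call = sw.call_site(gts, 0, gm)
        assert call.classification == "hard-like"
        gm_hot = GeneticMap.uniform(1.0, 10_000)
        call = sw.call_site(gts, 0, gm_hot)
        assert call.classification == "not-hard-like"
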