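import numpy as np
import pytest
from scipy import stats

import popdiffscan as pds
from popdiffscan import popdiff
from popdiffscan.simgen import (DemographicModel, SweepScenario,
                                simulate_neutral, simulate_single_population,
                                simulate_sweep, tune_sweep_trajectory,
                                expected_neutral_highd, migration_sensitivity)

SMALL = DemographicModel(n_afr=4000, n_ooa=2500, n_eur=2500, n_asn=2500,
                         n_founder_ooa=400, n_founder_split=400,
                         t_ooa=1750, t_split=1000, t_subdivide=100)


class TestNeutral:
    def test_watterson_theta(self):
        """Mean segregating-site count of a constant-size population
        matches the Watterson expectation θL·a_{n-1} within 15%."""
        S = [simulate_single_population(
            2000, region_bp=20_000, n_sample=50, seed=s,
            recombination_rate=1e-8, forward_generations=40)[0].shape[0]
            for s in range(200)]
        theta_l = 4 * 2000 * 1.5e-8 * 20_000
        a = sum(1 / i for i in range(1, 100))
        assert np.mean(S) == pytest.approx(theta_l * a, rel=0.15)

    def test_same_seed_is_bit_identical(self):
        a = simulate_neutral(SMALL, region_bp=20_000, n_per_pop=10, seed=5)
        b = simulate_neutral(SMALL, region_bp=20_000, n_per_pop=10, seed=5)
        np.testing.assert_array_equal(a.gts.H, b.gts.H)
        assert [v.key for v in a.gts.variants] == \
            [v.key for v in b.gts.variants]

    def test_zero_mutation_rate_gives_no_sites(self):
        m = DemographicModel(mutation_rate=0.0, **{
            k: getattr(SMALL, k) for k in
            ("n_afr", "n_ooa", "n_eur", "n_asn", "n_founder_ooa",
             "n_founder_split", "t_ooa", "t_split", "t_subdivide")})
        rep = simulate_neutral(m, region_bp=20_000, n_per_pop=10, seed=1)
        assert rep.gts.n_sites == 0

    def test_invalid_model_is_fatal_with_field_name(self):
        with pytest.raises(ValueError, match="mutation_rate"):
            DemographicModel(mutation_rate=-1)
        with pytest.raises(ValueError, match="t_ooa"):
            DemographicModel(t_ooa=100, t_split=2000)

    def test_region_too_small_is_fatal(self):
        with pytest.raises(ValueError, match="10 kb"):
            simulate_neutral(SMALL, region_bp=5_000, n_per_pop=5, seed=1)

    def test_panel_and_matrix_are_consistent(self, small_neutral_replicates):
        for rep in small_neutral_replicates:
            assert rep.gts.n_haplotypes == 2 * len(rep.panel)
            assert rep.panel.continents() == ["AFR", "ASN", "EUR"]
            pos = rep.gts.positions
            assert np.all(np.diff(pos) > 0)      # sorted, unique
            assert not rep.gts.monomorphic_mask().any()

    def test_continental_fst_in_human_like_range(
            self, small_neutral_replicates):
        """Mean per-site W&C F_ST between sampled continents falls in
        the range characteristic of the AFR/EUR/ASN system (~0.1)."""
        vals = []
        for rep in small_neutral_replicates:
            f = popdiff.daf(rep.gts, rep.panel, "continent")
            common = f.pooled.to_numpy() > 0.05
            for a, b in (("AFR", "EUR"), ("EUR", "ASN"), ("AFR", "ASN")):
                fst = popdiff.fst_from_counts(
                    f.derived[a], f.total[a], f.derived[b], f.total[b])
                vals.append(np.nanmean(fst[common]))
        assert 0.05 < np.mean(vals) < 0.25

    def test_subdivided_panel_has_ten_populations(self):
        rep = simulate_neutral(SMALL, region_bp=20_000, n_per_pop=5,
                               seed=9, subdivide=True)
        assert len(rep.panel.populations()) == 10
        assert {rep.panel.continent_of_population(p)
                for p in rep.panel.populations()} == {"AFR", "EUR", "ASN"}

    def test_folded_sfs_matches_neutral_expectation(self):
        """Pooled folded SFS of a constant-size population is
        consistent with ξ_i ∝ 1/i + 1/(n−i) (χ², α=0.01)."""
        n = 40
        counts = np.zeros(n // 2)
        for s in range(500):
            H, _ = simulate_single_population(
                1500, region_bp=5_000, n_sample=n // 2, seed=10_000 + s,
                recombination_rate=1e-7, forward_generations=10)
            if H.shape[0] == 0:
                continue
            d = H.sum(axis=1)
            folded = np.minimum(d, n - d)
            for f in folded:
                counts[min(int(f), n // 2) - 1] += 1
        expect = np.array([1 / i + 1 / (n - i) for i in range(1, n // 2)]
                          + [1 / (n // 2)])
        # 10 aggregated frequency bins
        edges = np.linspace(0, n // 2, 11).astype(int)
        obs_b = np.array([counts[a:b].sum()
                          for a, b in zip(edges[:-1], edges[1:])])
        exp_b = np.array([expect[a:b].sum()
                          for a, b in zip(edges[:-1], edges[1:])])
        exp_b = exp_b / exp_b.sum() * obs_b.sum()
        chi2 = ((obs_b - exp_b) ** 2 / exp_b).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=len(obs_b) - 1)


class TestSweep:
    def test_complete_sweep_fixes_selected_population(self):
        sc = SweepScenario(target_af=1.0, duration=400, population="AFR")
        rep = simulate_sweep(SMALL, sc, region_bp=20_000, n_per_pop=20,
                             seed=31)
        assert rep.end_freq >= 0.95
        assert rep.realized["AFR"] > 0.8

    def test_partial_target_honoured_over_seeds(self, benchmark_batch):
        """Rejection control keeps the end-of-sweep frequency within
        ±0.05 of the 0.6 target on every replicate."""
        sw = benchmark_batch.sweeps
        rows = sw[sw["target_af"] == 0.6]
        assert len(rows) >= 50
        assert ((rows["end_freq"] >= 0.55) & (rows["end_freq"] <= 0.65)).all()

    def test_selection_raises_focal_differentiation(self, benchmark_batch):
        """The selected variant's |ΔDAF| exceeds the replicate-internal
        neutral expectation for complete sweeps."""
        sw = benchmark_batch.sweeps
        hard = sw[(sw["target_af"] == 1.0) & ~sw["focal_lost"]]
        assert hard["ddaf"].mean() > 0.7

    def test_tuning_failure_reports_s_range(self):
        rng = np.random.default_rng(0)
        sizes = [200, 200, 200]
        M = np.full((3, 3), 1e-4)
        np.fill_diagonal(M, 1 - 2e-4)
        sc = SweepScenario(target_af=0.9, duration=200)
        with pytest.raises(RuntimeError, match="attempted s"):
            tune_sweep_trajectory(sizes, M, 0, sc, rescale=10.0, rng=rng,
                                  max_rounds=1, tries_per_round=1)

    def test_sweep_with_subdivision_unsupported(self):
        sc = SweepScenario(target_af=0.8, duration=400)
        with pytest.raises(ValueError, match="three-continent"):
            pds.simgen._run_simulation(SMALL, 20_000, 5, 1, subdivide=True,
                                       scenario=sc)


class TestRescaling:
    def test_rescaling_invariance_of_differentiation(self):
        """λ=5 and λ=10 give statistically indistinguishable
        distributions of the per-replicate maximum AFR-EUR |ΔDAF|
        (KS test, α=0.01)."""
        import dataclasses
        res = {}
        for lam in (5.0, 10.0):
            m = dataclasses.replace(SMALL, rescale=lam)
            vals = []
            for s in range(120):
                rep = simulate_neutral(m, region_bp=20_000, n_per_pop=15,
                                       seed=40_000 + s)
                f = popdiff.daf(rep.gts, rep.panel, "continent")
                d = np.abs((f.daf["AFR"] - f.daf["EUR"]).to_numpy())
                vals.append(d.max() if d.size else 0.0)
            res[lam] = np.asarray(vals)
        p = stats.ks_2samp(res[5.0], res[10.0]).pvalue
        assert p > 0.01


class TestNeutralExpectation:
    def test_scaled_count_arithmetic_and_migration_direction(self):
        cfg = pds.ScanConfig(thresh_between=0.35, top_percentile=5.0)
        df = migration_sensitivity(SMALL, [0.0, 1e-3], n_replicates=12,
                                   region_bp=20_000, scan_cfg=cfg,
                                   n_per_pop=15, seed=77)
        lo = df.loc[df["m_rate"] == 0.0, "scaled_count"].iloc[0]
        hi = df.loc[df["m_rate"] == 1e-3, "scaled_count"].iloc[0]
        # stronger migration homogenizes frequencies
        assert lo >= hi
        res = expected_neutral_highd(SMALL.with_migration(0.0), 12,
                                     20_000, cfg, n_per_pop=15, seed=77)
        total = sum(res["replicate_counts"])
        assert res["scaled_count"] == pytest.approx(
            total * res["accessible_bp"] / res["simulated_bp"])
        assert res["ci_low"] <= res["scaled_count"] + 1e-9
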